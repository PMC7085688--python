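# Methods

## Problem setting

Expression-profile classification — bulk or single-cell transcript counts
after upstream preprocessing — typically presents many thousands of
correlated features measured on at most a few hundred samples, split over
several diagnostic classes ("large p, small n", collinear, multi-class).
The package implements a one-vs-all (OVA) classifier, EPSVM, whose defining
property is *class-specific* feature selection: each binary subproblem
(class i against the rest) gets its own feature subset, proposed by the
elastic-net regularization path and chosen by cross-validation, instead of
one global subset shared by all classes.  The m calibrated binary machines
are fused by taking the class with the largest posterior probability.

## Model components

### Binary classifier

Each subproblem is a soft-margin kernel SVM with decision value
f(x) = Σᵢ yᵢaᵢK(xᵢ, x) + b, solved exactly in the dual by libsvm (via
scikit-learn).  The Gaussian kernel K(u, v) = exp(−g‖u − v‖²) is the
default; cost c and width g come from a grid of integer powers of two,
c ∈ 2^(−10..10), g ∈ 2^(−15..15).

### Probability calibration

Raw decision values of machines trained on *different* feature subsets are
not comparable, so each machine is calibrated with a Platt sigmoid
P(y=+1|x) = 1/(1 + exp(A·f(x) + B)).  (A, B) minimize the negative
log-likelihood with the regularized targets t⁺ = (N₊+1)/(N₊+2),
t⁻ = 1/(N₋+2), which keep the optimum finite on separated data.  The fit
is a damped Newton iteration with backtracking line search; the decision
values are standardized internally (and A, B mapped back) so the Newton
system stays well-conditioned even when an underfit configuration produces
near-constant decision values.  Non-convergence raises an error carrying
the last iterate; the model-fitting wrapper falls back to that iterate
with a warning, since any sigmoid is a strictly monotone (hence usable)
calibration.  By default the sigmoid is fitted on out-of-fold decision
values from an internal stratified 3-fold split of the training set;
in-sample calibration is available as a flag.

### Candidate subsets from the elastic-net path

For each subproblem the class label (coded ±1) is regressed on the
(z-scored) features under

    min_b ‖y − Xb‖² + λ [ α|b|₁ + (1 − α)‖b‖² ],

solved by cyclic coordinate descent (scikit-learn's `enet_path` under an
exact reparameterization of this objective) on 50 log-spaced λ values from
λ_max (the smallest λ with an all-zero solution, 2·maxⱼ|⟨xⱼ, y⟩|/α) down
to 0.01·λ_max.  The mixing weight α = 0.5 by default; the L1 part zeroes
coefficients and the L2 part lets groups of correlated features enter
together, which is the property that matters for collinear expression
blocks.  The distinct nonzero supports along the path, deduplicated and
ordered by decreasing λ, are the candidate class-specific subsets.  The
LASSO (α=1) and ridge (α=0) limits are reachable only through an explicit
override flag; ridge requires an explicit λ grid since it has no finite
all-zero threshold.

### Subset and hyperparameter selection

Every candidate subset is scored by stratified 5-fold cross-validation of
a calibrated SVM: the score is the out-of-fold binary NER ((SE+SP)/2,
robust to the ~1:(m−1) OVA imbalance), computed from the 0.5-probability
threshold.  Inside this loop the sigmoid is fitted in-sample — calibration
is monotone, so only the induced threshold matters for the binary NER —
which keeps the search at one SVM fit per fold.  Fold assignment is shared
across candidates so comparisons are paired.

On well-separated data many (subset, c, g) combinations tie at NER 1.0, so
ties are resolved in two stages.  Per candidate, the best (c, g) is the
one minimizing the out-of-fold log-loss of the calibrated probabilities (a
continuous proper score that separates robust configurations from
degenerate corners such as a near-zero kernel width).  Across NER-tied
candidates, the subset is chosen by a one-standard-error parsimony rule on
that same log-loss — the smallest subset whose loss is within one
fold-to-fold standard error of the best — the same compromise glmnet's
`lambda.1se` makes between fit and parsimony on a flat loss plateau.
Remaining ties go to smaller c, then smaller g.

Two search modes exist: `joint` grid-searches (c, g) separately for every
candidate; `fast` fixes (c, g) once per subproblem (chosen on the largest
candidate, where the kernel geometry is most representative) and then
scores all candidates with it.  `joint` multiplies the search cost by the
grid size; the benchmark driver and the reproduction script use `fast`.

### Fusion

Prediction evaluates all m calibrated machines on their own subsets and
returns argmax of the m posterior probabilities (ties to the smallest
class index).  The probability rows are deliberately *not* normalized to
sum to one: OVA posteriors are comparable but do not form a joint
distribution, and coupling them is out of scope.

## Baselines

The comparison arms replace the class-specific step with a single global
ranking followed by top-k selection:

- **ReliefF** (K = 5 neighbors): deterministic full pass over all training
  samples; per feature, mean range-normalized difference to the K nearest
  same-class neighbors is subtracted and, per other class, the mean
  difference to its K nearest members added with prior weight
  P(class)/(1 − P(own class)) (the Kononenko multi-class variant, chosen
  because the classic reference leaves the miss-weighting open).  Weights
  live in [−1, 1].
- **SVM-RFE**: recursive elimination driven by linear-SVM weights (cost
  fixed at 1), removing the lowest-wⱼ² feature each round; multi-class
  data uses the sum of wⱼ² over the m OVA machines.  A `chunk` option
  removes several features per round for large p (default 1).

For both, candidate subset sizes are the top 5%, 10%, …, 50% of the
ranking — inferred from the proportional selected-feature counts the
global methods exhibit in practice — and (k, c, g) is chosen by the same
paired stratified 5-fold CV on multi-class NER, ties to the smallest k,
then smallest c and g.  The final multi-class SVM uses libsvm's
one-vs-one voting, as a standard SVM implementation would.

## Evaluation protocol

For class i under OVA collapse, SEᵢ = TPᵢ/(TPᵢ+FNᵢ), SPᵢ = TNᵢ/(TNᵢ+FPᵢ),
NERᵢ = (SEᵢ+SPᵢ)/2, and the overall NER is the mean of the NERᵢ (balanced
accuracy generalized to OVA; for m = 2 it equals balanced accuracy and
NER₁ = NER₂ exactly).  A class absent from the truth labels is an error:
its NER is undefined.

The benchmark draws a stratified split (⌊⅔·n_c⌋ per class to train,
clamped to [1, n_c−1]), fits each arm on the training part, scores the
held-out part, and repeats with per-repeat seeds `base_seed + r`; the same
split serves every arm within a repeat (paired comparison, a
variance-reduction choice).  Means and standard deviations over repeats
are reported; failures in single repeats are recorded and skipped rather
than aborting the run.

## Synthetic data

The simulator generates dataset i (1 ≤ i ≤ 9) with m = i+2 classes of 30
samples and 40m features: in the 20m-wide base half, class l's block of 20
features is N(2, 1) and everything else N(0, 1); the second half repeats
the base half's *signal* draw; finally independent N(0, 2) noise is added
to every cell.  Base feature j and its repeat j + 20m therefore share the
signal but not the noise — within a class their population correlation is
1/5 — which creates the correlated-blocks structure the elastic net's
grouping property targets.  Exact duplication (sharing the noise draw too)
would make columns identical and the design degenerate; the independent-
noise reading is the one consistent with calling the data "collinear".
Samples are emitted class by class; all downstream splits are stratified,
so ordering carries no information.

What the simulator does *not* emulate: count-distribution artifacts
(overdispersion, zero inflation), library-size or batch effects, skewed
class sizes, and realistic gene-gene correlation beyond the block-pair
structure.  Passing the simulation benchmark therefore demonstrates the
selection-and-fusion machinery under known ground truth, not performance
on real RNA-seq; the text loader and ANOVA prefilter (keep features with
one-way ANOVA p ≤ 0.001; undefined F counts as filtered) are the entry
point for real matrices.

## Numerical choices

- Coordinate descent: tolerance 1e-6, max 10 000 iterations, warm starts
  along the λ path; supports deduplicated keeping the largest-λ copy;
  empty path (pathological input) falls back to the all-features subset
  with a warning.
- Platt Newton: gradient tolerance 1e-8, ≤ 200 iterations, sigmoid
  arguments clipped at ±500, Hessian damping grown adaptively from 1e-12
  until a descent step succeeds.
- Probabilities clipped to (1e-12, 1−1e-12): strictly inside (0, 1).
- libsvm iteration cap 200 000 — never binding on sane configurations at
  these sample sizes, bounds the pathological grid corners.
- p-values floored at the smallest positive double, so an ANOVA threshold
  of exactly 0 keeps nothing.
- Ties everywhere resolve toward the smaller/simpler object last (subset
  size, then c, then g, then class index), after the continuous criteria
  above.

## Problem sizes in the reproduction script

`scripts/acceptance.py` reruns the repeated-split benchmark at 10 repeats
per dataset with the (c, g) grid subsampled to every fifth power of two
and the `fast` selection mode.  These sizes are the package's default
desk-scale configuration; the selection machinery is identical under the
full grid and the `joint` search, which only enlarge the (c, g) space
being scanned.

## Known limitations

- OVA probabilities are uncalibrated *across* machines (no pairwise
  coupling); argmax fusion is exactly as specified, but row sums ≠ 1.
- The candidate path comes from a squared-error elastic net on ±1 labels,
  not a logistic elastic net; this is the design under test, not an
  approximation chosen for speed.
- ReliefF is O(n²p) per ranking; fine for hundreds of samples, not tuned
  for tens of thousands.
- With heavily imbalanced OVA subproblems no class weighting is applied;
  the NER metric absorbs imbalance at evaluation time, and imbalance
  effects are reported rather than corrected.
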