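# epsvm — class-specific feature selection for multi-class expression profiles

Classifying expression profiles (for example, tumor-educated platelet
RNA-seq used as a liquid-biopsy signal for cancer type) is a multi-class
problem with many thousands of correlated features and few samples per
class.  Conventional pipelines pick one *global* feature subset — a
ReliefF or SVM-RFE ranking truncated at a cross-validated size — and feed
it to a multi-class SVM.  `epsvm` implements the alternative this package
is named for: **class-specific** feature selection.

The m-class problem is decomposed one-vs-all (OVA).  For each binary
subproblem, the elastic net

&nbsp;&nbsp;&nbsp;&nbsp; β̂ = argmin ‖Y − Xβ‖² + λ[α|β|₁ + (1 − α)‖β‖²]

is solved along a λ path with the ±1 class label as the response; the
nonzero supports along the path are candidate feature subsets, and the one
with the best stratified 5-fold CV balanced accuracy of a Gaussian-kernel
SVM (jointly grid-searched over cost c and kernel width g) becomes that
class's subset.  Because each machine then sees different features, raw
SVM margins are not comparable across classes; each machine is therefore
Platt-calibrated,

&nbsp;&nbsp;&nbsp;&nbsp; P(y = 1 | x) = 1 / (1 + exp(A·f(x) + B)),

with (A, B) fitted by damped Newton on the regularized targets
t⁺ = (N₊+1)/(N₊+2), t⁻ = 1/(N₋+2), and prediction is
class = argmaxᵢ Pᵢ(x).  Evaluation uses the *not error rate*
NER = (1/m) Σᵢ (SEᵢ + SPᵢ)/2, a balanced-accuracy metric robust to the
1:(m−1) imbalance OVA creates.

The package also ships the two global-selection baselines (multi-class
ReliefF with K = 5 neighbors; linear SVM-RFE with OVA-summed w² and
top-k-by-CV selection), the NER/sensitivity/specificity evaluator, a
repeated-stratified-split benchmark driver, and a block-structured
collinear simulator that generates datasets with known class-specific
feature ground truth.  See `docs/methods.md` for the full model account.

## Worked example

```python
import numpy as np
from epsvm import (SimulationSpec, simulate_dataset, stratified_split,
                   fit_epsvm, predict_epsvm, compute_ner)

spec = SimulationSpec(index=1, seed=0)       # 3 classes x 30 samples, 120 features
ds = simulate_dataset(spec)
train, test = stratified_split(ds, 2/3, seed=0)

model = fit_epsvm(train, seed=0, selection_mode="fast")
for sel in model.selections:
    print(f"class {sel.positive_class}: {sel.subset_size} features, "
          f"c={sel.c:g}, g={sel.g:g}, CV NER={sel.cv_ner:.3f}")

labels, proba = predict_epsvm(model, test.X)
print(f"test NER = {compute_ner(test.y, labels, m=3).ner:.4f}")
```

Output:

```
class 1: 37 features, c=1024, g=3.05176e-05, CV NER=1.000
class 2: 48 features, c=1024, g=3.05176e-05, CV NER=1.000
class 3: 35 features, c=1024, g=3.05176e-05, CV NER=1.000
test NER = 0.9750
```

Each class got its own subset (35–48 of 120 features, concentrated in
that class's two correlated signal blocks), every subproblem reached CV
NER 1.0, and the fused classifier misses a single held-out sample (mean
per-class NER 0.975; over repeated splits the average is about 0.985).

The same pipeline runs from the shell:

```bash
epsvm simulate --index 1 --seed 7 --out-prefix data1
epsvm fit --matrix data1_matrix.csv --labels data1_labels.csv \
          --alpha 0.5 --seed 7 --fast --out model.json
epsvm predict --model model.json --matrix data1_matrix.csv --out pred.csv
epsvm benchmark --indices 1 --repeats 10 --seed 1 --out results/
```

External data enters through the same two-file format: a delimited
samples × features matrix with a header of feature ids and a sample-id
first column, plus a `sample_id,class_name` labels file.  The
`anova_prefilter` helper applies the standard one-way-ANOVA screen
(keep p ≤ 0.001) used to reduce raw expression matrices before fitting.

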