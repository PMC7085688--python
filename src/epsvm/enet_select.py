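"""Elastic-net regularization path as a candidate-subset generator.

For one binary subproblem the class label (coded +1/-1) is regressed on the
features under the penalized least-squares objective

    min_b  ||y - X b||^2 + lam * ( alpha * |b|_1 + (1 - alpha) * ||b||^2 )

with an unpenalized intercept and (by default) z-scored columns.  Solving it
on a log-spaced grid of ``lam`` from the all-zero solution downward yields a
sequence of nonzero supports of growing size; the deduplicated supports are
the candidate class-specific feature subsets the classifier later scores.

The solver is scikit-learn's cyclic coordinate descent.  Its objective

    1/(2n) ||y - X b||^2 + a * l1 * |b|_1 + a/2 * (1 - l1) * ||b||^2

matches the one above under the exact reparameterization

    l1 = alpha / (2 - alpha),        a = lam * (2 - alpha) / (2 n),

which is applied both ways so ``lambdas`` are always reported on the scale
of the objective written here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import enet_path as _sk_enet_path


class ENetError(ValueError):
    pass


@dataclass
class ENetConfig:
    """Elastic-net path controls.

    ``alpha`` is the L1/L2 mixing weight, strictly inside (0, 1) unless
    ``allow_boundary`` is set (alpha=1 gives the LASSO, alpha=0 ridge —
    ridge produces no exact zeros and requires an explicit ``lambdas``
    grid because its all-zero threshold is infinite).
    """

    alpha: float = 0.5
    n_lambda: int = 50
    lambda_min_ratio: float = 0.01
    standardize: bool = True
    max_iter: int = 10_000
    tol: float = 1e-6
    allow_boundary: bool = False
    lambdas: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.allow_boundary:
            if not 0.0 <= self.alpha <= 1.0:
                raise ENetError("alpha must lie in [0, 1]")
        elif not 0.0 < self.alpha < 1.0:
            raise ENetError(
                "alpha must lie strictly in (0, 1); pass allow_boundary=True "
                "for the LASSO (1) or ridge (0) limits"
            )
        if self.alpha == 0.0 and self.lambdas is None:
            raise ENetError("ridge limit (alpha=0) needs an explicit lambdas grid")


@dataclass
class CandidateSubsets:
    """Ordered candidate feature subsets from one regularization path.

    ``subsets[k]`` is the nonzero support at ``lambdas[k]``; lambdas are
    decreasing, so subset sizes tend to grow.  Empty supports are dropped
    and duplicate supports deduplicated keeping the largest-lambda copy.
    ``coefficients`` holds the matching coefficient vectors (p x k).
    """

    subsets: list[np.ndarray]
    lambdas: np.ndarray
    coefficients: np.ndarray | None = None
    fallback: bool = False

    def __len__(self) -> int:
        return len(self.subsets)


def _l1_ratio(alpha: float) -> float:
    return alpha / (2.0 - alpha)


def _lam_to_sklearn(lam: np.ndarray, alpha: float, n: int) -> np.ndarray:
    return np.asarray(lam, dtype=float) * (2.0 - alpha) / (2.0 * n)


def _sklearn_to_lam(a: np.ndarray, alpha: float, n: int) -> np.ndarray:
    return np.asarray(a, dtype=float) * 2.0 * n / (2.0 - alpha)


def _working_data(
    X: np.ndarray, y: np.ndarray, standardize: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Center y and center/scale X so the intercept is implicit and the
    penalty acts on a common column scale.  Constant columns are left
    centered (zero) rather than divided by a zero scale."""
    Xc = X - X.mean(axis=0)
    if standardize:
        scale = Xc.std(axis=0)
        scale[scale == 0.0] = 1.0
        Xc = Xc / scale
    return Xc, y - y.mean()


def enet_path(X: np.ndarray, y_binary: np.ndarray, cfg: ENetConfig) -> CandidateSubsets:
    """Fit the elastic net along a lambda grid and collect the supports.

    ``y_binary`` must contain both +1 and -1.  The grid runs from the
    smallest lambda with an all-zero solution down to
    ``lambda_min_ratio`` times that, log-spaced, unless ``cfg.lambdas``
    gives explicit values.  If every support on the path is empty the
    single all-features subset is returned with ``fallback=True`` and a
    warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_binary, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ENetError("X must be 2-D with one row per label")
    if not np.isfinite(X).all():
        raise ENetError("X contains non-finite values")
    if np.unique(np.sign(y)).size < 2:
        raise ENetError("y_binary must contain both classes")
    n, p = X.shape
    Xw, yw = _working_data(X, y, cfg.standardize)

    if cfg.alpha == 0.0:
        return _ridge_path(Xw, yw, cfg, p)

    l1 = _l1_ratio(cfg.alpha)
    if cfg.lambdas is not None:
        alphas = _lam_to_sklearn(np.sort(np.asarray(cfg.lambdas))[::-1], cfg.alpha, n)
    else:
        a_max = np.max(np.abs(Xw.T @ yw)) / (n * l1)
        alphas = np.geomspace(a_max, a_max * cfg.lambda_min_ratio, cfg.n_lambda)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        alphas_out, coefs, _ = _sk_enet_path(
            Xw,
            yw,
            l1_ratio=l1,
            alphas=alphas,
            max_iter=cfg.max_iter,
            tol=cfg.tol,
        )
    lambdas = _sklearn_to_lam(alphas_out, cfg.alpha, n)
    return _collect_supports(coefs, lambdas, p)


def _ridge_path(Xw: np.ndarray, yw: np.ndarray, cfg: ENetConfig, p: int) -> CandidateSubsets:
    # closed form (X'X + lam I)^-1 X'y per lambda; no sparsity, support = all
    lambdas = np.sort(np.asarray(cfg.lambdas, dtype=float))[::-1]
    G = Xw.T @ Xw
    Xty = Xw.T @ yw
    coefs = np.empty((p, lambdas.size))
    for k, lam in enumerate(lambdas):
        coefs[:, k] = np.linalg.solve(G + lam * np.eye(p), Xty)
    subsets = [np.arange(p) for _ in lambdas]
    return CandidateSubsets(subsets=subsets, lambdas=lambdas, coefficients=coefs)


def _collect_supports(
    coefs: np.ndarray, lambdas: np.ndarray, p: int
) -> CandidateSubsets:
    subsets: list[np.ndarray] = []
    kept_lams: list[float] = []
    kept_cols: list[int] = []
    seen: set[tuple[int, ...]] = set()
    for k in range(coefs.shape[1]):
        support = np.flatnonzero(coefs[:, k])
        key = tuple(support.tolist())
        if support.size == 0 or key in seen:
            continue
        seen.add(key)
        subsets.append(support)
        kept_lams.append(float(lambdas[k]))
        kept_cols.append(k)
    if not subsets:
        warnings.warn(
            "elastic-net path produced no nonzero support; "
            "falling back to the full feature set",
            stacklevel=2,
        )
        return CandidateSubsets(
            subsets=[np.arange(p)],
            lambdas=np.asarray([float(lambdas[-1])]),
            coefficients=coefs[:, -1:],
            fallback=True,
        )
    return CandidateSubsets(
        subsets=subsets,
        lambdas=np.asarray(kept_lams),
        coefficients=coefs[:, kept_cols],
    )


def subset_grouping_score(
    subsets: CandidateSubsets, known_pairs: Sequence[tuple[int, int]]
) -> float:
    """How often a selected feature's correlated partner is co-selected.

    For each subset on the path, take the selected features that belong to
    a known correlated pair and compute the fraction whose partner is also
    in the subset; average over subsets containing at least one pair
    member.  1.0 means pairs always enter together (the grouping effect),
    0.0 means partners are never co-selected.
    """
    if not known_pairs:
        raise ENetError("known_pairs must be nonempty")
    partner: dict[int, int] = {}
    for a, b in known_pairs:
        partner[int(a)] = int(b)
        partner[int(b)] = int(a)
    fractions = []
    for subset in subsets.subsets:
        chosen = set(int(j) for j in subset)
        members = [j for j in chosen if j in partner]
        if not members:
            continue
        fractions.append(
            sum(partner[j] in chosen for j in members) / len(members)
        )
    return float(np.mean(fractions)) if fractions else 0.0
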