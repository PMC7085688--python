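"""Global feature-selection baselines: ReliefF and linear SVM-RFE.

Both produce a single importance ranking over all features; a subset is then
chosen by evaluating top-k truncations of the ranking with a cross-validated
SVM.  This is the conventional "global features" pipeline that the
class-specific selection in :mod:`epsvm.epsvm` is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data import LabeledDataset
from .psvm import SVMConfig, SVMGrid, _SVC_MAX_ITER


@dataclass
class FeatureRanking:
    """Feature indices ordered most- to least-important with their scores."""

    order: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        p = self.order.size
        if sorted(self.order.tolist()) != list(range(p)):
            raise ValueError("order must be a permutation of 0..p-1")
        if self.scores.size != p:
            raise ValueError("scores must align with order")

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]


def _rank_descending(weights: np.ndarray) -> FeatureRanking:
    # stable: ties broken by ascending feature index
    order = np.argsort(-weights, kind="stable")
    return FeatureRanking(order=order, scores=weights[order])


def relieff_rank(ds: LabeledDataset, k_neighbors: int = 5) -> FeatureRanking:
    """Multi-class ReliefF feature weights, deterministic full pass.

    Every sample acts once as the pivot.  Per feature, the mean
    range-normalized difference to the ``k_neighbors`` nearest same-class
    samples (near hits) is subtracted, and for each other class the mean
    difference to its ``k_neighbors`` nearest members (near misses) is
    added with weight P(class)/(1 - P(pivot class)).  Weights land in
    [-1, 1]; ranking is by weight descending.
    """
    counts = ds.class_counts()
    if (counts <= k_neighbors).any():
        small = int(np.argmin(counts)) + 1
        raise ValueError(
            f"class {small} has only {counts[small - 1]} samples; "
            f"needs > {k_neighbors} — reduce k_neighbors"
        )
    X, y = ds.X, ds.y
    n, p = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0.0] = 1.0  # constant feature: all diffs are 0 anyway
    Xn = (X - X.min(axis=0)) / span

    dist = cdist(Xn, Xn, metric="cityblock")
    np.fill_diagonal(dist, np.inf)
    priors = counts / n
    class_rows = {cls: np.flatnonzero(y == cls) for cls in range(1, ds.n_classes + 1)}

    weights = np.zeros(p)
    for i in range(n):
        ci = y[i]
        hits_pool = class_rows[ci][class_rows[ci] != i]
        hits = hits_pool[np.argsort(dist[i, hits_pool], kind="stable")[:k_neighbors]]
        weights -= np.abs(Xn[hits] - Xn[i]).mean(axis=0) / n
        miss_norm = 1.0 - priors[ci - 1]
        for cj, rows in class_rows.items():
            if cj == ci:
                continue
            misses = rows[np.argsort(dist[i, rows], kind="stable")[:k_neighbors]]
            coef = priors[cj - 1] / miss_norm
            weights += coef * np.abs(Xn[misses] - Xn[i]).mean(axis=0) / n
    return _rank_descending(weights)


def _linear_w2(X: np.ndarray, y: np.ndarray, c: float) -> np.ndarray:
    """Sum of squared linear-SVM weights over the one-vs-all machines."""
    classes = np.unique(y)
    crit = np.zeros(X.shape[1])
    if classes.size == 2:
        pairs = [classes[:1]]
    else:
        pairs = [np.array([cls]) for cls in classes]
    for pos in pairs:
        ybin = np.where(np.isin(y, pos), 1, -1)
        svc = SVC(kernel="linear", C=c, max_iter=_SVC_MAX_ITER)
        svc.fit(X, ybin)
        crit += np.ravel(np.asarray(svc.coef_)) ** 2
    return crit


def svm_rfe_rank(
    ds: LabeledDataset, chunk: int = 1, c: float = 1.0
) -> FeatureRanking:
    """Recursive feature elimination driven by linear-SVM weights.

    At each round a linear SVM (cost ``c``) is fitted on the surviving
    features — one machine per one-vs-all subproblem for multi-class data,
    criterion summed — and the ``chunk`` lowest-|w|^2 features are dropped.
    Ranking is the reverse elimination order; scores are the criterion at
    the round a feature was eliminated (survivors keep their final value).
    """
    if ds.n_features < 2:
        raise ValueError("SVM-RFE needs at least 2 features")
    surviving = np.arange(ds.n_features)
    eliminated: list[int] = []
    scores = np.zeros(ds.n_features)
    while surviving.size > 1:
        crit = _linear_w2(ds.X[:, surviving], ds.y, c)
        n_drop = min(chunk, surviving.size - 1)
        # ascending criterion, ties by ascending feature index
        drop_local = np.argsort(crit, kind="stable")[:n_drop]
        scores[surviving] = crit
        eliminated.extend(surviving[drop_local].tolist())
        surviving = np.delete(surviving, drop_local)
    order = np.concatenate([surviving, np.asarray(eliminated[::-1], dtype=int)])
    return FeatureRanking(order=order, scores=scores[order])


def default_k_grid(p: int, fractions: Sequence[float] | None = None) -> list[int]:
    """Candidate subset sizes: top 5%, 10%, ..., 50% of the ranking."""
    if fractions is None:
        fractions = [f / 100 for f in range(5, 55, 5)]
    ks = sorted({max(1, round(f * p)) for f in fractions})
    return [k for k in ks if k <= p]


def select_topk_by_cv(
    ds: LabeledDataset,
    ranking: FeatureRanking,
    k_grid: Sequence[int],
    svm_grid: SVMGrid,
    folds: int = 5,
    random_state: int | None = None,
) -> tuple[np.ndarray, SVMConfig, float]:
    """Pick the best top-k truncation and (c, g) by cross-validated NER.

    Every (k, c, g) combination is scored by stratified ``folds``-fold CV
    of a Gaussian-kernel SVM (multi-class NER, folds shared across
    combinations so comparisons are paired).  Ties go to the smallest k,
    then smallest c, then smallest g.
    """
    from .evaluation import compute_ner  # local import to avoid a cycle

    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("k_grid must be nonempty")
    if max(k_grid) > ds.n_features:
        raise ValueError("k_grid values must not exceed the feature count")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=random_state)
    splits = list(skf.split(ds.X, ds.y))
    m = ds.n_classes

    best: tuple[float, int, float, float] | None = None
    best_result: tuple[np.ndarray, SVMConfig, float] | None = None
    for k in sorted(k_grid):
        cols = ranking.top(k)
        Xk = ds.X[:, cols]
        for cfg in svm_grid.configs("gaussian"):
            fold_scores = []
            for tr, te in splits:
                svc = SVC(C=cfg.c, kernel="rbf", gamma=cfg.g, max_iter=_SVC_MAX_ITER)
                svc.fit(Xk[tr], ds.y[tr])
                pred = svc.predict(Xk[te])
                fold_scores.append(compute_ner(ds.y[te], pred, m=m).ner)
            score = float(np.mean(fold_scores))
            key = (-score, k, cfg.c, cfg.g)
            if best is None or key < best:
                best = key
                best_result = (cols, cfg, score)
    assert best_result is not None
    return best_result
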