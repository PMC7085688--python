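"""Balanced-accuracy (NER) evaluation and the repeated-split benchmark.

For an m-class prediction run, each class i is collapsed one-vs-rest and
scored by sensitivity SE_i = TP/(TP+FN) and specificity SP_i = TN/(TN+FP);
NER_i = (SE_i + SP_i)/2 and the overall NER is the mean of the NER_i.  The
benchmark protocol draws a stratified train split (two-thirds per class by
default), runs each method arm (class-specific EPSVM, or a global ranking
plus top-k-by-CV SVM), scores the held-out third, and averages over
seeded repeats; splits are paired across arms within a repeat.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.svm import SVC

from .baselines import (
    default_k_grid,
    relieff_rank,
    select_topk_by_cv,
    svm_rfe_rank,
)
from .data import LabeledDataset, SimulationSpec, simulate_dataset
from .enet_select import ENetConfig
from .psvm import SVMGrid, _SVC_MAX_ITER

METHODS = ("epsvm", "svmrfe", "relieff")


@dataclass
class EvalReport:
    """Per-class SE/SP/NER_i plus the pooled NER and confusion matrix."""

    per_class: list[tuple[int, float, float, float]]
    ner: float
    confusion: np.ndarray

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.per_class, columns=["class", "SE", "SP", "NER_i"]
        ).set_index("class")
        df.loc["overall"] = [np.nan, np.nan, self.ner]
        return df


def compute_ner(
    y_true: np.ndarray, y_pred: np.ndarray, m: int | None = None
) -> EvalReport:
    """One-vs-rest SE/SP per class and their pooled NER.

    Every class 1..m must appear in ``y_true`` (specificity alone does not
    define a class's NER).  Predictions outside 1..m are rejected.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be equal-length and nonempty")
    if m is None:
        m = int(y_true.max())
    labels = list(range(1, m + 1))
    missing = sorted(set(labels) - set(np.unique(y_true).tolist()))
    if missing:
        raise ValueError(f"classes {missing} absent from y_true")
    if not set(np.unique(y_pred).tolist()) <= set(labels):
        raise ValueError("y_pred contains labels outside 1..m")

    conf = confusion_matrix(y_true, y_pred, labels=labels)
    n = conf.sum()
    per_class = []
    for i in range(m):
        tp = conf[i, i]
        fn = conf[i].sum() - tp
        fp = conf[:, i].sum() - tp
        tn = n - tp - fn - fp
        se = tp / (tp + fn)
        sp = tn / (tn + fp) if (tn + fp) > 0 else 1.0
        per_class.append((i + 1, float(se), float(sp), float((se + sp) / 2)))
    ner = float(np.mean([row[3] for row in per_class]))
    return EvalReport(per_class=per_class, ner=ner, confusion=conf)


def stratified_split(
    ds: LabeledDataset, train_fraction: float = 2 / 3, seed: int | None = None
) -> tuple[LabeledDataset, LabeledDataset]:
    """Per-class random split: floor(fraction * n_c) train samples, clamped
    to [1, n_c - 1]; the rest test.  Disjoint and exhaustive."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    counts = ds.class_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 samples to split")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls in range(1, ds.n_classes + 1):
        rows = np.flatnonzero(ds.y == cls)
        rng.shuffle(rows)
        n_train = int(np.clip(np.floor(train_fraction * rows.size), 1, rows.size - 1))
        train_idx.append(rows[:n_train])
        test_idx.append(rows[n_train:])
    return (
        ds.subset_samples(np.concatenate(train_idx)),
        ds.subset_samples(np.concatenate(test_idx)),
    )


@dataclass
class ExperimentConfig:
    """Knobs of one benchmark run; defaults follow the evaluation protocol
    (2/3 stratified split, 5-fold CV, 30 repeats, ReliefF K=5)."""

    n_repeats: int = 30
    train_fraction: float = 2 / 3
    base_seed: int = 0
    methods: Sequence[str] = METHODS
    enet: ENetConfig = field(default_factory=ENetConfig)
    svm_grid: SVMGrid = field(default_factory=SVMGrid.coarse)
    folds: int = 5
    relieff_k: int = 5
    rfe_chunk: int = 1
    k_fractions: Sequence[float] | None = None
    selection_mode: str = "joint"  # or "fast": one (c, g) per subproblem

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown method arms: {sorted(unknown)}")


def _run_baseline_arm(
    method: str,
    train: LabeledDataset,
    test: LabeledDataset,
    cfg: ExperimentConfig,
    seed: int,
) -> tuple[float, dict]:
    if method == "relieff":
        ranking = relieff_rank(train, k_neighbors=cfg.relieff_k)
    else:
        ranking = svm_rfe_rank(train, chunk=cfg.rfe_chunk)
    k_grid = default_k_grid(train.n_features, cfg.k_fractions)
    subset, svm_cfg, cv_score = select_topk_by_cv(
        train, ranking, k_grid, cfg.svm_grid, folds=cfg.folds, random_state=seed
    )
    svc = SVC(C=svm_cfg.c, kernel="rbf", gamma=svm_cfg.g, max_iter=_SVC_MAX_ITER)
    svc.fit(train.X[:, subset], train.y)
    pred = svc.predict(test.X[:, subset])
    report = compute_ner(test.y, pred, m=train.n_classes)
    detail = {
        "n_selected": int(subset.size),
        "c": svm_cfg.c,
        "g": svm_cfg.g,
        "cv_ner": cv_score,
    }
    return report.ner, detail


def _run_epsvm_arm(
    train: LabeledDataset,
    test: LabeledDataset,
    cfg: ExperimentConfig,
    seed: int,
) -> tuple[float, dict]:
    from .epsvm import fit_epsvm, predict_epsvm

    model = fit_epsvm(
        train,
        enet_cfg=cfg.enet,
        svm_grid=cfg.svm_grid,
        folds=cfg.folds,
        seed=seed,
        selection_mode=cfg.selection_mode,
    )
    pred, _ = predict_epsvm(model, test.X)
    report = compute_ner(test.y, pred, m=train.n_classes)
    detail = {
        "subset_sizes": [int(m.feature_subset.size) for m in model.class_models],
        "configs": [
            {"c": m.svm.config.c, "g": m.svm.config.g} for m in model.class_models
        ],
    }
    return report.ner, detail


#: a benchmark input: a fixed dataset, a simulation spec (regenerated per
#: repeat), or a callable seed -> LabeledDataset
DatasetSource = "LabeledDataset | SimulationSpec | Callable[[int], LabeledDataset]"


def _materialize(source, repeat_seed: int) -> LabeledDataset:
    if isinstance(source, LabeledDataset):
        return source
    if isinstance(source, SimulationSpec):
        # fresh realization per repeat, seeded off the repeat seed
        spec = SimulationSpec(
            index=source.index,
            n_per_class=source.n_per_class,
            mu_signal=source.mu_signal,
            sd_signal=source.sd_signal,
            sd_noise=source.sd_noise,
            seed=repeat_seed,
        )
        return simulate_dataset(spec)
    return source(repeat_seed)


def run_benchmark(
    cfg: ExperimentConfig,
    datasets: Mapping[str, "DatasetSource"],
    out_dir: str | Path | None = None,
    verbose: bool = False,
) -> pd.DataFrame:
    """Repeated-split comparison of the method arms.

    ``datasets`` maps a name to a fixed :class:`LabeledDataset` (split anew
    each repeat), a :class:`SimulationSpec` (a fresh realization is drawn
    each repeat), or a callable ``seed -> LabeledDataset``.  Repeat r uses
    seed ``base_seed + r`` for generation, split, and CV folds, and the
    same split for every arm, so arms are compared on identical data.
    Failures in one repeat are recorded and the run continues.

    Returns the summary table (dataset, method, mean_ner, sd_ner,
    n_repeats, n_failures); writes ``results.csv`` and per-repeat JSON
    logs under ``out_dir`` when given.
    """
    rows = []
    logs = []
    for name, source in datasets.items():
        per_method: dict[str, list[float]] = {mth: [] for mth in cfg.methods}
        failures: dict[str, int] = {mth: 0 for mth in cfg.methods}
        for r in range(cfg.n_repeats):
            seed = cfg.base_seed + r
            ds = _materialize(source, seed)
            train, test = stratified_split(ds, cfg.train_fraction, seed=seed)
            for method in cfg.methods:
                t0 = time.perf_counter()
                try:
                    if method == "epsvm":
                        ner, detail = _run_epsvm_arm(train, test, cfg, seed)
                    else:
                        ner, detail = _run_baseline_arm(method, train, test, cfg, seed)
                except Exception as exc:  # noqa: BLE001 - keep benchmarking
                    failures[method] += 1
                    logs.append(
                        {"dataset": name, "method": method, "repeat": r,
                         "seed": seed, "error": repr(exc)}
                    )
                    continue
                per_method[method].append(ner)
                logs.append(
                    {"dataset": name, "method": method, "repeat": r, "seed": seed,
                     "ner": ner, "seconds": time.perf_counter() - t0, **detail}
                )
                if verbose:
                    print(f"{name} {method} repeat {r}: NER={ner:.4f}")
        for method in cfg.methods:
            vals = per_method[method]
            rows.append(
                {
                    "dataset": name,
                    "method": method,
                    "mean_ner": float(np.mean(vals)) if vals else np.nan,
                    "sd_ner": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    "n_repeats": len(vals),
                    "n_failures": failures[method],
                }
            )
    results = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.csv", index=False)
        (out / "repeats.json").write_text(json.dumps(logs, indent=1))
    return results
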