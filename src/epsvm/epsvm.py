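"""EPSVM: one-vs-all multiclass classification with class-specific features.

The m-class problem is decomposed one-vs-all into m binary subproblems.
For each, the elastic-net regularization path proposes candidate
class-specific feature subsets; every candidate is scored by stratified
cross-validation of a Platt-calibrated Gaussian-kernel SVM, jointly with a
(c, g) grid search, and the winner becomes that class's subset.  At
prediction time each calibrated machine reports P(class i | x) on its own
subset — probabilities, unlike raw SVM margins over different feature
spaces, are mutually comparable — and the predicted class is the argmax.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .data import LabeledDataset
from .enet_select import CandidateSubsets, ENetConfig, enet_path
from .evaluation import compute_ner
from .psvm import PSVMModel, SVMConfig, SVMGrid, fit_psvm


@dataclass
class ClassSelection:
    """Bookkeeping for one subproblem: what was chosen and its CV score."""

    positive_class: int
    subset_size: int
    lam: float | None
    c: float
    g: float
    cv_ner: float


@dataclass
class EPSVMModel:
    """m calibrated one-vs-all machines, each on its own feature subset."""

    class_models: list[PSVMModel]
    class_names: list[str]
    selections: list[ClassSelection] = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.class_models)

    def to_dict(self) -> dict:
        return {
            "class_names": self.class_names,
            "class_models": [m.to_dict() for m in self.class_models],
            "selections": [vars(s) for s in self.selections],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EPSVMModel":
        return cls(
            class_models=[PSVMModel.from_dict(m) for m in d["class_models"]],
            class_names=list(d["class_names"]),
            selections=[ClassSelection(**s) for s in d.get("selections", [])],
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load_json(cls, path: str | Path) -> "EPSVMModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def decompose_ova(ds: LabeledDataset) -> list[tuple[int, np.ndarray]]:
    """One (positive class, +/-1 label vector) per class."""
    if ds.n_classes < 2:
        raise ValueError("need at least two classes to decompose")
    return [
        (cls, np.where(ds.y == cls, 1, -1))
        for cls in range(1, ds.n_classes + 1)
    ]


def _binary_ner(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """(SE + SP) / 2 on +/-1 labels."""
    pos = y_true == 1
    se = float(np.mean(y_pred[pos] == 1))
    sp = float(np.mean(y_pred[~pos] == -1))
    return (se + sp) / 2.0


def _cv_score_subset(
    X: np.ndarray,
    y: np.ndarray,
    subset: np.ndarray,
    cfg: SVMConfig,
    splits: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[float, float, float]:
    """Out-of-fold (mean binary NER, mean log-loss, log-loss SE).

    The NER is the selection score; the log-loss of the calibrated
    probabilities refines it — on easy subproblems many (subset, c, g)
    combinations tie at NER 1.0, and the proper scoring rule separates
    robustly calibrated models from degenerate ones.  Its fold-to-fold
    standard error feeds the one-standard-error parsimony rule.
    Inside this loop the sigmoid is fitted on in-sample decision values
    (calibration is monotone, so the induced threshold and ordering are
    what matters) to keep the search tractable.
    """
    Xs = X[:, subset]
    ners = []
    losses = []
    for tr, te in splits:
        model = fit_psvm(
            Xs[tr], y[tr], cfg, feature_subset=np.arange(subset.size),
            platt_insample=True,
        )
        p = model.predict_proba(Xs[te])
        pred = np.where(p > 0.5, 1, -1)
        ners.append(_binary_ner(y[te], pred))
        p_true = np.where(y[te] == 1, p, 1.0 - p)
        losses.append(float(-np.mean(np.log(p_true))))
    loss_se = float(np.std(losses, ddof=1) / np.sqrt(len(losses)))
    return float(np.mean(ners)), float(np.mean(losses)), loss_se


def select_class_specific(
    X: np.ndarray,
    y_binary: np.ndarray,
    enet_cfg: ENetConfig,
    svm_grid: SVMGrid,
    folds: int = 5,
    random_state: int | None = None,
    selection_mode: str = "joint",
    candidates: CandidateSubsets | None = None,
) -> tuple[np.ndarray, SVMConfig, float]:
    """Choose one class-specific subset and its (c, g) by CV.

    Candidates come from the elastic-net path on (X, y_binary) unless
    supplied.  ``joint`` mode grid-searches (c, g) per candidate; ``fast``
    mode first fixes (c, g) on the largest candidate, then scores all
    candidates with it.  CV folds are shared across candidates so the
    comparison is paired.  Selection maximizes out-of-fold binary NER;
    among NER-tied candidates the subset is chosen by a one-standard-error
    parsimony rule on the out-of-fold log-loss of the calibrated
    probabilities: the smallest subset whose loss is within one fold-SE of
    the best loss.  Remaining ties go to smaller c, then smaller g.
    """
    if candidates is None:
        candidates = enet_path(X, y_binary, enet_cfg)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=random_state)
    splits = list(skf.split(X, y_binary))

    if selection_mode == "fast":
        widest = max(range(len(candidates)), key=lambda k: candidates.subsets[k].size)
        probe = candidates.subsets[widest]
        cfgs = [
            min(
                ((cfg, _cv_score_subset(X, y_binary, probe, cfg, splits))
                 for cfg in svm_grid.configs("gaussian")),
                key=lambda t: (-t[1][0], t[1][1], t[0].c, t[0].g),
            )[0]
        ]
    elif selection_mode == "joint":
        cfgs = list(svm_grid.configs("gaussian"))
    else:
        raise ValueError(f"unknown selection_mode {selection_mode!r}")

    # per candidate, the best (c, g) by NER then calibrated log-loss
    scored: list[tuple[np.ndarray, SVMConfig, float, float, float, float | None]] = []
    for k, subset in enumerate(candidates.subsets):
        cand_best = None
        for cfg in cfgs:
            score, loss, loss_se = _cv_score_subset(X, y_binary, subset, cfg, splits)
            key = (-score, loss, cfg.c, cfg.g)
            if cand_best is None or key < cand_best[0]:
                lam = float(candidates.lambdas[k]) if k < candidates.lambdas.size else None
                cand_best = (key, (subset, cfg, score, loss, loss_se, lam))
        assert cand_best is not None
        scored.append(cand_best[1])

    best_ner = max(s[2] for s in scored)
    tied = [s for s in scored if s[2] == best_ner]
    loss_floor = min(s[3] for s in tied)
    se_at_floor = next(s[4] for s in tied if s[3] == loss_floor)
    eligible = [s for s in tied if s[3] <= loss_floor + se_at_floor]
    subset, cfg, score, _, _, _ = min(
        eligible, key=lambda s: (s[0].size, s[1].c, s[1].g)
    )
    return subset, cfg, score


def fit_epsvm(
    ds: LabeledDataset,
    enet_cfg: ENetConfig | None = None,
    svm_grid: SVMGrid | None = None,
    folds: int = 5,
    seed: int | None = None,
    selection_mode: str = "joint",
    platt_folds: int = 3,
    platt_insample: bool = False,
) -> EPSVMModel:
    """Fit the full one-vs-all model with class-specific subsets.

    Per subproblem: elastic-net candidates, CV subset/(c, g) selection,
    then a final calibrated SVM on the whole training set using the chosen
    subset and configuration.  Deterministic given ``seed``.
    """
    if enet_cfg is None:
        enet_cfg = ENetConfig()
    if svm_grid is None:
        svm_grid = SVMGrid.coarse()
    counts = ds.class_counts()
    if (counts < folds).any():
        raise ValueError(f"every class needs at least {folds} samples for CV")

    class_models: list[PSVMModel] = []
    selections: list[ClassSelection] = []
    # one seed shared by all subproblems: folds depend only on (seed, ybin),
    # so renumbering classes permutes the fitted machines consistently
    for cls, ybin in decompose_ova(ds):
        sub_seed = None if seed is None else seed % (2**31 - 1)
        candidates = enet_path(ds.X, ybin, enet_cfg)
        subset, cfg, score = select_class_specific(
            ds.X,
            ybin,
            enet_cfg,
            svm_grid,
            folds=folds,
            random_state=sub_seed,
            selection_mode=selection_mode,
            candidates=candidates,
        )
        model = fit_psvm(
            ds.X,
            ybin,
            cfg,
            feature_subset=subset,
            platt_folds=platt_folds,
            platt_insample=platt_insample,
            random_state=sub_seed,
        )
        lam = next(
            (
                float(candidates.lambdas[k])
                for k, s in enumerate(candidates.subsets)
                if s.size == subset.size and np.array_equal(s, subset)
            ),
            None,
        )
        class_models.append(model)
        selections.append(
            ClassSelection(
                positive_class=cls,
                subset_size=int(subset.size),
                lam=lam,
                c=cfg.c,
                g=cfg.g,
                cv_ner=score,
            )
        )
    return EPSVMModel(
        class_models=class_models,
        class_names=list(ds.class_names),
        selections=selections,
    )


def predict_epsvm(
    model: EPSVMModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and the m-column positive-class probability matrix.

    Column i is P(class i+1 | x) from machine i on its own subset; the
    label is the argmax, ties going to the smallest class index.  Rows are
    not normalized — one-vs-all probabilities are comparable but not a
    distribution.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    proba = np.column_stack([m.predict_proba(X) for m in model.class_models])
    labels = np.argmax(proba, axis=1) + 1  # argmax takes the first maximum
    return labels, proba
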