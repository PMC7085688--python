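"""Datasets: the labeled expression-matrix container, the block-structured
collinear simulator, delimited-text I/O, and the one-way ANOVA prefilter.

The simulator emulates "large p, small n" multi-class expression data with
correlated feature groups.  Dataset ``i`` (1 <= i <= 9) has ``i + 2`` classes
of ``n_per_class`` samples each.  The feature space splits into two halves of
``20 * (i + 2)`` features.  In the base half, class ``l`` draws its own
20-feature block from N(2, 1) and every other feature from N(0, 1); the
second half repeats the base half's signal pattern.  Independent N(0, 2)
noise is then added to every feature, so each base feature and its repeat
share the signal draw but not the noise — correlated, not identical columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

BLOCK_WIDTH = 20
#: smallest representable positive p-value; guards against underflow to 0.0
_P_FLOOR = np.nextafter(0.0, 1.0)


class DatasetError(ValueError):
    """Raised for malformed dataset inputs (shape, labels, parsing)."""


@dataclass
class LabeledDataset:
    """A numeric samples-by-features matrix with integer class labels.

    Labels are integers ``1..m``; every class must be represented.
    ``class_names[k]`` names class ``k + 1``.
    """

    X: np.ndarray
    y: np.ndarray
    feature_ids: list[str] = field(default_factory=list)
    class_names: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise DatasetError("X must be a 2-D samples x features matrix")
        n, p = self.X.shape
        if self.y.shape != (n,):
            raise DatasetError(
                f"label vector length {self.y.shape} does not match {n} samples"
            )
        if not np.isfinite(self.X).all():
            bad = np.argwhere(~np.isfinite(self.X))[0]
            raise DatasetError(
                f"non-finite value at sample {bad[0]}, feature {bad[1]}"
            )
        m = int(self.y.max(initial=0))
        present = set(np.unique(self.y).tolist())
        if present != set(range(1, m + 1)):
            raise DatasetError(
                f"labels must cover 1..{m}; saw classes {sorted(present)}"
            )
        if not self.feature_ids:
            self.feature_ids = [f"f{j + 1}" for j in range(p)]
        if len(self.feature_ids) != p:
            raise DatasetError("feature_ids length does not match feature count")
        if not self.class_names:
            self.class_names = [f"class{k}" for k in range(1, m + 1)]
        if len(self.class_names) != m:
            raise DatasetError("class_names length does not match class count")
        if not self.sample_ids:
            self.sample_ids = [f"s{i + 1}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise DatasetError("sample_ids length does not match sample count")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.y, minlength=self.n_classes + 1)[1:]

    def subset_samples(self, indices: np.ndarray) -> "LabeledDataset":
        """Row-subset keeping class numbering and names (classes may not
        all survive in the subset; callers splitting stratified keep all)."""
        indices = np.asarray(indices)
        ds = object.__new__(LabeledDataset)
        ds.X = self.X[indices]
        ds.y = self.y[indices]
        ds.feature_ids = list(self.feature_ids)
        ds.class_names = list(self.class_names)
        ds.sample_ids = [self.sample_ids[i] for i in indices]
        return ds


@dataclass
class SimulationSpec:
    """Parameters of one simulated dataset.

    ``index`` i in 1..9 gives ``i + 2`` classes, ``40 * (i + 2)`` features.
    ``mu_signal``/``sd_signal`` parameterize the in-class signal N(2, 1),
    ``sd_signal`` also scales the N(0, 1) background, and ``sd_noise`` the
    N(0, 2) measurement noise added to every feature.
    """

    index: int
    n_per_class: int = 30
    mu_signal: float = 2.0
    sd_signal: float = 1.0
    sd_noise: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 9:
            raise DatasetError(f"simulation index must be in [1, 9], got {self.index}")
        if self.n_per_class < 2:
            raise DatasetError("n_per_class must be at least 2")

    @property
    def n_classes(self) -> int:
        return self.index + 2

    @property
    def n_features(self) -> int:
        return 2 * BLOCK_WIDTH * self.n_classes

    def informative_blocks(self, cls: int) -> tuple[np.ndarray, np.ndarray]:
        """0-based index arrays of the two feature blocks whose mean is
        elevated for class ``cls`` (base block and its repeat)."""
        m = self.n_classes
        base = np.arange((cls - 1) * BLOCK_WIDTH, cls * BLOCK_WIDTH)
        return base, base + BLOCK_WIDTH * m


def simulate_dataset(spec: SimulationSpec) -> LabeledDataset:
    """Generate one block-structured collinear dataset.

    Samples are emitted class by class.  The same seed reproduces the
    matrix bit for bit.
    """
    m = spec.n_classes
    n = m * spec.n_per_class
    p_base = BLOCK_WIDTH * m
    rng = np.random.default_rng(spec.seed)

    signal = rng.normal(0.0, spec.sd_signal, size=(n, p_base))
    y = np.repeat(np.arange(1, m + 1), spec.n_per_class)
    for cls in range(1, m + 1):
        rows = y == cls
        cols = slice((cls - 1) * BLOCK_WIDTH, cls * BLOCK_WIDTH)
        signal[rows, cols] += spec.mu_signal

    X = np.concatenate([signal, signal], axis=1)
    X += rng.normal(0.0, spec.sd_noise, size=X.shape)
    return LabeledDataset(X=X, y=y)


def anova_prefilter(
    ds: LabeledDataset, p_threshold: float = 0.001
) -> np.ndarray:
    """Indices of features whose one-way ANOVA p-value is <= ``p_threshold``.

    Features with undefined F (zero variance everywhere) get p = 1 and are
    filtered.  Underflowed p-values are floored at the smallest positive
    float, so a threshold of exactly 0 keeps nothing.  Order is preserved.
    """
    if ds.n_classes < 2:
        raise DatasetError("ANOVA prefilter needs at least two classes")
    counts = ds.class_counts()
    if (counts < 2).any():
        raise DatasetError("every class needs at least two samples for ANOVA")
    groups = [ds.X[ds.y == cls] for cls in range(1, ds.n_classes + 1)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns give nan F
        _, pvals = stats.f_oneway(*groups, axis=0)
    defined = ~np.isnan(pvals)  # undefined F (zero variance) is never kept
    pvals = np.where(defined, np.maximum(pvals, _P_FLOOR), np.inf)
    return np.flatnonzero(pvals <= p_threshold)


def _delimiter_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def write_dataset(
    ds: LabeledDataset, matrix_path: str | Path, labels_path: str | Path
) -> None:
    """Write the matrix (sample id column + feature-id header) and a
    two-column ``sample_id,class_name`` labels file."""
    frame = pd.DataFrame(ds.X, index=ds.sample_ids, columns=ds.feature_ids)
    frame.index.name = "sample_id"
    frame.to_csv(matrix_path, sep=_delimiter_for(matrix_path))
    labels = pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "class_name": [ds.class_names[c - 1] for c in ds.y],
        }
    )
    labels.to_csv(labels_path, sep=_delimiter_for(labels_path), index=False)


def read_dataset(
    matrix_path: str | Path, labels_path: str | Path
) -> LabeledDataset:
    """Read a delimited expression matrix plus labels file.

    Class names become integer labels 1..m in order of first appearance in
    the labels file (restricted to samples present in the matrix).
    """
    try:
        frame = pd.read_csv(
            matrix_path, sep=_delimiter_for(matrix_path), index_col=0
        )
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise DatasetError(f"cannot parse matrix file {matrix_path}: {exc}") from exc
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        row, col = np.argwhere(numeric.isna().to_numpy())[0]
        raise DatasetError(
            f"non-numeric cell at sample {frame.index[row]!r}, "
            f"feature {frame.columns[col]!r} in {matrix_path}"
        )

    labels = pd.read_csv(labels_path, sep=_delimiter_for(labels_path))
    if labels.shape[1] < 2:
        raise DatasetError(
            f"labels file {labels_path} must have sample_id and class_name columns"
        )
    label_map = dict(
        zip(labels.iloc[:, 0].astype(str), labels.iloc[:, 1].astype(str))
    )
    sample_ids = [str(s) for s in frame.index]
    missing = [s for s in sample_ids if s not in label_map]
    if missing:
        raise DatasetError(
            f"labels file {labels_path} is missing sample ids: {missing}"
        )

    class_names: list[str] = []
    y = np.empty(len(sample_ids), dtype=int)
    for i, sid in enumerate(sample_ids):
        name = label_map[sid]
        if name not in class_names:
            class_names.append(name)
        y[i] = class_names.index(name) + 1
    return LabeledDataset(
        X=numeric.to_numpy(dtype=float),
        y=y,
        feature_ids=[str(c) for c in frame.columns],
        class_names=class_names,
        sample_ids=sample_ids,
    )
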