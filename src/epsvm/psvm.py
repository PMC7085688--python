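"""Kernel SVM with Platt sigmoid calibration (the probabilistic SVM, PSVM).

A soft-margin SVM gives a decision value f(x) = sum_i y_i a_i K(x_i, x) + b;
Platt scaling maps it to a posterior P(y=+1 | x) = 1 / (1 + exp(A f(x) + B))
by minimizing the negative log-likelihood of the regularized targets

    t+ = (N+ + 1) / (N+ + 2)   for positive samples,
    t- = 1 / (N- + 2)          for negative samples,

which keep the sigmoid finite even on perfectly separated decision values.
The sigmoid is fitted by a damped Newton iteration; by default the decision
values come from an internal stratified cross-validation on the training
set (out-of-fold values avoid the optimism of in-sample margins).

The SVM dual problem itself is solved by libsvm via scikit-learn; the
decision function is re-evaluated here from the stored support vectors so a
serialized model reproduces its outputs exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

#: libsvm iteration cap; generous for the few-hundred-sample problems this
#: package targets while bounding pathological (c, g) grid corners.
_SVC_MAX_ITER = 200_000
_PROB_EPS = 1e-12


class PlattConvergenceError(RuntimeError):
    """Newton iteration failed to reach the gradient tolerance.

    Carries the last iterate in ``last_params``.
    """

    def __init__(self, message: str, last_params: "PlattParams"):
        super().__init__(message)
        self.last_params = last_params


@dataclass
class SVMConfig:
    """Kernel and regularization of one SVM: ``gaussian`` uses
    K(u, v) = exp(-g ||u - v||^2); ``linear`` ignores ``g``."""

    kernel: str = "gaussian"
    c: float = 1.0
    g: float = 1.0

    def __post_init__(self) -> None:
        if self.kernel not in ("gaussian", "linear"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if not (np.isfinite(self.c) and self.c > 0):
            raise ValueError("cost c must be finite and positive")
        if self.kernel == "gaussian" and not (np.isfinite(self.g) and self.g > 0):
            raise ValueError("gaussian width g must be finite and positive")


@dataclass
class SVMGrid:
    """A (c, g) search grid, iterated c-major then g (both ascending)."""

    c_values: np.ndarray
    g_values: np.ndarray

    @classmethod
    def from_powers(
        cls, c_powers: "np.ndarray | range", g_powers: "np.ndarray | range"
    ) -> "SVMGrid":
        return cls(
            c_values=2.0 ** np.asarray(sorted(c_powers), dtype=float),
            g_values=2.0 ** np.asarray(sorted(g_powers), dtype=float),
        )

    @classmethod
    def full(cls) -> "SVMGrid":
        """c over 2^-10..2^10, g over 2^-15..2^15, integer powers of two."""
        return cls.from_powers(range(-10, 11), range(-15, 16))

    @classmethod
    def coarse(cls, step: int = 5) -> "SVMGrid":
        """The full grid subsampled every ``step`` powers of two — the
        reduced search used for the larger benchmark problems."""
        return cls.from_powers(range(-10, 11, step), range(-15, 16, step))

    def configs(self, kernel: str = "gaussian"):
        if kernel == "linear":
            for c in self.c_values:
                yield SVMConfig(kernel="linear", c=float(c))
            return
        for c in self.c_values:
            for g in self.g_values:
                yield SVMConfig(kernel=kernel, c=float(c), g=float(g))


@dataclass
class PlattParams:
    """Sigmoid slope/offset; A < 0 makes probability increase with f(x)."""

    A: float
    B: float


class SVMModel:
    """A trained binary SVM evaluated from its stored dual solution."""

    def __init__(
        self,
        config: SVMConfig,
        support_vectors: np.ndarray,
        dual_coef: np.ndarray,
        bias: float,
    ):
        self.config = config
        self.support_vectors = np.asarray(support_vectors, dtype=float)
        self.dual_coef = np.asarray(dual_coef, dtype=float).ravel()
        self.bias = float(bias)

    def _kernel_matrix(self, X: np.ndarray) -> np.ndarray:
        sv = self.support_vectors
        if self.config.kernel == "linear":
            return X @ sv.T
        sq = (
            np.sum(X**2, axis=1)[:, None]
            + np.sum(sv**2, axis=1)[None, :]
            - 2.0 * X @ sv.T
        )
        return np.exp(-self.config.g * np.maximum(sq, 0.0))

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.support_vectors.shape[1]:
            raise ValueError(
                f"expected {self.support_vectors.shape[1]} features, "
                f"got {X.shape[1]}"
            )
        return self._kernel_matrix(X) @ self.dual_coef + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        f = self.decision_values(X)
        return np.where(f >= 0.0, 1, -1)

    def to_dict(self) -> dict:
        return {
            "config": {
                "kernel": self.config.kernel,
                "c": self.config.c,
                "g": self.config.g,
            },
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "bias": self.bias,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SVMModel":
        return cls(
            config=SVMConfig(**d["config"]),
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            bias=d["bias"],
        )


def _as_pm1(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    labels = np.unique(y)
    if labels.size != 2 or not set(labels.tolist()) <= {-1, 1}:
        raise ValueError("y_binary must contain both +1 and -1 labels")
    return y.astype(int)


def fit_svm(X: np.ndarray, y_binary: np.ndarray, cfg: SVMConfig) -> SVMModel:
    """Train a soft-margin SVM and capture its dual solution.

    The returned model's decision values agree with the libsvm solution to
    floating-point accuracy, so sign(f) on the training set reproduces the
    fitted classifier.
    """
    X = np.asarray(X, dtype=float)
    y = _as_pm1(y_binary)
    svc = SVC(
        C=cfg.c,
        kernel="rbf" if cfg.kernel == "gaussian" else "linear",
        gamma=cfg.g if cfg.kernel == "gaussian" else "scale",
        max_iter=_SVC_MAX_ITER,
    )
    svc.fit(X, y)
    # sklearn orders binary classes [-1, +1] so dual_coef_ is y_i * a_i
    return SVMModel(
        config=cfg,
        support_vectors=svc.support_vectors_,
        dual_coef=svc.dual_coef_.ravel(),
        bias=float(svc.intercept_[0]),
    )


def platt_targets(y_binary: np.ndarray) -> np.ndarray:
    """Regularized sigmoid targets: (N+ + 1)/(N+ + 2) and 1/(N- + 2)."""
    y = _as_pm1(y_binary)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    t_pos = (n_pos + 1.0) / (n_pos + 2.0)
    t_neg = 1.0 / (n_neg + 2.0)
    return np.where(y == 1, t_pos, t_neg)


def platt_objective(A: float, B: float, f: np.ndarray, t: np.ndarray) -> float:
    """Negative log-likelihood of the sigmoid at (A, B), overflow-safe."""
    z = np.clip(A * f + B, -500.0, 500.0)
    # -[t log p + (1-t) log(1-p)] with p = 1/(1+e^z), stably:
    # = t*z + log(1+e^-z) for z>=0 ; (t-1)*z + log(1+e^z) for z<0
    return float(
        np.sum(
            np.where(
                z >= 0,
                t * z + np.log1p(np.exp(-np.abs(z))),
                (t - 1.0) * z + np.log1p(np.exp(-np.abs(z))),
            )
        )
    )


def fit_platt(
    decision_values: np.ndarray,
    y_binary: np.ndarray,
    max_iter: int = 200,
    grad_tol: float = 1e-8,
) -> PlattParams:
    """Fit the calibration sigmoid by damped Newton iteration.

    Converges when the gradient norm drops below ``grad_tol``; raises
    :class:`PlattConvergenceError` (carrying the last iterate) otherwise.
    """
    f_raw = np.asarray(decision_values, dtype=float)
    if not np.isfinite(f_raw).all():
        raise ValueError("decision values must be finite")
    t = platt_targets(y_binary)
    n_pos = int(np.sum(np.asarray(y_binary) == 1))
    n_neg = f_raw.size - n_pos

    # condition the iteration: fit on standardized decision values and map
    # (A, B) back; the objective and its optimum are unchanged, but the
    # Newton system stays well-scaled even for near-constant f
    mu = float(f_raw.mean())
    scale = float(f_raw.std())
    if scale == 0.0 or not np.isfinite(scale):
        scale = 1.0
    f = (f_raw - mu) / scale

    def _back(a: float, b: float) -> PlattParams:
        return PlattParams(A=a / scale, B=b - a * mu / scale)

    A = 0.0
    B = float(np.log((n_neg + 1.0) / (n_pos + 1.0)))
    obj = platt_objective(A, B, f, t)

    for _ in range(max_iter):
        z = np.clip(A * f + B, -500.0, 500.0)
        p = expit(-z)  # P(y=1) = 1/(1+e^z)
        d1 = t - p  # dF/dz per sample
        w = p * (1.0 - p)
        grad_A = float(np.dot(f, d1))
        grad_B = float(np.sum(d1))
        if max(abs(grad_A), abs(grad_B)) < grad_tol:
            return _back(A, B)

        # damped Newton: the Hessian ridge grows until the step decreases
        # the objective (it is singular when decision values are constant)
        moved = False
        sigma = 1e-12
        while sigma < 1e12:
            h11 = float(np.dot(f * f, w)) + sigma
            h22 = float(np.sum(w)) + sigma
            h12 = float(np.dot(f, w))
            det = h11 * h22 - h12 * h12
            dA = -(h22 * grad_A - h12 * grad_B) / det
            dB = -(-h12 * grad_A + h11 * grad_B) / det
            gd = grad_A * dA + grad_B * dB
            if gd < 0.0:
                step = 1.0
                for _ in range(20):  # backtracking halving
                    new_obj = platt_objective(A + step * dA, B + step * dB, f, t)
                    if new_obj <= obj + 1e-4 * step * gd:
                        A += step * dA
                        B += step * dB
                        obj = new_obj
                        moved = True
                        break
                    step /= 2.0
                if moved:
                    break
            sigma *= 100.0
        if not moved:
            # no descent direction left: gradient is numerically flat
            return _back(A, B)

    z = np.clip(A * f + B, -500.0, 500.0)
    d1 = t - expit(-z)
    if max(abs(float(np.dot(f, d1))), abs(float(np.sum(d1)))) < grad_tol:
        return _back(A, B)
    raise PlattConvergenceError(
        f"Platt sigmoid fit did not converge in {max_iter} iterations",
        _back(A, B),
    )


class PSVMModel:
    """A calibrated SVM tied to the feature subset it consumes.

    ``feature_subset`` holds global column indices; ``predict_proba``
    accepts either exactly those columns or the full feature space, which
    is sliced down.
    """

    def __init__(
        self,
        svm: SVMModel,
        platt: PlattParams,
        feature_subset: np.ndarray,
    ):
        self.svm = svm
        self.platt = platt
        self.feature_subset = np.asarray(feature_subset, dtype=int)

    def _slice(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        k = self.feature_subset.size
        if X.shape[1] == k:
            return X
        if X.shape[1] > int(self.feature_subset.max()):
            return X[:, self.feature_subset]
        missing = self.feature_subset[self.feature_subset >= X.shape[1]]
        raise ValueError(
            f"input lacks required feature indices {missing.tolist()}"
        )

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return self.svm.decision_values(self._slice(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(y=+1 | x), strictly inside (0, 1)."""
        z = self.platt.A * self.decision_values(X) + self.platt.B
        return np.clip(expit(-z), _PROB_EPS, 1.0 - _PROB_EPS)

    def predict_proba_negative(self, X: np.ndarray) -> np.ndarray:
        return 1.0 - self.predict_proba(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.predict_proba(X) > 0.5, 1, -1)

    def to_dict(self) -> dict:
        return {
            "svm": self.svm.to_dict(),
            "platt": {"A": self.platt.A, "B": self.platt.B},
            "feature_subset": self.feature_subset.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PSVMModel":
        return cls(
            svm=SVMModel.from_dict(d["svm"]),
            platt=PlattParams(**d["platt"]),
            feature_subset=np.asarray(d["feature_subset"], dtype=int),
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load_json(cls, path: str | Path) -> "PSVMModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_psvm(
    X: np.ndarray,
    y_binary: np.ndarray,
    cfg: SVMConfig,
    feature_subset: np.ndarray | None = None,
    platt_folds: int = 3,
    platt_insample: bool = False,
    random_state: int | None = None,
) -> PSVMModel:
    """Train the SVM on all samples, then calibrate the sigmoid.

    Calibration decision values are out-of-fold from a stratified
    ``platt_folds``-fold split (refitting the SVM per fold) unless
    ``platt_insample`` is set or a class is too small to stratify.
    """
    X = np.asarray(X, dtype=float)
    y = _as_pm1(y_binary)
    if feature_subset is None:
        feature_subset = np.arange(X.shape[1])
    feature_subset = np.asarray(feature_subset, dtype=int)
    Xs = X[:, feature_subset] if X.shape[1] != feature_subset.size else X

    svm = fit_svm(Xs, y, cfg)
    min_class = int(min(np.sum(y == 1), np.sum(y == -1)))
    if platt_insample or min_class < platt_folds:
        f_cal = svm.decision_values(Xs)
    else:
        f_cal = np.empty(y.size)
        skf = StratifiedKFold(
            n_splits=platt_folds, shuffle=True, random_state=random_state
        )
        for tr, te in skf.split(Xs, y):
            fold_svm = fit_svm(Xs[tr], y[tr], cfg)
            f_cal[te] = fold_svm.decision_values(Xs[te])
    try:
        platt = fit_platt(f_cal, y)
    except PlattConvergenceError as exc:
        # degenerate decision values (e.g. a badly underfit grid corner)
        # stall the Newton fit; the last iterate is still a strictly
        # monotone calibration, which is all downstream fusion needs
        warnings.warn(f"Platt fit did not converge; using last iterate ({exc})",
                      stacklevel=2)
        platt = exc.last_params
    return PSVMModel(svm=svm, platt=platt, feature_subset=feature_subset)
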