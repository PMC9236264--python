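"""Least-squares linear discriminant and soft-margin / RBF SVM classifiers.

The least-squares linear discriminant (LSLD) is the workhorse of the
pipeline: a linear decision function ``y = sum_n w_n x_n + b`` whose
weights and bias minimize the mean squared error against +/-1 class
targets. When the normal equations are singular (more features than
training rows, or collinear columns) the minimum-norm least-squares
solution is returned, which keeps the fit well-defined in the
high-dimensional small-sample regime this pipeline lives in.

All classifiers standardize features to zero mean / unit variance using
statistics of the *training rows only* (scale-sensitive fits would
otherwise leak test information); zero-variance training columns are zeroed
out rather than divided by zero.

SVMs delegate the quadratic program to scikit-learn's SVC — the contract
here is the soft-margin objective, not the solver — wrapped so that
standardization, hyperparameter tuning (stratified inner CV over a
2^-4..2^4 power-of-two grid) and decision scores follow the same interface
as the LSLD.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

#: Integer powers of two from 2^-4 to 2^4, the hyperparameter search grid.
DEFAULT_GRID: tuple[float, ...] = tuple(2.0 ** k for k in range(-4, 5))


def _check_two_class(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if not np.array_equal(classes, [-1.0, 1.0]):
        if classes.size < 2:
            raise ValueError("labels contain a single class")
        raise ValueError("labels must be encoded as -1 / +1")
    return y


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Train-fold mean / SD (population, ddof=0); zero-variance columns are
    flagged and their standardized values set to 0."""
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    zero_var = scale == 0.0
    if zero_var.any():
        logger.warning("zeroing %d zero-variance feature column(s)",
                       int(zero_var.sum()))
    safe = np.where(zero_var, 1.0, scale)
    return mean, safe, zero_var


def _standardize_apply(X: np.ndarray, mean: np.ndarray, scale: np.ndarray,
                       zero_var: np.ndarray) -> np.ndarray:
    Xs = (X - mean) / scale
    if zero_var.any():
        Xs[:, zero_var] = 0.0
    return Xs


def lsld_solve(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Minimum-norm least-squares solve of ``[X | 1] (w, b) = y`` on an
    already-standardized design; returns (w, b, training MSE)."""
    n = X.shape[0]
    A = np.column_stack([X, np.ones(n)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = A @ coef - y
    mse = float(resid @ resid / n)
    return coef[:-1], float(coef[-1]), mse


@dataclass
class LinearModel:
    """Fitted LSLD: weights, bias and the train-fold standardizer."""

    w: np.ndarray
    b: float
    feature_indices: tuple[int, ...] | None
    mean: np.ndarray
    scale: np.ndarray
    zero_variance: np.ndarray
    training_mse: float

    kind: str = "lsld"
    hyperparameters: dict = field(default_factory=dict)

    def _scores(self, X: np.ndarray) -> np.ndarray:
        Xs = _standardize_apply(X, self.mean, self.scale, self.zero_variance)
        return Xs @ self.w + self.b


@dataclass
class SvmModel:
    """Fitted soft-margin SVM (linear or RBF) with its standardizer and,
    after tuning, the inner-CV grid results."""

    svc: SVC
    kernel: str
    C: float
    gamma: float | None
    feature_indices: tuple[int, ...] | None
    mean: np.ndarray
    scale: np.ndarray
    zero_variance: np.ndarray
    inner_results: list[tuple[float, float | None, float]] = field(
        default_factory=list)

    @property
    def kind(self) -> str:
        return f"svm-{self.kernel}"

    @property
    def hyperparameters(self) -> dict:
        hp = {"C": self.C}
        if self.kernel == "rbf":
            hp["gamma"] = self.gamma
        return hp

    def _scores(self, X: np.ndarray) -> np.ndarray:
        Xs = _standardize_apply(X, self.mean, self.scale, self.zero_variance)
        return self.svc.decision_function(Xs)


FittedClassifier = LinearModel | SvmModel


def fit_lsld(
    X: np.ndarray,
    y: Sequence[float],
    feature_indices: Sequence[int] | None = None,
) -> LinearModel:
    """Fit the least-squares linear discriminant on (already restricted)
    training columns against +/-1 targets."""
    X = np.asarray(X, dtype=float)
    y = _check_two_class(np.asarray(y))
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y shapes are inconsistent")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    mean, scale, zero_var = _standardize_fit(X)
    Xs = _standardize_apply(X, mean, scale, zero_var)
    w, b, mse = lsld_solve(Xs, y)
    idx = tuple(int(i) for i in feature_indices) \
        if feature_indices is not None else None
    return LinearModel(w=w, b=b, feature_indices=idx, mean=mean, scale=scale,
                       zero_variance=zero_var, training_mse=mse)


def lsld_training_mse(X: np.ndarray, y: np.ndarray) -> float:
    """Training MSE of the LSLD on X, y — the GA fitness — without building
    a model object (hot path)."""
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    zero = scale == 0.0
    Xs = (X - mean) / np.where(zero, 1.0, scale)
    if zero.any():
        Xs[:, zero] = 0.0
    return lsld_solve(Xs, y)[2]


def decision_values(model: FittedClassifier, X: np.ndarray) -> np.ndarray:
    """Continuous decision scores, one per row of ``X``.

    ``X`` may be the full-width feature matrix (the model slices its own
    ``feature_indices``) or a matrix already restricted to the model's L
    columns. Sign gives the predicted class; exact zeros predict the
    negative (non-improver) class.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    L = model.mean.shape[0]
    if X.shape[1] != L:
        if model.feature_indices is None:
            raise ValueError(f"expected {L} feature columns, got {X.shape[1]}")
        if X.shape[1] <= max(model.feature_indices):
            raise ValueError("input is missing the model's feature columns")
        X = X[:, list(model.feature_indices)]
    return model._scores(X)


def predict_classes(model: FittedClassifier, X: np.ndarray) -> np.ndarray:
    """+/-1 predictions; ties at score 0 go to the negative class."""
    scores = decision_values(model, X)
    return np.where(scores > 0, 1, -1)


def fit_svm(
    X: np.ndarray,
    y: Sequence[float],
    kernel: str,
    C: float,
    gamma: float | None = None,
    feature_indices: Sequence[int] | None = None,
) -> SvmModel:
    """Fit a soft-margin SVM (linear or RBF kernel) at fixed (C, gamma)."""
    if kernel not in ("linear", "rbf"):
        raise ValueError(f"unknown kernel {kernel!r}")
    if C <= 0:
        raise ValueError("C must be positive")
    if kernel == "rbf":
        if gamma is None or gamma <= 0:
            raise ValueError("rbf kernel requires positive gamma")
    elif gamma is not None:
        raise ValueError("gamma is only meaningful for the rbf kernel")
    X = np.asarray(X, dtype=float)
    y = _check_two_class(np.asarray(y))
    mean, scale, zero_var = _standardize_fit(X)
    Xs = _standardize_apply(X, mean, scale, zero_var)
    svc = SVC(kernel=kernel, C=C,
              gamma=gamma if kernel == "rbf" else "scale")
    svc.fit(Xs, y)
    idx = tuple(int(i) for i in feature_indices) \
        if feature_indices is not None else None
    return SvmModel(svc=svc, kernel=kernel, C=C, gamma=gamma,
                    feature_indices=idx, mean=mean, scale=scale,
                    zero_variance=zero_var)


@dataclass(frozen=True)
class SvmSpec:
    """Kernel and hyperparameter grid for SVM tuning.

    Default grids are the nine integer powers of two spanning 2^-4..2^4,
    giving 9 candidates for the linear kernel and 81 (C, gamma) pairs for
    the RBF kernel.
    """

    kernel: str = "linear"
    C_grid: tuple[float, ...] = DEFAULT_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GRID

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if any(c <= 0 for c in self.C_grid) or \
                any(g <= 0 for g in self.gamma_grid):
            raise ValueError("grid values must be positive")

    def grid(self) -> list[tuple[float, float | None]]:
        """(C, gamma) candidates in ascending (C, gamma) order, so that the
        first strict improvement wins and ties prefer smaller C then
        smaller gamma."""
        if self.kernel == "linear":
            return [(C, None) for C in sorted(self.C_grid)]
        return [(C, g) for C in sorted(self.C_grid)
                for g in sorted(self.gamma_grid)]


def tune_svm(
    X: np.ndarray,
    y: Sequence[float],
    spec: SvmSpec,
    inner_k: int = 5,
    seed: int = 0,
    feature_indices: Sequence[int] | None = None,
) -> SvmModel:
    """Select (C, gamma) by stratified inner-CV balanced accuracy on the
    training partition only, then refit the winner on all training rows.

    Ties are broken toward smaller C, then smaller gamma. If a class has
    fewer members than ``inner_k`` the number of inner splits is reduced to
    the minority class size (logged), which at the limit is leave-one-out
    within that class.
    """
    X = np.asarray(X, dtype=float)
    y = _check_two_class(np.asarray(y))
    min_class = int(min(np.sum(y == 1), np.sum(y == -1)))
    k_eff = min(inner_k, min_class)
    if k_eff < inner_k:
        logger.warning("minority class (%d) smaller than inner_k=%d; "
                       "using %d inner splits", min_class, inner_k, k_eff)
    if k_eff < 2:
        raise ValueError("each class needs >= 2 members for inner CV")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True,
                          random_state=int(seed) % (2 ** 31))
    splits = list(skf.split(X, y))

    results: list[tuple[float, float | None, float]] = []
    best_score, best_params = -math.inf, None
    for C, gamma in spec.grid():
        fold_scores = []
        for train, val in splits:
            model = fit_svm(X[train], y[train], spec.kernel, C, gamma)
            preds = predict_classes(model, X[val])
            fold_scores.append(balanced_accuracy_score(y[val], preds))
        score = float(np.mean(fold_scores))
        results.append((C, gamma, score))
        if score > best_score:
            best_score, best_params = score, (C, gamma)

    C, gamma = best_params
    final = fit_svm(X, y, spec.kernel, C, gamma,
                    feature_indices=feature_indices)
    final.inner_results = results
    return final
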