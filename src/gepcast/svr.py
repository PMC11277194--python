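"""Epsilon-insensitive support-vector regression with an RBF kernel.

This stage models the residuals the symbolic-regression expression
leaves behind.  Fitting is delegated to a standard dual solver
(scikit-learn's SVR, i.e. libsvm); the fitted model is stored here in
explicit form — support points, their dual coefficients and the bias —
so that prediction is a plain kernel expansion

    f(x) = sum_i alpha_i exp(-gamma ||x - s_i||^2) + b

that serializes to plain text and has no runtime dependency on the
solver's internal state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVR

__all__ = ["SvrParams", "SvrModel", "fit_svr", "predict_svr"]


@dataclass(frozen=True)
class SvrParams:
    """RBF-SVR hyperparameters.

    Defaults are the tuned values of the hybrid pest model: cost
    ``C = 10``, kernel width ``gamma = 0.001``; the insensitive-tube
    half-width defaults to 0.1.
    """

    cost: float = 10.0
    gamma: float = 0.001
    epsilon_tube: float = 0.1

    def __post_init__(self) -> None:
        if self.cost <= 0:
            raise ValueError("cost must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.epsilon_tube < 0:
            raise ValueError("epsilon_tube must be non-negative")


@dataclass
class SvrModel:
    """Fitted regressor in explicit kernel-expansion form."""

    support_points: np.ndarray  # (n_sv, d)
    support_coefficients: np.ndarray  # (n_sv,)
    bias: float
    params: SvrParams

    @property
    def n_features(self) -> int:
        return int(self.support_points.shape[1])


def fit_svr(
    features: np.ndarray, targets: np.ndarray, params: SvrParams | None = None
) -> SvrModel:
    """Fit epsilon-SVR and return the explicit-form model.

    Inputs are expected on a comparable scale (the pipeline normalizes
    features to [0, 1] upstream).  The solver tolerance is tightened so
    the fit is reproducible and independent of sample order to high
    precision.
    """
    params = params or SvrParams()
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in training data")
    if len(y) < 2:
        raise ValueError("need at least 2 samples")
    solver = SVR(
        kernel="rbf",
        C=params.cost,
        gamma=params.gamma,
        epsilon=params.epsilon_tube,
        tol=1e-8,
        max_iter=-1,
    )
    solver.fit(X, y)
    return SvrModel(
        support_points=solver.support_vectors_.copy(),
        support_coefficients=solver.dual_coef_.ravel().copy(),
        bias=float(solver.intercept_[0]),
        params=params,
    )


def predict_svr(model: SvrModel, features: np.ndarray) -> np.ndarray:
    """Kernel-expansion prediction; empty input yields an empty array."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] == 0:
        return np.zeros(0)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1]}"
        )
    # squared distances via the expansion ||x||^2 - 2 x.s + ||s||^2
    sq = (
        np.sum(X**2, axis=1)[:, None]
        - 2.0 * X @ model.support_points.T
        + np.sum(model.support_points**2, axis=1)[None, :]
    )
    K = np.exp(-model.params.gamma * np.maximum(sq, 0.0))
    return K @ model.support_coefficients + model.bias
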