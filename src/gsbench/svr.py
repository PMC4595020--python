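"""Epsilon-insensitive support vector regression with four kernels.

Kernels follow the libsvm menu: linear u'v, polynomial (gamma u'v + r)^d,
radial exp(-gamma ||u - v||^2), and sigmoid tanh(gamma u'v + r).  The dual
problem (box constraints [0, C] on alpha and alpha*, equality constraint
sum(alpha - alpha*) = 0) is solved by libsvm via scikit-learn; the fitted
model exposes the dual coefficients, bias, and support vectors so that the
KKT-feasibility invariants can be verified directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.svm import SVR as _SkSVR

from .linear import _as_matrix, _as_vector

_KERNELS = ("linear", "polynomial", "radial", "sigmoid")
_SK_NAMES = {"linear": "linear", "polynomial": "poly", "radial": "rbf",
             "sigmoid": "sigmoid"}


@dataclass
class KernelSpec:
    kind: str = "radial"
    gamma: float | None = None  # None -> 1 / n_features
    coef0: float = 0.0
    degree: int = 3

    def __post_init__(self) -> None:
        if self.kind not in _KERNELS:
            raise ValueError(f"kernel must be one of {_KERNELS}")
        if self.gamma is not None and self.gamma <= 0 and self.kind != "linear":
            raise ValueError("gamma must be positive")
        if self.degree < 1:
            raise ValueError("degree must be a positive integer")

    def resolve_gamma(self, n_features: int) -> float:
        return self.gamma if self.gamma is not None else 1.0 / n_features


def compute_kernel(A, B, spec: KernelSpec) -> np.ndarray:
    """Kernel matrix K[i, j] = k(A_i, B_j) for the requested kernel."""
    A = _as_matrix(A)
    B = _as_matrix(B)
    if A.shape[1] != B.shape[1]:
        raise ValueError("feature dimensions differ between A and B")
    gamma = spec.resolve_gamma(A.shape[1])
    dots = A @ B.T
    if spec.kind == "linear":
        return dots
    if spec.kind == "polynomial":
        return (gamma * dots + spec.coef0) ** spec.degree
    if spec.kind == "radial":
        sq = (
            (A**2).sum(axis=1)[:, None]
            - 2.0 * dots
            + (B**2).sum(axis=1)[None, :]
        )
        K = np.exp(-gamma * np.maximum(sq, 0.0))
        if A is B:  # self-distance is exactly zero
            np.fill_diagonal(K, 1.0)
        return K
    return np.tanh(gamma * dots + spec.coef0)


@dataclass
class SvrModel:
    """Fitted epsilon-SVR in dual form."""

    dual_coefficients: np.ndarray  # alpha - alpha*, full training length
    bias: float
    support_indices: np.ndarray
    C: float
    epsilon: float
    kernel: KernelSpec
    X_train: np.ndarray
    x_means: np.ndarray | None = None
    x_scales: np.ndarray | None = None

    def predict(self, X) -> np.ndarray:
        return predict_svr(self, X)


def fit_svr(
    X, y, spec: KernelSpec | None = None, C: float = 1.0, epsilon: float = 0.1,
    standardize: bool = True,
) -> SvrModel:
    """Solve the epsilon-SVR dual with box constraint [0, C] per sample."""
    spec = spec or KernelSpec()
    X = _as_matrix(X)
    y = _as_vector(y)
    if C <= 0:
        raise ValueError("C must be positive")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    if standardize:
        x_means = X.mean(axis=0)
        x_scales = X.std(axis=0, ddof=0)
        x_scales[x_scales == 0] = 1.0
        Xs = (X - x_means) / x_scales
    else:
        x_means = x_scales = None
        Xs = X
    sk = _SkSVR(
        kernel=_SK_NAMES[spec.kind],
        gamma=spec.resolve_gamma(X.shape[1]),
        coef0=spec.coef0,
        degree=spec.degree,
        C=C,
        epsilon=epsilon,
        tol=1e-6,
        max_iter=-1,
    )
    sk.fit(Xs, y)
    dual = np.zeros(len(y))
    dual[sk.support_] = sk.dual_coef_.ravel()
    return SvrModel(
        dual_coefficients=dual,
        bias=float(sk.intercept_[0]),
        support_indices=sk.support_.copy(),
        C=C,
        epsilon=epsilon,
        kernel=spec,
        X_train=Xs,
        x_means=x_means,
        x_scales=x_scales,
    )


def predict_svr(model: SvrModel, X_new) -> np.ndarray:
    """f(x) = sum_i (alpha_i - alpha_i*) K(x_i, x) + b."""
    X_new = _as_matrix(X_new)
    if X_new.shape[1] != model.X_train.shape[1]:
        raise ValueError("feature dimension mismatch")
    if model.x_means is not None:
        X_new = (X_new - model.x_means) / model.x_scales
    K = compute_kernel(X_new, model.X_train, model.kernel)
    return K @ model.dual_coefficients + model.bias


class SVRGS(BaseEstimator, RegressorMixin):
    """Epsilon-SVR wrapper over the four-kernel menu."""

    def __init__(self, kernel: str = "radial", gamma: float | None = None,
                 coef0: float = 0.0, degree: int = 3, C: float = 1.0,
                 epsilon: float = 0.1, standardize: bool = True):
        self.kernel = kernel
        self.gamma = gamma
        self.coef0 = coef0
        self.degree = degree
        self.C = C
        self.epsilon = epsilon
        self.standardize = standardize

    def fit(self, X, y):
        spec = KernelSpec(kind=self.kernel, gamma=self.gamma, coef0=self.coef0,
                          degree=self.degree)
        self.model_ = fit_svr(X, y, spec, C=self.C, epsilon=self.epsilon,
                              standardize=self.standardize)
        return self

    def predict(self, X):
        return predict_svr(self.model_, X)
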