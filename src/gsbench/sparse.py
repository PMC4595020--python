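"""Sparse and greedy regression: Elastic Net / LASSO and adaptive FoBa.

The Elastic Net objective used here is

    min_b ||y - X b||^2 + lambda1 ||b||_1 + lambda2 ||b||_2^2

with centered (and by default standardized) predictors and centered response.
Rather than fixing lambda1, the model is parameterized by the *sparsity* --
the desired number of selected predictors -- and the solution is read off the
piecewise-linear regularization path at the first point whose active set has
that size.  The path is computed by LARS on the ridge-augmented system
[X; sqrt(lambda2) I], which reduces the Elastic Net to a LASSO problem with
the identical objective.  lambda2 = 0 gives the plain LASSO path, which
cannot select more than min(n - 1, p) predictors.

FoBa is the adaptive forward-backward greedy algorithm: each forward step adds
the feature with the largest squared-error decrease; after every forward step,
backward steps repeatedly remove the feature whose removal increases the
squared error least, as long as that increase is at most
backward_tolerance x the last forward decrease.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import lars_path

from .linear import _as_matrix, _as_vector, ridge_solve


@dataclass
class EnConfig:
    sparsity: int
    lambda2: float = 0.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.sparsity < 0:
            raise ValueError("sparsity must be non-negative")
        if self.lambda2 < 0:
            raise ValueError("lambda2 must be non-negative")


@dataclass
class SparseModel:
    """Sparse linear model with the selection path that produced it."""

    mu: float
    beta: np.ndarray
    support: np.ndarray
    path_trace: list[tuple[int, str, int, float]] = field(default_factory=list)
    x_means: np.ndarray | None = None
    x_scales: np.ndarray | None = None

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X)
        if self.x_means is not None:
            X = X - self.x_means
        if self.x_scales is not None:
            X = X / self.x_scales
        return self.mu + X @ self.beta


def _standardize(X, standardize: bool):
    xbar = X.mean(axis=0)
    Xc = X - xbar
    if standardize:
        scales = Xc.std(axis=0, ddof=0)
        scales[scales == 0] = 1.0
    else:
        scales = np.ones(X.shape[1])
    return Xc / scales, xbar, scales


def fit_elastic_net(X, y, cfg: EnConfig) -> SparseModel:
    """Elastic Net solved along the LARS-EN path, stopped at the requested
    number of selected predictors."""
    X = _as_matrix(X)
    y = _as_vector(y)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite entries in X or y")
    n, p = X.shape
    if cfg.sparsity > p:
        raise ValueError(f"sparsity {cfg.sparsity} exceeds feature count {p}")
    if cfg.lambda2 == 0 and cfg.sparsity > min(n - 1, p):
        raise ValueError(
            "LASSO cannot select more nonzero coefficients than the number of "
            f"samples (requested {cfg.sparsity} > min(n - 1, p) = {min(n - 1, p)})"
        )
    Xs, xbar, scales = _standardize(X, cfg.standardize)
    ybar = float(y.mean())
    yc = y - ybar

    if cfg.sparsity == 0:
        beta = np.zeros(p)
        return SparseModel(
            mu=ybar, beta=beta, support=np.array([], dtype=int),
            x_means=xbar, x_scales=scales,
        )

    if cfg.lambda2 > 0:
        X_aug = np.vstack([Xs, np.sqrt(cfg.lambda2) * np.eye(p)])
        y_aug = np.concatenate([yc, np.zeros(p)])
    else:
        X_aug, y_aug = Xs, yc

    alphas, _, coefs = lars_path(X_aug, y_aug, method="lasso", alpha_min=0.0)
    nnz = (coefs != 0).sum(axis=0)
    hits = np.flatnonzero(nnz == cfg.sparsity)
    if hits.size:
        j = int(hits[0])
    else:  # path never reaches the requested size; take its densest point
        j = int(np.argmax(nnz))
    beta = coefs[:, j]
    support = np.flatnonzero(beta)
    trace = []
    prev: set[int] = set()
    for step in range(1, j + 1):
        cur = set(np.flatnonzero(coefs[:, step]))
        for f in sorted(cur - prev):
            trace.append((step, "add", int(f), float(alphas[step])))
        for f in sorted(prev - cur):
            trace.append((step, "remove", int(f), float(alphas[step])))
        prev = cur
    return SparseModel(
        mu=ybar, beta=beta, support=support, path_trace=trace,
        x_means=xbar, x_scales=scales,
    )


def fit_lasso(X, y, sparsity: int, standardize: bool = True) -> SparseModel:
    return fit_elastic_net(X, y, EnConfig(sparsity=sparsity, lambda2=0.0,
                                          standardize=standardize))


def en_objective(X, y, model: SparseModel, lambda1: float, lambda2: float) -> float:
    """Elastic-Net objective at a fitted model (on the standardized scale)."""
    X = _as_matrix(X)
    y = _as_vector(y)
    Xs = (X - model.x_means) / model.x_scales
    r = (y - y.mean()) - Xs @ model.beta
    return float(r @ r + lambda1 * np.abs(model.beta).sum()
                 + lambda2 * model.beta @ model.beta)


# ---------------------------------------------------------------------------
# FoBa
# ---------------------------------------------------------------------------


def fit_foba(
    X,
    y,
    max_features: int,
    backward_tolerance: float = 0.5,
    min_improvement: float = 1e-10,
) -> SparseModel:
    """Adaptive forward-backward greedy least-squares regression.

    Forward ties are broken by the lowest column index.  The forward loop
    terminates at ``max_features`` active features or when the best available
    squared-error decrease falls below ``min_improvement * ||y_c||^2``.
    """
    X = _as_matrix(X)
    y = _as_vector(y)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite entries in X or y")
    n, p = X.shape
    if max_features > p:
        raise ValueError("max_features exceeds feature count")
    xbar = X.mean(axis=0)
    Xc = X - xbar
    ybar = float(y.mean())
    yc = y - ybar
    sst = float(yc @ yc)
    floor = min_improvement * max(sst, 1e-300)

    active: list[int] = []
    trace: list[tuple[int, str, int, float]] = []
    step = 0

    def sse_for(idx: list[int]) -> float:
        if not idx:
            return sst
        coef, *_ = np.linalg.lstsq(Xc[:, idx], yc, rcond=None)
        r = yc - Xc[:, idx] @ coef
        return float(r @ r)

    sse = sst
    while len(active) < max_features:
        # forward: exact SSE decrease for every candidate via orthogonalization
        if active:
            Q, _ = np.linalg.qr(Xc[:, active])
            Z = Xc - Q @ (Q.T @ Xc)
            r = yc - Q @ (Q.T @ yc)
        else:
            Z = Xc
            r = yc
        num = (r @ Z) ** 2
        den = np.einsum("ij,ij->j", Z, Z)
        gains = np.where(den > 1e-12, num / np.maximum(den, 1e-300), -np.inf)
        gains[active] = -np.inf
        best = int(np.argmax(gains))  # argmax returns the lowest tied index
        gain = float(gains[best])
        if not np.isfinite(gain) or gain <= floor:
            break
        step += 1
        active.append(best)
        sse = sse_for(active)
        trace.append((step, "add", best, sse))

        # backward: remove while the SSE increase stays within tolerance
        while len(active) > 1:
            increases = []
            for pos, feat in enumerate(active):
                rest = active[:pos] + active[pos + 1 :]
                increases.append((sse_for(rest) - sse, feat, pos))
            inc, feat, pos = min(increases, key=lambda t: (t[0], t[1]))
            if inc <= backward_tolerance * gain:
                step += 1
                del active[pos]
                sse = sse + inc
                trace.append((step, "remove", feat, sse))
            else:
                break

    beta = np.zeros(p)
    if active:
        coef, *_ = np.linalg.lstsq(Xc[:, active], yc, rcond=None)
        beta[active] = coef
    mu = ybar - xbar @ beta
    return SparseModel(
        mu=mu, beta=beta, support=np.array(sorted(active), dtype=int),
        path_trace=trace,
    )


# ---------------------------------------------------------------------------
# sklearn-style wrappers
# ---------------------------------------------------------------------------


class ElasticNetGS(BaseEstimator, RegressorMixin):
    """Elastic Net parameterized by selected-predictor count and lambda2."""

    def __init__(self, sparsity: int = 50, lambda2: float = 1.0,
                 standardize: bool = True):
        self.sparsity = sparsity
        self.lambda2 = lambda2
        self.standardize = standardize

    def fit(self, X, y):
        cfg = EnConfig(sparsity=min(self.sparsity, _as_matrix(X).shape[1]),
                       lambda2=self.lambda2, standardize=self.standardize)
        self.model_ = fit_elastic_net(X, y, cfg)
        self.selected_ = self.model_.support
        return self

    def predict(self, X):
        return self.model_.predict(X)


class LassoGS(ElasticNetGS):
    def __init__(self, sparsity: int = 50, standardize: bool = True):
        super().__init__(sparsity=sparsity, lambda2=0.0, standardize=standardize)


class FoBa(BaseEstimator, RegressorMixin):
    """Adaptive forward-backward greedy regression."""

    def __init__(self, max_features: int = 50, backward_tolerance: float = 0.5):
        self.max_features = max_features
        self.backward_tolerance = backward_tolerance

    def fit(self, X, y):
        self.model_ = fit_foba(
            X, y,
            max_features=min(self.max_features, _as_matrix(X).shape[1]),
            backward_tolerance=self.backward_tolerance,
        )
        self.selected_ = self.model_.support
        return self

    def predict(self, X):
        return self.model_.predict(X)
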