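"""Ridge / rrBLUP / GBLUP machinery.

The marker-effects model is y = mu*1 + X beta + e with beta ~ N(0, sigma_b2 I)
and e ~ N(0, sigma_e2 I).  Writing g = X beta and K = Xc Xc'/c this is the
individual-level (GBLUP) model y = mu*1 + g + e, g ~ N(0, sigma_a2 K) with
sigma_a2 = c * sigma_b2.  Restricted maximum likelihood for the two variance
components is computed by a spectral decomposition of K followed by a 1-D
search over the variance ratio delta = sigma_e2 / sigma_a2 (EMMA-style).

The BLUP solution for beta equals ridge regression with penalty
lambda = c * sigma_e2 / sigma_a2 and an unpenalized intercept, which is the
classical ridge <-> rrBLUP <-> GBLUP equivalence chain exercised by the tests.
Note the convention: the penalty uses the residual-to-additive variance ratio
sigma_e2/sigma_a2 (the form also used by the rrBLUP R package), not its
inverse.

Pairwise epistasis is modeled by augmenting the k raw markers with the
k(k-1)/2 products x_i * x_j (i < j, raw dosages).  The 'implicit' solver never
materializes those columns: the Gram matrix of the augmented features has the
closed form  K = M + (M*M - M2)/2  with M = X X' and M2 = (X*X)(X*X)'
(elementwise squares), so the kernel system is assembled in O(n^2) memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .data import GenotypeMatrix, PhenotypeVector


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    log_likelihood: float

    def __post_init__(self) -> None:
        if self.sigma_a2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")
        if self.sigma_a2 == 0 and self.sigma_e2 == 0:
            raise ValueError("variance components cannot both be zero")

    @property
    def heritability(self) -> float:
        h2 = self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)
        return float(min(max(h2, 0.0), 1.0))


@dataclass
class MarkerEffectsModel:
    """Fitted linear marker-effects model: mu + per-feature effect vector."""

    mu: float
    beta: np.ndarray
    variance: VarianceComponents | None = None
    marker_ids: list[str] | None = None

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X)
        return self.mu + X @ self.beta


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, GenotypeMatrix):
        return np.asarray(X.values, dtype=float)
    return np.asarray(X, dtype=float)


def _as_vector(y) -> np.ndarray:
    if isinstance(y, PhenotypeVector):
        return np.asarray(y.values, dtype=float)
    return np.asarray(y, dtype=float)


# ---------------------------------------------------------------------------
# Ridge
# ---------------------------------------------------------------------------


def ridge_solve(X, y, lam: float) -> MarkerEffectsModel:
    """Penalized least squares: min ||y - mu - X b||^2 + lam ||b||^2.

    The intercept is unpenalized.  lam = 0 falls back to (minimum-norm) least
    squares on the centered system.
    """
    X = _as_matrix(X)
    y = _as_vector(y)
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("non-finite entries in X or y")
    if lam < 0:
        raise ValueError("ridge penalty must be non-negative")
    n, p = X.shape
    xbar = X.mean(axis=0)
    Xc = X - xbar
    ybar = y.mean()
    yc = y - ybar
    if lam == 0:
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    elif p <= n:
        beta = np.linalg.solve(Xc.T @ Xc + lam * np.eye(p), Xc.T @ yc)
    else:  # dual form for p > n
        alpha = np.linalg.solve(Xc @ Xc.T + lam * np.eye(n), yc)
        beta = Xc.T @ alpha
    mu = ybar - xbar @ beta
    return MarkerEffectsModel(mu=float(mu), beta=beta)


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------


def _kernel_scale(X, kind: str = "trace") -> float:
    """Kinship normalization constant c.

    'vanraden': c = sum 2 p_k (1 - p_k) with p_k the observed allele frequency
    (appropriate for dosage matrices); 'trace': c = trace(Xc Xc')/n, which
    makes mean(diag K) = 1 for arbitrary feature matrices.
    """
    X = _as_matrix(X)
    Xc = X - X.mean(axis=0)
    if kind == "vanraden":
        p = X.mean(axis=0) / 2.0
        c = float(np.sum(2.0 * p * (1.0 - p)))
    elif kind == "trace":
        c = float(np.einsum("ij,ij->", Xc, Xc) / X.shape[0])
    else:
        raise ValueError(f"unknown kernel scale {kind!r}")
    if c <= 0:
        raise ValueError("degenerate feature matrix: kinship scale is zero")
    return c


def _restricted_spectrum(K: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues of K restricted to the orthogonal complement of the
    intercept, and the squared projections of y onto those eigenvectors."""
    n = len(y)
    Q, _ = np.linalg.qr(np.ones((n, 1)), mode="complete")
    A = Q[:, 1:]  # orthonormal basis with A' 1 = 0
    M = A.T @ K @ A
    evals, evecs = np.linalg.eigh((M + M.T) / 2.0)
    lam = np.clip(evals, 0.0, None)
    eta2 = (evecs.T @ (A.T @ y)) ** 2
    return lam, eta2


def _reml_kernel(K: np.ndarray, y: np.ndarray) -> VarianceComponents:
    """REML for y = mu + g + e, g ~ N(0, sigma_a2 K), intercept-only fixed
    effects, via eigendecomposition and a 1-D search over
    delta = sigma_e2/sigma_a2 on a log scale in [1e-9, 1e9]."""
    n = len(y)
    if n < 3:
        raise ValueError("REML needs at least 3 samples")
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant; variance components undefined")
    lam, eta2 = _restricted_spectrum(K, y)
    m = n - 1

    def neg_restricted_ll(log_delta: float) -> float:
        d = np.exp(log_delta)
        denom = lam + d
        s = np.sum(eta2 / denom)
        return 0.5 * (m * np.log(s) + np.sum(np.log(denom)))

    grid = np.linspace(np.log(1e-9), np.log(1e9), 61)
    vals = [neg_restricted_ll(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        neg_restricted_ll, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise RuntimeError(f"REML ratio search failed: {res.message}")
    delta = float(np.exp(res.x))
    sigma_a2 = float(np.sum(eta2 / (lam + delta)) / m)
    sigma_e2 = delta * sigma_a2
    const = 0.5 * m * (np.log(m / (2 * np.pi)) - 1.0)
    ll = const - float(res.fun)
    return VarianceComponents(sigma_a2=sigma_a2, sigma_e2=sigma_e2, log_likelihood=ll)


def reml_variance_components(X, y, scale: str = "trace") -> VarianceComponents:
    """REML variance components of the single-random-effect marker model."""
    X = _as_matrix(X)
    y = _as_vector(y)
    c = _kernel_scale(X, scale)
    Xc = X - X.mean(axis=0)
    K = Xc @ Xc.T / c
    return _reml_kernel(K, y)


def restricted_log_likelihood(X, y, ratio: float, scale: str = "trace") -> float:
    """Restricted log-likelihood at a fixed ratio delta = sigma_e2/sigma_a2
    (profiled over sigma_a2); used for optimizer sanity checks."""
    X = _as_matrix(X)
    y = _as_vector(y)
    c = _kernel_scale(X, scale)
    Xc = X - X.mean(axis=0)
    K = Xc @ Xc.T / c
    n = len(y)
    lam, eta2 = _restricted_spectrum(K, y)
    m = n - 1
    denom = lam + ratio
    s = np.sum(eta2 / denom)
    const = 0.5 * m * (np.log(m / (2 * np.pi)) - 1.0)
    return const - 0.5 * (m * np.log(s) + np.sum(np.log(denom)))


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


class RRBlup(BaseEstimator, RegressorMixin):
    """Ridge-regression BLUP of marker effects with REML variance components.

    Parameters
    ----------
    scale : {'vanraden', 'trace'}
        Kinship normalization used for the REML kernel.  Only the reported
        variance components depend on it; predictions do not.
    """

    def __init__(self, scale: str = "vanraden"):
        self.scale = scale

    def fit(self, X, y):
        X = _as_matrix(X)
        y = _as_vector(y)
        if X.shape[0] != len(y):
            raise ValueError("X and y have mismatched sample counts")
        vc = reml_variance_components(X, y, scale=self.scale)
        c = _kernel_scale(X, self.scale)
        lam = c * vc.sigma_e2 / max(vc.sigma_a2, 1e-300)
        model = ridge_solve(X, y, lam)
        self.model_ = MarkerEffectsModel(
            mu=model.mu, beta=model.beta, variance=vc
        )
        self.mu_ = model.mu
        self.beta_ = model.beta
        self.variance_ = vc
        self.lambda_ = lam
        return self

    def predict(self, X):
        return self.model_.predict(X)


class GBLUP(BaseEstimator, RegressorMixin):
    """Genomic BLUP: y = mu + g + e with g ~ N(0, sigma_a2 K).

    K is the VanRaden genomic relationship matrix Xc Xc'/c computed from the
    training dosages (c = sum 2 p_k (1-p_k) by default).  Prediction for new
    individuals uses the cross-kinship with the training set, so unphenotyped
    individuals can be scored after the fit.
    """

    def __init__(self, scale: str = "vanraden"):
        self.scale = scale

    def fit(self, X, y):
        X = _as_matrix(X)
        y = _as_vector(y)
        c = _kernel_scale(X, self.scale)
        self._xbar = X.mean(axis=0)
        Xc = X - self._xbar
        K = Xc @ Xc.T / c
        vc = _reml_kernel(K, y)
        self.variance_ = vc
        self.mu_ = float(y.mean())  # GLS intercept reduces to the mean (K 1 = 0)
        V = vc.sigma_a2 * K + vc.sigma_e2 * np.eye(len(y))
        self._w = np.linalg.solve(V, y - self.mu_)
        self.genetic_values_ = vc.sigma_a2 * (K @ self._w)
        self._Xc_train = Xc
        self._c = c
        self.K_ = K
        return self

    def predict(self, X):
        X = _as_matrix(X)
        K_new = (X - self._xbar) @ self._Xc_train.T / self._c
        return self.mu_ + self.variance_.sigma_a2 * (K_new @ self._w)

    @property
    def heritability_(self) -> float:
        return self.variance_.heritability


def fit_rrblup(g, y, scale: str = "vanraden") -> MarkerEffectsModel:
    return RRBlup(scale=scale).fit(g, y).model_


def fit_gblup(g, y, scale: str = "vanraden") -> tuple[np.ndarray, VarianceComponents]:
    est = GBLUP(scale=scale).fit(g, y)
    return est.genetic_values_, est.variance_


def estimate_heritability(g, y, scale: str = "vanraden") -> float:
    """Narrow-sense h2 = sigma_a2 / (sigma_a2 + sigma_e2) from the GBLUP REML
    fit, clamped to [0, 1]."""
    _, vc = fit_gblup(g, y, scale=scale)
    return vc.heritability


# ---------------------------------------------------------------------------
# Pairwise epistasis
# ---------------------------------------------------------------------------


def expand_epistasis(
    g, block_size: int = 512, max_features: int = 2_000_000
) -> np.ndarray:
    """Augment k markers with all k(k-1)/2 pairwise dosage products.

    Columns: the k originals followed by x_i * x_j for i < j in lexicographic
    order.  Products are generated in column blocks so peak memory stays
    proportional to n * block_size during assembly.
    """
    X = _as_matrix(g)
    n, k = X.shape
    n_pairs = k * (k - 1) // 2
    total = k + n_pairs
    if total > max_features:
        raise ValueError(
            f"{total} expanded features exceed the cap ({max_features}); "
            "use the implicit (kernel) epistasis solver instead"
        )
    out = np.empty((n, total), dtype=float)
    out[:, :k] = X
    col = k
    buf: list[np.ndarray] = []
    for i in range(k - 1):
        block = X[:, i][:, None] * X[:, i + 1 :]
        buf.append(block)
        if sum(b.shape[1] for b in buf) >= block_size or i == k - 2:
            chunk = np.concatenate(buf, axis=1)
            out[:, col : col + chunk.shape[1]] = chunk
            col += chunk.shape[1]
            buf = []
    return out


def _epistasis_gram(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Gram matrix of [markers | pairwise products] between sample sets A, B
    without materializing the product columns."""
    M = A @ B.T
    M2 = (A**2) @ (B**2).T
    return M + (M * M - M2) / 2.0


class EpistasisRRBlup(BaseEstimator, RegressorMixin):
    """rrBLUP on markers plus all pairwise interaction features.

    mode='explicit' materializes the augmented feature matrix and reuses
    :class:`RRBlup`; mode='implicit' solves the equivalent n x n kernel system
    (see module docstring) and never forms the interaction columns.  Both
    modes produce the same predictions up to numerical tolerance.
    """

    def __init__(self, mode: str = "implicit", max_features: int = 2_000_000):
        self.mode = mode
        self.max_features = max_features

    def fit(self, X, y):
        X = _as_matrix(X)
        y = _as_vector(y)
        if self.mode == "explicit":
            Z = expand_epistasis(X, max_features=self.max_features)
            self._inner = RRBlup(scale="trace").fit(Z, y)
            self.variance_ = self._inner.variance_
            return self
        if self.mode != "implicit":
            raise ValueError(f"unknown mode {self.mode!r}")
        self._X_train = X
        n = X.shape[0]
        K_raw = _epistasis_gram(X, X)
        # center the (implicit) feature columns by their training means
        self._row_means = K_raw.mean(axis=0)
        self._grand_mean = K_raw.mean()
        Kc = (
            K_raw
            - self._row_means[None, :]
            - self._row_means[:, None]
            + self._grand_mean
        )
        c = float(np.trace(Kc) / n)
        if c <= 0:
            raise ValueError("degenerate epistasis kernel")
        Kc /= c
        vc = _reml_kernel(Kc, y)
        self.variance_ = vc
        self.mu_ = float(y.mean())
        V = vc.sigma_a2 * Kc + vc.sigma_e2 * np.eye(n)
        self._w = vc.sigma_a2 / c * np.linalg.solve(V, y - self.mu_)
        return self

    def predict(self, X):
        if self.mode == "explicit":
            return self._inner.predict(expand_epistasis(_as_matrix(X)))
        X = _as_matrix(X)
        K_new = _epistasis_gram(X, self._X_train)
        # center the implicit features by their training means on both sides
        Kc = (
            K_new
            - K_new.mean(axis=1, keepdims=True)
            - self._row_means[None, :]
            + self._grand_mean
        )
        return self.mu_ + Kc @ self._w


def fit_epistasis_rrblup(g, y, mode: str = "implicit") -> EpistasisRRBlup:
    return EpistasisRRBlup(mode=mode).fit(g, y)
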