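"""Variable-selection front-ends: mutual information, mRMR, SIS/ISIS, PCA-FOBA.

Mutual information is the plug-in (maximum-likelihood) estimate in nats.
Genotype-genotype redundancy is computed directly on the {0, 1, 2} dosage
alphabet; marker-phenotype relevance first maps the continuous trait to the
ternary alphabet {-1, 0, 1} by z-score thresholding at +/-1 (sample standard
deviation, ddof = 1).

mRMR greedily selects the marker maximizing relevance minus mean redundancy
with the already-selected set; combined with rrBLUP on the selected columns it
forms the mRMR-GS prediction method, with the target size tuned by an internal
10-fold cross-validation on the training fold.  By default selection uses
training genotypes only; a transductive switch adds unlabeled test genotypes
to the redundancy estimation.

SIS screens predictors by |X'y| on unit-variance columns; ISIS iterates SIS on
ridge residuals, pooling the selected predictors across iterations.
PCA-FOBA computes principal-component scores transductively on the stacked
train + test matrix (as many components as samples) and runs FoBa on the
training-row scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .data import make_folds
from .linear import RRBlup, _as_matrix, _as_vector, ridge_solve
from .sparse import fit_foba


@dataclass
class MrmrConfig:
    candidate_target_sizes: tuple[int, ...] = (10, 25, 50, 100, 250, 500)
    inner_cv_folds: int = 10
    transductive: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inner_cv_folds < 2:
            raise ValueError("inner_cv_folds must be >= 2")
        if any(t < 1 for t in self.candidate_target_sizes):
            raise ValueError("candidate target sizes must be >= 1")


@dataclass
class SelectedFeatureSet:
    """Ordered selected feature indices with their selection-time scores."""

    order: np.ndarray
    scores: np.ndarray
    method: str = ""
    relevance_all: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(np.unique(self.order)) != len(self.order):
            raise ValueError("selected feature indices must be unique")
        if len(self.scores) != len(self.order):
            raise ValueError("one score per selected feature required")

    def __len__(self) -> int:
        return len(self.order)


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------


def mutual_information(x, y) -> float:
    """Plug-in mutual information (nats) of two discrete vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny) / len(x)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


def discretize_phenotype(y) -> np.ndarray:
    """Ternary z-score discretization: -1 if z < -1, +1 if z > 1, else 0."""
    y = _as_vector(y)
    if len(y) < 2:
        raise ValueError("need at least two values to discretize")
    sd = y.std(ddof=1)
    if sd == 0:
        return np.zeros(len(y), dtype=int)
    z = (y - y.mean()) / sd
    return np.where(z < -1, -1, np.where(z > 1, 1, 0)).astype(int)


def _mi_with_all(col: np.ndarray, X: np.ndarray) -> np.ndarray:
    """I(col; X[:, j]) for every column j, vectorized over the 3x3 (or fewer)
    contingency cells.  Both inputs must be small-integer coded."""
    n, p = X.shape
    col_vals = np.unique(col)
    x_vals = np.unique(X)
    joint = np.empty((len(col_vals), len(x_vals), p))
    for a, va in enumerate(col_vals):
        mask = (col == va).astype(float)
        for b, vb in enumerate(x_vals):
            joint[a, b] = mask @ (X == vb)
    joint /= n
    pa = joint.sum(axis=1)  # (len(col_vals), p)
    pb = joint.sum(axis=0)  # (len(x_vals), p)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint / (pa[:, None, :] * pb[None, :, :])
        terms = np.where(joint > 0, joint * np.log(ratio), 0.0)
    return terms.sum(axis=(0, 1))


def relevance_scores(X, y_discrete) -> np.ndarray:
    """I(x_j; c) for every marker column j against the discretized trait."""
    X = np.asarray(_as_matrix(X), dtype=int)
    return _mi_with_all(np.asarray(y_discrete, dtype=int), X)


def mrmr_select(g, y, target_size: int, X_extra=None) -> SelectedFeatureSet:
    """Greedy mRMR selection of ``target_size`` markers.

    The first marker maximizes I(x; c); each subsequent marker maximizes
    I(x_j; c) - mean_{i in S} I(x_j; x_i).  Redundancy is computed on the raw
    dosage alphabet; if ``X_extra`` (unlabeled genotypes) is given it joins
    the redundancy estimation (transductive mode).  Ties break to the lowest
    marker index.
    """
    X = np.asarray(_as_matrix(g), dtype=int)
    n, p = X.shape
    if target_size > p:
        raise ValueError(f"target_size {target_size} exceeds marker count {p}")
    y = _as_vector(y)
    c = discretize_phenotype(y) if not np.issubdtype(np.asarray(y).dtype, np.integer) else y
    relevance = _mi_with_all(np.asarray(c, dtype=int), X)
    X_red = X if X_extra is None else np.vstack([X, np.asarray(_as_matrix(X_extra), dtype=int)])

    order: list[int] = []
    scores: list[float] = []
    red_sum = np.zeros(p)
    available = np.ones(p, dtype=bool)
    for m in range(target_size):
        if m == 0:
            crit = relevance.copy()
        else:
            crit = relevance - red_sum / m
        crit[~available] = -np.inf
        j = int(np.argmax(crit))
        order.append(j)
        scores.append(float(crit[j]))
        available[j] = False
        red_sum += _mi_with_all(X_red[:, j], X_red)
    return SelectedFeatureSet(
        order=np.array(order), scores=np.array(scores), method="mrmr",
        relevance_all=relevance,
    )


class MrmrGS(BaseEstimator, RegressorMixin):
    """mRMR feature selection followed by rrBLUP on the selected markers.

    The target size is tuned by an internal cross-validation on the training
    fold: mRMR runs once per inner fold up to the largest candidate size, each
    candidate size is scored by the signed r^2 of the concatenated inner
    predictions (selection-order prefixes reuse the single run), and the best
    size is re-selected on the full training fold.
    """

    transductive_capable = True

    def __init__(
        self,
        candidate_target_sizes: tuple[int, ...] = (10, 25, 50, 100, 250, 500),
        inner_cv_folds: int = 10,
        transductive: bool = False,
        seed: int = 0,
    ):
        self.candidate_target_sizes = candidate_target_sizes
        self.inner_cv_folds = inner_cv_folds
        self.transductive = transductive
        self.seed = seed

    def fit(self, X, y, X_unlabeled=None):
        from .evaluate import signed_r2  # local import to avoid a cycle

        X = _as_matrix(X)
        y = _as_vector(y)
        n, p = X.shape
        sizes = sorted({min(t, p) for t in self.candidate_target_sizes})
        extra = X_unlabeled if self.transductive else None
        if len(sizes) > 1:
            k = min(self.inner_cv_folds, n)
            folds = make_folds(range(n), k=k, seed=self.seed)
            preds = {t: np.empty(n) for t in sizes}
            t_max = max(sizes)
            for f in range(1, k + 1):
                tr = folds.train_indices(f)
                te = folds.test_indices(f)
                sel = mrmr_select(X[tr], y[tr], t_max, X_extra=extra)
                for t in sizes:
                    cols = sel.order[:t]
                    model = RRBlup(scale="trace").fit(X[tr][:, cols], y[tr])
                    preds[t][te] = model.predict(X[te][:, cols])
            inner_scores = {t: signed_r2(y, preds[t]) for t in sizes}
            best = max(sizes, key=lambda t: (inner_scores[t], -t))
            self.inner_scores_ = inner_scores
        else:
            best = sizes[0]
            self.inner_scores_ = None
        self.target_size_ = best
        sel = mrmr_select(X, y, best, X_extra=extra)
        self.selected_features_ = sel
        self.selected_ = sel.order
        self.rrblup_ = RRBlup(scale="trace").fit(X[:, sel.order], y)
        return self

    def predict(self, X):
        X = _as_matrix(X)
        return self.rrblup_.predict(X[:, self.selected_])


def mrmr_gs_fit(g, y, cfg: MrmrConfig | None = None) -> MrmrGS:
    cfg = cfg or MrmrConfig()
    return MrmrGS(
        candidate_target_sizes=cfg.candidate_target_sizes,
        inner_cv_folds=cfg.inner_cv_folds,
        transductive=cfg.transductive,
        seed=cfg.seed,
    ).fit(g, y)


# ---------------------------------------------------------------------------
# SIS / ISIS
# ---------------------------------------------------------------------------


def sis_select(X, y, T: int) -> SelectedFeatureSet:
    """Sure-independence screening: top T components of |X'y| on scaled X."""
    X = _as_matrix(X)
    y = _as_vector(y)
    if T < 1:
        raise ValueError("T must be >= 1")
    p = X.shape[1]
    if T > p:
        warnings.warn(f"T={T} exceeds {p} features; clamping to {p}")
        T = p
    omega = np.abs(X.T @ y)
    order = np.argsort(-omega, kind="stable")[:T]
    return SelectedFeatureSet(order=order, scores=omega[order], method="sis")


class IsisGS(BaseEstimator, RegressorMixin):
    """Iterated SIS with ridge regression on the growing predictor union.

    Each iteration screens the current response (the previous ridge fit's
    residuals) by |X'y|, then refits ridge on the union of everything selected
    so far.  Columns are scaled to unit variance before screening.  The ridge
    penalty is chosen by a small internal grid CV when not given.
    """

    def __init__(self, T: int = 1000, n_iterations: int = 3,
                 ridge_lambda: float | None = None, seed: int = 0):
        self.T = T
        self.n_iterations = n_iterations
        self.ridge_lambda = ridge_lambda
        self.seed = seed

    def _pick_lambda(self, X, y) -> float:
        from .evaluate import signed_r2

        n = X.shape[0]
        k = min(5, n)
        folds = make_folds(range(n), k=k, seed=self.seed)
        grid = [1e-2, 1e-1, 1.0, 10.0, 100.0]
        best_lam, best_score = grid[0], -np.inf
        for lam in grid:
            pred = np.empty(n)
            for f in range(1, k + 1):
                tr, te = folds.train_indices(f), folds.test_indices(f)
                m = ridge_solve(X[tr], y[tr], lam)
                pred[te] = m.predict(X[te])
            s = signed_r2(y, pred)
            if s > best_score:
                best_score, best_lam = s, lam
        return best_lam

    def fit(self, X, y):
        X = _as_matrix(X)
        y = _as_vector(y)
        xbar = X.mean(axis=0)
        scales = X.std(axis=0, ddof=0)
        scales[scales == 0] = 1.0
        Xs = (X - xbar) / scales
        self._xbar, self._scales = xbar, scales

        union: list[int] = []
        self.iteration_unions_ = []
        response = y - y.mean()
        for _ in range(self.n_iterations):
            sel = sis_select(Xs, response, self.T)
            new = [int(j) for j in sel.order if j not in set(union)]
            union.extend(new)
            lam = self.ridge_lambda
            if lam is None:
                lam = self._pick_lambda(Xs[:, union], y)
            model = ridge_solve(Xs[:, union], y, lam)
            response = y - model.predict(Xs[:, union])
            self.iteration_unions_.append(list(union))
            self._model, self._lambda = model, lam
        self.selected_ = np.array(union, dtype=int)
        self.selected_features_ = SelectedFeatureSet(
            order=self.selected_, scores=np.zeros(len(union)), method="isis"
        )
        return self

    def predict(self, X):
        X = _as_matrix(X)
        Xs = (X - self._xbar) / self._scales
        return self._model.predict(Xs[:, self.selected_])


# ---------------------------------------------------------------------------
# PCA-FOBA
# ---------------------------------------------------------------------------


class PcaFoba(BaseEstimator, RegressorMixin):
    """Transductive PCA followed by FoBa regression on component scores.

    Principal components are computed on the stacked training + unlabeled test
    genotypes (the defining transductive contract), keeping
    min(n_total, n_markers) components; FoBa then selects among the
    training-row scores.  Prediction projects new samples onto the same
    components, which for the unlabeled rows supplied at fit time reproduces
    their transductive scores exactly.
    """

    transductive_capable = True

    def __init__(self, max_features: int = 50, backward_tolerance: float = 0.5):
        self.max_features = max_features
        self.backward_tolerance = backward_tolerance

    def fit(self, X, y, X_unlabeled=None):
        if X_unlabeled is None:
            raise ValueError(
                "PcaFoba is transductive: unlabeled test genotypes must be "
                "passed to fit(X, y, X_unlabeled=...)"
            )
        X = _as_matrix(X)
        Xu = _as_matrix(X_unlabeled)
        y = _as_vector(y)
        stack = np.vstack([X, Xu])
        self._mean = stack.mean(axis=0)
        u, s, vt = np.linalg.svd(stack - self._mean, full_matrices=False)
        n_comp = min(stack.shape)
        self._components = vt[:n_comp].T  # (p, n_comp)
        scores_train = (X - self._mean) @ self._components
        self.n_components_ = n_comp
        self.model_ = fit_foba(
            scores_train, y,
            max_features=min(self.max_features, n_comp),
            backward_tolerance=self.backward_tolerance,
        )
        self.selected_ = self.model_.support
        return self

    def transform(self, X):
        return (_as_matrix(X) - self._mean) @ self._components

    def predict(self, X):
        return self.model_.predict(self.transform(X))


def pca_foba_fit(X_train, y_train, X_test, **kwargs) -> PcaFoba:
    return PcaFoba(**kwargs).fit(X_train, y_train, X_unlabeled=X_test)


def isis_fit(g, y, T: int = 1000, n_iterations: int = 3,
             ridge_lambda: float | None = None) -> IsisGS:
    return IsisGS(T=T, n_iterations=n_iterations, ridge_lambda=ridge_lambda).fit(g, y)
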