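"""Shared-fold cross-validation protocol and benchmark summaries.

Every prediction method is scored by ten-fold cross-validation on one
precomputed fold partition: per fold the model is trained on the other nine
folds and predicts the held-out fold; the ten out-of-fold prediction vectors
are concatenated and the signed r^2 (squared Pearson correlation, negated when
the correlation is negative) is computed against the ground truth.  Global
predictability trains and evaluates on all samples; its excess over the CV
score is the overfitting gap.  Method-by-dataset score tables are min-max
normalized per dataset column.  For feature-selecting methods the per-fold
selections feed a stability profile: the fraction of all selected features
that recur in at least k of the folds.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone

from .data import Dataset, FoldAssignment, make_folds
from .featsel import SelectedFeatureSet, discretize_phenotype, relevance_scores
from .linear import _as_matrix, _as_vector


def signed_r2(truth, prediction) -> float:
    """Squared Pearson correlation carrying the correlation's sign.

    Zero-variance predictions are scored 0 (the correlation is undefined;
    a constant predictor carries no ranking information).
    """
    t = _as_vector(truth)
    p = _as_vector(prediction)
    if t.shape != p.shape:
        raise ValueError("truth and prediction must have equal length")
    if len(t) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(t) == 0:
        raise ValueError("truth is constant; correlation undefined")
    if np.ptp(p) == 0:
        warnings.warn("prediction has zero variance; signed r^2 defined as 0")
        return 0.0
    r = float(np.corrcoef(t, p)[0, 1])
    return float(np.sign(r) * r**2)


@dataclass
class CvResult:
    method: str
    dataset: str
    trait: str
    per_fold_predictions: list[tuple[np.ndarray, np.ndarray]]
    concatenated_prediction: np.ndarray
    signed_r2: float
    per_fold_selected_features: list[SelectedFeatureSet] | None = None
    failures: list[str] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.failures


def _fit_fold(est, X_tr, y_tr, X_te):
    """Fit an estimator on a training fold, passing the unlabeled test
    genotypes when the method is transductive."""
    if getattr(est, "transductive_capable", False):
        est.fit(X_tr, y_tr, X_unlabeled=X_te)
    else:
        est.fit(X_tr, y_tr)
    return est


def run_cross_validation(
    X, y, estimator, folds: FoldAssignment,
    method: str = "", dataset: str = "", trait: str = "",
) -> CvResult:
    """Shared-fold K-fold CV with concatenated out-of-fold predictions."""
    X = _as_matrix(X)
    y = _as_vector(y)
    n = len(y)
    concat = np.full(n, np.nan)
    per_fold = []
    selections: list[SelectedFeatureSet] = []
    failures: list[str] = []
    for f in range(1, folds.k + 1):
        tr = folds.train_indices(f)
        te = folds.test_indices(f)
        est = clone(estimator)
        try:
            _fit_fold(est, X[tr], y[tr], X[te])
            pred = est.predict(X[te])
        except Exception as exc:  # method failure: record, continue
            failures.append(f"fold {f}: {exc}")
            pred = np.full(len(te), np.nan)
        concat[te] = pred
        per_fold.append((te, pred))
        sel = getattr(est, "selected_features_", None)
        if sel is None and getattr(est, "selected_", None) is not None:
            sel = SelectedFeatureSet(
                order=est.selected_, scores=np.zeros(len(est.selected_))
            )
        if sel is not None:
            selections.append(sel)
    score = np.nan
    if not failures:
        score = signed_r2(y, concat)
    return CvResult(
        method=method, dataset=dataset, trait=trait,
        per_fold_predictions=per_fold, concatenated_prediction=concat,
        signed_r2=score,
        per_fold_selected_features=selections or None,
        failures=failures,
    )


def global_predictability(X, y, estimator) -> float:
    """Signed r^2 of a model trained and evaluated on all samples."""
    X = _as_matrix(X)
    y = _as_vector(y)
    est = clone(estimator)
    _fit_fold(est, X, y, X)
    return signed_r2(y, est.predict(X))


def overfit_gap(global_r2: float, cv_r2: float) -> float:
    """Global minus 10CV signed r^2; positive values indicate optimism."""
    return global_r2 - cv_r2


# ---------------------------------------------------------------------------
# Benchmark tables
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkTable:
    scores: pd.DataFrame  # methods x datasets
    normalized: pd.DataFrame | None = None
    row_summary: pd.DataFrame | None = None
    column_summary: pd.DataFrame | None = None


def normalize_scores(table: BenchmarkTable) -> BenchmarkTable:
    """Min-max normalize each dataset column; attach margin summaries.

    Row summaries (min/avg/median/max/sd) are over normalized values; column
    summaries are over the raw scores.  A constant column maps to 0.5.
    """
    scores = table.scores
    if scores.size == 0:
        raise ValueError("empty benchmark table")
    norm = scores.copy().astype(float)
    for col in norm.columns:
        x = norm[col].to_numpy(dtype=float)
        lo, hi = np.nanmin(x), np.nanmax(x)
        if hi > lo:
            norm[col] = (x - lo) / (hi - lo)
        else:
            warnings.warn(f"constant score column {col!r}; normalized to 0.5")
            norm[col] = 0.5
    def _summary(df: pd.DataFrame, axis: int) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "min": df.min(axis=axis),
                "avg": df.mean(axis=axis),
                "median": df.median(axis=axis),
                "max": df.max(axis=axis),
                "sd": df.std(axis=axis, ddof=1),
            }
        )
    return BenchmarkTable(
        scores=scores,
        normalized=norm,
        row_summary=_summary(norm, axis=1),
        column_summary=_summary(scores, axis=0),
    )


# ---------------------------------------------------------------------------
# Feature-selection stability
# ---------------------------------------------------------------------------


def stability_ratio(per_fold_selections: list[SelectedFeatureSet], k: int) -> float:
    """Fraction of all selected features chosen in at least k folds.

    Fold counts are per feature: two features each present in 8 folds need
    not share those folds.
    """
    K = len(per_fold_selections)
    if not 1 <= k <= K:
        raise ValueError(f"k must lie in 1..{K}")
    counts: dict[int, int] = {}
    for sel in per_fold_selections:
        for f in np.unique(sel.order):
            counts[int(f)] = counts.get(int(f), 0) + 1
    if not counts:
        raise ValueError("no features were selected in any fold")
    total = len(counts)
    at_least_k = sum(1 for c in counts.values() if c >= k)
    return at_least_k / total


def stability_profile(per_fold_selections: list[SelectedFeatureSet]) -> dict[int, float]:
    K = len(per_fold_selections)
    return {k: stability_ratio(per_fold_selections, k) for k in range(K, 0, -1)}


# ---------------------------------------------------------------------------
# Relevance profiles
# ---------------------------------------------------------------------------


def relevance_profile(X, y, top_q: int = 5) -> tuple[np.ndarray, float]:
    """Per-marker relevance I(x_j; c), sorted descending, plus a concentration
    statistic: mean of the top-q scores over the overall mean."""
    scores = relevance_scores(_as_matrix(X).astype(int), discretize_phenotype(y))
    curve = np.sort(scores)[::-1]
    overall = curve.mean()
    conc = float(curve[:top_q].mean() / overall) if overall > 0 else np.inf
    return curve, conc


# ---------------------------------------------------------------------------
# Benchmark driver
# ---------------------------------------------------------------------------


def method_registry() -> dict:
    """Name -> zero-argument estimator factory for all benchmark methods."""
    from .bayes import BayesA, BayesB, BayesCPi, BayesianLasso
    from .featsel import IsisGS, MrmrGS, PcaFoba
    from .linear import EpistasisRRBlup, GBLUP, RRBlup
    from .sparse import ElasticNetGS, FoBa, LassoGS
    from .svr import SVRGS

    return {
        "rrblup": RRBlup,
        "gblup": GBLUP,
        "epistasis_rrblup": EpistasisRRBlup,
        "bayes_a": BayesA,
        "bayes_b": BayesB,
        "bayes_cpi": BayesCPi,
        "blasso": BayesianLasso,
        "elastic_net": ElasticNetGS,
        "lasso": LassoGS,
        "foba": FoBa,
        "svr_linear": lambda **kw: SVRGS(kernel="linear", **kw),
        "svr_polynomial": lambda **kw: SVRGS(kernel="polynomial", **kw),
        "svr_radial": lambda **kw: SVRGS(kernel="radial", **kw),
        "svr_sigmoid": lambda **kw: SVRGS(kernel="sigmoid", **kw),
        "mrmr": MrmrGS,
        "isis": IsisGS,
        "pca_foba": PcaFoba,
    }


def build_estimator(name: str, params: dict | None = None):
    registry = method_registry()
    if name not in registry:
        raise ValueError(f"unknown method {name!r}; known: {sorted(registry)}")
    return registry[name](**(params or {}))


def run_benchmark(
    datasets: dict[str, Dataset],
    methods: dict[str, dict | None],
    folds_seed: int = 0,
    k: int = 10,
    out_dir=None,
) -> dict:
    """Run every method on every dataset/trait with shared folds.

    Returns a dict with the raw/normalized tables, per-run CvResults, and
    stability profiles for feature-selecting methods.  If ``out_dir`` is
    given, TSV reports and a provenance JSON are written there.
    """
    results: dict[tuple[str, str], CvResult] = {}
    stability: dict[tuple[str, str], dict[int, float]] = {}
    heritabilities: dict[str, float] = {}
    columns: list[str] = []
    from .linear import estimate_heritability

    for ds_name, ds in datasets.items():
        folds = ds.folds or make_folds(ds.genotypes.sample_ids, k=k, seed=folds_seed)
        X = ds.genotypes
        for trait, ph in ds.phenotypes.items():
            col = f"{ds_name}:{trait}"
            columns.append(col)
            try:
                heritabilities[col] = estimate_heritability(X, ph)
            except Exception:
                heritabilities[col] = np.nan
            for m_name, params in methods.items():
                est = build_estimator(m_name, params)
                res = run_cross_validation(
                    X, ph, est, folds, method=m_name, dataset=ds_name, trait=trait
                )
                results[(m_name, col)] = res
                if res.per_fold_selected_features:
                    stability[(m_name, col)] = stability_profile(
                        res.per_fold_selected_features
                    )

    scores = pd.DataFrame(
        {
            col: [results[(m, col)].signed_r2 for m in methods]
            for col in columns
        },
        index=list(methods),
    )
    table = normalize_scores(BenchmarkTable(scores=scores))
    out = {
        "table": table,
        "results": results,
        "stability": stability,
        "heritability": heritabilities,
    }
    if out_dir is not None:
        _write_reports(out, out_dir, folds_seed)
    return out


def _write_reports(out: dict, out_dir, folds_seed: int) -> None:
    import pathlib

    d = pathlib.Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    table: BenchmarkTable = out["table"]
    table.scores.to_csv(d / "scores.tsv", sep="\t")
    table.normalized.to_csv(d / "normalized.tsv", sep="\t")
    rows = [
        {"method": m, "dataset": c, "k": k, "ratio": r}
        for (m, c), prof in out["stability"].items()
        for k, r in prof.items()
    ]
    pd.DataFrame(rows).to_csv(d / "stability.tsv", sep="\t", index=False)
    pd.Series(out["heritability"], name="h2").rename_axis("dataset").to_csv(
        d / "heritability.tsv", sep="\t"
    )
    config_hash = hashlib.sha256(
        table.scores.to_csv().encode()
    ).hexdigest()[:16]
    (d / "provenance.json").write_text(
        json.dumps(
            {"folds_seed": folds_seed, "scores_hash": config_hash,
             "methods": list(table.scores.index),
             "datasets": list(table.scores.columns)},
            indent=2,
        )
    )
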