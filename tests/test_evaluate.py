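import numpy as np
import pandas as pd
import pytest
from sklearn.base import BaseEstimator, RegressorMixin

from gsbench import (
    BenchmarkTable,
    RRBlup,
    global_predictability,
    make_folds,
    normalize_scores,
    overfit_gap,
    relevance_profile,
    run_benchmark,
    run_cross_validation,
    signed_r2,
    stability_profile,
    stability_ratio,
)
from gsbench.featsel import SelectedFeatureSet


class MeanPredictor(BaseEstimator, RegressorMixin):
    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(len(X), self.mean_)


class TestSignedR2:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 5.0, 3.0])
        assert signed_r2(y, y) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        y = np.array([1.0, 2.0, 5.0, 3.0])
        assert signed_r2(y, -y) == pytest.approx(-1.0)

    def test_hand_computed_case(self):
        assert signed_r2([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.36)

    def test_zero_variance_prediction_is_zero_with_warning(self):
        with pytest.warns(UserWarning, match="zero variance"):
            assert signed_r2([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]) == 0.0

    def test_constant_truth_errors(self):
        with pytest.raises(ValueError, match="constant"):
            signed_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_affine_invariance_and_sign_flip(self, rng):
        t = rng.normal(size=50)
        p = t + rng.normal(0, 0.5, 50)
        base = signed_r2(t, p)
        assert signed_r2(t, 3.0 * p + 7.0) == pytest.approx(base)
        assert signed_r2(t, -p) == pytest.approx(-base)


class TestCrossValidation:
    def test_constant_predictor_scores_zero(self, rng):
        class Zero(MeanPredictor):
            def fit(self, X, y):
                self.mean_ = 0.0
                return self

        X = rng.normal(size=(40, 5))
        y = rng.normal(size=40)
        folds = make_folds(range(40), k=10, seed=0)
        with pytest.warns(UserWarning):
            res = run_cross_validation(X, y, Zero(), folds)
        assert res.signed_r2 == 0.0

    def test_fold_mean_predictor_carries_no_signal(self, rng):
        # fold means differ slightly, so the concatenated prediction is not
        # exactly constant, but it carries (essentially) no information
        X = rng.normal(size=(200, 5))
        y = rng.normal(size=200)
        folds = make_folds(range(200), k=10, seed=0)
        res = run_cross_validation(X, y, MeanPredictor(), folds)
        assert abs(res.signed_r2) <= 0.05

    def test_concatenation_covers_every_sample_once(self, rng):
        X = rng.normal(size=(43, 5))
        y = X[:, 0] + rng.normal(size=43)
        folds = make_folds(range(43), k=10, seed=1)
        res = run_cross_validation(X, y, RRBlup(scale="trace"), folds)
        assert res.concatenated_prediction.shape == (43,)
        assert not np.isnan(res.concatenated_prediction).any()
        covered = np.concatenate([te for te, _ in res.per_fold_predictions])
        assert sorted(covered) == list(range(43))

    def test_failures_are_recorded_not_raised(self, rng):
        class Exploder(MeanPredictor):
            def fit(self, X, y):
                raise RuntimeError("boom")

        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        folds = make_folds(range(30), k=5, seed=0)
        res = run_cross_validation(X, y, Exploder(), folds)
        assert not res.complete
        assert len(res.failures) == 5
        assert np.isnan(res.signed_r2)

    def test_global_exceeds_cv_for_flexible_model(self, oligogenic_dataset):
        ds = oligogenic_dataset
        X = ds.genotypes
        y = ds.phenotypes["trait1"]
        est = RRBlup()
        cv = run_cross_validation(X, y, est, ds.folds).signed_r2
        glob = global_predictability(X, y, est)
        assert glob >= cv
        assert overfit_gap(glob, cv) == pytest.approx(glob - cv)

    def test_overfit_gap_arithmetic(self):
        assert overfit_gap(0.9, 0.3) == pytest.approx(0.6)
        assert overfit_gap(0.5, 0.5) == 0.0


class TestNormalization:
    def test_linear_rescale(self):
        t = BenchmarkTable(scores=pd.DataFrame({"d": [0.2, 0.4, 0.6]},
                                               index=["a", "b", "c"]))
        out = normalize_scores(t)
        np.testing.assert_allclose(out.normalized["d"], [0.0, 0.5, 1.0])

    def test_best_and_worst_hit_bounds(self, rng):
        scores = pd.DataFrame(rng.normal(size=(5, 3)),
                              index=list("abcde"), columns=list("xyz"))
        out = normalize_scores(BenchmarkTable(scores=scores))
        for col in "xyz":
            assert out.normalized[col].max() == pytest.approx(1.0)
            assert out.normalized[col].min() == pytest.approx(0.0)

    def test_uniform_winner_has_unit_row_average(self):
        scores = pd.DataFrame(
            {"d1": [0.9, 0.5, 0.1], "d2": [0.8, 0.2, 0.4]},
            index=["best", "mid", "other"],
        )
        out = normalize_scores(BenchmarkTable(scores=scores))
        assert out.row_summary.loc["best", "avg"] == pytest.approx(1.0)

    def test_constant_column_maps_to_half(self):
        scores = pd.DataFrame({"d": [0.3, 0.3]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_scores(BenchmarkTable(scores=scores))
        assert (out.normalized["d"] == 0.5).all()

    def test_idempotent_on_normalized_columns(self, rng):
        scores = pd.DataFrame(rng.random((4, 2)), columns=["u", "v"])
        once = normalize_scores(BenchmarkTable(scores=scores))
        twice = normalize_scores(BenchmarkTable(scores=once.normalized))
        pd.testing.assert_frame_equal(once.normalized, twice.normalized)

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            normalize_scores(BenchmarkTable(scores=pd.DataFrame()))


def _sel(indices):
    return SelectedFeatureSet(order=np.array(indices, dtype=int),
                              scores=np.zeros(len(indices)))


class TestStability:
    def test_all_features_in_all_folds(self):
        sels = [_sel([1, 2, 3])] * 10
        assert stability_ratio(sels, 10) == 1.0

    def test_eighty_percent_in_seven_folds(self):
        # 10 distinct features; 8 of them appear in >= 7 folds, 2 in fewer
        sels = []
        for f in range(10):
            chosen = list(range(8))  # features 0..7 in every fold
            if f < 3:
                chosen.append(8)  # feature 8 in 3 folds
            if f < 2:
                chosen.append(9)  # feature 9 in 2 folds
            sels.append(_sel(chosen))
        assert stability_ratio(sels, 7) == pytest.approx(0.8)

    def test_ratio_at_k1_is_one(self, rng):
        sels = [_sel(rng.choice(50, size=10, replace=False)) for _ in range(10)]
        assert stability_ratio(sels, 1) == 1.0

    def test_matches_bruteforce_on_random_logs(self, rng):
        sels = [_sel(rng.choice(30, size=8, replace=False)) for _ in range(10)]
        prof = stability_profile(sels)
        # brute force per-feature fold counting
        counts = {}
        for s in sels:
            for f in s.order:
                counts[int(f)] = counts.get(int(f), 0) + 1
        for k in range(1, 11):
            expected = sum(c >= k for c in counts.values()) / len(counts)
            assert prof[k] == pytest.approx(expected)

    def test_monotone_in_k(self, rng):
        sels = [_sel(rng.choice(30, size=8, replace=False)) for _ in range(10)]
        prof = stability_profile(sels)
        vals = [prof[k] for k in range(10, 0, -1)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestRelevanceProfile:
    def test_curve_non_increasing(self, oligogenic_dataset):
        ds = oligogenic_dataset
        curve, _ = relevance_profile(ds.genotypes, ds.phenotypes["trait1"])
        assert np.all(np.diff(curve) <= 1e-15)

    def test_oligogenic_concentration(self, oligogenic_dataset):
        ds = oligogenic_dataset
        _, conc = relevance_profile(ds.genotypes, ds.phenotypes["trait1"])
        assert conc >= 5.0

    def test_infinitesimal_trait_is_flatter_than_oligogenic(self, oligogenic_dataset):
        # the plug-in MI estimator has a noise floor: even a trait with no
        # concentrated signal shows top-5/mean around 3 at 200 markers, so the
        # check is the contrast against the oligogenic profile, not an
        # absolute flatness bound
        from gsbench.profiles import make_profile

        def mean_conc(profile):
            concs = []
            for seed in (17, 18, 19):
                ds = make_profile(profile, seed=seed, n_markers=200,
                                  offspring_per_generation=75)
                _, c = relevance_profile(ds.genotypes, ds.phenotypes["trait1"])
                concs.append(c)
            return float(np.mean(concs))

        conc_flat = mean_conc("polygenic")
        conc_oligo = mean_conc("oligogenic")
        assert conc_flat <= conc_oligo / 1.5
        assert conc_flat <= 4.5


class TestBenchmarkDriver:
    def test_shapes_folds_and_determinism(self, oligogenic_dataset, tmp_path):
        ds = oligogenic_dataset
        methods = {"rrblup": None, "lasso": {"sparsity": 10}}
        out1 = run_benchmark({"oligo": ds}, methods, out_dir=tmp_path / "r1")
        out2 = run_benchmark({"oligo": ds}, methods, out_dir=tmp_path / "r2")
        assert out1["table"].scores.shape == (2, 1)
        pd.testing.assert_frame_equal(out1["table"].scores, out2["table"].scores)
        assert (tmp_path / "r1" / "scores.tsv").read_text() == (
            tmp_path / "r2" / "scores.tsv"
        ).read_text()
        assert (tmp_path / "r1" / "provenance.json").exists()
        # the lasso selects features, so a stability profile must exist
        assert ("lasso", "oligo:trait1") in out1["stability"]
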