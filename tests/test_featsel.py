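import numpy as np
import pytest

from gsbench import (
    IsisGS,
    MrmrGS,
    PcaFoba,
    discretize_phenotype,
    mrmr_select,
    mutual_information,
    sis_select,
)
from gsbench.featsel import relevance_scores


class TestMutualInformation:
    def test_independent_by_construction_is_zero(self):
        # full product design over {0,1}^2: empirical joint factorizes exactly
        x = np.array([0, 0, 1, 1])
        y = np.array([0, 1, 0, 1])
        assert abs(mutual_information(x, y)) < 1e-12

    def test_self_information_is_entropy(self):
        x = np.array([0, 0, 1, 1])
        assert abs(mutual_information(x, x) - np.log(2)) < 1e-12

    def test_symmetry(self, rng):
        x = rng.integers(0, 3, size=100)
        y = rng.integers(0, 3, size=100)
        assert mutual_information(x, y) == pytest.approx(mutual_information(y, x))

    def test_nonnegative(self, rng):
        for _ in range(20):
            x = rng.integers(0, 3, size=30)
            y = rng.integers(0, 2, size=30)
            assert mutual_information(x, y) >= -1e-15

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information([0, 1], [0, 1, 2])

    def test_vectorized_matches_scalar(self, rng):
        X = rng.integers(0, 3, size=(60, 15))
        c = rng.integers(-1, 2, size=60)
        vec = relevance_scores(X, c)
        scalar = [mutual_information(X[:, j], c) for j in range(15)]
        np.testing.assert_allclose(vec, scalar, atol=1e-12)


class TestDiscretize:
    def test_zscore_mapping(self):
        # z-scores ~ (-1.41, 0, 0, 0, 1.41): tails map to -1 / +1, bulk to 0
        y = np.array([-4.0, 0.0, 0.0, 0.0, 4.0])
        assert list(discretize_phenotype(y)) == [-1, 0, 0, 0, 1]

    def test_constant_is_all_zero(self):
        assert np.all(discretize_phenotype(np.full(5, 3.3)) == 0)

    def test_hand_computed_zscores(self):
        # y = (0,0,0,0,10): sample sd -> z = (-0.447 x4, 1.789)
        y = np.array([0.0, 0.0, 0.0, 0.0, 10.0])
        assert list(discretize_phenotype(y)) == [0, 0, 0, 0, 1]


class TestMrmr:
    def test_first_pick_maximizes_relevance(self, rng):
        X = rng.integers(0, 3, size=(120, 12))
        y = 1.5 * X[:, 7] + rng.normal(0, 0.4, 120)
        sel = mrmr_select(X, y, 3)
        c = discretize_phenotype(y)
        rel = relevance_scores(X, c)
        assert sel.order[0] == np.argmax(rel)

    def test_sequence_matches_bruteforce_incremental_criterion(self, rng):
        X = rng.integers(0, 3, size=(80, 6))
        y = X[:, 1] - X[:, 4] + rng.normal(0, 0.5, 80)
        c = discretize_phenotype(y)
        sel = mrmr_select(X, y, 3)
        # brute force: evaluate the incremental criterion for every candidate
        chosen: list[int] = []
        for _ in range(3):
            best, best_val = None, -np.inf
            for j in range(6):
                if j in chosen:
                    continue
                rel = mutual_information(X[:, j], c)
                red = (
                    np.mean([mutual_information(X[:, j], X[:, i]) for i in chosen])
                    if chosen else 0.0
                )
                val = rel - red
                if val > best_val + 1e-12:
                    best, best_val = j, val
            chosen.append(best)
        assert list(sel.order) == chosen

    def test_duplicate_of_first_pick_penalized(self, rng):
        base = rng.integers(0, 3, size=100)
        other = rng.integers(0, 3, size=100)
        y = 1.0 * base + 0.5 * other + rng.normal(0, 0.3, 100)
        X = np.column_stack([base, base, other])  # col 1 duplicates col 0
        sel = mrmr_select(X, y, 2)
        assert sel.order[0] in (0, 1)
        assert sel.order[1] == 2  # the exact duplicate is never picked second

    def test_column_permutation_invariance(self, rng):
        X = rng.integers(0, 3, size=(90, 8))
        y = X[:, 2] - 2 * X[:, 5] + rng.normal(0, 0.3, 90)
        sel = mrmr_select(X, y, 4)
        perm = rng.permutation(8)
        sel_p = mrmr_select(X[:, perm], y, 4)
        assert [perm[j] for j in sel_p.order] == list(sel.order)


class TestMrmrGS:
    def test_single_candidate_size_skips_inner_cv(self, oligogenic_dataset):
        ds = oligogenic_dataset
        X = ds.genotypes.values
        y = ds.phenotypes["trait1"].values
        est = MrmrGS(candidate_target_sizes=(15,), seed=0).fit(X, y)
        assert est.target_size_ == 15
        assert est.inner_scores_ is None
        sel = mrmr_select(X, y, 15)
        assert list(est.selected_) == list(sel.order)

    def test_recovers_true_qtl(self, oligogenic_dataset):
        ds = oligogenic_dataset
        X = ds.genotypes.values
        y = ds.phenotypes["trait1"].values
        qtl = {i for i, _ in ds.architecture.additive_qtl}
        est = MrmrGS(candidate_target_sizes=(10, 25), inner_cv_folds=5, seed=1)
        est.fit(X, y)
        assert est.target_size_ in (10, 25)
        assert len(qtl & set(est.selected_.tolist())) >= 3


class TestSis:
    def test_full_ranking_when_T_equals_p(self, rng):
        X = rng.normal(size=(40, 6))
        X = (X - X.mean(0)) / X.std(0)
        y = rng.normal(size=40)
        sel = sis_select(X, y, T=6)
        omega = np.abs(X.T @ y)
        assert list(sel.order) == list(np.argsort(-omega, kind="stable"))

    def test_hand_computed_omega(self):
        X = np.array([[1.0, 0.0, 2.0], [0.0, 1.0, 1.0], [1.0, 1.0, 0.0]])
        y = np.array([1.0, 2.0, 3.0])
        sel = sis_select(X, y, T=3)
        omega_hand = np.abs(X.T @ y)  # (4, 5, 4)
        np.testing.assert_allclose(np.sort(sel.scores)[::-1], np.sort(omega_hand)[::-1])
        assert sel.order[0] == 1

    def test_dominant_feature_ranked_first(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.normal(size=(100, 50))
            X = (X - X.mean(0)) / X.std(0)
            y = X[:, 0] + r.normal(0, 0.2, 100)
            if sis_select(X, y, T=5).order[0] == 0:
                hits += 1
        assert hits == 10

    def test_T_clamped_with_warning(self, rng):
        X = rng.normal(size=(20, 5))
        with pytest.warns(UserWarning, match="clamping"):
            sel = sis_select(X, rng.normal(size=20), T=1000)
        assert len(sel) == 5

    def test_sure_screening_at_desk_scale(self):
        kept = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.normal(size=(200, 1000))
            causal = r.choice(1000, 5, replace=False)
            beta = np.zeros(1000)
            beta[causal] = 0.5 * np.sign(r.normal(size=5)) * (1 + r.random(5))
            y = X @ beta + r.normal(size=200)
            Xs = (X - X.mean(0)) / X.std(0)
            sel = sis_select(Xs, y, T=100)
            kept.append(np.isin(causal, sel.order).mean())
        assert np.mean(kept) >= 0.9


class TestIsis:
    def test_no_screening_reduces_to_least_squares(self, rng):
        X = rng.normal(size=(60, 8))
        y = X @ rng.normal(size=8) + rng.normal(0, 0.3, 60)
        est = IsisGS(T=8, n_iterations=1, ridge_lambda=1e-10).fit(X, y)
        D = np.column_stack([np.ones(60), X])
        coef = np.linalg.solve(D.T @ D, D.T @ y)
        np.testing.assert_allclose(est.predict(X), D @ coef, atol=1e-5)

    def test_residual_screening_finds_second_feature(self, rng):
        n = 300
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        y = 2.0 * a + 0.4 * b
        noise = rng.normal(size=(n, 4)) * 0.05
        X = np.column_stack([a, b, noise])
        est = IsisGS(T=1, n_iterations=2, ridge_lambda=1e-6).fit(X, y)
        assert est.iteration_unions_[0] == [0]
        assert set(est.iteration_unions_[1]) == {0, 1}

    def test_union_never_shrinks(self, oligogenic_dataset):
        ds = oligogenic_dataset
        X = ds.genotypes.values.astype(float)
        y = ds.phenotypes["trait1"].values
        est = IsisGS(T=20, n_iterations=3, ridge_lambda=1.0).fit(X, y)
        sizes = [len(u) for u in est.iteration_unions_]
        assert sizes == sorted(sizes)


class TestPcaFoba:
    def test_component_count_is_min_samples_markers(self, rng):
        X = rng.normal(size=(10, 50))
        Xu = rng.normal(size=(5, 50))
        y = rng.normal(size=10)
        est = PcaFoba(max_features=3).fit(X, y, X_unlabeled=Xu)
        assert est.n_components_ == 15

    def test_scores_match_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(4, 6))
        y = rng.normal(size=4)
        Xu = rng.normal(size=(2, 6))
        est = PcaFoba(max_features=2).fit(X, y, X_unlabeled=Xu)
        stack = np.vstack([X, Xu])
        Sc = stack - stack.mean(axis=0)
        evals, evecs = np.linalg.eigh(Sc.T @ Sc)
        order = np.argsort(evals)[::-1]
        scores_pkg = est.transform(X)
        scores_oracle = Sc[:4] @ evecs[:, order[: est.n_components_]]
        for k in range(est.n_components_):
            col = scores_pkg[:, k]
            ocol = scores_oracle[:, k]
            assert min(np.abs(col - ocol).max(), np.abs(col + ocol).max()) < 1e-8

    def test_dominant_component_selected_first(self, rng):
        u = rng.normal(size=50)
        v = rng.normal(size=30)
        X = np.outer(u, v) + rng.normal(0, 1e-3, (50, 30))
        y = u.copy()
        est = PcaFoba(max_features=2).fit(X[:40], y[:40], X_unlabeled=X[40:])
        assert est.model_.path_trace[0][1:3] == ("add", 0)

    def test_missing_unlabeled_matrix_errors(self, rng):
        with pytest.raises(ValueError, match="transductive"):
            PcaFoba().fit(rng.normal(size=(10, 4)), rng.normal(size=10))
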