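"""Cohort statistics: gated tests, correlations, PAF/promax, group scores."""

import numpy as np
import pandas as pd
import pytest

from fibroquant import stats
from fibroquant import synthetic as syn


class TestTwoGroupTest:
    def test_identical_groups_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = stats.two_group_test(x, x.copy())
        assert res.p > 0.99

    def test_constant_equal_groups_p_one(self):
        res = stats.two_group_test(np.ones(5), np.ones(6))
        assert res.p == 1.0

    def test_clear_separation_uses_t_branch(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 20)
        y = rng.normal(3, 1, 20)
        res = stats.two_group_test(x, y)
        assert res.branch == "t"
        assert res.p < 0.001

    def test_heavy_tails_select_mannwhitney_branch(self):
        rng = np.random.default_rng(1)
        x = rng.standard_cauchy(50)
        y = rng.standard_cauchy(50) + 5
        res = stats.two_group_test(x, y)
        assert res.branch == "mannwhitney"

    def test_small_samples_skip_normality_gate(self):
        # n < 8: the omnibus test is invalid, nonparametric branch mandatory
        res = stats.two_group_test([1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0])
        assert res.branch == "mannwhitney"
        assert res.normality_p == (None, None)

    def test_branch_is_pure_function_of_gate(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 30)
        y = rng.normal(1, 1, 30)
        from scipy.stats import normaltest
        expect_t = (normaltest(x).pvalue > 0.05) and (normaltest(y).pvalue > 0.05)
        res = stats.two_group_test(x, y)
        assert (res.branch == "t") == expect_t

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            stats.two_group_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCorrelate:
    def test_perfect_linear_relation(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
        r, r2, p = stats.correlate(t, "a", "b")
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(3)
        t = pd.DataFrame({"a": rng.normal(size=200), "b": rng.normal(size=200)})
        r, r2, p = stats.correlate(t, "a", "b")
        assert abs(r) < 0.2

    def test_symmetry_and_r_squared_identity(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=30)
        t = pd.DataFrame({"a": a, "b": a + rng.normal(0, 0.5, 30)})
        r_ab, r2_ab, _ = stats.correlate(t, "a", "b")
        r_ba, r2_ba, _ = stats.correlate(t, "b", "a")
        assert r_ab == r_ba
        assert r2_ab == r_ab**2

    def test_pairwise_complete_handling(self):
        t = pd.DataFrame({"a": [1.0, 2.0, np.nan, 4.0, 5.0],
                          "b": [2.0, 4.0, 6.0, 8.0, np.nan]})
        r, *_ = stats.correlate(t, "a", "b")
        assert r == pytest.approx(1.0)

    def test_strong_correlation_regime_at_small_n(self):
        # bivariate normal with rho = 0.87 sampled at n = 15: over many draws
        # the mean R^2 sits near 0.75
        rng = np.random.default_rng(5)
        rho = 0.87
        r2s = []
        for _ in range(1000):
            x = rng.standard_normal(15)
            y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(15)
            r = np.corrcoef(x, y)[0, 1]
            r2s.append(r * r)
        assert np.mean(r2s) == pytest.approx(0.7527, abs=0.05)

    def test_zero_variance_rejected(self):
        t = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="zero-variance"):
            stats.correlate(t, "a", "b")


class TestBHAdjust:
    def test_monotone_and_bounded(self):
        p = np.array([0.001, 0.02, 0.04, 0.8])
        adj = stats.bh_adjust(p)
        assert np.all(adj >= p)
        assert np.all(adj <= 1.0)
        # step-up: adjusted values ordered like raw ones
        assert np.all(np.diff(adj[np.argsort(p)]) >= 0)

    def test_matches_hand_computation(self):
        p = np.array([0.01, 0.04, 0.03, 0.005])
        adj = stats.bh_adjust(p)
        # sorted raw: .005, .01, .03, .04 -> n/k * p: .02, .02, .04, .04
        np.testing.assert_allclose(np.sort(adj), [0.02, 0.02, 0.04, 0.04])


class TestPAF:
    def test_identity_matrix_gives_null_model(self):
        L, h2 = stats.paf(np.eye(5), 2)
        assert np.abs(h2).max() < 1e-6
        assert np.abs(L).max() < 1e-3

    def test_single_factor_closed_form(self):
        # uniform loadings 0.8: R = 0.64 off-diagonal
        p = 6
        R = np.full((p, p), 0.64)
        np.fill_diagonal(R, 1.0)
        L, h2 = stats.paf(R, 1)
        np.testing.assert_allclose(L[:, 0], 0.8, atol=1e-4)
        np.testing.assert_allclose(h2, 0.64, atol=1e-4)

    def test_population_two_factor_recovery(self):
        Ltrue = np.array([[0.8, 0.0], [0.7, 0.0], [0.0, 0.8], [0.0, 0.7]])
        R = Ltrue @ Ltrue.T
        np.fill_diagonal(R, 1.0)
        L, h2 = stats.paf(R, 2)
        P, phi = stats.promax(L)
        assert stats.congruence(Ltrue, P) > 0.99

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            stats.paf(np.array([[1.0, 0.5], [0.4, 1.0]]), 1)  # asymmetric
        with pytest.raises(ValueError):
            stats.paf(np.eye(3), 0)


class TestPromax:
    def test_simple_structure_is_fixed_point(self):
        L = np.array([[0.8, 0.0], [0.75, 0.0], [0.7, 0.05],
                      [0.0, 0.8], [0.05, 0.75], [0.0, 0.7]])
        P, phi = stats.promax(L)
        assert stats.congruence(L, P) > 0.99

    def test_correlated_factors_recovered(self):
        # plant factor correlation 0.5, n = 500
        rng = np.random.default_rng(6)
        Ltrue = np.array([[0.8, 0.0], [0.7, 0.0], [0.75, 0.0],
                          [0.0, 0.8], [0.0, 0.7], [0.0, 0.75]])
        phi_true = np.array([[1.0, 0.5], [0.5, 1.0]])
        chol = np.linalg.cholesky(phi_true)
        F = rng.standard_normal((500, 2)) @ chol.T
        X = F @ Ltrue.T + rng.normal(0, np.sqrt(0.3), (500, 6))
        R = np.corrcoef(X, rowvar=False)
        L, _ = stats.paf(R, 2)
        P, phi = stats.promax(L)
        assert abs(abs(phi[0, 1]) - 0.5) < 0.15

    def test_kappa_choice_does_not_flip_structure(self):
        L = np.array([[0.8, 0.0], [0.7, 0.1], [0.75, 0.0],
                      [0.0, 0.8], [0.1, 0.7], [0.0, 0.75]])
        P2, _ = stats.promax(L, kappa=2)
        P4, _ = stats.promax(L, kappa=4)
        assert stats.congruence(P2, P4) > 0.98

    def test_matches_statsmodels_rotation(self):
        from statsmodels.multivariate.factor_rotation import promax as sm_promax

        rng = np.random.default_rng(7)
        Ltrue = np.array([[0.8, 0.0], [0.7, 0.0], [0.75, 0.1],
                          [0.0, 0.8], [0.0, 0.7], [0.1, 0.75]])
        X = rng.standard_normal((400, 2)) @ Ltrue.T + rng.normal(0, 0.5, (400, 6))
        R = np.corrcoef(X, rowvar=False)
        L, _ = stats.paf(R, 2)
        ours, _ = stats.promax(L, kappa=4)
        theirs, _ = sm_promax(L, k=4)
        assert stats.congruence(theirs, ours) > 0.98

    def test_degenerate_loadings_rejected(self):
        with pytest.raises(ValueError):
            stats.promax(np.zeros((4, 2)))
        with pytest.raises(ValueError):
            stats.promax(np.ones((4, 1)))


class TestScreeSelect:
    def test_direct_count(self):
        assert stats.scree_select([2.5, 1.3, 0.4, 0.1]) == 2

    def test_boundary_inclusive(self):
        # identity correlation matrix: all eigenvalues exactly 1
        lam = np.linalg.eigvalsh(np.eye(6))
        assert stats.scree_select(lam) == 6

    def test_invariant_to_variable_order_and_sign(self):
        table = syn.gen_cohort(syn.default_cohort_truth(100, seed=13))
        cols = [f"var_{i}" for i in range(1, 5)]
        X = table[cols].to_numpy()
        lam1 = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
        Xp = X[:, [2, 0, 3, 1]] * np.array([1, -1, 1, -1])
        lam2 = np.sort(np.linalg.eigvalsh(np.corrcoef(Xp, rowvar=False)))[::-1]
        assert stats.scree_select(lam1) == stats.scree_select(lam2)
        np.testing.assert_allclose(lam1, lam2, atol=1e-12)

    def test_default_synthetic_cohort_returns_two(self):
        table = syn.gen_cohort(syn.default_cohort_truth(100, seed=0))
        model = stats.fit_factor_model(table, n_factors="auto")
        assert model.n_factors == 2


class TestGroupScores:
    def _model(self, variables, pattern):
        return stats.FactorModel(
            variables=tuple(variables),
            eigenvalues=np.array([2.0, 1.0]),
            n_factors=pattern.shape[1],
            pattern=pattern,
            communalities=np.full(len(variables), 0.5),
            factor_correlations=np.eye(pattern.shape[1]),
        )

    def test_equal_loadings_give_plain_mean(self):
        rng = np.random.default_rng(8)
        t = pd.DataFrame({"subject": [f"s{i}" for i in range(10)],
                          "group": ["a"] * 5 + ["b"] * 5,
                          "x": rng.normal(size=10), "y": rng.normal(size=10)})
        model = self._model(["x", "y"], np.array([[0.7], [0.7]]))
        # single factor: widen pattern artificially to satisfy n_factors >= 1
        model = stats.FactorModel(
            variables=("x", "y"), eigenvalues=np.array([1.5, 0.5]), n_factors=1,
            pattern=np.array([[0.7], [0.7]]), communalities=np.array([0.5, 0.5]),
            factor_correlations=np.eye(1),
        )
        gs = stats.group_scores(t, model)
        X = t[["x", "y"]].to_numpy()
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        np.testing.assert_allclose(gs.scores["factor_1"], Z.mean(axis=1), atol=1e-12)

    def test_single_loading_selects_one_variable(self):
        rng = np.random.default_rng(9)
        t = pd.DataFrame({"subject": [f"s{i}" for i in range(8)],
                          "group": ["a"] * 4 + ["b"] * 4,
                          "x": rng.normal(size=8), "y": rng.normal(size=8),
                          "z": rng.normal(size=8)})
        model = self._model(["x", "y", "z"],
                            np.array([[1.0, 0.0], [0.0, 0.9], [0.0, 0.4]]))
        gs = stats.group_scores(t, model)
        X = t["x"].to_numpy()
        zx = (X - X.mean()) / X.std(ddof=1)
        np.testing.assert_allclose(gs.scores["factor_1"], zx, atol=1e-12)

    def test_group_shift_separates_only_shifted_factor(self):
        # the shifted factor must always separate; the untouched factor's p is
        # uniform under the null, so require non-significance in most runs
        # rather than gambling a single seed on a 5%-level fluctuation
        shift = {"non-IPF": np.zeros(4), "IPF": np.array([1.2, 1.2, 0.0, 0.0])}
        null_ok = 0
        for seed in range(10):
            table = syn.gen_cohort(
                syn.default_cohort_truth(60, seed=seed, group_shift=shift))
            model = stats.fit_factor_model(table, n_factors=2)
            gs = stats.group_scores(table, model)
            # identify the factor aligned with the shifted variables (var_1, var_2)
            shifted = int(np.argmax(np.abs(model.pattern[0])))
            ps = []
            for j in range(2):
                a = gs.scores.loc[gs.scores["group"] == "non-IPF", f"factor_{j + 1}"]
                b = gs.scores.loc[gs.scores["group"] == "IPF", f"factor_{j + 1}"]
                ps.append(stats.two_group_test(a.to_numpy(), b.to_numpy()).p)
            assert ps[shifted] < 0.01, f"seed {seed}"
            null_ok += ps[1 - shifted] > 0.05
        assert null_ok >= 8

    def test_missing_subjects_excluded_and_logged(self):
        table = syn.gen_cohort(syn.default_cohort_truth(20, seed=11))
        table.loc[3, "var_2"] = np.nan
        model = stats.fit_factor_model(table, n_factors=2)
        with pytest.warns(UserWarning, match="excluded"):
            gs = stats.group_scores(table, model)
        assert table.loc[3, "subject"] in gs.excluded_subjects
        assert len(gs.scores) == len(table) - 1


class TestRecoveryAcrossSeeds:
    def test_planted_loadings_recovered_20_seeds(self):
        Ltrue = np.array([[0.8, 0.0], [0.7, 0.0], [0.0, 0.8], [0.0, 0.7]])
        for seed in range(20):
            table = syn.gen_cohort(syn.default_cohort_truth(250, seed=seed))
            with pytest.warns(UserWarning):
                model = stats.fit_factor_model(table, n_factors=2)
            assert stats.congruence(Ltrue, model.pattern) > 0.95, f"seed {seed}"
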