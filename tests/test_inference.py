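"""Tests for cluster-mass permutation inference, LOSO extraction and the
nested explanatory models."""

import numpy as np
import pytest
from scipy import stats

import helilearn as hl
from helilearn import inference


class TestSmoothing:
    def test_width_one_is_identity(self):
        x = np.random.default_rng(0).normal(size=(4, 20))
        np.testing.assert_array_equal(inference.smooth_across_bins(x, 1), x)

    def test_constant_rows_unchanged(self):
        x = np.full((2, 15), 3.7)
        np.testing.assert_allclose(inference.smooth_across_bins(x, 5), x)

    def test_moving_average_with_edge_truncation(self):
        got = inference.smooth_across_bins(np.array([0.0, 0.0, 3.0, 0.0, 0.0]), 3)
        np.testing.assert_allclose(got, [0.0, 1.0, 1.0, 1.0, 0.0])

    def test_rejects_even_or_oversized_width(self):
        x = np.zeros((2, 10))
        with pytest.raises(ValueError):
            inference.smooth_across_bins(x, 4)
        with pytest.raises(ValueError):
            inference.smooth_across_bins(x, 11)


class TestClusterPermutation:
    def test_uniform_strong_effect_spans_all_bins(self):
        rng = np.random.default_rng(1)
        data = 1.0 + 0.05 * rng.normal(size=(10, 90))
        res = inference.cluster_mass_permutation_test(data, n_permutations=500,
                                                      seed=0)
        assert len(res.clusters) == 1
        start, end, _, p = res.clusters[0]
        assert (start, end) == (0, 89)
        # smallest achievable level: only sign assignments equivalent to the
        # observed one (all-plus / all-minus, prob 2/2^10 per draw) can match
        # the observed mass
        assert p < 0.02

    def test_identical_groups_rarely_significant(self):
        rng = np.random.default_rng(2)
        hits = 0
        for i in range(10):
            pooled = rng.normal(size=(16, 90))
            res = inference.cluster_mass_permutation_test(
                pooled[:8], pooled[8:], n_permutations=200, seed=i)
            hits += any(p < 0.05 for *_, p in res.clusters)
        assert hits <= 2

    def test_null_familywise_rate_near_alpha(self):
        rng = np.random.default_rng(3)
        hits = 0
        for i in range(60):
            data = rng.normal(size=(12, 90))
            res = inference.cluster_mass_permutation_test(data,
                                                          n_permutations=200,
                                                          seed=i)
            hits += any(p < 0.05 for *_, p in res.clusters)
        assert hits <= 8  # ~5% expected; binomial slack

    def test_shift_invariance_of_two_group_test(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(6, 30))
        b = rng.normal(size=(6, 30)) + 0.8
        r1 = inference.cluster_mass_permutation_test(a, b, 300, seed=9)
        r2 = inference.cluster_mass_permutation_test(a + 5.0, b + 5.0, 300,
                                                     seed=9)
        assert len(r1.clusters) == len(r2.clusters)
        for c1, c2 in zip(r1.clusters, r2.clusters):
            assert c1[:2] == c2[:2]
            assert c1[2] == pytest.approx(c2[2], rel=1e-12)
            assert c1[3] == c2[3]

    def test_subject_order_does_not_change_observed_clusters(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(10, 40)) + np.linspace(0, 1, 40)
        r1 = inference.cluster_mass_permutation_test(a, n_permutations=400,
                                                     seed=3)
        perm = rng.permutation(10)
        r2 = inference.cluster_mass_permutation_test(a[perm],
                                                     n_permutations=400, seed=3)
        assert [c[:2] for c in r1.clusters] == [c[:2] for c in r2.clusters]
        for c1, c2 in zip(r1.clusters, r2.clusters):
            assert c1[2] == pytest.approx(c2[2], rel=1e-12)
            assert c1[3] == pytest.approx(c2[3], abs=0.05)

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            inference.cluster_mass_permutation_test(np.zeros((1, 10)))

    def test_few_permutations_warns(self):
        rng = np.random.default_rng(6)
        with pytest.warns(UserWarning):
            inference.cluster_mass_permutation_test(rng.normal(size=(5, 10)),
                                                    n_permutations=50)


class TestLoso:
    def test_concentrated_difference_selects_that_bin(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(8, 20), scale=0.1)
        b = rng.normal(size=(8, 20), scale=0.1)
        b[:, 7] += 5.0
        values, bins = inference.loso_extract(a, b, return_bins=True)
        assert np.all(bins == 7)
        assert len(values) == 16

    def test_choice_for_a_subject_ignores_that_subject(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(6, 15))
        b = rng.normal(size=(6, 15))
        _, bins = inference.loso_extract(a, b, return_bins=True)
        a2 = a.copy()
        a2[0] += 100.0  # wrecking subject 0's own rows
        _, bins2 = inference.loso_extract(a2, b, return_bins=True)
        assert bins2[0] == bins[0]

    def test_loso_reduces_selection_bias_relative_to_peeking(self):
        # LOSO keeps each subject's own data out of its bin choice, so the
        # majority of null runs show no group difference; picking the best
        # bin on the full sample is circular and nearly always "significant".
        # (Shared selection across the remaining subjects still leaves some
        # residual inflation above the nominal rate.)
        rng = np.random.default_rng(2)
        loso_hits = peek_hits = 0
        n_runs = 20
        for _ in range(n_runs):
            a = rng.normal(size=(10, 90))
            b = rng.normal(size=(10, 90))
            vals = inference.loso_extract(a, b)
            _, p = stats.ttest_ind(vals[:10], vals[10:])
            loso_hits += p < 0.05
            # circular version: pick the best bin on the full sample
            t_full = inference._two_sample_t(a, b)
            j = int(np.argmax(np.abs(t_full)))
            _, p_peek = stats.ttest_ind(a[:, j], b[:, j])
            peek_hits += p_peek < 0.05
        assert loso_hits < 0.5 * n_runs
        assert peek_hits >= 0.75 * n_runs
        assert peek_hits > loso_hits

    def test_group_size_floor(self):
        with pytest.raises(ValueError):
            inference.loso_extract(np.zeros((2, 5)), np.zeros((5, 5)))


class TestNestedF:
    def test_textbook_value(self):
        f, p = inference.nested_f_test(10.0, 10, 5.0, 8)
        assert f == pytest.approx(4.0, abs=1e-12)
        assert p == pytest.approx(stats.f.sf(4.0, 2, 8), abs=1e-12)

    def test_no_improvement_gives_zero(self):
        f, p = inference.nested_f_test(5.0, 10, 5.0, 8)
        assert f == 0.0 and p == pytest.approx(1.0)

    def test_violated_nesting_rejected(self):
        with pytest.raises(ValueError):
            inference.nested_f_test(5.0, 10, 6.0, 8)
        with pytest.raises(ValueError):
            inference.nested_f_test(5.0, 8, 4.0, 10)

    def test_agrees_with_statsmodels_anova(self):
        import statsmodels.api as sm
        from statsmodels.stats.anova import anova_lm
        rng = np.random.default_rng(7)
        for _ in range(20):
            n, k = 40, 3
            X = np.column_stack([np.ones(n), rng.normal(size=(n, k))])
            y = X @ rng.normal(size=k + 1) + rng.normal(size=n)
            reduced = sm.OLS(y, X[:, :2]).fit()
            full = sm.OLS(y, X).fit()
            table = anova_lm(reduced, full)
            f, p = inference.nested_f_test(reduced.ssr, reduced.df_resid,
                                           full.ssr, full.df_resid)
            assert f == pytest.approx(table["F"].iloc[1], abs=1e-10)
            assert p == pytest.approx(table["Pr(>F)"].iloc[1], abs=1e-10)

    def test_null_covariate_p_values_are_uniform(self):
        rng = np.random.default_rng(8)
        pvals = []
        n = 114
        for _ in range(500):
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            y = rng.normal(size=n)
            noise_col = rng.normal(size=(n, 1))
            b_r, *_ = np.linalg.lstsq(X, y, rcond=None)
            b_f, *_ = np.linalg.lstsq(np.hstack([X, noise_col]), y, rcond=None)
            rss_r = float(np.sum((y - X @ b_r) ** 2))
            rss_f = float(np.sum((y - np.hstack([X, noise_col]) @ b_f) ** 2))
            _, p = inference.nested_f_test(rss_r, n - 2, rss_f, n - 3)
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestAgeModels:
    def test_recovers_generated_age_dependence(self):
        spec = hl.CohortSpec(age_per_log_uu=4.0)
        subjects = hl.generate_cohort(40, 40, spec, seed=5)
        t = hl.cohort_table(subjects)
        res = inference.age_explanatory_model(
            t["age"].to_numpy(), {"log_uu": t["log_uu_true"].to_numpy()},
            {"raven": t["raven"].to_numpy(), "ospan": t["ospan"].to_numpy()})
        meas = res.models["measures"]
        assert meas["coef"][meas["terms"].index("log_uu")] > 0
        comparisons = dict(((r, f), (F, p)) for r, f, F, p in res.comparisons)
        assert comparisons[("covariates", "full")][1] < 0.05

    def test_orthogonal_covariates_leave_measure_effect(self):
        rng = np.random.default_rng(9)
        n = 100
        measure = rng.normal(size=n)
        age = 50 + 5 * measure + rng.normal(size=n)
        cov = rng.normal(size=n)  # unrelated to age
        res = inference.age_explanatory_model(age, {"m": measure},
                                              {"c": cov})
        comps = dict(((r, f), F) for r, f, F, p in res.comparisons)
        # measure explains age with or without the covariate
        assert comps[("intercept", "measures")] > 10
        assert comps[("covariates", "full")] > 10

    def test_without_measures_no_degenerate_comparison(self):
        res = inference.age_explanatory_model(np.arange(10.0), {}, None)
        assert res.comparisons == []
        assert list(res.models) == ["intercept"]
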