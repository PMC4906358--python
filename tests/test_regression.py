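"""Tests for trial exclusions, weighting and the sliding-window regression."""

import numpy as np
import pandas as pd
import pytest

import helilearn as hl
from helilearn import regression as reg
from conftest import pooled_sessions


def tiny_tables(buckets, bags, catch=None, mu=150.0, block=None):
    n = len(bags)
    catch = [False] * n if catch is None else catch
    block = [0] * n if block is None else block
    task = pd.DataFrame({"trial": range(n), "block": block, "helicopter": mu,
                         "bag": bags, "noise_sd": 10.0,
                         "is_changepoint": False, "is_catch": catch,
                         "is_gold": True})
    beh = pd.DataFrame({"trial": range(n), "block": block, "bucket": buckets})
    return task, beh


class TestPreprocess:
    def test_excludes_update_far_from_any_delta_rule(self):
        # bucket 100, bag 140, next bucket 160: 20 units beyond the segment
        task, beh = tiny_tables([100.0, 100.0, 160.0, 160.0],
                                [120.0, 140.0, 150.0, 150.0])
        trials = reg.preprocess_trials(task, beh)
        assert not trials.loc[1, "included"]

    def test_update_on_delta_rule_segment_is_kept(self):
        task, beh = tiny_tables([100.0, 100.0, 120.0, 120.0],
                                [120.0, 140.0, 150.0, 150.0])
        trials = reg.preprocess_trials(task, beh)
        assert trials.loc[1, "included"]

    def test_catch_trial_update_toward_helicopter_is_kept(self):
        # moving past the bag toward the visible helicopter is a valid
        # delta-rule update on catch trials only
        task, beh = tiny_tables([100.0, 100.0, 145.0, 145.0],
                                [120.0, 120.0, 150.0, 150.0],
                                catch=[False, True, False, False], mu=150.0)
        trials = reg.preprocess_trials(task, beh)
        assert trials.loc[1, "included"]
        task2, beh2 = tiny_tables([100.0, 100.0, 145.0, 145.0],
                                  [120.0, 120.0, 150.0, 150.0], mu=150.0)
        assert not reg.preprocess_trials(task2, beh2).loc[1, "included"]

    def test_zero_error_and_block_edges_excluded(self):
        task, beh = tiny_tables([100.0, 110.0, 110.0, 120.0, 125.0],
                                [110.0, 110.0, 120.0, 130.0, 140.0])
        trials = reg.preprocess_trials(task, beh)
        assert not trials.loc[0, "included"]   # first of block
        assert not trials.loc[1, "included"]   # zero prediction error
        assert not trials.loc[4, "included"]   # last of block
        assert trials.loc[2, "included"]

    def test_all_excluded_raises(self):
        task, beh = tiny_tables([100.0, 100.0], [100.0, 100.0])
        with pytest.raises(ValueError):
            reg.preprocess_trials(task, beh)

    def test_exclusion_fraction_is_small_for_model_like_agents(self, task_cfg):
        task, beh = pooled_sessions("normative", 3, uv=2.0)
        trials = reg.preprocess_trials(task, beh)
        assert trials.attrs["excluded_fraction"] < 0.05


class TestModelRegressors:
    def test_generative_agent_recovers_own_latents(self, task_cfg,
                                                   session_task, model_cfg):
        agent = hl.AgentSpec.of_kind("normative", uv=0.0, lrv=0.0)
        beh = hl.simulate_agent(session_task, agent, task_cfg)
        regs = reg.compute_model_regressors(session_task, beh, model_cfg)
        traj = hl.run_model(session_task, model_cfg)
        np.testing.assert_allclose(regs["surprise"], traj["omega"], atol=1e-9)
        np.testing.assert_allclose(regs["uncertainty"], traj["tau"], atol=1e-9)

    def test_larger_errors_get_larger_surprise(self, session_task, model_cfg):
        rng = np.random.default_rng(1)
        beh = pd.DataFrame({"trial": session_task["trial"],
                            "block": session_task["block"],
                            "bucket": rng.uniform(0, 300, len(session_task))})
        regs = reg.compute_model_regressors(session_task, beh, model_cfg)
        delta = np.abs(session_task["bag"].to_numpy()
                       - beh["bucket"].to_numpy())
        surprise = regs["surprise"].to_numpy()
        big = delta > 60
        small = delta < 5
        assert surprise[big].mean() > surprise[small].mean()


class TestRidgeSolve:
    def test_reduces_to_ols_without_penalty(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        beta = reg.ridge_weighted_solve(A, y, ridge=0.0)
        expect, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(beta, expect, atol=1e-10)

    def test_closed_form_single_column(self):
        # (A'A + 0.1)^-1 A'y = 2 / 2.1 with A = [1, 1]', y = [1, 1]'
        beta = reg.ridge_weighted_solve(np.array([[1.0], [1.0]]),
                                        np.array([1.0, 1.0]), ridge=0.1,
                                        penalize_intercept=True)
        assert beta[0] == pytest.approx(2.0 / 2.1, abs=1e-12)

    def test_shrinkage_is_monotone_in_penalty(self):
        rng = np.random.default_rng(3)
        A = np.column_stack([np.ones(40), rng.normal(size=(40, 3))])
        y = rng.normal(size=40)
        norms = [np.linalg.norm(reg.ridge_weighted_solve(A, y, ridge=lam)[1:])
                 for lam in (0.0, 0.1, 1.0, 10.0)]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_weights_change_the_solution(self):
        A = np.column_stack([np.ones(4), [0.0, 1.0, 2.0, 3.0]])
        y = np.array([0.0, 1.0, 2.0, 9.0])
        w_hi_last = np.array([1.0, 1.0, 1.0, 100.0])
        b0 = reg.ridge_weighted_solve(A, y, ridge=0.0)
        b1 = reg.ridge_weighted_solve(A, y, w_hi_last, ridge=0.0)
        assert b1[1] > b0[1]


class TestHeteroscedasticWeights:
    def _design(self, n, noise_fn, seed):
        rng = np.random.default_rng(seed)
        rel = rng.uniform(0, 3, n)
        A = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = A @ np.array([1.0, 2.0]) + noise_fn(rel, rng)
        return A, y, rel

    def test_homoscedastic_weights_are_flat(self):
        A, y, rel = self._design(5000, lambda r, rng: rng.normal(0, 2, len(r)), 0)
        w = reg.estimate_heteroscedastic_weights([(A, y, rel)])[0]
        assert np.std(w) / np.mean(w) < 0.2

    def test_growing_noise_gives_decreasing_weights(self):
        from scipy import stats
        A, y, rel = self._design(5000,
                                 lambda r, rng: rng.normal(0, 1, len(r)) * (0.5 + r),
                                 1)
        w = reg.estimate_heteroscedastic_weights([(A, y, rel)])[0]
        rho = stats.spearmanr(rel, w).statistic
        assert rho < -0.9

    def test_tiny_dataset_gets_equal_weights(self):
        A, y, rel = self._design(5, lambda r, rng: np.zeros(len(r)), 2)
        w = reg.estimate_heteroscedastic_weights([(A, y, rel)])[0]
        assert np.allclose(w, w[0])


class TestSlidingWindows:
    def test_window_zero_holds_smallest_errors(self):
        n = 1000
        bounds = reg._window_bounds(n)
        assert bounds[0] == (0, 100)

    def test_each_bin_holds_ten_percent(self):
        for n in (400, 1000, 731):
            for lo, hi in reg._window_bounds(n):
                assert hi - lo == pytest.approx(0.1 * n, abs=1.0)

    def test_matches_per_bin_ols_on_disjoint_windows(self, task_cfg, model_cfg):
        task, beh = pooled_sessions("normative", 2, uv=2.0)
        trials = reg.preprocess_trials(task, beh)
        regs = reg.compute_model_regressors(task, beh, model_cfg)
        ds = reg.RegressionDataset.from_tables(trials, regs)
        # 4 disjoint windows of 25% each
        out = reg.sliding_window_fit(ds, ridge=0.0, n_bins=4, window_frac=0.25)
        order = np.argsort(ds.rel_err, kind="stable")
        n = len(ds)
        for b in range(4):
            rows = order[int(b * n / 4):int((b + 1) * n / 4)]
            A, y = ds.design(rows)
            expect, *_ = np.linalg.lstsq(A, y, rcond=None)
            np.testing.assert_allclose(out.coefficients[b], expect, atol=1e-8)

    def test_fixed_rate_agent_recovered_in_every_bin(self, task_cfg, model_cfg):
        task, beh = pooled_sessions("fixed_learning_rate", 10, uv=0.5)
        out = hl.analyze_cohort([task], [beh], [model_cfg])[0]
        d = out.coefficients[:, reg.COEF_NAMES.index("delta")]
        assert np.abs(d - 0.5).max() < 0.06
        # interaction profiles hover around zero (individual bins are noisy
        # where the within-bin factor variation is tiny)
        inter = out.coefficients[:, 2:7]
        assert np.abs(inter.mean(axis=0)).max() < 0.1
        assert np.abs(np.median(inter, axis=0)).max() < 0.05

    def test_normative_learning_rate_rises_with_error_magnitude(
            self, task_cfg, model_cfg):
        task, beh = pooled_sessions("normative", 10, uv=1.0)
        out = hl.analyze_cohort([task], [beh], [model_cfg])[0]
        d = out.coefficients[:, reg.COEF_NAMES.index("delta")]
        assert d[-10:].mean() > d[:10].mean() + 0.1

    def test_cue_integration_shows_in_helicopter_coefficient(self, task_cfg,
                                                             model_cfg):
        j = reg.COEF_NAMES.index("helicopter")
        task, beh = pooled_sessions("normative", 5, uv=1.0)
        integrating = hl.analyze_cohort([task], [beh], [model_cfg])[0]
        # same agent with an uninformative cue ignores the helicopter
        blind_params = hl.FlexibleParams(cue_sd=1e6, update_variability=1.0)
        cfg = hl.TaskConfig(seed=7)
        tasks, behs = [], []
        for i in range(5):
            t = hl.generate_session(hl.TaskConfig(seed=500 + i))
            agent = hl.AgentSpec(model_kind="normative", params=blind_params,
                                 update_variability=1.0, seed=i)
            b = hl.simulate_agent(t, agent, cfg)
            t = t.copy()
            t["block"] += 2 * i
            b["block"] += 2 * i
            tasks.append(t)
            behs.append(b)
        task2 = pd.concat(tasks, ignore_index=True)
        beh2 = pd.concat(behs, ignore_index=True)
        ignoring = hl.analyze_cohort([task2], [beh2], [model_cfg])[0]
        assert integrating.coefficients[:, j].mean() > 0.2
        assert abs(ignoring.coefficients[:, j].mean()) < 0.1

    def test_reduced_bins_warning_on_tiny_data(self):
        rng = np.random.default_rng(0)
        n = 30
        ds = reg.RegressionDataset(
            delta=rng.normal(size=n), update=rng.normal(size=n),
            rel_err=rng.uniform(0, 2, n), surprise=rng.uniform(0, 1, n),
            uncertainty=rng.uniform(0, 1, n), noise_sd=np.full(n, 10.0),
            value=rng.integers(0, 2, n).astype(float),
            visibility=np.zeros(n), mu=np.full(n, 150.0),
            bucket=rng.uniform(0, 300, n))
        with pytest.warns(UserWarning):
            out = reg.sliding_window_fit(ds, n_bins=90)
        assert out.coefficients.shape[0] == 30

    def test_long_format_round_trip(self):
        w = reg.WindowedCoefficients(np.zeros((3, len(reg.COEF_NAMES))),
                                     np.arange(3.0), np.full(3, 10),
                                     list(reg.COEF_NAMES))
        frame = w.to_frame("s1")
        assert set(frame.columns) == {"subject", "bin", "coefficient_name",
                                      "value", "bin_median_rel_err", "n"}
        assert len(frame) == 3 * len(reg.COEF_NAMES)
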