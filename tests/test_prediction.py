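"""Marginal and baseline-updated prediction, metrics, calibration."""

import numpy as np
import pandas as pd
import pytest

import egfrtraj as et
from egfrtraj.blmm import Design, PosteriorDraws


def _toy_draws(beta, G, sigma, columns, n_draws=1):
    beta = np.tile(np.asarray(beta, dtype=float), (n_draws, 1))
    spec = et.ModelSpec(
        [c for c in columns if c not in ("intercept", "time")
         and not c.endswith(":time")],
        include_interactions=any(c.endswith(":time") for c in columns))
    return PosteriorDraws(
        beta=beta, sigma=np.full(n_draws, float(sigma)),
        G=np.tile(np.asarray(G, dtype=float), (n_draws, 1, 1)),
        b=None, chain=np.zeros(n_draws, dtype=int), columns=list(columns),
        subject_ids=np.array(["train"]), spec=spec)


def _design_for(subjects, times, x=None, y=None):
    n = len(times)
    columns = ["intercept", "time"]
    parts = [np.ones((n, 1)), np.asarray(times, float)[:, None]]
    if x is not None:
        columns += ["x", "x:time"]
        parts += [np.asarray(x, float)[:, None],
                  (np.asarray(x, float) * np.asarray(times, float))[:, None]]
    ids, codes = np.unique(subjects, return_inverse=True)
    return Design(X=np.concatenate(parts, axis=1),
                  y=np.zeros(n) if y is None else np.asarray(y, float),
                  times=np.asarray(times, float), subject_codes=codes,
                  subject_ids=ids, columns=columns)


class TestMarginal:
    def test_prediction_is_fixed_effect_surface(self):
        draws = _toy_draws([40.0, -1.5], np.eye(2), 1.0,
                           ["intercept", "time"])
        design = _design_for(["A", "A", "B"], [0.0, 2.0, 1.0])
        pred = et.predict_marginal(draws, design)
        np.testing.assert_allclose(pred.draws[0], [40.0, 37.0, 38.5])

    def test_identical_covariates_identical_trajectories(self):
        draws = _toy_draws([40.0, -1.0, 2.0, -0.5], np.eye(2), 1.0,
                           ["intercept", "time", "x", "x:time"])
        design = _design_for(["A", "A", "B", "B"], [0.0, 2.0, 0.0, 2.0],
                             x=[0.7, 0.7, 0.7, 0.7])
        pred = et.predict_marginal(draws, design)
        np.testing.assert_allclose(pred.draws[:, :2], pred.draws[:, 2:])

    def test_stats_fingerprint_mismatch_rejected(self, small_fit):
        design, spec, draws, _ = small_fit
        from dataclasses import replace
        tampered = replace(design, stats_fp="deadbeef00000000")
        with pytest.raises(ValueError, match="standardized"):
            et.predict_marginal(draws, tampered)

    def test_plugin_truth_recovery(self, small_cohort):
        """Degenerate posterior at the generating coefficients reproduces
        the generator's fixed-effect surface exactly."""
        c = small_cohort
        names = c.config.predictor_names
        cols = ["intercept", "time"] + names + [f"{p}:time" for p in names]
        beta = np.array([c.truth["intercept"], c.truth["time_slope"]]
                        + [c.truth["beta_base"][p] for p in names]
                        + [c.truth["beta_slope"][p] for p in names])
        draws = _toy_draws(beta, np.eye(2), 1.0, cols)
        design_cov = c.truth["design"]
        spec = et.ModelSpec(names)
        design = et.build_design(c.records, design_cov, spec)
        pred = et.predict_marginal(draws, design)
        order = {s: i for i, s in enumerate(c.covariates["subject_id"])}
        ix = np.array([order[s] for s in pred.subject_id])
        level = np.asarray(c.truth["level"]) - np.asarray(c.truth["b0"])
        slope = np.asarray(c.truth["slope"]) - np.asarray(c.truth["b1"])
        expected = level[ix] + slope[ix] * pred.times
        np.testing.assert_allclose(pred.draws[0], expected, atol=1e-8)


class TestUpdateByBaseline:
    def test_worked_gain_example(self):
        """G = [[25,10],[10,4]], sigma^2 = 25, r0 = 10 => BLUP (5, 2)."""
        draws = _toy_draws([0.0, 0.0], [[25.0, 10.0], [10.0, 4.0]], 5.0,
                           ["intercept", "time"])
        design = _design_for(["A", "A"], [0.0, 1.0], y=[10.0, 0.0])
        pred = et.update_by_baseline(draws, design)
        np.testing.assert_allclose(pred.cond_mean[0, 0], [5.0, 2.0])
        np.testing.assert_allclose(pred.draws[0], [5.0, 7.0])

    def test_infinite_noise_recovers_marginal(self):
        draws = _toy_draws([40.0, -1.0], [[25.0, 10.0], [10.0, 4.0]], 1e8,
                           ["intercept", "time"])
        design = _design_for(["A", "A"], [0.0, 3.0], y=[70.0, 0.0])
        upd = et.update_by_baseline(draws, design)
        marg = et.predict_marginal(draws, design)
        np.testing.assert_allclose(upd.draws, marg.draws, atol=1e-4)

    def test_noiseless_update_interpolates_baseline(self):
        draws = _toy_draws([40.0, -1.0], [[25.0, 10.0], [10.0, 4.0]], 1e-9,
                           ["intercept", "time"])
        design = _design_for(["A", "A"], [0.0, 1.0], y=[52.0, 0.0])
        upd = et.update_by_baseline(draws, design)
        assert upd.draws[0, 0] == pytest.approx(52.0, abs=1e-6)

    def test_brute_force_conditioning_oracle(self, rng):
        """Exact agreement with dense joint-Gaussian conditioning."""
        n_draws, n_subj = 40, 3
        beta = rng.normal(size=(n_draws, 2)) + [45.0, -1.0]
        Graw = rng.normal(size=(n_draws, 2, 2))
        G = Graw @ Graw.transpose(0, 2, 1) + 0.5 * np.eye(2)
        sigma = rng.uniform(1.0, 6.0, n_draws)
        spec = et.ModelSpec([], include_interactions=False)
        draws = PosteriorDraws(beta=beta, sigma=sigma, G=G, b=None,
                               chain=np.zeros(n_draws, dtype=int),
                               columns=["intercept", "time"],
                               subject_ids=np.array(["t"]), spec=spec)
        subj = ["A", "A", "B", "B", "C", "C"]
        times = [0.0, 2.0, 0.0, 3.0, 0.0, 4.0]
        y = [50.0, 0.0, 38.0, 0.0, 61.0, 0.0]
        design = _design_for(subj, times, y=y)
        pred = et.update_by_baseline(draws, design)

        y0 = np.array([50.0, 38.0, 61.0])
        for d in range(n_draws):
            z0 = np.array([1.0, 0.0])
            joint = np.zeros((3, 3))
            joint[:2, :2] = G[d]
            joint[2, :2] = z0 @ G[d]
            joint[:2, 2] = G[d] @ z0
            joint[2, 2] = z0 @ G[d] @ z0 + sigma[d] ** 2
            for s in range(n_subj):
                r0 = y0[s] - (beta[d, 0] + beta[d, 1] * 0.0)
                mean_bf = joint[:2, 2] / joint[2, 2] * r0
                cov_bf = joint[:2, :2] - np.outer(
                    joint[:2, 2], joint[2, :2]) / joint[2, 2]
                np.testing.assert_allclose(pred.cond_mean[d, s], mean_bf,
                                           atol=1e-8)
                np.testing.assert_allclose(pred.cond_cov[d], cov_bf,
                                           atol=1e-8)

    def test_conditional_covariance_is_reduction(self, rng):
        Graw = rng.normal(size=(20, 2, 2))
        G = Graw @ Graw.transpose(0, 2, 1) + 0.1 * np.eye(2)
        draws = _toy_draws([40.0, -1.0], np.eye(2), 2.0,
                           ["intercept", "time"], n_draws=20)
        draws.G = G
        design = _design_for(["A", "A"], [0.0, 2.0], y=[50.0, 0.0])
        pred = et.update_by_baseline(draws, design)
        for d in range(20):
            reduction = G[d] - pred.cond_cov[d]
            assert np.all(np.linalg.eigvalsh(reduction) > -1e-10)

    def test_tower_property_recovers_marginal(self, rng):
        """Averaging updates over model-simulated baselines ~ marginal."""
        G = np.array([[25.0, 10.0], [10.0, 4.0]])
        sigma = 4.0
        beta = np.array([45.0, -1.0])
        n_sim = 4000
        y0 = beta[0] + rng.normal(0, np.sqrt(G[0, 0] + sigma**2), n_sim)
        draws = _toy_draws(beta, G, sigma, ["intercept", "time"])
        preds = []
        for y0_i in y0[:400]:
            design = _design_for(["A", "A"], [0.0, 3.0], y=[y0_i, 0.0])
            preds.append(et.update_by_baseline(draws, design).draws[0, 1])
        marginal = beta[0] + beta[1] * 3.0
        k = (G[0, 0] + 3.0 * G[1, 0]) / (G[0, 0] + sigma**2)
        se = np.sqrt(G[0, 0] + sigma**2) * abs(k) / np.sqrt(400)
        assert abs(np.mean(preds) - marginal) < 3 * se

    def test_requires_single_baseline_record(self):
        draws = _toy_draws([0.0, 0.0], np.eye(2), 1.0, ["intercept", "time"])
        design = _design_for(["A", "A"], [1.0, 2.0])
        with pytest.raises(ValueError, match="time 0"):
            et.update_by_baseline(draws, design)


class TestMetrics:
    def test_perfect_predictions(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        met = et.r2_rmse(obs[None, :], obs, p=2)
        assert met["r2"][0] == pytest.approx(1.0)
        assert met["adj_r2"][0] == pytest.approx(1.0)
        assert met["rmse"][0] == pytest.approx(0.0)

    def test_adjusted_r2_formula(self):
        # R2 = 0.30, n = 100, p = 2  =>  1 - 0.70*99/97
        rng = np.random.default_rng(1)
        obs = rng.standard_normal(100)
        # build predictions achieving an exact R2 of 0.30
        resid = obs - obs.mean()
        pred = obs - np.sqrt(0.70) * resid
        met = et.r2_rmse(pred[None, :], obs, p=2)
        assert met["r2"][0] == pytest.approx(0.30)
        assert met["adj_r2"][0] == pytest.approx(1 - 0.70 * 99 / 97)
        assert met["adj_r2"][0] == pytest.approx(0.2856, abs=1e-4)

    def test_constant_prediction_gives_zero_r2(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = np.full((1, 3), 2.0)
        met = et.r2_rmse(pred, obs, p=1)
        assert met["r2"][0] == pytest.approx(0.0)
        assert met["adj_r2"][0] < 0

    def test_adjusted_refused_when_underdetermined(self):
        with pytest.raises(ValueError, match="adjusted"):
            et.r2_rmse(np.zeros((1, 3)), np.arange(3.0), p=3)

    def test_bayes_r2_range(self, rng):
        pred = rng.standard_normal((10, 50))
        vals = et.bayes_r2(pred, np.full(10, 2.0))
        assert np.all((vals >= 0) & (vals <= 1))


class TestCalibration:
    def test_perfect_predictions_slope_one(self, rng):
        times = rng.uniform(0, 4, 200)
        obs = rng.normal(45, 10, 200)
        table = et.calibration_by_followup(obs, obs, times,
                                           [-0.01, 1.0, 2.0, 3.0, 5.0])
        filled = table[table["n"] > 0]
        np.testing.assert_allclose(filled["slope"], 1.0, atol=1e-8)
        np.testing.assert_allclose(filled["intercept"], 0.0, atol=1e-6)

    def test_constant_bias_appears_in_intercept(self, rng):
        times = rng.uniform(0, 4, 200)
        obs = rng.normal(45, 10, 200)
        table = et.calibration_by_followup(obs - 5.0, obs, times,
                                           [-0.01, 2.0, 5.0])
        filled = table[table["n"] > 0]
        np.testing.assert_allclose(filled["slope"], 1.0, atol=1e-8)
        np.testing.assert_allclose(filled["intercept"], 5.0, atol=1e-6)

    def test_empty_bin_reported(self, rng):
        times = np.array([0.1, 0.2, 3.5, 3.6])
        obs = np.array([40.0, 41.0, 30.0, 29.0])
        table = et.calibration_by_followup(obs, obs, times,
                                           [0.0, 1.0, 2.0, 4.0])
        assert (table["n"] == 0).sum() == 1
        assert len(table) == 3
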