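"""Sampler correctness against conjugate oracles, summaries, diagnostics."""

import numpy as np
import pandas as pd
import pytest

import egfrtraj as et
from egfrtraj.blmm import split_rhat


def _flat_records(n, times, rng):
    rows = []
    for i in range(n):
        for t in times:
            rows.append((f"S{i:03d}", float(t), 0.0))
    return pd.DataFrame(rows, columns=["subject_id", "time_years", "egfr"])


class TestBuildDesign:
    def test_column_layout_single_predictor(self, small_cohort):
        c = small_cohort
        dc, _ = et.transform_predictors(c.covariates.drop(columns="subject_id"))
        dc.index = c.covariates["subject_id"].to_numpy()
        spec = et.ModelSpec(["TNFR1"])
        d = et.build_design(c.records, dc, spec)
        assert d.columns == ["intercept", "time", "TNFR1", "TNFR1:time"]
        np.testing.assert_allclose(d.X[:, 3], d.X[:, 2] * d.times)

    def test_main_model_has_64_columns(self, small_cohort):
        c = small_cohort
        dc, _ = et.transform_predictors(c.covariates.drop(columns="subject_id"))
        dc.index = c.covariates["subject_id"].to_numpy()
        spec = et.ModelSpec(c.config.predictor_names)
        d = et.build_design(c.records, dc, spec)
        assert d.X.shape[1] == 2 + 2 * 31 == 64

    def test_unmatched_subject_reported(self, small_cohort):
        c = small_cohort
        dc, _ = et.transform_predictors(c.covariates.drop(columns="subject_id"))
        dc.index = c.covariates["subject_id"].to_numpy()
        bad = c.records.copy()
        bad.loc[0, "subject_id"] = "GHOST"
        with pytest.raises(ValueError, match="GHOST"):
            et.build_design(bad, dc, et.ModelSpec(["TNFR1"]))


class TestConjugateOracles:
    def test_ridge_posterior_without_random_effects(self, rng):
        """Fixed sigma + Gaussian prior: sampler matches the closed form."""
        n, scale, sigma = 60, 3.0, 2.0
        records = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)],
            "time_years": rng.uniform(0, 4, n), "egfr": 0.0})
        cov = pd.DataFrame(rng.standard_normal((n, 2)), columns=["a", "b"],
                           index=records["subject_id"])
        spec = et.ModelSpec(["a", "b"], include_interactions=False,
                            prior_family="gaussian_fixed",
                            prior_hyperparams={"scale": scale},
                            random_effects=False, fixed_resid_sd=sigma,
                            mcmc=et.McmcConfig(chains=2, warmup=100,
                                               draws=1500, seed=2))
        design = et.build_design(records, cov, spec)
        beta_true = np.array([50.0, -1.0, 2.0, -3.0])
        design.y[:] = design.X @ beta_true + sigma * rng.standard_normal(n)

        draws, diag = et.fit_blmm(design, spec)
        A = design.X.T @ design.X / sigma**2 + np.eye(4) / scale**2
        post_cov = np.linalg.inv(A)
        post_mean = post_cov @ design.X.T @ design.y / sigma**2

        sd = np.sqrt(np.diag(post_cov))
        ess = np.array([diag.ess[f"beta[{c}]"] for c in design.columns])
        mc_se = sd / np.sqrt(ess)
        assert np.all(np.abs(draws.beta.mean(0) - post_mean) < 3 * mc_se)
        assert np.allclose(draws.beta.std(0), sd, rtol=0.15)

    def test_gls_posterior_with_fixed_variance_components(self, rng):
        """5 subjects, 2 predictors, fixed (G, sigma): matches GLS oracle."""
        G = np.array([[9.0, 1.0], [1.0, 1.0]])
        sigma, scale = 2.0, 5.0
        records = _flat_records(5, [0, 1, 2, 3], rng)
        cov = pd.DataFrame(rng.standard_normal((5, 2)), columns=["a", "b"],
                           index=[f"S{i:03d}" for i in range(5)])
        spec = et.ModelSpec(["a", "b"], include_interactions=False,
                            prior_family="gaussian_fixed",
                            prior_hyperparams={"scale": scale},
                            fixed_resid_sd=sigma, fixed_random_cov=G,
                            mcmc=et.McmcConfig(chains=2, warmup=200,
                                               draws=2500, seed=5))
        design = et.build_design(records, cov, spec)
        rng2 = np.random.default_rng(42)
        b = rng2.multivariate_normal(np.zeros(2), G, size=5)
        beta_true = np.array([48.0, -1.0, 3.0, -2.0])
        design.y[:] = (design.X @ beta_true
                       + b[design.subject_codes, 0]
                       + b[design.subject_codes, 1] * design.times
                       + sigma * rng2.standard_normal(len(design.y)))

        draws, diag = et.fit_blmm(design, spec)

        # dense GLS oracle over the stacked marginal covariance
        n = len(design.y)
        Z = np.zeros((n, 10))
        for r, (s, t) in enumerate(zip(design.subject_codes, design.times)):
            Z[r, 2 * s] = 1.0
            Z[r, 2 * s + 1] = t
        V = Z @ np.kron(np.eye(5), G) @ Z.T + sigma**2 * np.eye(n)
        Vi = np.linalg.inv(V)
        A = design.X.T @ Vi @ design.X + np.eye(4) / scale**2
        post_cov = np.linalg.inv(A)
        post_mean = post_cov @ design.X.T @ Vi @ design.y

        sd = np.sqrt(np.diag(post_cov))
        ess = np.array([diag.ess[f"beta[{c}]"] for c in design.columns])
        mc_se = sd / np.sqrt(np.maximum(ess, 10))
        assert np.all(np.abs(draws.beta.mean(0) - post_mean) < 3 * mc_se)
        assert np.allclose(draws.beta.std(0), sd, rtol=0.2)

    def test_near_noiseless_fit_concentrates_on_truth(self, rng):
        records = _flat_records(30, [0, 1, 2], rng)
        ids = [f"S{i:03d}" for i in range(30)]
        cov = pd.DataFrame({"x": rng.standard_normal(30)}, index=ids)
        spec = et.ModelSpec(["x"], prior_family="student_t_weak",
                            random_effects=False, fixed_resid_sd=1e-3,
                            mcmc=et.McmcConfig(chains=2, warmup=200,
                                               draws=400, seed=1))
        design = et.build_design(records, cov, spec)
        design.y[:] = design.X @ np.array([40.0, -1.0, 3.0, 0.0])
        draws, _ = et.fit_blmm(design, spec)
        med = np.median(draws.beta, axis=0)
        np.testing.assert_allclose(med, [40.0, -1.0, 3.0, 0.0], atol=0.01)


class TestHorseshoe:
    def test_shrinkage_monotone_in_expected_nonnull_count(self):
        """Smaller p0 never inflates the true-null coefficient medians.

        Checked on the aggregate (mean |posterior median| over all null
        main effects) on one fixed dataset; individual coefficients carry
        Monte-Carlo noise of the same order as the medians themselves.
        """
        cfg = et.CohortConfig(n_subjects=300, seed=21, missing_rate=0.0,
                              biomarker_egfr_rank_corr=0.0)
        c = et.generate_cohort(cfg)
        dc, _ = et.transform_predictors(c.covariates.drop(columns="subject_id"))
        dc.index = c.covariates["subject_id"].to_numpy()
        truth = c.truth["beta_base"]
        shrink = []
        for p0 in (2, 5, 10):
            spec = et.ModelSpec(
                cfg.predictor_names, prior_family="regularized_horseshoe",
                prior_hyperparams={"p0": float(p0)},
                mcmc=et.McmcConfig(chains=2, warmup=300, draws=500, seed=8))
            design = et.build_design(c.records, dc, spec)
            draws, _ = et.fit_blmm(design, spec)
            summ = et.summarize_coefficients(draws).set_index("term")
            nulls = [t for t in summ.index
                     if t in truth and truth[t] == 0.0]
            shrink.append(float(summ.loc[nulls, "median"].abs().mean()))
        assert shrink[0] <= shrink[1] + 5e-4
        assert shrink[1] <= shrink[2] + 5e-4

    def test_random_effect_recovery_with_dense_visits(self):
        """Many visits and small noise: posterior b correlates with truth."""
        cfg = et.CohortConfig(
            n_subjects=60, visit_schedule=tuple(float(v) for v in range(21)),
            resid_sd=1.0, dropout_rate=0.0, missing_rate=0.0, seed=13,
            p_clinical=2, p_biomarkers=2,
            true_beta_base={"TNFR1": -3.0}, true_beta_slope={},
            biomarker_egfr_rank_corr=-0.3)
        c = et.generate_cohort(cfg)
        dc, _ = et.transform_predictors(c.covariates.drop(columns="subject_id"))
        dc.index = c.covariates["subject_id"].to_numpy()
        spec = et.ModelSpec(cfg.predictor_names,
                            prior_family="student_t_weak",
                            mcmc=et.McmcConfig(chains=2, warmup=200,
                                               draws=300, seed=4))
        design = et.build_design(c.records, dc, spec)
        draws, _ = et.fit_blmm(design, spec)
        b_mean = draws.b.mean(axis=0)
        order = np.argsort(c.covariates["subject_id"].to_numpy())
        for k in range(2):
            truth = np.asarray(c.truth["b0" if k == 0 else "b1"])[order]
            assert np.corrcoef(b_mean[:, k], truth)[0, 1] > 0.95


class TestSummaries:
    def test_symmetric_draws(self):
        beta = np.concatenate([np.full((100, 1), 3.0) + 2.0,
                               np.full((100, 1), 3.0) - 2.0]).reshape(-1, 1)
        draws = _draws_from_beta(beta, ["intercept"])
        summ = et.summarize_coefficients(draws)
        assert summ["median"].iloc[0] == pytest.approx(3.0)
        assert summ["q2.5"].iloc[0] + summ["q97.5"].iloc[0] == \
            pytest.approx(6.0)

    def test_linear_interpolation_percentiles(self):
        beta = np.arange(1.0, 101.0).reshape(-1, 1)
        summ = et.summarize_coefficients(_draws_from_beta(beta, ["x"]))
        assert summ["q2.5"].iloc[0] == pytest.approx(3.475)
        assert summ["q97.5"].iloc[0] == pytest.approx(97.525)

    def test_constant_draws(self):
        beta = np.full((50, 1), 7.0)
        summ = et.summarize_coefficients(_draws_from_beta(beta, ["x"]))
        assert (summ[["median", "q2.5", "q97.5"]].iloc[0] == 7.0).all()

    def test_baseline_slope_pairing(self, small_fit):
        _, _, draws, _ = small_fit
        summ = et.summarize_coefficients(draws)
        tn = summ[summ["predictor"] == "TNFR1"]
        assert set(tn["role"]) == {"baseline", "slope"}


def _draws_from_beta(beta, columns):
    n = len(beta)
    spec = et.ModelSpec([c for c in columns if c not in ("intercept", "time")],
                        include_interactions=False)
    return et.PosteriorDraws(
        beta=beta, sigma=np.ones(n), G=None, b=None,
        chain=np.repeat([0, 1], [n - n // 2, n // 2]), columns=columns,
        subject_ids=np.array(["s"]), spec=spec)


class TestPooling:
    def test_draw_counts_add(self, small_fit):
        _, _, draws, _ = small_fit
        pooled = et.pool_posteriors([draws] * 20)
        assert pooled.n_draws == 20 * draws.n_draws

    def test_identical_posteriors_keep_quantiles(self, small_fit):
        # linear-interpolation quantiles of a duplicated sample shift by
        # O(1/n); equality holds up to that interpolation error
        _, _, draws, _ = small_fit
        pooled = et.pool_posteriors([draws, draws])
        scale = np.abs(np.median(draws.beta, axis=0)) + 1.0
        diff = np.abs(np.percentile(pooled.beta, [2.5, 50, 97.5], axis=0)
                      - np.percentile(draws.beta, [2.5, 50, 97.5], axis=0))
        assert np.all(diff < 0.05 * scale)

    def test_disjoint_point_masses_mix(self):
        a = _draws_from_beta(np.full((100, 1), -1.0), ["x"])
        b = _draws_from_beta(np.full((100, 1), 1.0), ["x"])
        pooled = et.pool_posteriors([a, b])
        med = float(np.median(pooled.beta))
        assert -1.0 <= med <= 1.0
        assert pooled.beta.var() >= a.beta.var()

    def test_mismatched_specs_rejected(self, small_fit):
        _, _, draws, _ = small_fit
        other = _draws_from_beta(np.zeros((10, 1)), ["x"])
        with pytest.raises(ValueError, match="spec"):
            et.pool_posteriors([draws, other])


class TestConvergence:
    def test_iid_chains_pass(self, rng):
        beta = rng.standard_normal((4000, 1))
        draws = _draws_from_beta(beta, ["x"])
        draws.chain = np.repeat(np.arange(4), 1000)
        diag = et.check_convergence(draws)
        assert diag.r_hat["beta[x]"] < 1.01

    def test_constant_distinct_chains_fail(self):
        beta = np.concatenate([np.zeros(100), np.ones(100)]).reshape(-1, 1)
        draws = _draws_from_beta(beta, ["x"])
        draws.chain = np.repeat([0, 1], 100)
        diag = et.check_convergence(draws)
        assert diag.r_hat["beta[x]"] == np.inf
        assert not diag.passed

    def test_single_chain_refused(self):
        draws = _draws_from_beta(np.zeros((50, 1)), ["x"])
        draws.chain = np.zeros(50, dtype=int)
        with pytest.raises(ValueError, match="chain"):
            et.check_convergence(draws)

    def test_split_rhat_detects_trend(self):
        drift = np.linspace(0, 5, 400).reshape(2, 200)
        assert split_rhat(drift) > 1.2
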