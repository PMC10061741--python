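# egfrtraj

Bayesian modeling of longitudinal kidney-function trajectories in people
with chronic kidney disease (CKD) and diabetes mellitus.

People with diabetes and moderately reduced kidney function (estimated
glomerular filtration rate, eGFR, of 25–70 ml/min/1.73m²) decline at very
different individual rates. Clinicians and trialists want to know two
things: how well baseline clinical variables and serum protein biomarkers
predict the *whole future eGFR trajectory*, and how much those predictors
still add once the patient's *baseline eGFR itself* is used — because some
markers (filtration markers such as TNFR1 or RAGE) mostly proxy the current
eGFR level, while others (injury markers such as KIM1, or albuminuria)
carry information about the future *rate of decline*. This package
implements that analysis end to end, together with a synthetic cohort
generator that emulates the statistical structure of such a study
(restricted patient-level data cannot be shipped), so every stage is
testable and reproducible.

## The model

For subject *i* at observation time *t_ij* (years since baseline),

```
eGFR_ij = x_i' β + (time and time-interaction terms) + u0_i + u1_i t_ij + ε_ij
        = β0 + β_t t_ij + Σ_k x_ik (β_k + γ_k t_ij) + u0_i + u1_i t_ij + ε_ij
(u0_i, u1_i) ~ N(0, G),   ε_ij ~ N(0, σ²)
```

Each predictor contributes a **baseline coefficient** β_k (association with
overall eGFR level) and a **slope coefficient** γ_k (association with eGFR
decline per year). Predictors are standardized (biomarkers and the urine
albumin-creatinine ratio after log2 transform), so coefficients read in
units of outcome change per predictor SD. Three prior families are
available: weakly informative Student-t (univariable and clinical models),
the regularized horseshoe (the combined clinical + biomarker "main" model,
which enforces sparsity), and fixed Gaussian priors (conjugate oracle used
by the test-suite). Inference is a blocked Gibbs sampler with the random
effects marginalized out of the fixed-effect and residual-variance updates
(see `docs/methods.md`).

The two prediction objectives:

* **marginal** — fixed effects only; scores the entire held-out trajectory;
* **baseline-updated** — per posterior draw, a new subject's random effects
  are conditioned on their observed baseline eGFR y₀ by exact Gaussian
  conditioning (mean `G z₀ (z₀'G z₀ + σ²)⁻¹ (y₀ − x₀'β)`, the BLUP); only
  post-baseline records are scored.

Out-of-sample performance (posterior distributions of R², adjusted R²,
RMSE) comes from repeated fivefold cross-validation grouped by subject,
with standardization and multiple imputation (chained equations, m
completions, posteriors pooled) re-derived inside every training fold.
Predictor importance is the increase in cross-validated RMSE when one
predictor (main + interaction term) is removed (leave-one-variable-out),
and nested submodels obtained by projecting the reference posterior onto
smaller designs trace how few predictors suffice.

## Worked example

```python
import egfrtraj as et

cfg = et.CohortConfig(n_subjects=150, seed=2, missing_rate=0.03,
                      random_effect_cov=((100., -2.), (-2., 2.25)))
cohort = et.generate_cohort(cfg)

spec = et.ModelSpec(cfg.predictor_names,
                    prior_family="regularized_horseshoe",
                    mcmc=et.McmcConfig(chains=2, warmup=250, draws=250))
res = et.run_cv(cohort.records, cohort.covariates, spec,
                k=5, repeats=2, seed=4, m_imputations=2)
for mode in res.modes:
    m = res.pooled[mode]
    print(mode, "R2 %.3f [%.3f, %.3f]  RMSE %.2f"
          % (m["r2"]["median"], m["r2"]["q2.5"], m["r2"]["q97.5"],
             m["rmse"]["median"]))
```

prints (exactly, for this seed):

```
marginal R2 0.229 [0.183, 0.273]  RMSE 11.17
baseline_updated R2 0.678 [0.652, 0.697]  RMSE 7.34
```

Read: baseline covariates alone explain ~23% of held-out eGFR variation
(median posterior R², with its 95% credible interval), at a root mean
squared error of ~11 ml/min/1.73m². Conditioning each held-out subject's
random effects on their single observed baseline eGFR raises R² to ~0.68
and cuts the RMSE to ~7.3 — the qualitative signature of this analysis:
baseline eGFR dominates, and only decline-informative predictors add value
on top of it.

The same workflow is available from the shell:

```bash
egfrtraj simulate --config config.yaml --workdir run/
egfrtraj qc --config config.yaml --workdir run/
egfrtraj fit --config config.yaml --workdir run/
egfrtraj cv --config config.yaml --workdir run/
egfrtraj importance --config config.yaml --workdir run/
egfrtraj report --config config.yaml --workdir run/
```

All artifacts are CSV/JSON, seed-stamped, and byte-reproducible given the
same configuration.

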