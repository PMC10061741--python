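# Methods

This note documents the statistical model, the numerical choices behind the
sampler, the synthetic data-generating process, and the design decisions
taken where several defensible options existed. Nothing here states an
empirical result that the test-suite or `scripts/acceptance.py` does not
itself compute.

## Outcome and cohort assembly

The outcome is eGFR (ml/min/1.73m²) from the 2009 CKD-EPI creatinine
equation, with the race coefficient fixed at 1 (the emulated cohort is
all-Caucasian by its exclusion criteria). Inclusion requires diabetes
mellitus (HbA1c ≥ 6.5% or a prescription with ATC code prefix A10),
baseline eGFR in the closed interval [25, 70], and at least one
post-baseline eGFR record; the exclusion tally is reported in that fixed
order (DM → eGFR range → follow-up), so its components are
order-dependent by construction and sum to the number of removed subjects.

Immunoassay QC: per plate, a measurement is the mean of technical
replicates and is valid iff the replicate CV (sample sd with denominator
n−1 — the usual convention for duplicate QC, not stated more precisely by
assay practice — divided by the mean) is ≤ 15%. For samples rerun on
several plates, validity additionally requires the CV across plate means
to be < 20%, and the plate entry with smallest replicate CV supplies the
reported value ("preferred" is implemented as take-smallest-CV, not as
averaging). Out-of-range concentrations are truncated to fixed points:
lowest standard / √2 below range, highest standard × √2 above; truncation
is idempotent.

## The mixed model

y_ij = x_ij'β + u0_i + u1_i·t_ij + ε_ij with (u0,u1) ~ N(0,G) and
ε ~ N(0,σ²). The fixed design is `[1, t, mains, mains × t]` in a fixed,
documented column order. Observation time stays in years (unstandardized)
so slope coefficients read per year; predictors are z-scored (log2 first
for biomarkers and UACR; binary predictors 0/1), and z-scoring uses the
sample sd (n−1). Coefficients can be reported per outcome SD
(`standardized=True`), which is how sparsity thresholds are expressed.

Priors:

* `student_t_weak` — independent t(df=3, scale=2.5) on predictor
  coefficients, t(3, 10) on intercept and time, all on the internally
  standardized outcome scale.
* `regularized_horseshoe` — per-coefficient half-Cauchy local scales λ_j,
  global half-Cauchy scale τ with τ₀ = p₀/((D−p₀)√n)·σ (p₀ = expected
  non-null count, default 5, D = number of shrunk terms), and a Student-t
  slab (scale 2, df 4) through λ̃²_j = c²λ²_j/(c² + τ²λ²_j). The intercept
  and the time main effect keep the weakly informative t prior — shrinking
  time itself would distort the outcome model. All hyperparameters are
  exposed in configuration.
* `gaussian_fixed` — fixed Gaussian N(0, s²) priors, optionally with fixed
  σ and fixed G; this makes the posterior available in closed form and is
  used as the oracle in the tests, with no internal outcome rescaling.
* Variance parameters: half-Cauchy(25) on σ, and the Huang–Wand prior on
  G (half-t(2) marginals on both sds with scale 25 outcome units, uniform
  marginal correlation), chosen for weak informativeness and conditional
  conjugacy.

## Sampler

A blocked Gibbs sampler, validated against the conjugate closed forms:

1. σ² | β, G — the random effects are integrated out (Woodbury identity on
   the per-subject 2×2 blocks) and log σ² is updated by univariate slice
   sampling. The conjugate update conditional on b mixes very poorly when
   the random-intercept variance dominates σ².
2. β | σ², G, prior scales — joint Gaussian update with the random effects
   again marginalized (partially collapsed Gibbs). This decouples the
   fixed intercept/time from the means of the subject effects, the other
   classic slow direction.
3. b | β, σ², G — exact per-subject 2×2 Gaussian draws (vectorized
   closed-form Cholesky).
4. G | b — inverse-Wishart via the Huang–Wand auxiliary inverse-gamma
   variables.
5. Prior scales — inverse-gamma updates for the Student-t local variances;
   vectorized univariate slice sampling (step-out + shrinkage, width 2 on
   the log scale) for the horseshoe λ_j, τ and slab c².

Marginalize-then-reimpute ordering keeps the partially collapsed scheme
valid: b is redrawn before any step conditions on it. Default budget is 4
chains × (1000 warmup + 1000 kept); tests and the acceptance script use 2
chains × (100–500 warmup + 150–1000 kept), which the oracle checks show is
adequate at those problem sizes. Convergence is summarized by split-R̂
(pass threshold 1.01) and bulk ESS (floor 100, via arviz) per fixed-effect
coefficient and σ; parameters fixed by configuration are excluded from the
verdict, and a single chain is refused rather than silently diagnosed.

Known behaviour: near-null horseshoe coefficients sit in a funnel-shaped
(β_j, λ_j) geometry and mix more slowly than the rest; at the reduced test
budgets a few of them can show R̂ around 1.02–1.05 while their posterior
medians are stable at ~10⁻³ SD units. The default budget resolves this.

## Prediction and evaluation

Marginal predictions are Xβ per draw, random effects at zero. Baseline
updating conditions (u0,u1) on the single observed time-0 eGFR per draw:
with z₀ = (1,0), r₀ = y₀ − x₀'β, the conditional law is Gaussian with mean
Gz₀(z₀'Gz₀+σ²)⁻¹r₀ (the BLUP) and covariance G − Gz₀(z₀'Gz₀+σ²)⁻¹z₀'G,
computed exactly (not a point-estimate plug-in). Metric evaluation uses
the per-draw conditional-mean predictions; uncertainty bands can
additionally sample the conditional covariance and, by default, residual
noise (flagged in the prediction metadata). Conditioning on more than the
baseline record is deliberately unsupported.

Out-of-sample R² is 1 − SSE/SST on held-out data (can be negative);
adjusted R² is 1 − (1−R²)(n−1)/(n−p−1) with p the number of fixed effects
excluding the intercept; the variance-ratio Bayesian R² is provided
separately for in-sample use. Cross-validation is fivefold grouped by
subject, repeated (default 5×), with per-repeat seed streams and fold
sizes within one of each other. Everything fold-dependent
(standardization statistics, imputation models) is derived from the
training fold only; grouped integrity is asserted on every split. Pooled
metrics are computed per posterior draw over the *concatenated* held-out
predictions of all splits — not as averages of per-fold metrics — then
summarized as median with 50%/95% equal-tailed intervals (linear
interpolation percentiles throughout). In updated mode the baseline record
is used for conditioning and excluded from scoring. Calibration tables
(observed vs posterior-median predicted, least-squares slope/intercept,
per follow-up-time bin) report empty bins explicitly.

## Importance and projection

Leave-one-variable-out removes a predictor's main and interaction terms
together, re-runs the full CV with identical folds/seeds, and ranks by the
increase in pooled CV-RMSE (descending; ties broken by name). The nested
submodel sequence starts at {intercept, time} and adds predictors in the
global ranking order. Submodel parameters come from Gaussian KL projection
of each training fold's reference posterior: per draw,
β⊥ = argmin‖X_ref β_ref − X_sub β‖² (minimum-norm with a warning if the
submodel design is rank-deficient) and σ⊥² = σ_ref² + ‖X_ref β_ref −
X_sub β⊥‖²/n, with the random-effect structure carried over unchanged —
submodels differ only in fixed-effect terms. Projection is exact on the
full design and idempotent. LOVO at full scale is 31 × the CV cost; the
shipped scaled defaults use reduced MCMC budgets and fewer repeats, with
all knobs in configuration.

## Multiple imputation

Chained equations on the transformed (log2/z) scale: Bayesian linear
conditionals with normal/inverse-gamma posterior draws for continuous
variables, logistic conditionals with asymptotic-normal parameter draws
for binary ones (falling back to the observed frequency under separation),
10 burn-in sweeps, m = 20 completions by default. Baseline eGFR is
included as a fully observed predictor of missing covariates; longitudinal
eGFR outcomes are never imputed (the mixed model handles unbalanced visits
natively). The imputer freezes each chain's final parameter draws, and new
data (CV test folds) are completed by replaying those frozen conditionals,
so test-fold information never enters the imputation model. Models are
fitted per completion and the posteriors pooled by concatenating draws.

## Synthetic cohorts

The generator emulates the cohort shape the analysis targets: 838 subjects
with diabetes, baseline eGFR ~96% within 25–70, eGFR measured at
alternating in-person visits (schedule 0, 2, 4 years + N(0, 0.1²) jitter
truncated at 0, baseline exact), hence a median of 2 post-baseline
measurements over ~4 years; ~5.5% of subjects drop out (per-visit
geometric hazard derived from the overall rate; dropout is
outcome-independent by design); ~3% of biomarker cells are missing (MCAR
by default, an eGFR-dependent MAR mechanism is available); 12 clinical
covariates with plausible marginals and 19 log-normal biomarkers.

True effects are sparse by default — 4 non-null baseline effects (TNFR1
−4, RAGE −2.5, IL1R1 −1.5, age −2 ml/min/1.73m² per SD) and 2 non-null
slope effects (KIM1 −0.75, UACR −0.5 per SD per year) out of 31 — with a
fixed intercept of 46, a population decline of −1/year, random-effect
covariance diag-ish [[64, −2], [−2, 2.25]] and residual sd 4. Effects
apply to the population-standardized design, which is stored alongside the
latent intercepts/slopes in the truth sidecar for recovery tests.

The biomarker–eGFR rank correlation (target median −0.30) is induced by a
shared latent factor among biomarkers that also carries the non-null
biomarker effects; the loading is calibrated by root-finding from the
Spearman↔Pearson relation for Gaussian copulas. Correlating covariates
with the random intercept instead would have violated the mixed-model
assumption the analysis itself makes and biased every coefficient; the
chosen mechanism keeps all null effects exactly null. A consequence: a
non-zero correlation target requires at least one non-null biomarker main
effect (enforced with a clear error), and the biomarker–biomarker
correlation level is tied to the calibrated loading (about 0.4 pairwise
under the defaults) — the generator does not control it independently.

What passing tests on these cohorts do *not* show: robustness to
informative dropout, non-Gaussian eGFR noise, non-linear predictor
effects, assay batch effects, or real biomarker correlation structure —
none of which the generator emulates.

## Problem sizes used by the shipped checks

Sparsity recovery runs at n = 800 with the full 31-predictor panel and
reduced MCMC (2 chains × 300/400, pooled over 2 imputations); update-gain
and importance checks run at n = 150 with 5–6 predictors, fivefold CV and
1–2 repeats; the end-to-end reproducibility run uses n = 120. These sizes
were chosen so the whole validation suite completes in minutes while every
qualitative property (null shrinkage, coverage, update gain, ranking
fidelity) is decidable; all of them scale up through configuration.

## Known limitations

* Credible intervals of horseshoe-shrunk coefficients are not calibrated
  confidence intervals: effects of borderline size are occasionally shrunk
  just past their nominal 95% interval (aggregate coverage of the default
  non-null effects stays ≥ 80–90% in the shipped checks, and the
  acceptance script reports it each run).
* The LOVO ΔRMSE of strongly correlated predictors is individually small
  (removal is compensated by the twin) — importance is a property of the
  predictor *set*, and duplicated information is ranked as exchangeable.
* Baseline updating uses exactly one conditioning record at t = 0;
  dynamic updating over accumulating follow-up is out of scope.
* The imputer's logistic conditionals use asymptotic parameter draws, not
  exact posteriors; with nearly-constant binary covariates in small folds
  it degrades to a frequency draw.
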