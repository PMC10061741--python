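"""Synthetic longitudinal CKD/diabetes cohorts.

Generates cohorts with the statistical structure the downstream analysis
assumes: per-subject eGFR trajectories from a linear mixed model with random
intercepts and slopes, a baseline covariate table of clinical predictors and
log-normal protein biomarkers, configurable sparsity of true effects,
biomarker–eGFR rank correlation, visit-time jitter, dropout, and biomarker
missingness.  A plate-level fixture generator supports the immunoassay QC
stage.

The generative model for subject i at time t_ij is

    eGFR_ij = b0 + x_i' beta_base + (b_t + x_i' beta_slope) * t_ij
              + u0_i + u1_i * t_ij + eps_ij

with (u0, u1) ~ N(0, G), eps ~ N(0, sigma^2).  Effects apply to the
population-standardized design (log2 + z-score for biomarkers and UACR,
z-score for continuous clinical variables, 0/1 for binary), so the
generating coefficients live on the same scale the models report.

Biomarkers share a latent severity factor that also carries the non-null
biomarker main effects; the factor loading is calibrated numerically so the
median Spearman correlation between biomarkers and baseline eGFR hits the
configured target without correlating covariates with the random effects
(which would violate the mixed-model assumptions the analysis makes).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "CLINICAL_PREDICTORS",
    "BIOMARKERS",
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "inject_missingness",
    "generate_plate_data",
]

# Clinical predictors in canonical order; scaled-down configs take a prefix.
CLINICAL_PREDICTORS = (
    "age", "sex", "bmi", "smoking", "map", "cholesterol",
    "uacr", "hba1c", "hemoglobin", "bp_med", "dm_med", "lipid_med",
)
BINARY_PREDICTORS = frozenset({"sex", "smoking", "bp_med", "dm_med", "lipid_med"})

# Serum biomarker panel (Luminex/ELISA); the markers that carry the default
# non-null effects come first so scaled-down panels retain them.
BIOMARKERS = (
    "TNFR1", "RAGE", "KIM1", "IL1R1", "GDF15", "MMP7", "Chemerin",
    "Fas", "FasLigand", "CCL11", "CCL15", "uPA", "A1M", "Angiopoietin1",
    "Angiopoietin2", "CCL5", "CCL14", "Galectin3", "Myoglobin",
)

# (mean, sd) on the raw scale of continuous clinical variables; UACR is
# parameterized on the log2 scale.
_CLINICAL_MARGINALS = {
    "age": (67.0, 7.5),
    "bmi": (32.0, 5.5),
    "map": (97.0, 11.0),
    "cholesterol": (195.0, 45.0),
    "uacr_log2": (5.2, 3.4),
    "hba1c": (7.1, 0.95),
    "hemoglobin": (13.7, 1.6),
}
_BINARY_PREVALENCE = {
    "sex": 0.34,        # coded 1 = female
    "smoking": 0.50,    # coded 1 = ever
    "bp_med": 0.95,
    "dm_med": 0.83,
    "lipid_med": 0.66,
}
# log2-scale location/scale for biomarker concentrations (arbitrary but
# plausible assay scales; the analysis only sees the log2/z transform).
_BIOMARKER_LOG2_LOC = 8.0
_BIOMARKER_LOG2_SCALE = 0.9


def _default_beta_base() -> dict[str, float]:
    # few non-null main effects: filtration/inflammation markers plus age,
    # all lowering eGFR level (ml/min/1.73m2 per SD of predictor)
    return {"TNFR1": -4.0, "RAGE": -2.5, "IL1R1": -1.5, "age": -2.0}


def _default_beta_slope() -> dict[str, float]:
    # few non-null decline effects: kidney-injury marker and albuminuria
    return {"KIM1": -0.75, "uacr": -0.5}


@dataclass
class CohortConfig:
    """Configuration of the synthetic cohort generator.

    Defaults emulate the cohort shape the analysis targets: n = 838 subjects
    with diabetes and moderately reduced kidney function, baseline eGFR
    mostly within 25–70 ml/min/1.73m2, eGFR measured at in-person visits
    two years apart (median two post-baseline measurements over ~4 years),
    ~5–6% dropout, ~3% missing biomarker values, and biomarkers with a
    median Spearman correlation of about −0.30 with baseline eGFR.
    """

    n_subjects: int = 838
    visit_schedule: tuple[float, ...] = (0.0, 2.0, 4.0)
    visit_jitter_sd: float = 0.1
    p_clinical: int = 12
    p_biomarkers: int = 19
    true_beta_base: dict[str, float] = field(default_factory=_default_beta_base)
    true_beta_slope: dict[str, float] = field(default_factory=_default_beta_slope)
    intercept: float = 46.0                      # ml/min/1.73m2
    time_slope: float = -1.0                     # ml/min/1.73m2 per year
    random_effect_cov: tuple[tuple[float, float], tuple[float, float]] = (
        (64.0, -2.0), (-2.0, 2.25))
    resid_sd: float = 4.0                        # ml/min/1.73m2
    biomarker_egfr_rank_corr: float = -0.30
    missing_rate: float = 0.03
    dropout_rate: float = 0.055
    seed: int = 0

    def validate(self) -> None:
        G = np.asarray(self.random_effect_cov, dtype=float)
        if G.shape != (2, 2) or not np.allclose(G, G.T):
            raise ValueError("random_effect_cov must be a symmetric 2x2 matrix")
        eig = np.linalg.eigvalsh(G)
        if np.any(eig < 0) or (np.any(eig <= 0) and not np.all(G == 0)):
            # all-zero covariance (degenerate, noise-free checks) is allowed
            if not np.all(G == 0):
                raise ValueError(
                    f"random_effect_cov is not positive definite: {G.tolist()}")
        for name, rate in (("missing_rate", self.missing_rate),
                           ("dropout_rate", self.dropout_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        t = np.asarray(self.visit_schedule, dtype=float)
        if t[0] != 0.0 or np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("visit_schedule must start at 0 and be strictly increasing")
        if not 1 <= self.p_clinical <= len(CLINICAL_PREDICTORS):
            raise ValueError("p_clinical out of range")
        if not 1 <= self.p_biomarkers <= len(BIOMARKERS):
            raise ValueError("p_biomarkers out of range")
        if self.resid_sd < 0:
            raise ValueError("resid_sd must be non-negative")
        unknown = (set(self.true_beta_base) | set(self.true_beta_slope)) - set(
            self.predictor_names)
        if unknown:
            raise ValueError(f"true effects refer to unknown predictors: {sorted(unknown)}")

    @property
    def clinical_names(self) -> list[str]:
        return list(CLINICAL_PREDICTORS[: self.p_clinical])

    @property
    def biomarker_names(self) -> list[str]:
        return list(BIOMARKERS[: self.p_biomarkers])

    @property
    def predictor_names(self) -> list[str]:
        return self.clinical_names + self.biomarker_names


@dataclass
class SyntheticCohort:
    """A generated cohort: long eGFR records, wide covariates, and truth."""

    records: pd.DataFrame       # subject_id, time_years, egfr
    covariates: pd.DataFrame    # subject_id + clinical + biomarker columns
    missing_mask: pd.DataFrame  # subject_id + boolean biomarker columns
    truth: dict                 # generating parameters and latent effects
    config: CohortConfig

    @property
    def subject_ids(self) -> np.ndarray:
        return self.covariates["subject_id"].to_numpy()

    def baseline_egfr(self) -> pd.Series:
        base = self.records[self.records["time_years"] == 0.0]
        return base.set_index("subject_id")["egfr"]

    def write(self, outdir: str | Path) -> None:
        """Write long records, wide covariates and the truth sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(outdir / "records.csv", index=False)
        self.covariates.to_csv(outdir / "covariates.csv", index=False)
        self.missing_mask.to_csv(outdir / "missing_mask.csv", index=False)
        truth = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.truth.items()
            if k != "design"
        }
        truth["config"] = _config_to_jsonable(self.config)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)


def _config_to_jsonable(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["visit_schedule"] = list(config.visit_schedule)
    d["random_effect_cov"] = [list(r) for r in config.random_effect_cov]
    return d


def _calibrate_factor_loading(config: CohortConfig, jitter: np.ndarray) -> float:
    """Loading of the shared biomarker factor hitting the rank-corr target.

    For bivariate normal variables with correlation r the Spearman
    correlation is (6/pi) asin(r/2); we invert that and solve for the
    common-factor loading c such that a null biomarker's latent correlation
    with baseline eGFR equals the required r.
    """
    rho = config.biomarker_egfr_rank_corr
    if rho == 0.0 or rho is None:
        return 0.0
    if not -1.0 < rho < 1.0:
        raise ValueError("biomarker_egfr_rank_corr must lie in (-1, 1)")
    r_target = 2.0 * np.sin(np.pi * rho / 6.0)

    bio = config.biomarker_names
    beta_bio = np.array([config.true_beta_base.get(b, 0.0) for b in bio])
    if np.all(beta_bio == 0.0):
        raise ValueError(
            "biomarker_egfr_rank_corr != 0 requires at least one non-null "
            "biomarker main effect; set the target to 0 for null generators")
    clin = config.clinical_names
    beta_clin_sq = sum(
        config.true_beta_base.get(cname, 0.0) ** 2
        for cname in clin if cname not in BINARY_PREDICTORS)
    # binary predictors with effects contribute p(1-p) variance
    for cname in clin:
        if cname in BINARY_PREDICTORS:
            p = _BINARY_PREVALENCE[cname]
            beta_clin_sq += config.true_beta_base.get(cname, 0.0) ** 2 * p * (1 - p)
    tau0_sq = float(np.asarray(config.random_effect_cov)[0, 0])
    sigma_sq = config.resid_sd ** 2
    med_jit = float(np.median(jitter))

    def gap(c: float) -> float:
        load = c * jitter
        s = float(beta_bio @ load)
        var_bio = float(np.sum(beta_bio**2)) + s**2 - float(
            np.sum(beta_bio**2 * load**2))
        sd0 = np.sqrt(var_bio + beta_clin_sq + tau0_sq + sigma_sq)
        return (c * med_jit) * s / sd0 - r_target

    lo, hi = 1e-6, 0.98
    if gap(lo) * gap(hi) > 0:
        raise ValueError(
            "cannot reach the configured biomarker_egfr_rank_corr with the "
            "configured effect sizes")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10))


def _generate_covariates(config: CohortConfig, rng: np.random.Generator):
    """Raw covariate table plus the population-standardized design."""
    n = config.n_subjects
    raw = {}
    design = {}
    stats: dict[str, dict] = {}

    for name in config.clinical_names:
        if name in BINARY_PREDICTORS:
            x = (rng.random(n) < _BINARY_PREVALENCE[name]).astype(float)
            raw[name] = x
            design[name] = x
            stats[name] = {"transform": "binary", "mean": 0.0, "sd": 1.0}
        elif name == "uacr":
            loc, scale = _CLINICAL_MARGINALS["uacr_log2"]
            z = rng.standard_normal(n)
            raw[name] = 2.0 ** (loc + scale * z)
            design[name] = z
            stats[name] = {"transform": "log2_z", "mean": loc, "sd": scale}
        else:
            loc, scale = _CLINICAL_MARGINALS[name]
            z = rng.standard_normal(n)
            raw[name] = loc + scale * z
            design[name] = z
            stats[name] = {"transform": "z", "mean": loc, "sd": scale}

    bio = config.biomarker_names
    jitter = 1.0 + 0.15 * np.cos(1.0 + np.arange(len(bio)))  # fixed spread
    c = _calibrate_factor_loading(config, jitter)
    m = rng.standard_normal(n)
    for j, name in enumerate(bio):
        load = c * jitter[j]
        z = load * m + np.sqrt(max(0.0, 1.0 - load**2)) * rng.standard_normal(n)
        loc = _BIOMARKER_LOG2_LOC + 0.4 * j
        raw[name] = 2.0 ** (loc + _BIOMARKER_LOG2_SCALE * z)
        design[name] = z
        stats[name] = {"transform": "log2_z", "mean": loc,
                       "sd": _BIOMARKER_LOG2_SCALE}

    subject_id = np.array([f"S{i:04d}" for i in range(n)])
    covariates = pd.DataFrame({"subject_id": subject_id, **raw})
    design_df = pd.DataFrame(design, index=subject_id)
    return covariates, design_df, stats, c


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a synthetic cohort under the configured mixed model.

    Deterministic given ``config`` (including its seed).  Raises
    ``ValueError`` for invalid configurations (non-PD random-effect
    covariance, rates outside [0, 1], non-increasing visit schedule).
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    n = config.n_subjects

    covariates, design, stats, loading = _generate_covariates(config, rng)
    subject_id = covariates["subject_id"].to_numpy()

    names = config.predictor_names
    X = design[names].to_numpy()
    beta_base = np.array([config.true_beta_base.get(p, 0.0) for p in names])
    beta_slope = np.array([config.true_beta_slope.get(p, 0.0) for p in names])

    G = np.asarray(config.random_effect_cov, dtype=float)
    if np.all(G == 0):
        b = np.zeros((n, 2))
    else:
        b = rng.multivariate_normal(np.zeros(2), G, size=n,
                                    method="cholesky")

    level = config.intercept + X @ beta_base + b[:, 0]
    slope = config.time_slope + X @ beta_slope + b[:, 1]

    sched = np.asarray(config.visit_schedule, dtype=float)
    n_post = len(sched) - 1
    if config.dropout_rate > 0 and n_post > 0:
        hazard = 1.0 - (1.0 - config.dropout_rate) ** (1.0 / n_post)
    else:
        hazard = 0.0

    rows = []
    for i in range(n):
        times = [0.0]
        for t_plan in sched[1:]:
            if hazard > 0 and rng.random() < hazard:
                break  # dropout: later visits truncated
            t = t_plan + config.visit_jitter_sd * rng.standard_normal()
            times.append(max(t, 1e-3))
        times = np.asarray(times)
        eps = config.resid_sd * rng.standard_normal(len(times))
        egfr = level[i] + slope[i] * times + eps
        for t, y in zip(times, egfr):
            rows.append((subject_id[i], float(t), float(max(y, 1.0))))

    records = pd.DataFrame(rows, columns=["subject_id", "time_years", "egfr"])

    missing_mask = pd.DataFrame(
        False, index=range(n), columns=config.biomarker_names)
    missing_mask.insert(0, "subject_id", subject_id)

    truth = {
        "b0": b[:, 0], "b1": b[:, 1],
        "level": level, "slope": slope,
        "beta_base": dict(zip(names, beta_base)),
        "beta_slope": dict(zip(names, beta_slope)),
        "intercept": config.intercept,
        "time_slope": config.time_slope,
        "factor_loading": loading,
        "transform_stats": stats,
        "design": design,
    }
    cohort = SyntheticCohort(records=records, covariates=covariates,
                             missing_mask=missing_mask, truth=truth,
                             config=config)
    if config.missing_rate > 0:
        cohort = inject_missingness(cohort, config.missing_rate, "MCAR",
                                    seed=config.seed + 1)
    return cohort


def inject_missingness(cohort: SyntheticCohort, rate: float,
                       mechanism: str = "MCAR", seed: int = 0,
                       mar_strength: float = 2.0) -> SyntheticCohort:
    """Mask biomarker cells at the given expected rate.

    ``MCAR`` masks uniformly; ``MAR-on-eGFR`` makes masking more likely for
    subjects with lower baseline eGFR (logistic weighting with slope
    ``mar_strength`` per baseline-eGFR standard deviation), rescaled so the
    expected masked fraction still equals ``rate``.  Baseline (time-0) eGFR
    records are never masked — only covariate biomarker cells are eligible.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"missingness rate must lie in [0, 1), got {rate}")
    if mechanism not in ("MCAR", "MAR-on-eGFR"):
        raise ValueError(f"unknown missingness mechanism: {mechanism!r}")
    if rate == 0.0:
        return cohort

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA55]))
    bio = cohort.config.biomarker_names
    n = len(cohort.covariates)

    if mechanism == "MCAR":
        p = np.full(n, rate)
    else:
        egfr0 = cohort.baseline_egfr().reindex(
            cohort.covariates["subject_id"]).to_numpy()
        zscore = (egfr0 - egfr0.mean()) / egfr0.std()
        w = special.expit(-mar_strength * zscore)
        p = np.minimum(rate * w / w.mean(), 0.99)

    mask = rng.random((n, len(bio))) < p[:, None]

    covariates = cohort.covariates.copy()
    vals = covariates[bio].to_numpy(dtype=float)
    vals[mask] = np.nan
    covariates[bio] = vals

    missing_mask = cohort.missing_mask.copy()
    missing_mask[bio] = missing_mask[bio].to_numpy() | mask

    return SyntheticCohort(records=cohort.records, covariates=covariates,
                           missing_mask=missing_mask, truth=cohort.truth,
                           config=cohort.config)


def generate_plate_data(n_analytes: int, n_samples: int,
                        rerun_fraction: float, seed: int = 0,
                        replicate_violation_fraction: float = 0.0,
                        n_interplate_violations: int = 0,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate immunoassay plate fixtures with known QC ground truth.

    Returns ``(plates, truth)``.  ``plates`` has one row per replicate with
    columns analyte, sample_id, plate_id, replicate_index, raw_concentration,
    standard_low, standard_high.  ``truth`` records, per sample x analyte,
    whether the QC stage should report it valid and why not otherwise.

    Violations are constructed exactly: a ``replicate_violation_fraction``
    of sample x analyte entries get duplicate spreads with CV in 18–30%
    (> the 15% validity bound); ``n_interplate_violations`` rerun samples
    get plate means differing enough to push the inter-plate CV above 20%.
    Reruns are drawn from the first samples to keep the construction
    deterministic given the seed.
    """
    if n_analytes <= 0 or n_samples <= 0:
        raise ValueError("n_analytes and n_samples must be positive")
    if not 0.0 <= rerun_fraction <= 1.0:
        raise ValueError("rerun_fraction must lie in [0, 1]")
    n_rerun = int(round(rerun_fraction * n_samples))
    if n_interplate_violations > n_rerun:
        raise ValueError("more inter-plate violations requested than reruns")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB10]))
    rows = []
    truth_rows = []
    for a in range(n_analytes):
        analyte = f"AN{a:02d}"
        low = 3.2 * 2.0 ** a
        high = low * 2048.0
        base = np.exp(rng.uniform(np.log(low * 4), np.log(high / 4), n_samples))
        n_viol = int(round(replicate_violation_fraction * n_samples))
        viol = np.zeros(n_samples, dtype=bool)
        if n_viol:
            # keep replicate violations disjoint from reruns so each entry
            # has a single unambiguous expected QC outcome
            pool = np.arange(n_rerun, n_samples)
            if len(pool) < n_viol:
                raise ValueError("too many violations for the non-rerun pool")
            viol[rng.choice(pool, size=n_viol, replace=False)] = True

        for s in range(n_samples):
            sample = f"P{s:05d}"
            if viol[s]:
                g = rng.uniform(0.18, 0.30) / np.sqrt(2.0)  # CV = g*sqrt(2)
            else:
                g = rng.uniform(0.005, 0.10) / np.sqrt(2.0)
            pair = (base[s] * (1 - g), base[s] * (1 + g))
            for k, v in enumerate(pair):
                rows.append((analyte, sample, "plate1", k, v, low, high))

            rerun = s < n_rerun
            inter_viol = False
            if rerun:
                inter_viol = s < n_interplate_violations
                shift = 1.6 if inter_viol else 1.0 + rng.uniform(0.01, 0.08)
                m2 = base[s] * shift
                g2 = rng.uniform(0.005, 0.10) / np.sqrt(2.0)
                for k, v in enumerate((m2 * (1 - g2), m2 * (1 + g2))):
                    rows.append((analyte, sample, "plate2", k, v, low, high))

            if viol[s]:
                expected, reason = False, "replicate_cv"
            elif inter_viol:
                expected, reason = False, "interplate_cv"
            else:
                expected, reason = True, ""
            truth_rows.append((analyte, sample, rerun, expected, reason))

    plates = pd.DataFrame(rows, columns=[
        "analyte", "sample_id", "plate_id", "replicate_index",
        "raw_concentration", "standard_low", "standard_high"])
    truth = pd.DataFrame(truth_rows, columns=[
        "analyte", "sample_id", "rerun", "expected_valid", "reason"])
    return plates, truth
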