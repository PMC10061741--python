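"""Bayesian linear mixed models for longitudinal eGFR trajectories.

Model:  y_ij = x_ij' beta + u0_i + u1_i * t_ij + eps_ij, with per-subject
random intercepts and slopes (u0, u1) ~ N(0, G) and eps ~ N(0, sigma^2).
The fixed design contains an intercept, observation time, one main term per
predictor (its association with overall eGFR level) and one time-interaction
term per predictor (its association with eGFR decline).

Three coefficient prior families are provided:

* ``student_t_weak`` — independent weakly informative Student-t priors,
  used by the univariable and clinical models;
* ``regularized_horseshoe`` — heavy-tailed local scales with a global scale
  and a Student-t slab bounding large coefficients, enforcing sparsity in
  the combined clinical + biomarker model;
* ``gaussian_fixed`` — fixed Gaussian priors (optionally with fixed
  variance components), giving a conjugate model with a closed-form
  posterior used as an oracle in the test-suite.

Inference is a blocked Gibbs sampler: conjugate Gaussian updates for fixed
and random effects, Huang–Wand auxiliary inverse-gamma/inverse-Wishart
updates for the random-effect covariance (half-t(2) marginals on the sds,
uniform marginal correlation), auxiliary inverse-gamma updates for the
half-Cauchy residual scale and Student-t local variances, and univariate
slice sampling for the regularized-horseshoe local/global/slab scales.

The outcome is standardized internally for the two weakly-informative
families (prior scales are therefore in outcome-sd units) and all draws are
returned on the original ml/min/1.73m2 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import invwishart

__all__ = [
    "McmcConfig",
    "ModelSpec",
    "Design",
    "PosteriorDraws",
    "FitDiagnostics",
    "build_design",
    "fit_blmm",
    "summarize_coefficients",
    "pool_posteriors",
    "check_convergence",
    "split_rhat",
]

_HALF_T_NU = 2.0          # Huang-Wand: half-t(2) marginals for RE sds
_RE_SD_SCALE = 25.0       # prior scale of random-effect sds (outcome units)
_SIGMA_SCALE = 25.0       # half-Cauchy scale of the residual sd


@dataclass
class McmcConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.chains < 1 or self.warmup < 0 or self.draws < 1:
            raise ValueError("invalid MCMC configuration")


def _default_hyper(prior_family: str) -> dict:
    if prior_family == "student_t_weak":
        return {"df": 3.0, "scale": 2.5, "intercept_scale": 10.0,
                "time_scale": 10.0}
    if prior_family == "regularized_horseshoe":
        return {"p0": 5.0, "slab_scale": 2.0, "slab_df": 4.0,
            "intercept_scale": 10.0, "time_scale": 10.0, "t_df": 3.0}
    if prior_family == "gaussian_fixed":
        return {"scale": 10.0}
    raise ValueError(f"unknown prior family: {prior_family!r}")


@dataclass
class ModelSpec:
    """Definition of one BLMM: terms, priors and the sampling budget."""

    predictor_names: list[str]
    include_interactions: bool = True
    prior_family: str = "student_t_weak"
    prior_hyperparams: dict = field(default_factory=dict)
    random_effects: bool = True
    fixed_resid_sd: float | None = None
    fixed_random_cov: np.ndarray | None = None
    mcmc: McmcConfig = field(default_factory=McmcConfig)

    def __post_init__(self) -> None:
        hyper = _default_hyper(self.prior_family)
        hyper.update(self.prior_hyperparams)
        self.prior_hyperparams = hyper
        if any(v <= 0 for v in hyper.values() if isinstance(v, (int, float))):
            raise ValueError("prior hyperparameters must be positive")
        self.mcmc.validate()

    @property
    def columns(self) -> list[str]:
        cols = ["intercept", "time"] + list(self.predictor_names)
        if self.include_interactions:
            cols += [f"{p}:time" for p in self.predictor_names]
        return cols

    def matches(self, other: "ModelSpec") -> bool:
        return (self.columns == other.columns
                and self.prior_family == other.prior_family
                and self.random_effects == other.random_effects)


@dataclass
class Design:
    """Aligned fixed/random design matrices and outcome for one model."""

    X: np.ndarray               # (n_obs, p) fixed design
    y: np.ndarray               # (n_obs,) outcome (eGFR)
    times: np.ndarray           # (n_obs,) years since baseline
    subject_codes: np.ndarray   # (n_obs,) index into subject_ids
    subject_ids: np.ndarray     # (n_subjects,)
    columns: list[str]
    stats_fp: str | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


def build_design(records: pd.DataFrame, design_cov: pd.DataFrame,
                 spec: ModelSpec, stats_fp: str | None = None) -> Design:
    """Assemble the fixed design [1, t, mains, mains x t] and outcome.

    ``design_cov`` holds the standardized predictors, indexed by subject id.
    Rows follow ``records`` order; interaction columns are the elementwise
    product of the main column and observation time.
    """
    missing = set(records["subject_id"]) - set(design_cov.index)
    if missing:
        raise ValueError(f"subjects missing from covariate table: "
                         f"{sorted(missing)[:5]}")
    unknown = [p for p in spec.predictor_names if p not in design_cov.columns]
    if unknown:
        raise ValueError(f"predictors not in covariate table: {unknown}")

    subject_ids, subject_codes = np.unique(records["subject_id"].to_numpy(),
                                           return_inverse=True)
    t = records["time_years"].to_numpy(dtype=float)
    Xmain = design_cov.loc[records["subject_id"],
                           spec.predictor_names].to_numpy(dtype=float)
    parts = [np.ones((len(records), 1)), t[:, None], Xmain]
    if spec.include_interactions:
        parts.append(Xmain * t[:, None])
    X = np.concatenate(parts, axis=1)
    y = records["egfr"].to_numpy(dtype=float)
    return Design(X=X, y=y, times=t, subject_codes=subject_codes,
                  subject_ids=subject_ids, columns=spec.columns,
                  stats_fp=stats_fp)


@dataclass
class PosteriorDraws:
    """Sampled joint posterior of one fitted BLMM (original outcome scale)."""

    beta: np.ndarray            # (n_draws, p)
    sigma: np.ndarray           # (n_draws,)
    G: np.ndarray | None        # (n_draws, 2, 2) or None without REs
    b: np.ndarray | None        # (n_draws, n_subjects, 2) or None
    chain: np.ndarray           # (n_draws,) chain index
    columns: list[str]
    subject_ids: np.ndarray
    spec: ModelSpec
    y_scale: float = 1.0        # outcome sd used for standardized reporting
    stats_fp: str | None = None

    @property
    def n_draws(self) -> int:
        return len(self.sigma)

    def beta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.beta, columns=self.columns)


@dataclass
class FitDiagnostics:
    r_hat: dict[str, float]
    ess: dict[str, float]
    warnings: list[str]
    passed: bool

    @property
    def max_r_hat(self) -> float:
        vals = [v for v in self.r_hat.values() if np.isfinite(v)]
        if len(vals) < len(self.r_hat):
            return float("inf")
        return max(vals) if vals else float("nan")


# ---------------------------------------------------------------------------
# slice sampling (vectorized over independent univariate targets)

def _slice_sample(u: np.ndarray, logpdf, rng: np.random.Generator,
                  width: float = 2.0, max_step: int = 16) -> np.ndarray:
    """One slice-sampling update per coordinate of independent targets."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    f0 = logpdf(u)
    logy = f0 + np.log(rng.random(u.shape))
    lo = u - width * rng.random(u.shape)
    hi = lo + width
    for _ in range(max_step):
        grow = logpdf(lo) > logy
        if not grow.any():
            break
        lo = np.where(grow, lo - width, lo)
    for _ in range(max_step):
        grow = logpdf(hi) > logy
        if not grow.any():
            break
        hi = np.where(grow, hi + width, hi)

    out = u.copy()
    active = np.ones(u.shape, dtype=bool)
    for _ in range(100):
        x = lo + (hi - lo) * rng.random(u.shape)
        ok = (logpdf(x) > logy) & active
        out[ok] = x[ok]
        active &= ~ok
        if not active.any():
            break
        shrink_lo = active & (x < u)
        shrink_hi = active & (x >= u)
        lo[shrink_lo] = x[shrink_lo]
        hi[shrink_hi] = x[shrink_hi]
    return out


def _hs_log_lambda_target(beta_sq, tau2, c2):
    """log density of u = log(lambda_j^2) given beta_j, tau, c."""
    def logpdf(u):
        eu = np.exp(u)
        lt2 = c2 * eu / (c2 + tau2 * eu)
        return (-0.5 * np.log(lt2) - beta_sq / (2.0 * tau2 * lt2)
                + 0.5 * u - np.logaddexp(0.0, u))
    return logpdf


# ---------------------------------------------------------------------------
# Gibbs sampler

class _PriorState:
    """Per-chain state of the coefficient-prior scale parameters."""

    def __init__(self, spec: ModelSpec, p: int, n_obs: int):
        self.family = spec.prior_family
        h = spec.prior_hyperparams
        self.p = p
        self.shrunk = np.zeros(p, dtype=bool)
        self.shrunk[2:] = True  # intercept and time are never shrunk
        if self.family == "gaussian_fixed":
            scale = np.broadcast_to(np.asarray(h["scale"], dtype=float), (p,))
            self.v = scale.astype(float) ** 2
        elif self.family == "student_t_weak":
            self.t_scales = np.full(p, h["scale"])
            self.t_scales[0] = h["intercept_scale"]
            self.t_scales[1] = h["time_scale"]
            self.t_df = h["df"]
            self.psi = np.ones(p)
            self.v = self.t_scales**2 * self.psi
        else:  # regularized horseshoe on predictor terms, t on intercept/time
            self.t_scales = np.array([h["intercept_scale"], h["time_scale"]])
            self.t_df = h["t_df"]
            self.psi = np.ones(2)
            d_eff = max(p - 2, 1)
            p0 = min(h["p0"], d_eff - 0.5) if d_eff > 1 else 0.5
            self.tau0_base = p0 / max(d_eff - p0, 0.5) / np.sqrt(n_obs)
            self.slab_scale = h["slab_scale"]
            self.slab_df = h["slab_df"]
            self.log_lambda2 = np.zeros(p - 2)
            self.log_tau2 = 2.0 * np.log(self.tau0_base)
            self.c2 = h["slab_scale"] ** 2
            self.v = np.ones(p)
            self._refresh_v()

    def _refresh_v(self):
        lam2 = np.exp(self.log_lambda2)
        tau2 = np.exp(self.log_tau2)
        lt2 = self.c2 * lam2 / (self.c2 + tau2 * lam2)
        self.v[:2] = self.t_scales**2 * self.psi
        self.v[2:] = tau2 * lt2

    def update(self, beta: np.ndarray, sigma2: float,
               rng: np.random.Generator) -> None:
        if self.family == "gaussian_fixed":
            return
        if self.family == "student_t_weak":
            rate = (self.t_df + beta**2 / self.t_scales**2) / 2.0
            self.psi = rate / rng.gamma((self.t_df + 1.0) / 2.0, 1.0, self.p)
            self.v = self.t_scales**2 * self.psi
            return

        # intercept/time Student-t scales
        b2 = beta[:2] ** 2
        rate = (self.t_df + b2 / self.t_scales**2) / 2.0
        self.psi = rate / rng.gamma((self.t_df + 1.0) / 2.0, 1.0, 2)

        beta_sq = beta[2:] ** 2
        tau2 = np.exp(self.log_tau2)
        self.log_lambda2 = _slice_sample(
            self.log_lambda2, _hs_log_lambda_target(beta_sq, tau2, self.c2),
            rng)
        lam2 = np.exp(self.log_lambda2)

        tau0 = self.tau0_base * np.sqrt(sigma2)

        def tau_target(u):
            t2 = np.exp(u)
            lt2 = self.c2 * lam2[:, None] / (self.c2 + t2[None, :] * lam2[:, None])
            ll = np.sum(-0.5 * np.log(t2[None, :] * lt2)
                        - beta_sq[:, None] / (2.0 * t2[None, :] * lt2), axis=0)
            return ll + 0.5 * u - np.log(tau0**2 + t2)

        self.log_tau2 = float(_slice_sample(
            np.array([self.log_tau2]), tau_target, rng)[0])
        tau2 = np.exp(self.log_tau2)

        nu_s, s_s = self.slab_df, self.slab_scale

        def c_target(u):
            cc = np.exp(u)
            lt2 = cc[None, :] * lam2[:, None] / (cc[None, :] + tau2 * lam2[:, None])
            ll = np.sum(-0.5 * np.log(lt2)
                        - beta_sq[:, None] / (2.0 * tau2 * lt2), axis=0)
            prior = -(nu_s / 2.0) * u - nu_s * s_s**2 / (2.0 * cc)
            return ll + prior

        self.c2 = float(np.exp(_slice_sample(
            np.array([np.log(self.c2)]), c_target, rng)[0]))
        self._refresh_v()


def _run_chain(design: Design, spec: ModelSpec, seed_key: list[int],
               y_scale: float):
    """One MCMC chain; returns kept draws (standardized outcome scale)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed_key))
    X, y, t = design.X, design.y, design.times
    code = design.subject_codes
    n, p = X.shape
    n_subj = design.n_subjects
    use_re = spec.random_effects

    XtX = X.T @ X
    Xty = X.T @ y
    n_i = np.bincount(code, minlength=n_subj).astype(float)
    st_i = np.bincount(code, weights=t, minlength=n_subj)
    st2_i = np.bincount(code, weights=t * t, minlength=n_subj)
    if use_re:
        # per-subject cross-products X_i' Z_i and Z_i' y_i, constant across
        # iterations; used to marginalize the random effects in the beta
        # update (partially collapsed Gibbs, which decouples the fixed
        # intercept/slope from the subject-effect means)
        A_z = np.zeros((n_subj, p, 2))
        np.add.at(A_z[:, :, 0], code, X)
        np.add.at(A_z[:, :, 1], code, X * t[:, None])
        u_z = np.column_stack([np.bincount(code, weights=y, minlength=n_subj),
                               np.bincount(code, weights=y * t,
                                           minlength=n_subj)])

    prior = _PriorState(spec, p, n)
    beta = np.zeros(p)
    beta[0] = float(np.mean(y))
    b = np.zeros((n_subj, 2))

    fixed_sigma = spec.fixed_resid_sd is not None
    sigma2 = (spec.fixed_resid_sd / y_scale) ** 2 if fixed_sigma else 1.0
    a_sigma = 1.0
    sig_scale = _SIGMA_SCALE / y_scale

    fixed_G = spec.fixed_random_cov is not None
    if fixed_G:
        G = np.asarray(spec.fixed_random_cov, dtype=float) / y_scale**2
    else:
        G = np.eye(2)
    a_G = np.ones(2)
    A_re = _RE_SD_SCALE / y_scale

    warm, keep = spec.mcmc.warmup, spec.mcmc.draws
    out_beta = np.empty((keep, p))
    out_sigma = np.empty(keep)
    out_G = np.empty((keep, 2, 2)) if use_re else None
    out_b = np.empty((keep, n_subj, 2)) if use_re else None

    for it in range(warm + keep):
        if use_re and not fixed_sigma:
            # residual variance | beta, G — random effects integrated out
            # (slice sampling on the marginal likelihood; the conjugate
            # update conditional on b mixes poorly when the random-effect
            # variance dominates sigma^2)
            Gi = np.linalg.inv(G)
            sign_G, logdet_G = np.linalg.slogdet(G)
            r = y - X @ beta
            rr = float(r @ r)
            r1 = np.bincount(code, weights=r, minlength=n_subj)
            rt = np.bincount(code, weights=r * t, minlength=n_subj)

            def sigma_target(u):
                out = np.empty_like(u)
                for i_u, ui in enumerate(u):
                    s2 = np.exp(ui)
                    P11 = n_i / s2 + Gi[0, 0]
                    P12 = st_i / s2 + Gi[0, 1]
                    P22 = st2_i / s2 + Gi[1, 1]
                    det = P11 * P22 - P12**2
                    quad = (P22 * r1**2 - 2 * P12 * r1 * rt
                            + P11 * rt**2) / det
                    qf = rr / s2 - float(np.sum(quad)) / s2**2
                    logdet = (n * np.log(s2) + float(np.sum(np.log(det)))
                              + n_subj * logdet_G)
                    lp = 0.5 * ui - np.log(sig_scale**2 + s2)
                    out[i_u] = -0.5 * (logdet + qf) + lp
                return out

            sigma2 = float(np.exp(_slice_sample(
                np.array([np.log(sigma2)]), sigma_target, rng)[0]))

        if use_re:
            # fixed effects | G, sigma, scales — random effects integrated
            # out via Woodbury on the per-subject 2x2 blocks
            Gi = np.linalg.inv(G)
            P11 = n_i / sigma2 + Gi[0, 0]
            P12 = st_i / sigma2 + Gi[0, 1]
            P22 = st2_i / sigma2 + Gi[1, 1]
            det = P11 * P22 - P12**2
            M11, M12, M22 = P22 / det, -P12 / det, P11 / det
            # B_s = A_s M_s  (n_subj, p, 2)
            B0 = A_z[:, :, 0] * M11[:, None] + A_z[:, :, 1] * M12[:, None]
            B1 = A_z[:, :, 0] * M12[:, None] + A_z[:, :, 1] * M22[:, None]
            flatB = np.concatenate([B0, B1], axis=0)      # (2 n_subj, p)
            flatA = np.concatenate([A_z[:, :, 0], A_z[:, :, 1]], axis=0)
            corr = flatB.T @ flatA / sigma2**2
            A = XtX / sigma2 - corr + np.diag(1.0 / prior.v)
            rhs = (Xty / sigma2
                   - (B0.T @ u_z[:, 0] + B1.T @ u_z[:, 1]) / sigma2**2)
        else:
            A = XtX / sigma2 + np.diag(1.0 / prior.v)
            rhs = Xty / sigma2
        cf = linalg.cho_factor(A, lower=True)
        mean = linalg.cho_solve(cf, rhs)
        z = rng.standard_normal(p)
        beta = mean + linalg.solve_triangular(cf[0], z, lower=True, trans="T")

        if use_re:
            # random effects | beta, G, sigma (per-subject 2x2 Gaussian)
            r = y - X @ beta
            r1 = np.bincount(code, weights=r, minlength=n_subj)
            rt = np.bincount(code, weights=r * t, minlength=n_subj)
            m0 = (P22 * r1 - P12 * rt) / (det * sigma2)
            m1 = (P11 * rt - P12 * r1) / (det * sigma2)
            # sample via closed-form 2x2 Cholesky of the precision
            L11 = np.sqrt(P11)
            L21 = P12 / L11
            L22 = np.sqrt(P22 - L21**2)
            z1 = rng.standard_normal(n_subj)
            z2 = rng.standard_normal(n_subj)
            e1 = (z1 - (L21 / L22) * z2) / L11
            e2 = z2 / L22
            b = np.column_stack([m0 + e1, m1 + e2])

            if not fixed_G:
                # Huang-Wand: IW draw with auxiliary scales
                S = b.T @ b
                scale = 2.0 * _HALF_T_NU * np.diag(1.0 / a_G) + S
                df = _HALF_T_NU + 1.0 + n_subj
                G = invwishart.rvs(df, scale, random_state=rng)
                Gi = np.linalg.inv(G)
                shape = (_HALF_T_NU + 2.0) / 2.0
                rate = _HALF_T_NU * np.diag(Gi) + 1.0 / A_re**2
                a_G = rate / rng.gamma(shape, 1.0, 2)

        if not fixed_sigma and not use_re:
            resid = y - X @ beta
            ssr = float(resid @ resid)
            sigma2 = (1.0 / a_sigma + ssr / 2.0) / rng.gamma((n + 1.0) / 2.0)
            a_sigma = (1.0 / sig_scale**2 + 1.0 / sigma2) / rng.gamma(1.0)

        prior.update(beta, sigma2, rng)

        if it >= warm:
            k = it - warm
            out_beta[k] = beta
            out_sigma[k] = np.sqrt(sigma2)
            if use_re:
                out_G[k] = G
                out_b[k] = b

    return out_beta, out_sigma, out_G, out_b


def fit_blmm(design: Design, spec: ModelSpec, seed: int | None = None,
             ) -> tuple[PosteriorDraws, FitDiagnostics]:
    """Sample the joint posterior of the configured BLMM.

    Reproducible given the seed (``spec.mcmc.seed`` unless overridden).
    Convergence problems surface in the returned diagnostics; singular fixed
    designs are reported as a warning (the proper priors keep the posterior
    well defined).
    """
    if not np.all(np.isfinite(design.X)) or not np.all(np.isfinite(design.y)):
        raise ValueError("design contains non-finite values; impute or drop "
                         "missing cells before fitting")
    if spec.random_effects and design.n_subjects < 2:
        raise ValueError("random effects require at least 2 subjects")
    if list(design.columns) != spec.columns:
        raise ValueError("design columns do not match the model spec")
    seed = spec.mcmc.seed if seed is None else seed

    warns: list[str] = []
    if design.X.shape[1] <= 64:
        if np.linalg.matrix_rank(design.X) < design.X.shape[1]:
            warns.append("fixed design is rank-deficient; coefficients are "
                         "identified only through the prior")

    # internal outcome standardization for the weakly-informative families
    if spec.prior_family == "gaussian_fixed":
        center, scale = 0.0, 1.0
    else:
        center = float(np.mean(design.y))
        scale = float(np.std(design.y))
        if scale == 0.0:
            scale = 1.0
    sdesign = replace(design, y=(design.y - center) / scale)

    chains = []
    for c in range(spec.mcmc.chains):
        chains.append(_run_chain(sdesign, spec, [int(seed), c, 0x617], scale))

    keep = spec.mcmc.draws
    beta = np.concatenate([ch[0] for ch in chains])
    sigma = np.concatenate([ch[1] for ch in chains])
    chain_ix = np.repeat(np.arange(spec.mcmc.chains), keep)
    use_re = spec.random_effects
    G = np.concatenate([ch[2] for ch in chains]) if use_re else None
    b = np.concatenate([ch[3] for ch in chains]) if use_re else None

    # back-transform to the original outcome scale
    beta = beta * scale
    beta[:, 0] += center
    sigma = sigma * scale
    if use_re:
        G = G * scale**2
        b = b * scale

    sd_y = float(np.std(design.y))
    draws = PosteriorDraws(beta=beta, sigma=sigma, G=G, b=b, chain=chain_ix,
                           columns=list(design.columns),
                           subject_ids=design.subject_ids, spec=spec,
                           y_scale=sd_y if sd_y > 0 else 1.0,
                           stats_fp=design.stats_fp)
    diag = check_convergence(draws, extra_warnings=warns)
    return draws, diag


# ---------------------------------------------------------------------------
# summaries, pooling, diagnostics

def summarize_coefficients(draws: PosteriorDraws,
                           standardized: bool = False) -> pd.DataFrame:
    """Posterior medians with 50% and 95% equal-tailed credible intervals.

    Percentile endpoints (2.5/25/75/97.5) use linear interpolation over the
    pooled draws.  Each predictor's main (baseline) and time-interaction
    (slope) coefficients are paired through the ``predictor``/``role``
    columns.  With ``standardized=True`` coefficients are reported per
    outcome standard deviation.
    """
    if draws.n_draws == 0:
        raise ValueError("no posterior draws to summarize")
    beta = draws.beta / draws.y_scale if standardized else draws.beta
    q = np.percentile(beta, [2.5, 25.0, 50.0, 75.0, 97.5], axis=0)
    rows = []
    for j, col in enumerate(draws.columns):
        if col.endswith(":time"):
            predictor, role = col[:-5], "slope"
        elif col in ("intercept", "time"):
            predictor, role = col, "structural"
        else:
            predictor, role = col, "baseline"
        rows.append((col, predictor, role, q[2, j], q[0, j], q[1, j],
                     q[3, j], q[4, j]))
    return pd.DataFrame(rows, columns=[
        "term", "predictor", "role", "median", "q2.5", "q25", "q75", "q97.5"])


def pool_posteriors(draws_list: list[PosteriorDraws]) -> PosteriorDraws:
    """Pool posteriors across imputed-dataset fits by concatenating draws."""
    if not draws_list:
        raise ValueError("nothing to pool")
    first = draws_list[0]
    for other in draws_list[1:]:
        if not first.spec.matches(other.spec):
            raise ValueError("cannot pool posteriors with different model specs")
        if first.b is not None and not np.array_equal(
                first.subject_ids, other.subject_ids):
            raise ValueError("cannot pool posteriors over different subjects")
    cat = lambda xs: None if xs[0] is None else np.concatenate(xs)
    return PosteriorDraws(
        beta=np.concatenate([d.beta for d in draws_list]),
        sigma=np.concatenate([d.sigma for d in draws_list]),
        G=cat([d.G for d in draws_list]),
        b=cat([d.b for d in draws_list]),
        chain=np.concatenate([d.chain + 1000 * i
                              for i, d in enumerate(draws_list)]),
        columns=first.columns, subject_ids=first.subject_ids,
        spec=first.spec, y_scale=first.y_scale, stats_fp=first.stats_fp)


def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat for one parameter; ``chains`` has shape (m, n)."""
    m, n = chains.shape
    half = n // 2
    if half < 2:
        return float("nan")
    split = chains[:, : 2 * half].reshape(2 * m, half)
    within = split.var(axis=1, ddof=1)
    W = float(within.mean())
    B = half * float(split.mean(axis=1).var(ddof=1))
    if W == 0.0:
        return 1.0 if B == 0.0 else float("inf")
    var_plus = (half - 1) / half * W + B / half
    return float(np.sqrt(var_plus / W))


def _ess_all(stacked: np.ndarray) -> np.ndarray:
    """Bulk effective sample sizes via arviz; input (chains, draws, k)."""
    import arviz as az
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        val = az.ess(az.convert_to_dataset(stacked))
    return np.asarray(val["x"]).ravel()


def check_convergence(draws: PosteriorDraws, rhat_max: float = 1.01,
                      ess_min: float = 100.0,
                      extra_warnings: list[str] | None = None,
                      ) -> FitDiagnostics:
    """Split-R-hat and effective-sample-size verdict for the main parameters.

    Pass iff every monitored parameter has split-R-hat below ``rhat_max``
    and effective sample size above ``ess_min``.  Refuses to compute R-hat
    from a single chain.
    """
    n_chains = len(np.unique(draws.chain))
    if n_chains < 2:
        raise ValueError("R-hat requires at least 2 chains")
    per = draws.n_draws // n_chains
    order = np.argsort(draws.chain, kind="stable")

    monitored = {f"beta[{c}]": draws.beta[order, j].reshape(n_chains, per)
                 for j, c in enumerate(draws.columns)}
    monitored["sigma"] = draws.sigma[order].reshape(n_chains, per)

    # parameters fixed by configuration (constant across all draws) carry
    # no sampling uncertainty and are excluded from the verdict
    fixed = {k for k, v in monitored.items() if np.all(v == v.flat[0])}
    r_hat = {k: (1.0 if k in fixed else split_rhat(v))
             for k, v in monitored.items()}
    free = [k for k in monitored if k not in fixed]
    if free:
        stacked = np.stack([monitored[k] for k in free], axis=-1)
        ess = dict(zip(free, _ess_all(stacked)))
    else:
        ess = {}
    warns = list(extra_warnings or [])
    bad_r = [k for k, v in r_hat.items() if not (v < rhat_max)]
    bad_e = [k for k, v in ess.items() if not (v > ess_min)]
    if bad_r:
        warns.append(f"R-hat above {rhat_max} for: {bad_r[:8]}")
    if bad_e:
        warns.append(f"ESS below {ess_min} for: {bad_e[:8]}")
    return FitDiagnostics(r_hat=r_hat, ess=ess, warnings=warns,
                          passed=not bad_r and not bad_e)
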