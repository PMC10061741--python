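"""Multiple imputation of missing baseline covariates by chained equations.

Conditional models are Bayesian linear regressions on the transformed
modeling scale (log2 + z for biomarkers and UACR, z for other continuous
variables) with normal/inverse-gamma posterior parameter draws, and
logistic regressions with asymptotic-normal parameter draws for binary
variables.  Baseline eGFR is included as a fully observed predictor of
missingness by default.

The imputer is fitted on training data only: it runs m parallel chains of
chained-equation sweeps on the training table and freezes each chain's
final per-variable parameter draw.  Applying the imputer to new data (the
cross-validation test fold) replays those frozen conditionals for a fixed
number of sweeps, so no information from the new data's distribution enters
the imputation model.  Longitudinal eGFR outcomes are never imputed — the
mixed model handles unbalanced visit patterns natively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import transform_predictors

__all__ = ["ImputationModel", "fit_imputer", "impute"]

_RIDGE = 1e-6


@dataclass
class ImputationModel:
    stats: dict                      # transformation stats (training scale)
    columns: list[str]               # variables, visit sequence order
    incomplete: list[str]            # variables with conditional models
    binary: set[str]
    m: int
    n_iter: int
    use_baseline_egfr: bool
    params: list[dict] = field(default_factory=list)  # per chain: col -> draw
    baseline_stats: tuple[float, float] | None = None


def _bayes_linear_draw(X: np.ndarray, y: np.ndarray,
                       rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Posterior draw (beta, sigma) of a ridge-stabilized linear model."""
    n, k = X.shape
    XtX = X.T @ X + _RIDGE * np.eye(k)
    coef = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ coef
    ssr = float(resid @ resid)
    df = max(n - k, 2)
    sigma2 = ssr / rng.chisquare(df) if ssr > 0 else 1e-12
    cov = sigma2 * np.linalg.inv(XtX)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(k))
    beta = coef + L @ rng.standard_normal(k)
    return beta, float(np.sqrt(sigma2))


def _logistic_draw(X: np.ndarray, y: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray | float:
    """Asymptotic-normal parameter draw of a logistic conditional.

    Falls back to the observed frequency (returned as a float) when the
    MLE fails, e.g. under perfect separation in small folds.
    """
    import warnings

    import statsmodels.api as sm
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=50)
        cov = np.asarray(res.cov_params())
        L = np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0]))
        return np.asarray(res.params) + L @ rng.standard_normal(cov.shape[0])
    except Exception:
        return float(np.clip(y.mean(), 1e-3, 1 - 1e-3))


def fit_imputer(covariates: pd.DataFrame,
                baseline_egfr: pd.Series | None = None,
                m: int = 20, n_iter: int = 10, seed: int = 0,
                min_obs: int = 20) -> ImputationModel:
    """Fit the chained-equations imputer on training covariates.

    ``covariates`` holds raw-scale predictors (plus ``subject_id``);
    ``baseline_egfr`` (indexed by subject id) is used as an additional fully
    observed predictor when supplied.  Raises for variables with no (or
    fewer than ``min_obs``) observed values.
    """
    if m < 2:
        raise ValueError("multiple imputation needs m >= 2 completions")
    design, stats = transform_predictors(covariates)
    cols = list(design.columns)
    n = len(design)

    n_obs = design.notna().sum()
    empty = [c for c in cols if n_obs[c] == 0]
    if empty:
        raise ValueError(f"variables with no observed values: {empty}")
    sparse = [c for c in cols if 0 < n_obs[c] < min_obs]
    if sparse:
        raise ValueError(
            f"variables observed for fewer than {min_obs} subjects: {sparse}")

    binary = {c for c in cols if stats[c]["transform"] == "binary"}
    # visit sequence: least missing first
    incomplete = sorted((c for c in cols if n_obs[c] < n),
                        key=lambda c: (n - n_obs[c], c))

    base_stats = None
    Z = design.to_numpy(dtype=float)
    extra = np.empty((n, 0))
    if baseline_egfr is not None:
        e0 = baseline_egfr.reindex(covariates["subject_id"]).to_numpy(float)
        mu, sd = float(np.mean(e0)), float(np.std(e0, ddof=1))
        sd = sd if sd > 0 else 1.0
        base_stats = (mu, sd)
        extra = ((e0 - mu) / sd)[:, None]

    model = ImputationModel(stats=stats, columns=cols, incomplete=incomplete,
                            binary=binary, m=m, n_iter=n_iter,
                            use_baseline_egfr=baseline_egfr is not None,
                            baseline_stats=base_stats)
    col_ix = {c: j for j, c in enumerate(cols)}
    miss = np.isnan(Z)
    for chain in range(m):
        rng = np.random.default_rng(np.random.SeedSequence([seed, chain, 0x171]))
        W = Z.copy()
        # initialize missing cells from observed marginals
        for c in incomplete:
            j = col_ix[c]
            obs = Z[~miss[:, j], j]
            W[miss[:, j], j] = rng.choice(obs, size=int(miss[:, j].sum()))
        params: dict[str, tuple] = {}
        for _ in range(n_iter):
            for c in incomplete:
                j = col_ix[c]
                others = np.delete(np.arange(len(cols)), j)
                X = np.concatenate(
                    [np.ones((n, 1)), W[:, others], extra], axis=1)
                obs_mask = ~miss[:, j]
                if c in binary:
                    theta = _logistic_draw(X[obs_mask], W[obs_mask, j], rng)
                    params[c] = ("logistic", theta)
                    if miss[:, j].any():
                        if isinstance(theta, float):
                            p_hat = np.full(int(miss[:, j].sum()), theta)
                        else:
                            from scipy.special import expit
                            p_hat = expit(X[miss[:, j]] @ theta)
                        W[miss[:, j], j] = (rng.random(len(p_hat)) < p_hat)
                else:
                    beta, sd_c = _bayes_linear_draw(X[obs_mask],
                                                    W[obs_mask, j], rng)
                    params[c] = ("linear", beta, sd_c)
                    if miss[:, j].any():
                        mu_mis = X[miss[:, j]] @ beta
                        W[miss[:, j], j] = mu_mis + sd_c * rng.standard_normal(
                            len(mu_mis))
        # conditional models for the fully observed variables too, so new
        # data (e.g. a CV test fold) can have any cell imputed
        for c in cols:
            if c in params:
                continue
            j = col_ix[c]
            others = np.delete(np.arange(len(cols)), j)
            X = np.concatenate([np.ones((n, 1)), W[:, others], extra], axis=1)
            if c in binary:
                params[c] = ("logistic", _logistic_draw(X, W[:, j], rng))
            else:
                beta, sd_c = _bayes_linear_draw(X, W[:, j], rng)
                params[c] = ("linear", beta, sd_c)
        model.params.append(params)
    return model


def _back_transform(values: np.ndarray, stat: dict) -> np.ndarray:
    kind = stat["transform"]
    if kind == "binary":
        return values
    raw = values * stat["sd"] + stat["mean"]
    return 2.0**raw if kind == "log2_z" else raw


def impute(imputer: ImputationModel, covariates: pd.DataFrame,
           m: int | None = None, seed: int = 0,
           baseline_egfr: pd.Series | None = None,
           n_sweeps: int = 5) -> list[pd.DataFrame]:
    """Produce m completed covariate tables (original scale).

    Observed cells are identical to the input in every completion; missing
    cells are filled by replaying the imputer's frozen conditional-model
    parameter draws (one frozen chain per completion) for ``n_sweeps``
    chained sweeps.  Deterministic given the seed.
    """
    m = imputer.m if m is None else m
    if m > imputer.m:
        raise ValueError(f"imputer was fitted with m = {imputer.m} chains")
    if imputer.use_baseline_egfr and baseline_egfr is None:
        raise ValueError("imputer was fitted with baseline eGFR; supply it")

    design, _ = transform_predictors(
        covariates[["subject_id"] + imputer.columns], imputer.stats)
    Z = design.to_numpy(dtype=float)
    n = len(design)
    miss = np.isnan(Z)
    col_ix = {c: j for j, c in enumerate(imputer.columns)}

    extra = np.empty((n, 0))
    if imputer.use_baseline_egfr:
        mu, sd = imputer.baseline_stats
        e0 = baseline_egfr.reindex(covariates["subject_id"]).to_numpy(float)
        extra = ((e0 - mu) / sd)[:, None]

    targets = [c for c in imputer.columns if miss[:, col_ix[c]].any()]
    completions = []
    for chain in range(m):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, chain, 0x1B2]))
        params = imputer.params[chain]
        W = Z.copy()
        for c in targets:
            # training mean on the transformed scale is ~0 by construction
            W[miss[:, col_ix[c]], col_ix[c]] = 0.0
        for sweep in range(n_sweeps):
            for c in targets:
                j = col_ix[c]
                rows = miss[:, j]
                others = np.delete(np.arange(len(imputer.columns)), j)
                X = np.concatenate(
                    [np.ones((int(rows.sum()), 1)), W[rows][:, others],
                     extra[rows]], axis=1)
                spec = params[c]
                if spec[0] == "logistic":
                    theta = spec[1]
                    if isinstance(theta, float):
                        p_hat = np.full(X.shape[0], theta)
                    else:
                        from scipy.special import expit
                        p_hat = expit(X @ theta)
                    W[rows, j] = (rng.random(len(p_hat)) < p_hat)
                else:
                    _, beta, sd_c = spec
                    W[rows, j] = X @ beta + sd_c * rng.standard_normal(
                        X.shape[0])

        out = covariates.copy()
        for c in imputer.columns:
            j = col_ix[c]
            if miss[:, j].any():
                col = out[c].to_numpy(dtype=float)
                col[miss[:, j]] = _back_transform(W[miss[:, j], j],
                                                  imputer.stats[c])
                out[c] = col
        completions.append(out)
    return completions
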