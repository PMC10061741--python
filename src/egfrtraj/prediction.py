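"""Trajectory prediction: marginal and baseline-updated, with metrics.

Marginal predictions use fixed effects only (random effects at zero) and
quantify what baseline covariates alone say about the whole eGFR
trajectory.  Baseline-updated predictions condition each unseen subject's
random effects on their single observed baseline (time-0) eGFR: with random
design z0 = (1, 0) and residual r0 = y0 - x0'beta, the random-effect
posterior within one parameter draw is Gaussian with

    mean  =  G z0 (z0' G z0 + sigma^2)^-1 r0          (the BLUP)
    cov   =  G  -  G z0 (z0' G z0 + sigma^2)^-1 z0' G

computed exactly per posterior draw.  Performance is summarized by the
posterior distributions of R^2 (1 - SSE/SST on the evaluated records),
adjusted R^2 and RMSE, plus calibration stratified by follow-up time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blmm import Design, PosteriorDraws

__all__ = [
    "TrajectoryPrediction",
    "predict_marginal",
    "update_by_baseline",
    "r2_rmse",
    "bayes_r2",
    "summarize_metric",
    "calibration_by_followup",
]


@dataclass
class TrajectoryPrediction:
    """Per-draw predicted eGFR for a set of records of one or more subjects.

    ``draws`` holds the conditional-mean prediction per posterior draw
    (n_draws x n_records); sampled predictive draws including random-effect
    conditional covariance and, optionally, residual noise are in
    ``predictive`` when requested.  The point prediction is the per-record
    posterior median of ``draws``.
    """

    subject_id: np.ndarray
    times: np.ndarray
    draws: np.ndarray
    mode: str                           # "marginal" | "baseline_updated"
    predictive: np.ndarray | None = None
    includes_noise: bool = False
    cond_mean: np.ndarray | None = None  # (n_draws, n_subjects, 2)
    cond_cov: np.ndarray | None = None   # (n_draws, 2, 2)
    cond_subjects: np.ndarray | None = None

    @property
    def point(self) -> np.ndarray:
        return np.median(self.draws, axis=0)

    def frame(self) -> pd.DataFrame:
        q = np.percentile(self.draws, [2.5, 50.0, 97.5], axis=0)
        return pd.DataFrame({
            "subject_id": self.subject_id, "time_years": self.times,
            "q2.5": q[0], "q50": q[1], "q97.5": q[2], "mode": self.mode})


def _check_stats(draws: PosteriorDraws, design: Design) -> None:
    if (draws.stats_fp is not None and design.stats_fp is not None
            and draws.stats_fp != design.stats_fp):
        raise ValueError(
            "new data were standardized with different statistics than the "
            "training data; rebuild the design with the training stats")


def predict_marginal(draws: PosteriorDraws, design: Design,
                     ) -> TrajectoryPrediction:
    """Fixed-effects-only predictions, per posterior draw."""
    _check_stats(draws, design)
    if list(design.columns) != list(draws.columns):
        raise ValueError("design columns do not match the fitted model")
    pred = draws.beta @ design.X.T  # (n_draws, n_records)
    subj = design.subject_ids[design.subject_codes]
    return TrajectoryPrediction(subject_id=subj, times=design.times,
                                draws=pred, mode="marginal")


def update_by_baseline(draws: PosteriorDraws, design: Design,
                       sample_predictive: bool = False,
                       include_noise: bool = True,
                       seed: int = 0) -> TrajectoryPrediction:
    """Condition random effects on each subject's observed baseline eGFR.

    ``design`` must contain exactly one time-0 record per subject (the
    conditioning observation, whose outcome supplies y0); predictions are
    produced for every record, with post-baseline records the intended
    evaluation set.  Requires a model fitted with random effects.
    """
    _check_stats(draws, design)
    if draws.G is None:
        raise ValueError("baseline updating requires a random-effects model")
    if list(design.columns) != list(draws.columns):
        raise ValueError("design columns do not match the fitted model")

    is_base = design.times == 0.0
    counts = np.bincount(design.subject_codes[is_base],
                         minlength=design.n_subjects)
    if np.any(counts != 1):
        bad = design.subject_ids[np.where(counts != 1)[0][:5]]
        raise ValueError(
            "baseline updating needs exactly one conditioning record at "
            f"time 0 per subject; offending subjects: {list(bad)}")

    X0 = design.X[is_base]
    y0 = design.y[is_base]
    code0 = design.subject_codes[is_base]
    order = np.argsort(code0)
    X0, y0 = X0[order], y0[order]          # row i <-> subject code i

    G = draws.G                             # (D, 2, 2)
    sigma2 = draws.sigma**2                 # (D,)
    denom = G[:, 0, 0] + sigma2             # z0' G z0 + sigma^2
    k = G[:, :, 0] / denom[:, None]         # (D, 2) gain G z0 / denom

    r0 = y0[None, :] - draws.beta @ X0.T    # (D, n_subj)
    cond_mean = k[:, None, :] * r0[:, :, None]          # (D, n_subj, 2)
    cond_cov = G - (G[:, :, 0][:, :, None]
                    * G[:, 0, :][:, None, :]) / denom[:, None, None]

    fixed = draws.beta @ design.X.T         # (D, n_records)
    c = design.subject_codes
    pred = (fixed + cond_mean[:, c, 0]
            + cond_mean[:, c, 1] * design.times[None, :])

    predictive = None
    if sample_predictive:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB1]))
        D, n_subj = r0.shape
        # closed-form 2x2 Cholesky of each draw's conditional covariance
        c11 = np.sqrt(np.maximum(cond_cov[:, 0, 0], 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            c21 = np.where(c11 > 0, cond_cov[:, 1, 0] / c11, 0.0)
        c22 = np.sqrt(np.maximum(cond_cov[:, 1, 1] - c21**2, 0.0))
        z = rng.standard_normal((2, D, n_subj))
        db0 = c11[:, None] * z[0]
        db1 = c21[:, None] * z[0] + c22[:, None] * z[1]
        predictive = pred + db0[:, c] + db1[:, c] * design.times[None, :]
        if include_noise:
            predictive = predictive + draws.sigma[:, None] * \
                rng.standard_normal(predictive.shape)

    subj = design.subject_ids[design.subject_codes]
    return TrajectoryPrediction(
        subject_id=subj, times=design.times, draws=pred,
        mode="baseline_updated", predictive=predictive,
        includes_noise=include_noise and sample_predictive,
        cond_mean=cond_mean, cond_cov=cond_cov,
        cond_subjects=design.subject_ids)


def r2_rmse(pred_draws: np.ndarray, observed: np.ndarray,
            p: int | None = None) -> dict[str, np.ndarray]:
    """Posterior distributions of R^2, adjusted R^2 and RMSE.

    Per draw, R^2 = 1 - SSE/SST about the observed mean (negative values
    are possible out of sample), RMSE = sqrt(mean squared error), and — when
    ``p`` (the number of fixed effects excluding the intercept) is given —
    adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1).
    """
    observed = np.asarray(observed, dtype=float)
    pred_draws = np.atleast_2d(pred_draws)
    if pred_draws.shape[1] != len(observed):
        raise ValueError("prediction/observation length mismatch")
    n = len(observed)
    sse = np.sum((observed[None, :] - pred_draws) ** 2, axis=1)
    sst = float(np.sum((observed - observed.mean()) ** 2))
    r2 = 1.0 - sse / sst
    out = {"r2": r2, "rmse": np.sqrt(sse / n)}
    if p is not None:
        if n <= p + 1:
            raise ValueError(
                f"adjusted R^2 undefined: n = {n} observations but "
                f"p = {p} fixed effects requires n > p + 1")
        out["adj_r2"] = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return out


def bayes_r2(pred_draws: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """In-sample Bayesian R^2: var(yhat) / (var(yhat) + sigma^2), per draw."""
    fit_var = np.var(pred_draws, axis=1)
    return fit_var / (fit_var + np.asarray(sigma) ** 2)


def summarize_metric(values: np.ndarray) -> dict[str, float]:
    """Median and 50%/95% equal-tailed interval of a posterior metric."""
    q = np.percentile(values, [2.5, 25.0, 50.0, 75.0, 97.5])
    return {"median": q[2], "q2.5": q[0], "q25": q[1], "q75": q[3],
            "q97.5": q[4]}


def calibration_by_followup(point_pred: np.ndarray, observed: np.ndarray,
                            times: np.ndarray,
                            bin_edges: list[float]) -> pd.DataFrame:
    """Observed-vs-predicted calibration stratified by follow-up time.

    Bins are [edge_k, edge_k+1); per bin the table reports n, R^2, RMSE and
    the least-squares slope/intercept of observed ~ predicted.  Empty bins
    are reported as rows with n = 0 rather than dropped.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2:
        raise ValueError("need at least two bin edges")
    if times.min() < edges[0] or times.max() >= edges[-1]:
        raise ValueError("bins do not cover the observed times")
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (times >= lo) & (times < hi)
        if not m.any():
            rows.append((lo, hi, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        obs, pred = observed[m], point_pred[m]
        met = r2_rmse(pred[None, :], obs)
        if len(obs) >= 2 and np.ptp(pred) > 0:
            slope, intercept = np.polyfit(pred, obs, 1)
        else:
            slope, intercept = np.nan, np.nan
        rows.append((lo, hi, int(m.sum()), float(met["r2"][0]),
                     float(met["rmse"][0]), slope, intercept))
    return pd.DataFrame(rows, columns=[
        "time_lo", "time_hi", "n", "r2", "rmse", "slope", "intercept"])
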