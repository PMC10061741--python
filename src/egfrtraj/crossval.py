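"""Repeated fivefold cross-validation grouped by subject.

Out-of-sample performance is estimated for both prediction objectives:
``marginal`` (fixed effects only, scoring the whole held-out trajectory
including baseline) and ``baseline_updated`` (random effects conditioned on
each held-out subject's time-0 eGFR, scoring post-baseline records only).

All per-fold preprocessing — standardization statistics, imputation models
— is derived from the training fold alone.  Metrics are pooled by
concatenating held-out predictions across every fold and repeat and
computing R^2 / adjusted R^2 / RMSE per posterior draw over the whole
concatenated set (not by averaging per-fold metrics), then summarized as
posterior median with 50%/95% credible intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blmm import ModelSpec, build_design, fit_blmm, pool_posteriors
from .imputation import fit_imputer, impute
from .prediction import (calibration_by_followup, predict_marginal, r2_rmse,
                         summarize_metric, update_by_baseline)
from .preprocessing import stats_fingerprint, transform_predictors

__all__ = ["CVResult", "make_folds", "run_cv"]

DEFAULT_YEAR_BINS = (-0.001, 0.5, 1.5, 2.5, 3.5, 10.0)


def make_folds(subject_ids: np.ndarray, k: int = 5, repeats: int = 5,
               seed: int = 0) -> pd.DataFrame:
    """Subject-level fold assignments; sizes within a repeat differ by <= 1.

    Each repeat draws an independent permutation from its own seed stream,
    so the whole table is deterministic given (subject_ids, k, repeats,
    seed).
    """
    subject_ids = np.asarray(subject_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(subject_ids):
        raise ValueError(f"k = {k} exceeds the {len(subject_ids)} subjects")
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("subject ids must be unique")
    rows = []
    for rep in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep, 0xF01]))
        perm = rng.permutation(subject_ids)
        for fold, chunk in enumerate(np.array_split(perm, k)):
            rows.extend((rep, fold, s) for s in chunk)
    return pd.DataFrame(rows, columns=["repeat", "fold", "subject_id"])


@dataclass
class CVResult:
    folds: pd.DataFrame
    per_split: pd.DataFrame
    pooled: dict                      # mode -> metric -> summary dict
    pooled_draws: dict                # mode -> metric -> (n_draws,) array
    by_year: pd.DataFrame
    modes: tuple[str, ...]
    seed: int
    fold_fits: list = field(default_factory=list, repr=False)

    def pooled_frame(self) -> pd.DataFrame:
        rows = []
        for mode, metrics in self.pooled.items():
            for metric, summ in metrics.items():
                rows.append({"mode": mode, "metric": metric, **summ})
        return pd.DataFrame(rows)


def _fit_on_training(train_records, train_cov, spec, seed, m_imputations,
                     imputer_seed):
    """Standardize, impute and fit on one training fold; returns
    (pooled draws, training stats, stats fingerprint)."""
    pred_cols = ["subject_id"] + list(spec.predictor_names)
    cov = train_cov[pred_cols]
    has_missing = cov[spec.predictor_names].isna().any().any()

    egfr0 = (train_records[train_records["time_years"] == 0.0]
             .set_index("subject_id")["egfr"])

    if has_missing:
        if m_imputations < 2:
            raise ValueError("training fold has missing predictors; "
                             "set m_imputations >= 2")
        imputer = fit_imputer(cov, baseline_egfr=egfr0, m=m_imputations,
                              seed=imputer_seed)
        completed = impute(imputer, cov, seed=imputer_seed,
                           baseline_egfr=egfr0)
    else:
        imputer = None
        completed = [cov]

    fits = []
    stats = None
    for i, table in enumerate(completed):
        design_cov, stats_i = transform_predictors(
            table.drop(columns="subject_id"))
        design_cov.index = table["subject_id"].to_numpy()
        if stats is None:
            stats = stats_i
        fp = stats_fingerprint(stats_i)
        design = build_design(train_records, design_cov, spec, stats_fp=fp)
        draws, _ = fit_blmm(design, spec, seed=seed + i)
        fits.append((draws, stats_i, fp, design))

    pooled = pool_posteriors([f[0] for f in fits]) if len(fits) > 1 else fits[0][0]
    return pooled, fits, imputer


def _test_designs(test_records, test_cov, spec, fits, imputer, egfr0_test,
                  imputer_seed):
    """Per-imputation test designs standardized with the matching
    training-fold statistics (never the held-out data)."""
    pred_cols = ["subject_id"] + list(spec.predictor_names)
    cov = test_cov[pred_cols]
    has_missing = cov[spec.predictor_names].isna().any().any()
    if has_missing and imputer is None:
        raise ValueError("test fold has missing predictors but no imputer "
                         "was fitted on the training fold")
    if imputer is not None:
        completed = impute(imputer, cov, seed=imputer_seed + 1,
                           baseline_egfr=egfr0_test)
    else:
        completed = [cov] * len(fits)
    designs = []
    for table, (_, stats_i, fp, _design) in zip(completed, fits):
        design_cov, _ = transform_predictors(
            table.drop(columns="subject_id"), training_stats=stats_i)
        design_cov.index = table["subject_id"].to_numpy()
        designs.append(build_design(test_records, design_cov, spec,
                                    stats_fp=fp))
    return designs


def run_cv(records: pd.DataFrame, covariates: pd.DataFrame, spec: ModelSpec,
           k: int = 5, repeats: int = 5,
           modes: tuple[str, ...] = ("marginal", "baseline_updated"),
           seed: int = 0, m_imputations: int = 2,
           year_bins: tuple[float, ...] = DEFAULT_YEAR_BINS,
           keep_fold_fits: bool = False) -> CVResult:
    """Grouped, repeated k-fold cross-validation of one model spec.

    Per split: standardization and imputation are fitted on the training
    subjects, the model is fitted on each completed training set (posteriors
    pooled over imputations), and held-out subjects are predicted marginally
    and/or after conditioning on their baseline eGFR.  Grouped-CV integrity
    (no subject in both sides of a split) is asserted on every split.
    """
    for mode in modes:
        if mode not in ("marginal", "baseline_updated"):
            raise ValueError(f"unknown prediction mode: {mode!r}")
    subject_ids = covariates["subject_id"].to_numpy()
    folds = make_folds(subject_ids, k=k, repeats=repeats, seed=seed)

    acc: dict[str, dict[str, list]] = {
        m: {"pred": [], "obs": [], "times": [], "point": []} for m in modes}
    per_split_rows = []
    fold_fits = []
    p_fixed = len(spec.columns) - 1

    for rep in range(repeats):
        rep_folds = folds[folds["repeat"] == rep]
        for fold in range(k):
            test_ids = set(rep_folds[rep_folds["fold"] == fold]["subject_id"])
            train_ids = set(rep_folds["subject_id"]) - test_ids
            assert not (train_ids & test_ids), "grouped-CV integrity violated"

            tr_rec = records[records["subject_id"].isin(train_ids)]
            te_rec = records[records["subject_id"].isin(test_ids)]
            tr_cov = covariates[covariates["subject_id"].isin(train_ids)]
            te_cov = covariates[covariates["subject_id"].isin(test_ids)]

            fit_seed = seed + 7919 * rep + 104729 * fold
            draws, fits, imputer = _fit_on_training(
                tr_rec, tr_cov, spec, fit_seed, m_imputations,
                imputer_seed=fit_seed + 13)

            egfr0_te = (te_rec[te_rec["time_years"] == 0.0]
                        .set_index("subject_id")["egfr"])
            designs = _test_designs(te_rec, te_cov, spec, fits, imputer,
                                    egfr0_te, imputer_seed=fit_seed + 13)

            if keep_fold_fits:
                fold_fits.append({"repeat": rep, "fold": fold,
                                  "draws": draws, "fits": fits,
                                  "test_designs": designs,
                                  "test_records": te_rec})

            for mode in modes:
                preds = []
                for (d_i, _st, _fp, _ds), design in zip(fits, designs):
                    if mode == "marginal":
                        pr = predict_marginal(d_i, design)
                        score_mask = np.ones(len(design.y), dtype=bool)
                    else:
                        pr = update_by_baseline(d_i, design)
                        score_mask = design.times > 0.0
                    preds.append(pr.draws[:, score_mask])
                design0 = designs[0]
                pred = np.concatenate(preds, axis=0)
                obs = design0.y[score_mask]
                tms = design0.times[score_mask]
                if len(obs) == 0:
                    continue
                met = r2_rmse(pred, obs)
                per_split_rows.append({
                    "repeat": rep, "fold": fold, "mode": mode,
                    "n_obs": len(obs),
                    "r2_median": float(np.median(met["r2"])),
                    "rmse_median": float(np.median(met["rmse"]))})
                acc[mode]["pred"].append(pred)
                acc[mode]["obs"].append(obs)
                acc[mode]["times"].append(tms)
                acc[mode]["point"].append(np.median(pred, axis=0))

    pooled, pooled_draws = {}, {}
    by_year_rows = []
    for mode in modes:
        pred = np.concatenate(acc[mode]["pred"], axis=1)
        obs = np.concatenate(acc[mode]["obs"])
        tms = np.concatenate(acc[mode]["times"])
        met = r2_rmse(pred, obs, p=p_fixed)
        pooled_draws[mode] = met
        pooled[mode] = {name: summarize_metric(vals)
                        for name, vals in met.items()}
        point = np.concatenate(acc[mode]["point"])
        cal = calibration_by_followup(point, obs, tms, list(year_bins))
        cal.insert(0, "mode", mode)
        by_year_rows.append(cal)

    return CVResult(folds=folds, per_split=pd.DataFrame(per_split_rows),
                    pooled=pooled, pooled_draws=pooled_draws,
                    by_year=pd.concat(by_year_rows, ignore_index=True),
                    modes=tuple(modes), seed=seed, fold_fits=fold_fits)
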