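"""Descriptive cohort reporting.

Demographics-table summaries (median [IQR] for continuous variables,
n (%) for categorical ones, missing counts per variable) and per-subject
eGFR slope estimates from person-specific least-squares regressions.
Quartiles use linear interpolation throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import BINARY_PREDICTORS

__all__ = ["per_subject_slopes", "summarize_cohort"]


def per_subject_slopes(records: pd.DataFrame) -> pd.Series:
    """Per-subject eGFR slope (ml/min/1.73m2 per year) via OLS on time.

    Subjects with fewer than two distinct observation times get NaN.
    """
    out = {}
    for subj, grp in records.groupby("subject_id", sort=True):
        t = grp["time_years"].to_numpy(dtype=float)
        y = grp["egfr"].to_numpy(dtype=float)
        if len(t) < 2 or np.ptp(t) == 0:
            out[subj] = np.nan
            continue
        out[subj] = float(np.polyfit(t, y, 1)[0])
    return pd.Series(out, name="egfr_slope")


def _median_iqr(x: np.ndarray) -> str:
    q25, q50, q75 = np.percentile(x, [25.0, 50.0, 75.0])
    return f"{q50:.2f} [{q25:.2f}, {q75:.2f}]"


def summarize_cohort(records: pd.DataFrame,
                     covariates: pd.DataFrame) -> pd.DataFrame:
    """Demographics table: one row per variable plus outcome summaries."""
    if len(covariates) == 0:
        raise ValueError("empty cohort")
    n = len(covariates)
    rows = []

    egfr0 = records[records["time_years"] == 0.0]["egfr"].to_numpy()
    rows.append(("baseline_egfr", "continuous", _median_iqr(egfr0), 0, 0.0))

    n_post = (records[records["time_years"] > 0.0]
              .groupby("subject_id").size()
              .reindex(covariates["subject_id"]).fillna(0).to_numpy())
    rows.append(("post_baseline_visits", "continuous", _median_iqr(n_post),
                 0, 0.0))

    slopes = per_subject_slopes(records).dropna().to_numpy()
    if len(slopes):
        rows.append(("egfr_slope_per_year", "continuous",
                     _median_iqr(slopes), 0, 0.0))

    for col in covariates.columns:
        if col == "subject_id":
            continue
        x = covariates[col].to_numpy(dtype=float)
        n_miss = int(np.isnan(x).sum())
        obs = x[~np.isnan(x)]
        if col in BINARY_PREDICTORS or set(np.unique(obs)) <= {0.0, 1.0}:
            k = int(obs.sum())
            summary = f"{k} ({100.0 * k / max(len(obs), 1):.1f}%)"
            kind = "categorical"
        else:
            summary = _median_iqr(obs) if len(obs) else "-"
            kind = "continuous"
        rows.append((col, kind, summary, n_miss, 100.0 * n_miss / n))

    return pd.DataFrame(rows, columns=[
        "variable", "type", "summary", "missing_n", "missing_pct"])
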