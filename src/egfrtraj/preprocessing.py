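"""Cohort assembly and immunoassay quality control.

Implements the eGFR computation (CKD-EPI 2009 creatinine equation), the
diabetes-mellitus definition, the cohort inclusion filters, the
replicate/inter-plate CV rules for Luminex/ELISA measurements with
standard-range truncation, and the predictor transformation (log2 + z-score)
used by all models.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import BINARY_PREDICTORS, BIOMARKERS

__all__ = [
    "compute_egfr_ckdepi",
    "diagnose_dm",
    "apply_inclusion",
    "QCResult",
    "qc_select_measurement",
    "qc_plates",
    "truncate_to_standard_range",
    "transform_predictors",
    "stats_fingerprint",
]

# CV validity bounds for immunoassay replicates and inter-plate reruns
REPLICATE_CV_MAX = 0.15
INTERPLATE_CV_MAX = 0.20


def compute_egfr_ckdepi(scr: float, age: float, sex: str) -> float:
    """Estimated GFR (ml/min/1.73m2) from the 2009 CKD-EPI creatinine equation.

    ``scr`` is serum creatinine in mg/dL; ``sex`` is ``"female"`` or
    ``"male"``.  The race coefficient is fixed at 1 (the cohort this
    pipeline emulates is all-Caucasian by its exclusion criteria).
    """
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scr <= 0) or np.any(age <= 0):
        raise ValueError("serum creatinine and age must be positive")
    if sex == "female":
        kappa, alpha, sex_factor = 0.7, -0.329, 1.018
    elif sex == "male":
        kappa, alpha, sex_factor = 0.9, -0.411, 1.0
    else:
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    ratio = scr / kappa
    egfr = (141.0 * np.minimum(ratio, 1.0) ** alpha
            * np.maximum(ratio, 1.0) ** -1.209
            * 0.993 ** age * sex_factor)
    return float(egfr) if egfr.ndim == 0 else egfr


def diagnose_dm(hba1c: float | None, drug_atc_codes: list[str] | None) -> bool:
    """Diabetes mellitus: HbA1c >= 6.5% or any antidiabetic (ATC A10*) drug."""
    if hba1c is not None and not (isinstance(hba1c, float) and math.isnan(hba1c)):
        if hba1c >= 6.5:
            return True
    for code in drug_atc_codes or ():
        if str(code).startswith("A10"):
            return True
    return False


def apply_inclusion(records: pd.DataFrame, covariates: pd.DataFrame,
                    dm_flags: pd.Series | None = None,
                    egfr_range: tuple[float, float] = (25.0, 70.0),
                    ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Apply the cohort inclusion filters, in order DM -> eGFR range -> follow-up.

    Retains subjects with diabetes, baseline eGFR within ``egfr_range``
    (closed interval) and at least one post-baseline eGFR record.  The tally
    counts exclusions per criterion in application order, so the components
    sum to (input subjects - retained subjects).

    ``dm_flags`` (indexed by subject id) overrides the built-in DM
    determination, which otherwise uses the ``hba1c`` column plus either an
    ``atc_codes`` column (list-valued) or the ``dm_med`` intake indicator as
    evidence of antidiabetic prescription.
    """
    subjects = covariates["subject_id"]
    base = records[records["time_years"] == 0.0]
    missing_baseline = set(subjects) - set(base["subject_id"])
    if missing_baseline:
        raise ValueError(
            f"subjects without a time-0 record: {sorted(missing_baseline)[:5]}")

    if dm_flags is None:
        def _dm(row) -> bool:
            hba1c = row.get("hba1c")
            if "atc_codes" in row.index:
                codes = row["atc_codes"]
            elif row.get("dm_med", 0) >= 1:
                codes = ["A10"]
            else:
                codes = []
            return diagnose_dm(hba1c, codes)
        dm_flags = covariates.apply(_dm, axis=1)
        dm_flags.index = subjects.to_numpy()
    dm_flags = dm_flags.reindex(subjects.to_numpy())

    egfr0 = base.set_index("subject_id")["egfr"].reindex(subjects.to_numpy())
    n_post = (records[records["time_years"] > 0.0]
              .groupby("subject_id").size().reindex(subjects.to_numpy())
              .fillna(0))

    keep = pd.Series(True, index=subjects.to_numpy())
    tally = {}
    fail_dm = ~dm_flags.astype(bool)
    tally["dm"] = int((keep & fail_dm).sum())
    keep &= ~fail_dm
    fail_egfr = (egfr0 < egfr_range[0]) | (egfr0 > egfr_range[1])
    tally["egfr_range"] = int((keep & fail_egfr).sum())
    keep &= ~fail_egfr
    fail_fup = n_post < 1
    tally["followup"] = int((keep & fail_fup).sum())
    keep &= ~fail_fup

    kept_ids = keep.index[keep.to_numpy()]
    rec_f = records[records["subject_id"].isin(kept_ids)].reset_index(drop=True)
    cov_f = covariates[covariates["subject_id"].isin(kept_ids)].reset_index(drop=True)
    return rec_f, cov_f, tally


def _cv(values: np.ndarray) -> float:
    """Coefficient of variation with sample sd (denominator n-1)."""
    m = float(np.mean(values))
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1)) / m


@dataclass
class QCResult:
    value: float | None
    valid: bool
    reason: str = ""
    replicate_cv: float = float("nan")
    interplate_cv: float = float("nan")


def qc_select_measurement(replicates: pd.DataFrame) -> QCResult:
    """QC one sample x analyte given its replicate rows across plates.

    Per plate the value is the replicate mean, valid iff the replicate CV
    (sample sd / mean) is <= 15%.  When the sample was rerun on several
    plates, the measurement is valid only if the CV across plate means is
    < 20% and at least one plate entry passes the replicate rule; the plate
    entry with smallest replicate CV supplies the reported value.
    """
    per_plate = []
    for plate, grp in replicates.groupby("plate_id", sort=True):
        vals = grp["raw_concentration"].to_numpy(dtype=float)
        mean = float(np.mean(vals))
        if mean <= 0:
            return QCResult(None, False, "non_positive_mean")
        per_plate.append((plate, mean, _cv(vals)))

    best = min(per_plate, key=lambda t: (t[2], t[0]))
    if len(per_plate) == 1:
        plate, mean, cv = per_plate[0]
        if cv > REPLICATE_CV_MAX:
            return QCResult(None, False, "replicate_cv", replicate_cv=cv)
        return QCResult(mean, True, replicate_cv=cv)

    means = np.array([m for _, m, _ in per_plate])
    inter_cv = _cv(means)
    if inter_cv >= INTERPLATE_CV_MAX:
        return QCResult(None, False, "interplate_cv",
                        replicate_cv=best[2], interplate_cv=inter_cv)
    if best[2] > REPLICATE_CV_MAX:
        return QCResult(None, False, "replicate_cv",
                        replicate_cv=best[2], interplate_cv=inter_cv)
    return QCResult(best[1], True, replicate_cv=best[2], interplate_cv=inter_cv)


def qc_plates(plates: pd.DataFrame, truncate: bool = True) -> pd.DataFrame:
    """QC every sample x analyte of a plate table.

    Returns a report with columns sample_id, analyte, value, status, reason.
    Valid values are truncated to the assay standard range unless
    ``truncate`` is disabled.
    """
    rows = []
    for (analyte, sample), grp in plates.groupby(["analyte", "sample_id"],
                                                 sort=True):
        res = qc_select_measurement(grp)
        value = res.value
        if res.valid and truncate:
            value = truncate_to_standard_range(
                value, float(grp["standard_low"].iloc[0]),
                float(grp["standard_high"].iloc[0]))
        rows.append((sample, analyte, value,
                     "valid" if res.valid else "invalid", res.reason,
                     res.replicate_cv, res.interplate_cv))
    return pd.DataFrame(rows, columns=[
        "sample_id", "analyte", "value", "status", "reason",
        "replicate_cv", "interplate_cv"])


def truncate_to_standard_range(value: float, standard_low: float,
                               standard_high: float) -> float:
    """Truncate out-of-range concentrations to fixed standard-derived values.

    Values below the lowest standard map to standard_low / sqrt(2), values
    above the highest standard to standard_high * sqrt(2); in-range values
    are unchanged (hence the operation is idempotent).
    """
    if standard_low <= 0 or standard_high <= 0 or standard_low >= standard_high:
        raise ValueError("standards must be positive with low < high")
    if value < standard_low:
        return standard_low / math.sqrt(2.0)
    if value > standard_high:
        return standard_high * math.sqrt(2.0)
    return value


def _infer_transforms(columns: list[str]) -> dict[str, str]:
    kinds = {}
    for col in columns:
        if col in BINARY_PREDICTORS:
            kinds[col] = "binary"
        elif col == "uacr" or col in BIOMARKERS:
            kinds[col] = "log2_z"
        else:
            kinds[col] = "z"
    return kinds


def transform_predictors(covariates: pd.DataFrame,
                         training_stats: dict | None = None,
                         transforms: dict[str, str] | None = None,
                         ) -> tuple[pd.DataFrame, dict]:
    """Standardize predictors for modeling; returns (design, stats).

    Biomarkers and UACR are log2-transformed then z-scored; other continuous
    predictors are z-scored; binary predictors are passed through as 0/1.
    Z-scoring uses mean and sample sd (denominator n-1).  When
    ``training_stats`` is supplied (the cross-validation path) the stored
    means/sds are applied verbatim so no held-out information enters the
    scaling; the returned stats are then the supplied ones.

    Missing cells propagate as NaN.  Non-positive values reaching log2 and
    constant columns (sd = 0) raise with the offending subject/column named.
    """
    cols = [c for c in covariates.columns if c != "subject_id"]
    if training_stats is not None:
        kinds = {c: training_stats[c]["transform"] for c in cols}
    else:
        kinds = transforms or _infer_transforms(cols)

    design = {}
    stats = {} if training_stats is None else training_stats
    subj = covariates["subject_id"] if "subject_id" in covariates else None
    for col in cols:
        x = covariates[col].to_numpy(dtype=float)
        kind = kinds[col]
        if kind == "binary":
            design[col] = x
            if training_stats is None:
                stats[col] = {"transform": "binary", "mean": 0.0, "sd": 1.0}
            continue
        if kind == "log2_z":
            bad = np.where(~np.isnan(x) & (x <= 0))[0]
            if len(bad):
                who = subj.iloc[bad[0]] if subj is not None else bad[0]
                raise ValueError(
                    f"non-positive value in {col!r} for subject {who}: "
                    f"{x[bad[0]]} cannot be log2-transformed")
            x = np.log2(x)
        if training_stats is None:
            mean = float(np.nanmean(x))
            sd = float(np.nanstd(x, ddof=1))
            if sd == 0 or not np.isfinite(sd):
                raise ValueError(f"column {col!r} is constant (sd = 0); "
                                 "cannot standardize")
            stats[col] = {"transform": kind, "mean": mean, "sd": sd}
        else:
            mean = training_stats[col]["mean"]
            sd = training_stats[col]["sd"]
        design[col] = (x - mean) / sd

    index = subj.to_numpy() if subj is not None else covariates.index
    return pd.DataFrame(design, index=index), stats


def stats_fingerprint(stats: dict) -> str:
    """Stable fingerprint of a transformation-stats object."""
    payload = json.dumps(stats, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
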