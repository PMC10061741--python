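"""Variable importance and reference-model projection.

Importance ranks predictors by the increase in pooled cross-validated RMSE
when one predictor (its main term and its time interaction together) is
removed from the full model — separately for the marginal objective and the
baseline-updated objective, whose rankings typically differ.

Submodels approximate the full ("reference") model by projection: per
posterior draw the reference linear predictor X_full beta_ref is projected
onto the submodel design by least squares,

    beta_proj   = argmin_b || X_full beta_ref - X_sub b ||^2
    sigma_proj^2 = sigma_ref^2 + || X_full beta_ref - X_sub beta_proj ||^2 / n

(the Gaussian KL projection); the random-effect structure is carried over
unchanged.  The nested submodel sequence starts from {intercept, time} and
adds predictors in ranking order, reporting cross-validated performance per
submodel with the full model as the reference band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .blmm import Design, ModelSpec, PosteriorDraws
from .crossval import CVResult, run_cv
from .prediction import predict_marginal, r2_rmse, summarize_metric, \
    update_by_baseline

__all__ = [
    "ImportanceRanking",
    "SubmodelSequence",
    "lovo_ranking",
    "project_reference",
    "submodel_sequence",
]


@dataclass
class ImportanceRanking:
    table: pd.DataFrame        # predictor, delta_rmse, rank, valid
    mode: str
    full_rmse: float

    @property
    def ordered(self) -> list[str]:
        return list(self.table["predictor"])


def lovo_ranking(records: pd.DataFrame, covariates: pd.DataFrame,
                 spec: ModelSpec, mode: str = "marginal",
                 k: int = 5, repeats: int = 2, seed: int = 0,
                 m_imputations: int = 2,
                 full_cv: CVResult | None = None) -> ImportanceRanking:
    """Leave-one-variable-out importance by pooled CV-RMSE increase.

    For each predictor the full model is re-cross-validated without that
    predictor's main and interaction terms (same folds, same seeds) and
    delta RMSE = RMSE(without) - RMSE(full) is recorded from the pooled
    held-out posterior-median RMSE.  Ordering is descending with ties
    broken alphabetically.  A failed refit invalidates that predictor's
    entry with an explicit flag instead of aborting the ranking.
    """
    cv_kwargs = dict(k=k, repeats=repeats, modes=(mode,), seed=seed,
                     m_imputations=m_imputations)
    if full_cv is None:
        full_cv = run_cv(records, covariates, spec, **cv_kwargs)
    full_rmse = full_cv.pooled[mode]["rmse"]["median"]

    rows = []
    for pred in spec.predictor_names:
        sub = dc_replace(spec, predictor_names=[
            p for p in spec.predictor_names if p != pred])
        try:
            cv = run_cv(records, covariates, sub, **cv_kwargs)
            delta = cv.pooled[mode]["rmse"]["median"] - full_rmse
            rows.append((pred, delta, True))
        except Exception as err:  # pragma: no cover - defensive
            warnings.warn(f"LOVO refit failed for {pred!r}: {err}")
            rows.append((pred, np.nan, False))

    table = pd.DataFrame(rows, columns=["predictor", "delta_rmse", "valid"])
    table = table.sort_values(["delta_rmse", "predictor"],
                              ascending=[False, True],
                              na_position="last").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return ImportanceRanking(table=table, mode=mode, full_rmse=full_rmse)


def _submodel_spec(spec: ModelSpec, predictors: list[str]) -> ModelSpec:
    return dc_replace(spec, predictor_names=list(predictors))


def _subdesign(design: Design, spec_full: ModelSpec,
               predictors: list[str]) -> tuple[Design, np.ndarray]:
    """Column-subset design for a nested submodel of the full design."""
    sub_cols = ["intercept", "time"] + list(predictors)
    if spec_full.include_interactions:
        sub_cols += [f"{p}:time" for p in predictors]
    ix = np.array([design.columns.index(c) for c in sub_cols])
    sub = dc_replace(design, X=design.X[:, ix], columns=sub_cols)
    return sub, ix


def project_reference(draws: PosteriorDraws, full_design: Design,
                      sub_design: Design) -> PosteriorDraws:
    """Project a reference posterior onto a submodel design, per draw.

    The submodel's columns must be a subset of the full design's columns.
    Rank-deficient submodel designs fall back to the minimum-norm
    least-squares solution with a warning.
    """
    missing = set(sub_design.columns) - set(full_design.columns)
    if missing:
        raise ValueError(f"submodel columns not in the full design: "
                         f"{sorted(missing)}")
    Xf, Xs = full_design.X, sub_design.X
    if Xf.shape[0] != Xs.shape[0]:
        raise ValueError("full and submodel designs must share rows")
    n, ksub = Xs.shape
    if np.linalg.matrix_rank(Xs) < ksub:
        warnings.warn("submodel design is rank-deficient; using the "
                      "minimum-norm projection")
    # beta_proj' = pinv(Xs) Xf beta'; computed via one pseudoinverse
    M = np.linalg.pinv(Xs) @ Xf                       # (ksub, kfull)
    beta_proj = draws.beta @ M.T                      # (D, ksub)
    resid = draws.beta @ Xf.T - beta_proj @ Xs.T      # (D, n)
    sigma_proj = np.sqrt(draws.sigma**2 + np.sum(resid**2, axis=1) / n)

    sub_names = [c for c in sub_design.columns
                 if c not in ("intercept", "time") and not c.endswith(":time")]
    return PosteriorDraws(
        beta=beta_proj, sigma=sigma_proj, G=draws.G, b=draws.b,
        chain=draws.chain, columns=list(sub_design.columns),
        subject_ids=draws.subject_ids,
        spec=_submodel_spec(draws.spec, sub_names),
        y_scale=draws.y_scale, stats_fp=draws.stats_fp)


@dataclass
class SubmodelSequence:
    table: pd.DataFrame          # mode, size, predictors, metric summaries
    reference: dict              # mode -> pooled metric summaries
    ranking: list[str]
    modes: tuple[str, ...]


def submodel_sequence(records: pd.DataFrame, covariates: pd.DataFrame,
                      spec: ModelSpec, ranking: list[str],
                      modes: tuple[str, ...] = ("marginal",),
                      k: int = 5, repeats: int = 2, seed: int = 0,
                      m_imputations: int = 2, max_size: int = 15,
                      full_cv: CVResult | None = None) -> SubmodelSequence:
    """Cross-validated performance of the nested projected submodels.

    The reference (full) model is fitted once per CV training fold; each
    submodel's parameters are obtained by projecting that fold's reference
    posterior (no refitting, no test-fold information), and held-out
    predictions are scored exactly as in ``run_cv`` — marginally, or after
    conditioning on the held-out subjects' baseline eGFR with the projected
    parameters.  The sequence is fixed to the supplied global ranking.
    """
    if full_cv is None or not full_cv.fold_fits:
        full_cv = run_cv(records, covariates, spec, k=k, repeats=repeats,
                         modes=tuple(modes), seed=seed,
                         m_imputations=m_imputations, keep_fold_fits=True)
    sizes = list(range(0, min(max_size, len(ranking)) + 1))
    p_fixed = len(spec.columns) - 1

    rows = []
    for size in sizes:
        preds = ranking[:size]
        acc = {m: {"pred": [], "obs": []} for m in modes}
        for ff in full_cv.fold_fits:
            for d_i, test_design in zip(
                    _per_fit_draws(ff), ff["test_designs"]):
                sub_test, _ = _subdesign(test_design, spec, preds)
                # project on the training-fold reference fit
                proj = d_i["proj_cache"].get(size)
                if proj is None:
                    sub_train, _ = _subdesign(d_i["train_design"], spec, preds)
                    proj = project_reference(d_i["draws"],
                                             d_i["train_design"], sub_train)
                    d_i["proj_cache"][size] = proj
                for mode in modes:
                    if mode == "marginal":
                        pr = predict_marginal(proj, sub_test)
                        mask = np.ones(len(sub_test.y), dtype=bool)
                    else:
                        pr = update_by_baseline(proj, sub_test)
                        mask = sub_test.times > 0.0
                    acc[mode]["pred"].append(pr.draws[:, mask])
                    acc[mode]["obs"].append(sub_test.y[mask])
        for mode in modes:
            # concatenate across imputation fits (draw axis) then folds
            n_fits = len(full_cv.fold_fits[0]["fits"])
            per_fold = []
            obs_fold = []
            n_folds = len(full_cv.fold_fits)
            for f in range(n_folds):
                chunk = acc[mode]["pred"][f * n_fits:(f + 1) * n_fits]
                per_fold.append(np.concatenate(chunk, axis=0))
                obs_fold.append(acc[mode]["obs"][f * n_fits])
            pred = np.concatenate(per_fold, axis=1)
            obs = np.concatenate(obs_fold)
            p_sub = 1 + (2 if spec.include_interactions else 1) * size
            met = r2_rmse(pred, obs, p=p_sub)
            rows.append({"mode": mode, "size": size,
                         "predictors": "+".join(preds) if preds else "(none)",
                         **{f"r2_{k2}": v for k2, v in
                            summarize_metric(met["r2"]).items()},
                         "rmse_median": float(np.median(met["rmse"]))})

    reference = {m: full_cv.pooled[m] for m in modes}
    return SubmodelSequence(table=pd.DataFrame(rows), reference=reference,
                            ranking=list(ranking), modes=tuple(modes))


def _per_fit_draws(fold_fit: dict) -> list[dict]:
    """Per-imputation reference draws with their training designs."""
    if "_per_fit" in fold_fit:
        return fold_fit["_per_fit"]
    out = [{"draws": draws, "train_design": design, "proj_cache": {}}
           for draws, _stats, _fp, design in fold_fit["fits"]]
    fold_fit["_per_fit"] = out
    return out
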