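"""End-to-end orchestration of the analysis.

The stages run in the study's order: derive per-patient features, screen
candidate predictors of clinical benefit univariably (two-sided p <= 0.05),
select among the survivors by adaptive LASSO, fit the multivariable
logistic model pruned by the stay criterion (<= 0.10), and — when every
retained predictor is a binary indicator — derive the points-based score
and classify each patient. Missing covariate values are excluded listwise
per analysis, not per cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .features import FeatureTable, PatientClinical, RuleSet, build_feature_table
from .models import (
    FittedModel,
    ModelBuildConfig,
    PointScoreModel,
    alasso_select,
    classification_metrics,
    derive_point_score,
    fit_multivariable,
    score_patient,
)
from .stats import TestResult, univariable_logistic

__all__ = [
    "feature_frame",
    "DEFAULT_CANDIDATES",
    "univariable_screen",
    "PipelineResult",
    "run_pipeline",
]

#: Candidate predictors of clinical benefit considered by the screen.
DEFAULT_CANDIDATES: tuple[str, ...] = (
    "visceral_mets",
    "nlr_ge5",
    "ecog_ge1",
    "hb",
    "plt",
    "age",
    "snv_ge10",
    "cnv_count",
    "sig_apobec",
    "sig_ct_cpg",
    "sig_ercc2",
    "cdkn2b_del",
    "ddr_inclusive",
)


def feature_frame(
    table: FeatureTable, clinical: Sequence[PatientClinical]
) -> pd.DataFrame:
    """Join derived features to clinical covariates, one row per patient.

    Boolean flags become floats; missing values become NaN so that each
    downstream analysis can apply its own listwise exclusion.
    """
    by_id = {r.patient_id: r for r in table.records}
    rows = []
    for p in clinical:
        r = by_id.get(p.patient_id)
        if r is None:
            raise ValueError(f"no feature record for patient {p.patient_id}")

        def flag(value: Optional[bool]) -> float:
            return np.nan if value is None else float(value)

        rows.append(
            {
                "patient_id": p.patient_id,
                "age": p.age,
                "male": float(p.gender == "male"),
                "bladder": float(p.site == "bladder"),
                "visceral_mets": float(p.visceral_mets),
                "ecog_ge1": flag(r.ecog_ge1),
                "nlr": np.nan if p.nlr is None else p.nlr,
                "nlr_ge5": flag(r.nlr_ge5),
                "hb": np.nan if p.hb is None else p.hb,
                "plt": np.nan if p.plt is None else p.plt,
                "arm": p.arm,
                "cb": np.nan if p.cb is None else float(p.cb == "CB"),
                "pfs_months": np.nan if p.pfs_months is None else p.pfs_months,
                "pfs_event": np.nan if p.pfs_event is None else float(p.pfs_event),
                "os_months": np.nan if p.os_months is None else p.os_months,
                "os_event": np.nan if p.os_event is None else float(p.os_event),
                "snv_count": float(r.snv_count),
                "cnv_count": float(r.cnv_count),
                "sig_apobec": r.sig_apobec,
                "sig_ct_cpg": r.sig_ct_cpg,
                "sig_ercc2": r.sig_ercc2,
                "snv_ge10": flag(r.snv_ge10),
                "snv_ge_median": flag(r.snv_ge_median),
                "cnv_gt0": flag(r.cnv_gt0),
                "cdkn2a_del": float(r.cdkn2a_del),
                "cdkn2b_del": float(r.cdkn2b_del),
                "ddr_inclusive": float(r.ddr_inclusive),
                "ddr_restrictive": float(r.ddr_restrictive),
            }
        )
    return pd.DataFrame(rows)


def univariable_screen(
    frame: pd.DataFrame,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Univariable logistic screen of each candidate against clinical
    benefit on its own complete cases; returns the result table and the
    variables passing the two-sided p <= alpha criterion."""
    results = []
    passed: list[str] = []
    for var in candidates:
        sub = frame[[var, "cb"]].dropna()
        row: dict[str, object] = {"variable": var, "n": len(sub)}
        try:
            res: TestResult = univariable_logistic(sub[var], sub["cb"].astype(int))
            row.update(
                {
                    "odds_ratio": res.estimate,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p_value": res.p_value,
                    "flags": ";".join(res.flags),
                }
            )
            if res.p_value is not None and res.p_value <= alpha:
                passed.append(var)
        except ValueError as exc:
            row.update({"odds_ratio": None, "p_value": None, "flags": f"error:{exc}"})
        results.append(row)
    return pd.DataFrame(results), passed


@dataclass(frozen=True)
class PipelineResult:
    features: FeatureTable
    feature_frame: pd.DataFrame
    associations: pd.DataFrame
    screened: tuple[str, ...]
    selected: tuple[str, ...]
    model: Optional[FittedModel]
    point_score: Optional[PointScoreModel]
    scores: Optional[pd.DataFrame]
    metrics: Optional[Mapping[str, object]]


_BINARY_TOL = {0.0, 1.0}


def run_pipeline(
    clinical: Sequence[PatientClinical],
    variants,
    cnv_calls,
    annotations,
    catalog=None,
    rules: RuleSet = RuleSet(),
    config: ModelBuildConfig = ModelBuildConfig(),
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    explicit_points: Optional[Mapping[str, float]] = None,
    threshold: float = -1.0,
) -> PipelineResult:
    """Run features -> univariable screen -> ALASSO -> multivariable fit ->
    point score. Deterministic given the inputs and ``config.seed``.

    When ``explicit_points`` is supplied, the point score uses that pinned
    mapping (the published-model reproduction path); otherwise coefficients
    are rounded to the nearest half point. The score stage is skipped (with
    the result fields left None) when no model was fit or a retained
    predictor is not a binary indicator.
    """
    table = build_feature_table(
        clinical, variants, cnv_calls, annotations, catalog=catalog, rules=rules
    )
    frame = feature_frame(table, clinical)
    associations, screened = univariable_screen(frame, candidates, config.univariable_alpha)

    model: Optional[FittedModel] = None
    selected: list[str] = []
    if screened:
        complete = frame[screened + ["cb"]].dropna()
        if complete["cb"].nunique() == 2 and len(complete) > len(screened):
            selected = alasso_select(
                complete[screened], complete["cb"].astype(int), config
            )
            if selected:
                model = fit_multivariable(
                    complete[selected],
                    complete["cb"].astype(int),
                    family="logistic",
                    stay_alpha=config.stay_alpha,
                )

    point_score = scores = metrics = None
    if model is not None:
        binary = all(
            set(frame[v].dropna().unique()) <= _BINARY_TOL for v in model.variables
        )
        if binary:
            if explicit_points is not None:
                point_score = derive_point_score(
                    model, rounding="explicit", threshold=threshold,
                    explicit_points=explicit_points,
                )
            else:
                point_score = derive_point_score(model, threshold=threshold)
            rows = []
            for _, row in frame.iterrows():
                flags = {
                    v: (None if np.isnan(row[v]) else bool(row[v]))
                    for v in point_score.variable_points
                }
                if any(v is None for v in flags.values()):
                    rows.append(
                        {"patient_id": row["patient_id"], "score": None,
                         "predicted": None, "excluded": "missing_covariate"}
                    )
                    continue
                s, pred = score_patient(point_score, flags)
                rows.append(
                    {"patient_id": row["patient_id"], "score": s, "predicted": pred,
                     "excluded": ""}
                )
            scores = pd.DataFrame(rows)
            merged = scores.merge(frame[["patient_id", "cb"]], on="patient_id")
            usable = merged[(merged["excluded"] == "") & merged["cb"].notna()]
            if len(usable) and usable["cb"].nunique() == 2:
                metrics = classification_metrics(
                    list(usable["predicted"]),
                    ["CB" if c == 1.0 else "NCB" for c in usable["cb"]],
                )
    return PipelineResult(
        features=table,
        feature_frame=frame,
        associations=associations,
        screened=tuple(screened),
        selected=tuple(selected),
        model=model,
        point_score=point_score,
        scores=scores,
        metrics=metrics,
    )
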