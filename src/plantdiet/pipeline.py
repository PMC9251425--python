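"""End-to-end analysis of one cohort dataset.

Glues the stages together: recalls -> baseline profiles -> energy filter ->
diet index -> exclusion flow -> Cox models (quintile HRs, trend, per-SD),
spline dose-response, PH check and ROC, for one outcome and one index.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .evaluate import compare_auc, compute_auc, model_score_for_roc
from .food_groups import FoodGroupMap
from .outcomes import AnalysisSample, build_analysis_sample
from .survival import (CoxModelSpec, _exposure_columns, fit_cox, fit_rcs,
                       hr_per_sd, hr_quintiles, model_covariates,
                       stratified_analysis, test_ph, trend_test)


@dataclass
class OutcomeAnalysis:
    """All headline results for one outcome x index x adjustment model."""

    sample: AnalysisSample
    quintile_hr: pd.DataFrame
    p_trend: float
    per_sd: pd.Series
    spline: object | None = None
    ph_p: pd.Series | None = None
    auc: dict | None = None
    stratified: dict | None = None


def analyze_outcome(dataset, outcome: str, index: str = "pdi", model: int = 3,
                    food_group_map: FoodGroupMap | None = None,
                    with_spline: bool = False, with_ph: bool = False,
                    with_roc: bool = False,
                    strata: str | None = None) -> OutcomeAnalysis:
    """Run the full analysis pipeline for one outcome."""
    sample = build_analysis_sample(dataset.baseline, dataset.recalls,
                                   dataset.waves, outcome, index,
                                   food_group_map)
    df = sample.data
    cov = model_covariates(model)
    fit = fit_cox(df, cov, _exposure_columns(df, "quintile"))
    trend = trend_test(df, sample.quintile_medians, cov)
    per_sd = hr_per_sd(df, cov)

    spline = None
    if with_spline:
        spline = fit_rcs(df, model_covariates(model, include_bp=True))
    ph = None
    if with_ph:
        ph = test_ph(df, cov, _exposure_columns(df, "per_sd"))
    auc = None
    if with_roc:
        scores = model_score_for_roc(df, model_covariates(3, include_bp=True))
        auc = compute_auc(scores, df["event"].astype(int))
    strat = None
    if strata:
        strat = stratified_analysis(df, sample.quintile_medians, cov, strata)
    return OutcomeAnalysis(sample=sample, quintile_hr=hr_quintiles(fit),
                           p_trend=trend.p, per_sd=per_sd, spline=spline,
                           ph_p=ph, auc=auc, stratified=strat)


def compare_indices_roc(dataset, outcome: str,
                        food_group_map: FoodGroupMap | None = None) -> dict:
    """Paired AUC comparison of PDI-based vs hPDI-based prediction models."""
    cov = model_covariates(3, include_bp=True)
    spec = CoxModelSpec(outcome)  # validates the outcome/model combination
    samples = {}
    for index in ("pdi", "hpdi"):
        s = build_analysis_sample(dataset.baseline, dataset.recalls,
                                  dataset.waves, outcome, index,
                                  food_group_map)
        samples[index] = s
    # same subjects under both scores by construction (same exclusion flow)
    df_a, df_b = samples["pdi"].data, samples["hpdi"].data
    scores_a = model_score_for_roc(df_a, cov)
    scores_b = model_score_for_roc(df_b, cov)
    labels = df_a["event"].astype(int)
    out = compare_auc(scores_a, scores_b, labels)
    out["auc_pdi"] = compute_auc(scores_a, labels)
    out["auc_hpdi"] = compute_auc(scores_b, labels)
    out["outcome"] = spec.outcome
    return out
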