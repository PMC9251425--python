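"""Outcome ascertainment, exclusion flow, and follow-up accounting.

Three incident outcomes are ascertained from wave-indexed measurements:

* overweight/obesity: BMI >= 24 kg/m^2 (Chinese Working Group threshold);
* hypertension: SBP >= 140 mmHg, DBP >= 90 mmHg, or self-report /
  antihypertensive medication;
* type 2 diabetes: at biomarker waves (2009), fasting glucose >= 7.0 mmol/L,
  HbA1c >= 6.5%, or self-report / hypoglycemic medication; at the 2015 wave,
  self-report / medication only (biomarkers are ignored even if recorded).

An analysis sample for an outcome applies, in order: the energy-range
filter, prevalent CVD/cancer exclusion, loss-to-follow-up exclusion,
prevalent-outcome exclusion, and missing-outcome exclusion; the exclusion
ledger records each step so that excluded + retained always equals the
input count.  Events are dated to the first attended wave at which the
outcome definition is met; follow-up runs from the baseline year to the
event wave or the last outcome-informative wave.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from warnings import warn

import numpy as np
import pandas as pd

from .errors import ChronologyError, SchemaError
from .food_groups import FoodGroupMap
from .index import PlantDietIndexScorer
from .intake import build_profiles, filter_energy

OUTCOMES = ("overweight_obesity", "hypertension", "t2d")

BMI_THRESHOLD = 24.0
SBP_THRESHOLD = 140.0
DBP_THRESHOLD = 90.0
FPG_THRESHOLD = 7.0
HBA1C_THRESHOLD = 6.5

#: wave years at which T2D biomarkers (FPG/HbA1c) are part of the definition
BIOMARKER_WAVES = (2009,)

BASELINE_COLUMNS = [
    "participant_id", "baseline_year", "age", "sex", "urban", "education",
    "met_per_day", "smoker", "drinker", "height_m", "weight_kg", "sbp", "dbp",
    "self_report_htn", "on_bp_medication", "self_report_t2d",
    "on_glucose_medication", "cvd_or_cancer",
]
WAVE_COLUMNS = [
    "participant_id", "wave_year", "weight_kg", "height_m", "sbp", "dbp",
    "fpg", "hba1c", "self_report_htn", "on_bp_medication",
    "self_report_t2d", "on_glucose_medication",
]


# ---------------------------------------------------------------------------
# Classification primitives
# ---------------------------------------------------------------------------
def compute_bmi(weight_kg, height_m):
    """BMI = weight (kg) / height (m)^2; inputs must be positive."""
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if np.any(w[~np.isnan(w)] <= 0) or np.any(h[~np.isnan(h)] <= 0):
        raise ValueError("weight and height must be positive")
    out = w / h ** 2
    return out if out.ndim else float(out)


def classify_overweight(bmi, threshold: float = BMI_THRESHOLD):
    """Overweight/obesity flag: BMI >= threshold; NaN propagates to None."""
    b = np.asarray(bmi, dtype=float)
    out = np.where(np.isnan(b), np.nan, (b >= threshold).astype(float))
    return out if out.ndim else (None if np.isnan(out) else bool(out))


def _truthy(x) -> np.ndarray:
    """Missing-tolerant boolean: NaN/None -> False, else bool(x)."""
    arr = pd.to_numeric(pd.Series(np.atleast_1d(x)), errors="coerce")
    return arr.fillna(0.0).to_numpy(dtype=float) != 0


def classify_hypertension(sbp, dbp, self_report, on_medication):
    """Hypertension flag; None when every criterion is unobservable."""
    s = np.asarray(pd.Series(np.atleast_1d(sbp)), dtype=float)
    d = np.asarray(pd.Series(np.atleast_1d(dbp)), dtype=float)
    rep = _truthy(self_report) | _truthy(on_medication)
    pos = (np.nan_to_num(s, nan=-np.inf) >= SBP_THRESHOLD) \
        | (np.nan_to_num(d, nan=-np.inf) >= DBP_THRESHOLD) | rep
    observable = ~np.isnan(s) | ~np.isnan(d) \
        | ~pd.isna(pd.Series(np.atleast_1d(self_report))).to_numpy() \
        | ~pd.isna(pd.Series(np.atleast_1d(on_medication))).to_numpy()
    out = np.where(observable, pos.astype(float), np.nan)
    if np.ndim(sbp) or np.ndim(dbp):
        return out
    return None if np.isnan(out[0]) else bool(out[0])


def classify_t2d(wave_year, fpg, hba1c, self_report, on_medication,
                 biomarker_waves=BIOMARKER_WAVES):
    """T2D flag under the wave-specific rule.

    Biomarker waves use FPG/HbA1c thresholds plus self-report/medication;
    other waves use self-report/medication only (recorded biomarkers are
    ignored).  Returns None at a biomarker wave where everything is missing.
    """
    years = np.asarray(np.atleast_1d(wave_year))
    g = np.asarray(pd.Series(np.atleast_1d(fpg)), dtype=float)
    a = np.asarray(pd.Series(np.atleast_1d(hba1c)), dtype=float)
    rep_raw = pd.isna(pd.Series(np.atleast_1d(self_report))).to_numpy() \
        & pd.isna(pd.Series(np.atleast_1d(on_medication))).to_numpy()
    rep = _truthy(self_report) | _truthy(on_medication)
    bio = np.isin(years, np.asarray(biomarker_waves))
    bio_pos = (np.nan_to_num(g, nan=-np.inf) >= FPG_THRESHOLD) \
        | (np.nan_to_num(a, nan=-np.inf) >= HBA1C_THRESHOLD)
    pos = np.where(bio, bio_pos | rep, rep)
    observable = np.where(bio, ~np.isnan(g) | ~np.isnan(a) | ~rep_raw, ~rep_raw)
    out = np.where(observable, pos.astype(float), np.nan)
    if np.ndim(wave_year):
        return out
    return None if np.isnan(out[0]) else bool(out[0])


# ---------------------------------------------------------------------------
# Follow-up time
# ---------------------------------------------------------------------------
def compute_follow_up(baseline_year, event_wave_year=None, censor_wave_year=None):
    """Follow-up years: (event wave if event else censor wave) - baseline."""
    end = event_wave_year if event_wave_year is not None else censor_wave_year
    if end is None:
        raise ChronologyError("neither event nor censor wave year given")
    if end <= baseline_year:
        raise ChronologyError(
            f"end year {end} not after baseline year {baseline_year}")
    return float(end - baseline_year)


def person_years(sample: pd.DataFrame) -> float:
    """Total person-years of follow-up in an analysis sample."""
    return float(sample["follow_up_years"].sum())


# ---------------------------------------------------------------------------
# Wave-level ascertainment
# ---------------------------------------------------------------------------
def _wave_status(waves: pd.DataFrame, outcome: str) -> pd.Series:
    """Per wave-row outcome status: 1 met, 0 not met, NaN undeterminable."""
    if outcome == "overweight_obesity":
        bmi = waves["weight_kg"] / waves["height_m"] ** 2
        return pd.Series(np.where(bmi.isna(), np.nan,
                                  (bmi >= BMI_THRESHOLD).astype(float)),
                         index=waves.index)
    if outcome == "hypertension":
        return pd.Series(classify_hypertension(
            waves["sbp"], waves["dbp"],
            waves["self_report_htn"], waves["on_bp_medication"]),
            index=waves.index)
    if outcome == "t2d":
        return pd.Series(classify_t2d(
            waves["wave_year"].to_numpy(), waves["fpg"], waves["hba1c"],
            waves["self_report_t2d"], waves["on_glucose_medication"]),
            index=waves.index)
    raise ValueError(f"unknown outcome {outcome!r}")


def ascertain_outcome(waves: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Collapse wave rows to one row per participant for one outcome.

    Returns columns ``event`` (bool), ``event_wave_year`` (NaN if none),
    ``censor_wave_year`` (last determinable wave), and ``determinable``
    (False when no attended wave allowed outcome evaluation).
    """
    df = waves[["participant_id", "wave_year"]].copy()
    df["status"] = _wave_status(waves, outcome)
    df = df.sort_values(["participant_id", "wave_year"])
    ok = df.dropna(subset=["status"])
    events = ok[ok["status"] > 0].groupby("participant_id")["wave_year"].min()
    last_ok = ok.groupby("participant_id")["wave_year"].max()
    out = pd.DataFrame(index=df["participant_id"].unique())
    out.index.name = "participant_id"
    out["event_wave_year"] = events.reindex(out.index)
    out["censor_wave_year"] = last_ok.reindex(out.index)
    out["event"] = out["event_wave_year"].notna()
    out["determinable"] = out["censor_wave_year"].notna()
    return out


def prevalent_at_baseline(baseline: pd.DataFrame, outcome: str) -> pd.Series:
    """Prevalence flag at baseline from the baseline measurement block."""
    if outcome == "overweight_obesity":
        bmi = baseline["weight_kg"] / baseline["height_m"] ** 2
        return (bmi >= BMI_THRESHOLD).fillna(False)
    if outcome == "hypertension":
        flags = classify_hypertension(baseline["sbp"], baseline["dbp"],
                                      baseline["self_report_htn"],
                                      baseline["on_bp_medication"])
        return pd.Series(flags, index=baseline.index).fillna(0).astype(bool)
    if outcome == "t2d":
        # no baseline biomarkers: self-report / medication only
        rep = _truthy(baseline["self_report_t2d"]) \
            | _truthy(baseline["on_glucose_medication"])
        return pd.Series(rep, index=baseline.index)
    raise ValueError(f"unknown outcome {outcome!r}")


# ---------------------------------------------------------------------------
# Analysis-sample construction
# ---------------------------------------------------------------------------
@dataclass
class AnalysisSample:
    """Per-outcome analysis cohort after the exclusion flow."""

    outcome: str
    index_name: str
    data: pd.DataFrame
    ledger: dict[str, int] = field(default_factory=dict)
    quintile_medians: pd.Series | None = None

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    @property
    def person_years(self) -> float:
        return person_years(self.data)


def build_analysis_sample(baseline: pd.DataFrame, recalls: pd.DataFrame,
                          waves: pd.DataFrame, outcome: str,
                          index: str = "pdi",
                          food_group_map: FoodGroupMap | None = None,
                          energy_bounds: tuple[float, float] = (500.0, 5000.0),
                          ) -> AnalysisSample:
    """Apply the exclusion flow and assemble one outcome's analysis sample.

    Order of exclusions: energy filter -> prevalent CVD/cancer ->
    loss to follow-up -> prevalent outcome -> missing outcome.  Diet-index
    totals, z-scores and exposure quintiles are computed within the retained
    sample.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    missing = [c for c in BASELINE_COLUMNS if c not in baseline.columns]
    if missing:
        raise SchemaError("baseline", missing)
    base = baseline.set_index("participant_id")
    ledger = {"input": len(base)}

    profiles = build_profiles(recalls, food_group_map)
    profiles = profiles.reindex(base.index)
    # 1. energy filter (participants with no dietary data counted separately)
    prof_present = profiles.dropna(subset=["total_energy"])
    ledger["missing_diet"] = len(base) - len(prof_present)
    kept, elog = filter_energy(prof_present, *energy_bounds)
    ledger["energy"] = elog.n_excluded
    # 2. prevalent CVD / cancer
    cvd = base.loc[kept.index, "cvd_or_cancer"].astype(bool)
    kept = kept.loc[~cvd]
    ledger["prevalent_cvd_cancer"] = int(cvd.sum())
    # 3. loss to follow-up (no attended wave at all)
    followed = kept.index.isin(waves["participant_id"].unique())
    ledger["lost_to_followup"] = int((~followed).sum())
    kept = kept.loc[followed]
    # 4. prevalent outcome at baseline
    prev = prevalent_at_baseline(base.loc[kept.index], outcome)
    prev = prev.reindex(kept.index).fillna(False).astype(bool)
    ledger["prevalent_outcome"] = int(prev.sum())
    kept = kept.loc[~prev]
    # 5. missing outcome over follow-up
    asc = ascertain_outcome(waves[waves["participant_id"].isin(kept.index)], outcome)
    asc = asc.reindex(kept.index)
    determinable = asc["determinable"].fillna(False).astype(bool)
    ledger["missing_outcome"] = int((~determinable).sum())
    kept = kept.loc[determinable]
    asc = asc.loc[kept.index]
    ledger["retained"] = len(kept)

    if kept.empty:
        warn(f"analysis sample for {outcome!r} is empty", RuntimeWarning,
             stacklevel=2)
        return AnalysisSample(outcome, index, _empty_sample(), ledger)

    # follow-up time from the participant-specific baseline year
    end = asc["event_wave_year"].where(asc["event"], asc["censor_wave_year"])
    fu = end - kept["baseline_year"]
    if (fu <= 0).any():
        raise ChronologyError("event/censor wave not after baseline year")

    if len(kept) < 5:
        # too few participants for quintile ranking; exposure left unscored
        warn(f"analysis sample for {outcome!r} has n={len(kept)} < 5; "
             "diet-index exposure not computed", RuntimeWarning, stacklevel=2)
        scores = pd.DataFrame({"quintile": np.nan, "total": np.nan,
                               "z": np.nan}, index=kept.index)
        medians = None
    else:
        scorer = PlantDietIndexScorer(index, food_group_map)
        scores = scorer.fit(kept).transform(kept)
        medians = scorer.quintile_medians_

    covar = base.loc[kept.index]
    bmi = covar["weight_kg"] / covar["height_m"] ** 2
    data = pd.DataFrame({
        "quintile": scores["quintile"],
        "index_total": scores["total"],
        "index_z": scores["z"],
        "urban": covar["urban"].astype(int),
        "age": covar["age"].astype(float),
        "sex": covar["sex"].astype(int),
        "total_energy": kept["total_energy"].astype(float),
        "education": covar["education"].astype(int),
        "met_per_day": covar["met_per_day"].astype(float),
        "smoker": covar["smoker"].astype(int),
        "drinker": covar["drinker"].astype(int),
        "bmi": bmi.astype(float),
        "sbp": covar["sbp"].astype(float),
        "dbp": covar["dbp"].astype(float),
        "baseline_year": kept["baseline_year"].astype(int),
        "follow_up_years": fu.astype(float),
        "event": asc["event"].astype(bool),
        "event_wave_year": asc["event_wave_year"],
    })
    return AnalysisSample(outcome, index, data, ledger, medians)


def _empty_sample() -> pd.DataFrame:
    cols = ["quintile", "index_total", "index_z", "urban", "age", "sex",
            "total_energy", "education", "met_per_day", "smoker", "drinker",
            "bmi", "sbp", "dbp", "baseline_year", "follow_up_years", "event",
            "event_wave_year"]
    return pd.DataFrame(columns=cols)
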