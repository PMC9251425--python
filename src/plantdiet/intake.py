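"""From raw 24-h recall records to baseline intake profiles.

A recall table holds one row per participant x survey year x recall day x
food group with grams consumed, plus the day's total energy (kcal).  The
baseline profile of a participant is the per-group mean over the (up to 3)
recall days of each baseline survey year, averaged across the (up to 2)
baseline years; participants present in only one baseline year use that
year alone.  Profiles with implausible total energy (< 500 or > 5,000
kcal/day; boundaries retained) are excluded before index construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingDataError, SchemaError
from .food_groups import FoodGroupMap

RECALL_COLUMNS = ["participant_id", "year", "day", "group_id", "grams", "kcal"]

ENERGY_MIN_KCAL = 500.0
ENERGY_MAX_KCAL = 5000.0


def _require_columns(df: pd.DataFrame, required, table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(table, missing)


def aggregate_recalls(recalls: pd.DataFrame,
                      food_group_map: FoodGroupMap | None = None) -> pd.Series:
    """Aggregate one participant-year of recall rows to mean daily intakes.

    Returns a Series of g/day per group (groups reported on no day get 0)
    plus ``total_energy`` (mean kcal/day over the recall days).
    Raises :class:`MissingDataError` when no day-records are present.
    """
    _require_columns(recalls, RECALL_COLUMNS, "recalls")
    fmap = food_group_map or FoodGroupMap.default()
    if recalls.empty:
        raise MissingDataError("no recall day-records for participant-year")
    days = sorted(recalls["day"].unique())
    # grams per day per group, absent groups counted as 0 on every day
    per_day = (recalls.pivot_table(index="day", columns="group_id",
                                   values="grams", aggfunc="sum", fill_value=0.0)
               .reindex(columns=fmap.group_ids, fill_value=0.0)
               .reindex(index=days, fill_value=0.0))
    out = per_day.mean(axis=0)
    kcal = recalls.groupby("day")["kcal"].first()
    out["total_energy"] = float(kcal.mean())
    return out


def average_baseline_years(profiles_by_year: dict[int, pd.Series]) -> pd.Series:
    """Average per-year intake profiles into one baseline profile.

    Element-wise mean when multiple years are present; pass-through for a
    single year.  The earliest year present is recorded as ``baseline_year``
    (it anchors follow-up time).
    """
    present = {y: p for y, p in profiles_by_year.items() if p is not None}
    if not present:
        raise MissingDataError("no baseline dietary year present")
    stacked = pd.concat(present.values(), axis=1)
    out = stacked.mean(axis=1)
    out["baseline_year"] = min(present)
    return out


def build_profiles(recalls: pd.DataFrame,
                   food_group_map: FoodGroupMap | None = None,
                   baseline_years: tuple[int, ...] = (2004, 2006)) -> pd.DataFrame:
    """Vectorised recall -> profile pipeline for a whole cohort.

    Equivalent to :func:`aggregate_recalls` per participant-year followed by
    :func:`average_baseline_years`, but computed with grouped operations.
    Returns a DataFrame indexed by participant_id with the food-group g/day
    columns, ``total_energy`` and ``baseline_year``.
    """
    _require_columns(recalls, RECALL_COLUMNS, "recalls")
    fmap = food_group_map or FoodGroupMap.default()
    rec = recalls[recalls["year"].isin(baseline_years)]
    if rec.empty:
        raise MissingDataError("no recall records in the baseline years")

    # mean g/day per participant-year-group: sum over days / number of days
    n_days = (rec.groupby(["participant_id", "year"])["day"].nunique()
              .rename("n_days"))
    grams = (rec.groupby(["participant_id", "year", "group_id"], sort=False)["grams"]
             .sum().unstack("group_id", fill_value=0.0)
             .reindex(columns=fmap.group_ids, fill_value=0.0))
    grams = grams.div(n_days, axis=0)

    # mean kcal/day per participant-year (kcal is a day-level total)
    kcal = (rec.drop_duplicates(["participant_id", "year", "day"])
            .groupby(["participant_id", "year"])["kcal"].mean()
            .rename("total_energy"))
    per_year = grams.join(kcal)

    profile = per_year.groupby(level="participant_id").mean()
    profile["baseline_year"] = (per_year.reset_index("year")
                                .groupby(level="participant_id")["year"].min())
    return profile


@dataclass
class EnergyExclusionLog:
    """Counts of profiles excluded by the energy-range filter."""

    n_low: int
    n_high: int

    @property
    def n_excluded(self) -> int:
        return self.n_low + self.n_high


def filter_energy(profiles: pd.DataFrame,
                  low: float = ENERGY_MIN_KCAL,
                  high: float = ENERGY_MAX_KCAL) -> tuple[pd.DataFrame, EnergyExclusionLog]:
    """Drop profiles with total energy strictly below ``low`` or above ``high``.

    Boundary values are retained (the exclusion rule is a strict inequality
    on both sides).  Returns the retained profiles and an exclusion log.
    """
    e = profiles["total_energy"].to_numpy(dtype=float)
    low_mask = e < low
    high_mask = e > high
    retained = profiles.loc[~(low_mask | high_mask)]
    return retained, EnergyExclusionLog(int(low_mask.sum()), int(high_mask.sum()))
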