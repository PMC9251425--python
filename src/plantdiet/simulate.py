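"""Synthetic cohort generator with known ground truth.

Emulates the structure of a Chinese longitudinal nutrition cohort: three
24-h recall days per participant in up to two baseline survey years
(2004/2006), 17 food groups with zero-inflated log-normal intakes coupled
to total energy, baseline covariates, and outcome measurements observed
only at follow-up waves (2009/2015).

A standardised latent diet-quality score ``z`` shifts the log-intake of
every food group along its healthy/unhealthy direction, so the observable
diet index computed downstream from the generated recalls tracks ``z``
closely -- the whole scoring path, not the latent truth, is what analysis
stages see.  Event times are drawn from a constant-hazard (exponential)
model ``h = h0 * exp(beta * z + gamma . covariates)`` (Weibull shape and a
time-decaying index effect are available for PH-violation experiments), and
events surface only at the first attended wave at or after the latent event
time, through measurements that then satisfy the diagnostic definition.

Ground truth (``z``, latent event times, prevalence flags) is written
alongside the observable tables for recovery tests but is never consumed by
analysis stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import AlignmentError, ConfigurationError, SchemaError
from .food_groups import DEFAULT_GROUPS, HEALTHY_PLANT
from .outcomes import BASELINE_COLUMNS, OUTCOMES, WAVE_COLUMNS
from .intake import RECALL_COLUMNS

TRUTH_COLUMNS = ["participant_id", "true_index_z"]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------
@dataclass
class GroupParams:
    """Intake distribution of one food group.

    ``median_g``: median g/day among consumers; ``log_sd``: SD of log intake;
    ``zero_prob``: fraction of never-consumers; ``energy_slope``: log-intake
    shift per SD of total energy; ``latent_loading``: log-intake shift per SD
    of the latent diet-quality score (sign encodes the group's direction);
    ``zero_link``: correlation between the consumer/never-consumer threshold
    variable and the (direction-signed) latent score, so diet quality moves
    occurrence as well as amount while the marginal ``zero_prob`` is kept.
    """

    median_g: float
    log_sd: float = 0.55
    zero_prob: float = 0.0
    energy_slope: float = 0.25
    latent_loading: float = 0.0
    zero_link: float = 0.6


@dataclass
class CovariateParams:
    """Marginal distributions of the baseline covariates."""

    p_male: float = 0.48
    p_urban: float = 0.30
    age_mean: float = 46.0
    age_sd: float = 13.0
    age_min: float = 18.0
    age_max: float = 80.0
    education_probs: tuple = (0.45, 0.34, 0.13, 0.08)
    met_mean: float = 185.0
    met_sd: float = 125.0
    p_smoker: float = 0.33
    p_drinker: float = 0.34
    energy_mean: float = 2230.0
    energy_sd: float = 600.0


@dataclass
class OutcomeParams:
    """Hazard model and observation parameters for one outcome."""

    baseline_hazard: float       # events / person-year at covariate means
    loghr_index: float           # log HR per SD of the latent diet score
    loghr_age: float = 0.0       # log HR per SD of age
    loghr_male: float = 0.0
    baseline_prevalence: float = 0.0
    p_missing: float = 0.15      # per-wave probability the block is missing
    weibull_shape: float = 1.0
    index_effect_halflife: float | None = None  # years; None = constant effect


def default_group_params() -> dict[str, GroupParams]:
    """Default 17-group intake distributions (g/day medians, zero inflation).

    Latent loadings are aligned with the hPDI directions: healthy plant
    groups rise with diet quality, less-healthy plant and animal groups fall.
    """
    medians = {
        "whole_grains": (25.0, 0.45), "fruits": (40.0, 0.45),
        "vegetables": (350.0, 0.0), "nuts": (8.0, 0.75),
        "legumes": (40.0, 0.35), "tea_coffee": (5.0, 0.85),
        "vegetable_oils": (35.0, 0.02),
        "refined_grains": (420.0, 0.0), "potatoes": (70.0, 0.25),
        "sugary_drinks": (15.0, 0.80), "sweets_desserts": (12.0, 0.70),
        "preserved_foods": (15.0, 0.55),
        "animal_fats": (8.0, 0.50), "dairy": (20.0, 0.85),
        "eggs": (30.0, 0.30), "fish_seafood": (35.0, 0.50),
        "meat": (80.0, 0.15),
    }
    out = {}
    for g, (med, zp) in medians.items():
        loading = 1.0 if DEFAULT_GROUPS[g] == HEALTHY_PLANT else -1.0
        out[g] = GroupParams(median_g=med, zero_prob=zp, latent_loading=loading)
    return out


def default_outcome_params() -> dict[str, OutcomeParams]:
    return {
        "overweight_obesity": OutcomeParams(
            baseline_hazard=0.042, loghr_index=float(np.log(0.89)),
            loghr_male=0.05, baseline_prevalence=0.32, p_missing=0.18),
        "hypertension": OutcomeParams(
            baseline_hazard=0.040, loghr_index=float(np.log(0.88)),
            loghr_age=0.30, loghr_male=0.10, baseline_prevalence=0.31,
            p_missing=0.15),
        "t2d": OutcomeParams(
            baseline_hazard=0.0095, loghr_index=float(np.log(0.93)),
            loghr_age=0.45, loghr_male=0.05, baseline_prevalence=0.035,
            p_missing=0.20),
    }


@dataclass
class SimulationConfig:
    """All generator knobs; validated on construction."""

    n_participants: int = 1000
    seed: int = 0
    wave_years: tuple = (2004, 2006, 2009, 2015)
    p_both_years: float = 0.70    # dietary assessment in both 2004 and 2006
    p_only_first: float = 0.15    # 2004 only; remainder 2006 only
    p_ltfu: float = 0.25          # never seen at a follow-up wave
    p_attend: tuple = (0.90, 0.88)  # per follow-up wave, given retained
    p_cvd_cancer: float = 0.015
    truth_scheme: str = "hpdi"    # index whose habitual value drives hazards
    covariates: CovariateParams = field(default_factory=CovariateParams)
    group_params: dict = field(default_factory=default_group_params)
    outcomes: dict = field(default_factory=default_outcome_params)

    def __post_init__(self):
        self.validate()

    def validate(self):
        if not isinstance(self.n_participants, (int, np.integer)) \
                or self.n_participants <= 0:
            raise ConfigurationError("n_participants", "must be a positive integer")
        if list(self.wave_years) != sorted(set(self.wave_years)):
            raise ConfigurationError("wave_years", "must be strictly increasing")
        for name, gp in self.group_params.items():
            if not 0 <= gp.zero_prob < 1:
                raise ConfigurationError(f"group_params[{name}].zero_prob",
                                         "must be in [0, 1)")
            if gp.median_g <= 0:
                raise ConfigurationError(f"group_params[{name}].median_g",
                                         "must be positive")
            if not 0 <= gp.zero_link <= 1:
                raise ConfigurationError(f"group_params[{name}].zero_link",
                                         "must be in [0, 1]")
        for name, op in self.outcomes.items():
            if op.baseline_hazard < 0:
                raise ConfigurationError(f"outcomes[{name}].baseline_hazard",
                                         "must be non-negative")
            if not 0 <= op.baseline_prevalence < 1:
                raise ConfigurationError(f"outcomes[{name}].baseline_prevalence",
                                         "must be in [0, 1)")
        for p, nm in ((self.p_both_years, "p_both_years"),
                      (self.p_only_first, "p_only_first"),
                      (self.p_ltfu, "p_ltfu"), (self.p_cvd_cancer, "p_cvd_cancer")):
            if not 0 <= p <= 1:
                raise ConfigurationError(nm, "must be in [0, 1]")

    # -- helpers -----------------------------------------------------------
    @property
    def baseline_years(self) -> tuple:
        return tuple(y for y in self.wave_years if y <= 2006)

    @property
    def followup_years(self) -> tuple:
        return tuple(y for y in self.wave_years if y > 2006)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2 ** 31), stage])


# ---------------------------------------------------------------------------
# Participants and truth
# ---------------------------------------------------------------------------
def generate_participants(config: SimulationConfig) -> pd.DataFrame:
    """Baseline covariate records (one row per participant).

    Deterministic given the config seed.  ``_energy_target`` is the latent
    habitual energy intake driving the recall generator (underscore columns
    are generator-internal and are not written to disk).
    """
    rng = _rng(config, 0)
    n = config.n_participants
    cv = config.covariates
    df = pd.DataFrame({"participant_id": np.arange(1, n + 1)})
    df["sex"] = (rng.random(n) < cv.p_male).astype(int)
    df["urban"] = (rng.random(n) < cv.p_urban).astype(int)
    df["age"] = np.clip(rng.normal(cv.age_mean, cv.age_sd, n),
                        cv.age_min, cv.age_max).round(1)
    df["education"] = rng.choice(len(cv.education_probs), size=n,
                                 p=cv.education_probs)
    df["met_per_day"] = np.round(np.clip(
        rng.normal(cv.met_mean, cv.met_sd, n), 5.0, None), 1)
    df["smoker"] = (rng.random(n) < cv.p_smoker).astype(int)
    df["drinker"] = (rng.random(n) < cv.p_drinker).astype(int)
    df["cvd_or_cancer"] = (rng.random(n) < config.p_cvd_cancer).astype(int)

    u = rng.random(n)
    both = u < config.p_both_years
    only_first = (~both) & (u < config.p_both_years + config.p_only_first)
    y0, y1 = config.baseline_years[0], config.baseline_years[-1]
    df["diet_year_first"] = np.where(both | only_first, y0, y1)
    df["diet_year_second"] = np.where(both, y1, 0)
    df["baseline_year"] = df["diet_year_first"]
    df["_energy_target"] = np.clip(
        rng.normal(cv.energy_mean, cv.energy_sd, n), 250.0, 6000.0).round(0)
    return df


def _habitual_profile(cohort: pd.DataFrame, config: SimulationConfig,
                      rng: np.random.Generator,
                      diet_factor: np.ndarray) -> pd.DataFrame:
    """Habitual (noise-free) mean daily intake per group for each participant.

    The diet-quality factor shifts each group's log intake along its
    ``latent_loading`` and tilts consumer/never-consumer status through
    ``zero_link`` (the marginal zero probability is preserved).
    """
    n = len(cohort)
    groups = list(config.group_params)
    cv = config.covariates
    energy = cohort["_energy_target"].to_numpy(dtype=float)
    e_z = (energy - cv.energy_mean) / cv.energy_sd

    med = np.array([config.group_params[g].median_g for g in groups])
    sd = np.array([config.group_params[g].log_sd for g in groups])
    slope = np.array([config.group_params[g].energy_slope for g in groups])
    load = np.array([config.group_params[g].latent_loading for g in groups])
    zp = np.array([config.group_params[g].zero_prob for g in groups])
    link = np.array([config.group_params[g].zero_link for g in groups])

    base_log = (np.log(med)[None, :] + slope[None, :] * e_z[:, None]
                + load[None, :] * diet_factor[:, None]
                + sd[None, :] * rng.standard_normal((n, len(groups))))
    signed = link * np.sign(load)
    latent_u = (signed[None, :] * diet_factor[:, None]
                + np.sqrt(1.0 - signed ** 2)[None, :]
                * rng.standard_normal((n, len(groups))))
    consumer = latent_u >= norm.ppf(zp)[None, :]
    prof = pd.DataFrame(np.exp(base_log) * consumer, columns=groups)
    prof["total_energy"] = energy
    return prof


def generate_truth(cohort: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Ground truth: habitual intakes, true index z, prevalence, event times.

    The true index is the diet index computed on the habitual (noise-free)
    intake profile -- the estimand the recall-based pipeline measures --
    standardised within the cohort; event times are drawn from the hazard
    model on that score.  Habitual profiles are carried in ``hab_*`` columns
    so the recall generator can add measurement noise around them.
    """
    from .index import compute_index  # local import; no cycle at module load

    rng = _rng(config, 1)
    n = len(cohort)
    cv = config.covariates
    truth = pd.DataFrame({"participant_id": cohort["participant_id"].to_numpy()})
    diet_factor = rng.standard_normal(n)
    habitual = _habitual_profile(cohort, config, rng, diet_factor)
    if n >= 5:
        totals = compute_index(habitual, config.truth_scheme)["total"]
        truth["true_index_z"] = ((totals - totals.mean())
                                 / totals.std(ddof=1)).to_numpy()
    else:
        truth["true_index_z"] = diet_factor
    for g in config.group_params:
        truth[f"hab_{g}"] = habitual[g].to_numpy()

    age_z = (cohort["age"].to_numpy() - cv.age_mean) / cv.age_sd
    male = cohort["sex"].to_numpy() - cv.p_male
    for name, op in config.outcomes.items():
        truth[f"prevalent_{name}"] = (rng.random(n) < op.baseline_prevalence)
        eta = op.loghr_age * age_z + op.loghr_male * male
        truth[f"event_time_{name}"] = _draw_event_times(
            rng, op, eta, truth["true_index_z"].to_numpy())
    return truth


def _draw_event_times(rng, op: OutcomeParams, eta_cov: np.ndarray,
                      z: np.ndarray) -> np.ndarray:
    """Years from baseline to the latent event (inf when hazard is zero)."""
    n = len(z)
    if op.baseline_hazard == 0:
        return np.full(n, np.inf)
    if op.index_effect_halflife is None:
        rate = op.baseline_hazard * np.exp(eta_cov + op.loghr_index * z)
        e = rng.exponential(1.0, n)
        t = e / rate
        if op.weibull_shape != 1.0:
            # S(t) = exp(-(h rate) t^k): preserves PH in the covariates
            t = (e / rate) ** (1.0 / op.weibull_shape)
        return t
    # time-decaying index effect: discrete yearly hazard steps
    t = np.full(n, np.inf)
    alive = np.ones(n, dtype=bool)
    for year in range(1, 41):
        decay = 2.0 ** (-(year - 0.5) / op.index_effect_halflife)
        h = op.baseline_hazard * np.exp(eta_cov + op.loghr_index * z * decay)
        hit = alive & (rng.random(n) < 1.0 - np.exp(-h))
        t[hit] = year - rng.random(int(hit.sum()))
        alive &= ~hit
    return t


# ---------------------------------------------------------------------------
# Recalls
# ---------------------------------------------------------------------------
def generate_recalls(cohort: pd.DataFrame, config: SimulationConfig,
                     truth: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recall records: participant x year x day x food group -> grams, kcal.

    Three day-records per participant per attended baseline year.  Day
    grams are the participant's habitual mean intake (from ``truth``, or
    drawn fresh with a null diet-quality factor when no truth is supplied)
    under multiplicative day-to-day and year-to-year recall noise.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    rng = _rng(config, 2)
    n = len(cohort)
    groups = list(config.group_params)
    n_g = len(groups)

    if truth is not None:
        _check_aligned(cohort, truth)
        habitual = truth[[f"hab_{g}" for g in groups]].to_numpy(dtype=float)
    else:
        habitual = _habitual_profile(cohort, config, rng,
                                     np.zeros(n))[groups].to_numpy()
    energy = cohort["_energy_target"].to_numpy(dtype=float)

    frames = []
    years = np.stack([cohort["diet_year_first"].to_numpy(),
                      cohort["diet_year_second"].to_numpy()])
    for yi in range(2):
        yr = years[yi]
        mask = yr > 0
        idx = np.where(mask)[0]
        if idx.size == 0:
            continue
        year_shift = 0.15 * rng.standard_normal(idx.size)
        mean_g = habitual[idx] * np.exp(year_shift[:, None])
        day_noise = rng.standard_normal((idx.size, 3, n_g)) * 0.30
        grams = mean_g[:, None, :] * np.exp(day_noise)  # (n_sel, 3, 17)
        kcal = energy[idx, None] * np.exp(0.08 * rng.standard_normal((idx.size, 3)))
        pid = cohort["participant_id"].to_numpy()[idx]
        frames.append(pd.DataFrame({
            "participant_id": np.repeat(pid, 3 * n_g),
            "year": np.repeat(yr[idx], 3 * n_g),
            "day": np.tile(np.repeat([1, 2, 3], n_g), idx.size),
            "group_id": np.tile(groups, 3 * idx.size),
            "grams": np.round(grams.reshape(-1), 2),
            "kcal": np.round(np.repeat(kcal.reshape(-1), n_g), 1),
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["participant_id", "year", "day"],
                           kind="stable", ignore_index=True)


# ---------------------------------------------------------------------------
# Outcome measurements
# ---------------------------------------------------------------------------
def _check_aligned(cohort: pd.DataFrame, truth: pd.DataFrame) -> None:
    if not np.array_equal(cohort["participant_id"].to_numpy(),
                          truth["participant_id"].to_numpy()):
        raise AlignmentError("cohort and truth participant ids differ")


def generate_outcomes(cohort: pd.DataFrame, truth: pd.DataFrame,
                      config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Baseline measurement block and wave-indexed measurement table.

    A participant's measurements first satisfy an outcome definition at the
    first attended wave year at or after their latent event time;
    measurements before that stay below the diagnostic thresholds.
    Prevalent cases present above-threshold at baseline already.
    """
    _check_aligned(cohort, truth)
    rng = _rng(config, 3)
    n = len(cohort)
    male = cohort["sex"].to_numpy() == 1

    height = np.round(np.where(male, rng.normal(1.68, 0.06, n),
                               rng.normal(1.57, 0.055, n)), 3)
    prev_ow = truth["prevalent_overweight_obesity"].to_numpy()
    prev_ht = truth["prevalent_hypertension"].to_numpy()
    prev_dm = truth["prevalent_t2d"].to_numpy()

    base = cohort[["participant_id", "baseline_year", "age", "sex", "urban",
                   "education", "met_per_day", "smoker", "drinker",
                   "cvd_or_cancer"]].copy()
    base["height_m"] = height
    bmi0 = _draw_bmi(rng, prev_ow)
    base["weight_kg"] = np.round(bmi0 * height ** 2, 1)
    sbp0, dbp0, rep_ht0, med_ht0 = _draw_bp(rng, prev_ht)
    base["sbp"], base["dbp"] = sbp0, dbp0
    base["self_report_htn"], base["on_bp_medication"] = rep_ht0, med_ht0
    base["self_report_t2d"] = prev_dm.astype(int)
    base["on_glucose_medication"] = (prev_dm & (rng.random(n) < 0.6)).astype(int)

    # wave attendance
    retained = rng.random(n) >= config.p_ltfu
    attend = {}
    for wi, wy in enumerate(config.followup_years):
        attend[wy] = retained & (rng.random(n) < config.p_attend[wi])
    any_attended = np.logical_or.reduce(list(attend.values()))
    first_wave = config.followup_years[0]
    attend[first_wave] = attend[first_wave] | (retained & ~any_attended)

    baseline_year = cohort["baseline_year"].to_numpy()
    rows = []
    for wy in config.followup_years:
        idx = np.where(attend[wy])[0]
        if idx.size == 0:
            continue
        m = idx.size
        elapsed = wy - baseline_year[idx]
        wave = pd.DataFrame({
            "participant_id": cohort["participant_id"].to_numpy()[idx],
            "wave_year": wy,
        })
        # overweight/obesity block
        status = prev_ow[idx] | (truth["event_time_overweight_obesity"]
                                 .to_numpy()[idx] <= elapsed)
        miss = rng.random(m) < config.outcomes["overweight_obesity"].p_missing
        bmi = _draw_bmi(rng, status)
        wave["weight_kg"] = np.where(miss, np.nan,
                                     np.round(bmi * height[idx] ** 2, 1))
        wave["height_m"] = np.where(miss, np.nan, height[idx])
        # hypertension block
        status = prev_ht[idx] | (truth["event_time_hypertension"]
                                 .to_numpy()[idx] <= elapsed)
        miss = rng.random(m) < config.outcomes["hypertension"].p_missing
        sbp, dbp, rep, med = _draw_bp(rng, status)
        wave["sbp"] = np.where(miss, np.nan, sbp)
        wave["dbp"] = np.where(miss, np.nan, dbp)
        wave["self_report_htn"] = np.where(miss, np.nan, rep)
        wave["on_bp_medication"] = np.where(miss, np.nan, med)
        # T2D block
        status = prev_dm[idx] | (truth["event_time_t2d"].to_numpy()[idx] <= elapsed)
        miss = rng.random(m) < config.outcomes["t2d"].p_missing
        biomarker_wave = wy == config.followup_years[0]
        fpg, hba1c, rep, med = _draw_t2d(rng, status, biomarker_wave)
        wave["fpg"] = np.where(miss, np.nan, fpg)
        wave["hba1c"] = np.where(miss, np.nan, hba1c)
        wave["self_report_t2d"] = np.where(miss, np.nan, rep)
        wave["on_glucose_medication"] = np.where(miss, np.nan, med)
        rows.append(wave)
    waves = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=WAVE_COLUMNS)
    return base[BASELINE_COLUMNS], waves[WAVE_COLUMNS]


def _draw_bmi(rng, above: np.ndarray) -> np.ndarray:
    n = len(above)
    return np.round(np.where(above, 24.0 + rng.gamma(2.0, 1.0, n),
                             rng.uniform(18.5, 23.7, n)), 1)


def _draw_bp(rng, status: np.ndarray):
    n = len(status)
    # below threshold everywhere for non-cases
    sbp = np.round(np.clip(rng.normal(117.0, 10.0, n), 90.0, 139.0), 0)
    dbp = np.round(np.clip(rng.normal(75.0, 7.0, n), 55.0, 89.0), 0)
    rep = np.zeros(n)
    med = np.zeros(n)
    if status.any():
        k = int(status.sum())
        high_sbp = rng.random(k) < 0.75
        sbp_hi = np.round(np.where(high_sbp, 140.0 + rng.exponential(10.0, k),
                                   rng.normal(128.0, 7.0, k).clip(95, 139)), 0)
        dbp_hi = np.round(np.where(high_sbp,
                                   rng.normal(88.0, 8.0, k).clip(60, 115),
                                   90.0 + rng.exponential(6.0, k)), 0)
        sbp[status], dbp[status] = sbp_hi, dbp_hi
        rep[status] = (rng.random(k) < 0.5).astype(float)
        med[status] = (rep[status] > 0) & (rng.random(k) < 0.6)
    return sbp, dbp, rep, med


def _draw_t2d(rng, status: np.ndarray, biomarker_wave: bool):
    n = len(status)
    if not biomarker_wave:
        fpg = np.full(n, np.nan)
        hba1c = np.full(n, np.nan)
        rep = status.astype(float)
        med = (status & (rng.random(n) < 0.6)).astype(float)
        return fpg, hba1c, rep, med
    fpg = np.round(np.clip(rng.normal(5.2, 0.5, n), 3.5, 6.9), 2)
    hba1c = np.round(np.clip(rng.normal(5.4, 0.3, n), 4.0, 6.4), 1)
    rep = np.zeros(n)
    med = np.zeros(n)
    if status.any():
        k = int(status.sum())
        hi_fpg = rng.random(k) < 0.7
        hi_a1c = rng.random(k) < 0.5
        hi_rep = rng.random(k) < 0.4
        none = ~(hi_fpg | hi_a1c | hi_rep)
        hi_fpg |= none  # at least one criterion must fire at the event wave
        fpg[status] = np.round(np.where(hi_fpg, 7.0 + rng.exponential(1.2, k),
                                        fpg[status]), 2)
        hba1c[status] = np.round(np.where(hi_a1c, 6.5 + rng.exponential(0.7, k),
                                          hba1c[status]), 1)
        rep[status] = hi_rep.astype(float)
        med[status] = (hi_rep & (rng.random(k) < 0.5)).astype(float)
    return fpg, hba1c, rep, med


# ---------------------------------------------------------------------------
# Dataset orchestration and I/O
# ---------------------------------------------------------------------------
@dataclass
class SyntheticDataset:
    """All tables of one simulated cohort (truth is for tests only)."""

    baseline: pd.DataFrame
    recalls: pd.DataFrame
    waves: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig | None = None


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete synthetic cohort dataset from one config."""
    cohort = generate_participants(config)
    truth = generate_truth(cohort, config)
    recalls = generate_recalls(cohort, config, truth)
    baseline, waves = generate_outcomes(cohort, truth, config)
    return SyntheticDataset(baseline=baseline, recalls=recalls, waves=waves,
                            truth=truth, config=config)


_SCHEMAS = {
    "baseline": BASELINE_COLUMNS,
    "recalls": RECALL_COLUMNS,
    "waves": WAVE_COLUMNS,
    "truth": TRUTH_COLUMNS,
}


def write_dataset(dataset: SyntheticDataset, directory) -> Path:
    """Write the dataset as CSV tables plus a manifest (seed, config hash)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tables = {"baseline": dataset.baseline, "recalls": dataset.recalls,
              "waves": dataset.waves, "truth": dataset.truth}
    manifest = {"tables": {}}
    for name, df in tables.items():
        missing = [c for c in _SCHEMAS[name] if c not in df.columns]
        if missing:
            raise SchemaError(name, missing)
        df.to_csv(directory / f"{name}.csv", index=False)
        manifest["tables"][name] = len(df)
    if dataset.config is not None:
        manifest["seed"] = int(dataset.config.seed)
        manifest["config_hash"] = dataset.config.hash()
        manifest["n_participants"] = int(dataset.config.n_participants)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return directory


def read_dataset(directory) -> SyntheticDataset:
    """Read a dataset written by :func:`write_dataset` (schema-checked)."""
    directory = Path(directory)
    out = {}
    for name in ("baseline", "recalls", "waves", "truth"):
        df = pd.read_csv(directory / f"{name}.csv")
        missing = [c for c in _SCHEMAS[name] if c not in df.columns]
        if missing:
            raise SchemaError(name, missing)
        out[name] = df
    return SyntheticDataset(**out)
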