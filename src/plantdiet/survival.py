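"""Cox proportional-hazards analyses of diet-index exposure.

Three nested covariate sets mirror the usual epidemiological adjustment
sequence: model 1 adjusts for urban/rural residence, age, sex and total
energy intake; model 2 adds education, physical activity (MET/day), smoking
and alcohol; model 3 adds baseline BMI (and, for dose-response and ROC
analyses, baseline SBP/DBP).  Exposure enters as exposure-quintile
indicators (Q1 reference), as a continuous per-1-SD z-score, as the
quintile-median "trend" variable, or as a restricted cubic spline.

Partial-likelihood maximisation is delegated to lifelines' CoxPHFitter
(Efron tie correction -- event times are wave years, so ties are heavy);
the surrounding contracts (reference normalisation, trend substitution,
spline basis and curve, time-interaction PH checks, stratified re-fits)
live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter
from lifelines.exceptions import ConvergenceError as LLConvergenceError

from .errors import ConvergenceError, SampleSizeError

MODEL_COVARIATES = {
    1: ["urban", "age", "sex", "total_energy"],
    2: ["urban", "age", "sex", "total_energy",
        "education", "met_per_day", "smoker", "drinker"],
    3: ["urban", "age", "sex", "total_energy",
        "education", "met_per_day", "smoker", "drinker", "bmi"],
}
CATEGORICAL = ("education",)

DURATION_COL = "follow_up_years"
EVENT_COL = "event"


def model_covariates(model: int, include_bp: bool = False) -> list[str]:
    """Covariate names for adjustment model 1, 2 or 3."""
    if model not in MODEL_COVARIATES:
        raise ValueError("model must be 1, 2 or 3")
    cov = list(MODEL_COVARIATES[model])
    if include_bp:
        cov += ["sbp", "dbp"]
    return cov


@dataclass
class CoxModelSpec:
    """What to fit: outcome, exposure form, adjustment set, strata, ties."""

    outcome: str
    exposure: str = "quintile"  # quintile | per_sd | trend | spline
    model: int = 3
    include_bp: bool = False
    strata: str | None = None  # None | "sex" | "age"
    tie_method: str = "efron"

    def __post_init__(self):
        if self.exposure not in ("quintile", "per_sd", "trend", "spline"):
            raise ValueError(f"unknown exposure form {self.exposure!r}")
        if self.tie_method != "efron":
            raise ValueError("only the Efron tie correction is implemented")
        if self.strata not in (None, "sex", "age"):
            raise ValueError("strata must be None, 'sex' or 'age'")

    @property
    def covariates(self) -> list[str]:
        return model_covariates(self.model, self.include_bp)


@dataclass
class CoxFit:
    """A fitted Cox model: coefficients, covariance and HR summaries."""

    summary: pd.DataFrame  # index: term; coef, se, hr, hr_lower, hr_upper, p
    covariance: pd.DataFrame
    n: int
    n_events: int
    log_likelihood: float
    dropped: list[str] = field(default_factory=list)
    model: CoxPHFitter | None = None

    def __getitem__(self, term: str) -> pd.Series:
        return self.summary.loc[term]


def _encode(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Expand categorical covariates into indicator columns."""
    out = pd.DataFrame(index=df.index)
    for c in covariates:
        if c in CATEGORICAL:
            d = pd.get_dummies(df[c].astype(int), prefix=c, drop_first=True)
            out = pd.concat([out, d.astype(float)], axis=1)
        else:
            out[c] = df[c].astype(float)
    return out


def _exposure_columns(df: pd.DataFrame, exposure: str,
                      quintile_medians: pd.Series | None = None,
                      spline_knots: np.ndarray | None = None) -> pd.DataFrame:
    if exposure == "quintile":
        q = df["quintile"].astype(int)
        out = pd.DataFrame({f"Q{k}": (q == k).astype(float) for k in range(2, 6)},
                           index=df.index)
        return out[[c for c in out if out[c].sum() > 0]]
    if exposure == "per_sd":
        return df[["index_z"]].astype(float)
    if exposure == "trend":
        if quintile_medians is None:
            raise ValueError("trend exposure requires quintile medians")
        med = df["quintile"].map(quintile_medians)
        if med.isna().any():
            raise ValueError("quintile level without a median score")
        return pd.DataFrame({"trend": med.astype(float)})
    if exposure == "spline":
        x = df["index_total"].to_numpy(dtype=float)
        basis = rcs_basis(x, spline_knots)
        out = pd.DataFrame(basis, index=df.index,
                           columns=[f"rcs{j}" for j in range(basis.shape[1])])
        return out
    raise ValueError(exposure)


def fit_cox(df: pd.DataFrame, covariates: list[str],
            exposure_df: pd.DataFrame | None = None,
            duration_col: str = DURATION_COL, event_col: str = EVENT_COL,
            ) -> CoxFit:
    """Fit a Cox PH model (Efron ties) of ``exposure_df`` + covariates.

    Constant columns carry no information and are dropped with a warning;
    fewer than two events is an error.
    """
    n_events = int(df[event_col].sum())
    if n_events < 2:
        raise SampleSizeError(f"need at least 2 events, got {n_events}")
    design = _encode(df, covariates)
    if exposure_df is not None:
        design = pd.concat([exposure_df.astype(float), design], axis=1)
    dropped = [c for c in design.columns if design[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant covariates: {dropped}",
                      RuntimeWarning, stacklevel=2)
        design = design.drop(columns=dropped)
    fit_df = design.copy()
    fit_df[duration_col] = df[duration_col].astype(float)
    fit_df[event_col] = df[event_col].astype(int)

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(fit_df, duration_col=duration_col, event_col=event_col,
                    fit_options={"precision": 1e-9})
    except LLConvergenceError as exc:  # pragma: no cover - diagnostic path
        raise ConvergenceError(f"Cox fit failed to converge: {exc}") from exc

    s = cph.summary
    summary = pd.DataFrame({
        "coef": s["coef"],
        "se": s["se(coef)"],
        "hr": s["exp(coef)"],
        "hr_lower": s["exp(coef) lower 95%"],
        "hr_upper": s["exp(coef) upper 95%"],
        "p": s["p"],
    })
    return CoxFit(summary=summary, covariance=cph.variance_matrix_,
                  n=len(df), n_events=n_events,
                  log_likelihood=float(cph.log_likelihood_),
                  dropped=dropped, model=cph)


# ---------------------------------------------------------------------------
# Quintile HRs, trend, per-SD
# ---------------------------------------------------------------------------
def hr_quintiles(fit: CoxFit) -> pd.DataFrame:
    """HR (95% CI) for Q2..Q5 vs the Q1 reference (HR identically 1)."""
    rows = {"Q1": {"hr": 1.0, "hr_lower": np.nan, "hr_upper": np.nan,
                   "p": np.nan}}
    for k in range(2, 6):
        term = f"Q{k}"
        if term in fit.summary.index:
            r = fit.summary.loc[term]
            rows[term] = {"hr": r["hr"], "hr_lower": r["hr_lower"],
                          "hr_upper": r["hr_upper"], "p": r["p"]}
        else:
            rows[term] = {"hr": np.nan, "hr_lower": np.nan,
                          "hr_upper": np.nan, "p": np.nan}
    return pd.DataFrame(rows).T


@dataclass
class TrendTestResult:
    coef: float
    se: float
    p: float
    quintile_medians: pd.Series


def trend_test(df: pd.DataFrame, quintile_medians: pd.Series,
               covariates: list[str]) -> TrendTestResult:
    """Linear-trend test: each participant carries their quintile's median
    index score as a continuous exposure; Wald p of that term is p-trend."""
    if pd.Series(quintile_medians).nunique() <= 1:
        raise ValueError("all quintile medians equal; trend undefined")
    expo = _exposure_columns(df, "trend", quintile_medians=quintile_medians)
    fit = fit_cox(df, covariates, expo)
    r = fit["trend"]
    return TrendTestResult(float(r["coef"]), float(r["se"]), float(r["p"]),
                           pd.Series(quintile_medians))


def hr_per_sd(df: pd.DataFrame, covariates: list[str]) -> pd.Series:
    """HR (95% CI) per 1-SD increase of the index z-score."""
    fit = fit_cox(df, covariates, _exposure_columns(df, "per_sd"))
    r = fit["index_z"]
    return pd.Series({"hr": r["hr"], "hr_lower": r["hr_lower"],
                      "hr_upper": r["hr_upper"], "p": r["p"],
                      "coef": r["coef"], "se": r["se"]})


# ---------------------------------------------------------------------------
# Restricted cubic splines
# ---------------------------------------------------------------------------
def harrell_knots(x: np.ndarray, n_knots: int = 4) -> np.ndarray:
    """Percentile knot placement (5/35/65/95 for 4 knots)."""
    quantiles = {3: (0.10, 0.50, 0.90),
                 4: (0.05, 0.35, 0.65, 0.95),
                 5: (0.05, 0.275, 0.50, 0.725, 0.95)}[n_knots]
    knots = np.quantile(np.asarray(x, dtype=float), quantiles)
    if len(np.unique(knots)) < n_knots:
        raise ValueError(
            "too few distinct index values for the requested knots; "
            "use fewer knots")
    return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted (natural) cubic spline basis: linear term + k-2 curvature
    terms, linear beyond the boundary knots (truncated power form)."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = len(t)
    scale = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        term = (np.clip(x - t[j], 0, None) ** 3
                - np.clip(x - t[k - 2], 0, None) ** 3
                * (t[-1] - t[j]) / (t[-1] - t[k - 2])
                + np.clip(x - t[-1], 0, None) ** 3
                * (t[k - 2] - t[j]) / (t[-1] - t[k - 2]))
        cols.append(term / scale)
    return np.column_stack(cols)


@dataclass
class SplineCurve:
    """Dose-response curve: HR vs index value relative to a reference."""

    knots: np.ndarray
    reference: float
    grid: pd.DataFrame  # columns: index_value, hr, hr_lower, hr_upper


def fit_rcs(df: pd.DataFrame, covariates: list[str], n_knots: int = 4,
            reference: float | None = None, n_grid: int = 101) -> SplineCurve:
    """Restricted-cubic-spline dose-response for the index total.

    Knots at Harrell percentiles; the curve is normalised to HR = 1 at the
    reference value (sample median by default) and carries pointwise Wald
    95% bands from the spline coefficients' covariance.
    """
    x = df["index_total"].to_numpy(dtype=float)
    knots = harrell_knots(x, n_knots)
    expo = _exposure_columns(df, "spline", spline_knots=knots)
    fit = fit_cox(df, covariates, expo)

    terms = [c for c in expo.columns if c in fit.summary.index]
    beta = fit.summary.loc[terms, "coef"].to_numpy()
    cov = fit.covariance.loc[terms, terms].to_numpy()

    if reference is None:
        reference = float(np.median(x))
    grid_x = np.union1d(np.linspace(x.min(), x.max(), n_grid), [reference])
    basis_g = rcs_basis(grid_x, knots)
    basis_r = rcs_basis(np.array([reference]), knots)
    kept = [int(c.replace("rcs", "")) for c in terms]
    contrast = basis_g[:, kept] - basis_r[:, kept]
    eta = contrast @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", contrast, cov, contrast))
    grid = pd.DataFrame({
        "index_value": grid_x,
        "hr": np.exp(eta),
        "hr_lower": np.exp(eta - 1.96 * se),
        "hr_upper": np.exp(eta + 1.96 * se),
    })
    return SplineCurve(knots=knots, reference=reference, grid=grid)


# ---------------------------------------------------------------------------
# Proportional-hazards check
# ---------------------------------------------------------------------------
def _episode_split(df: pd.DataFrame, terms: pd.DataFrame,
                   duration_col: str, event_col: str) -> pd.DataFrame:
    """Long format split at distinct event times for time-varying terms."""
    times = np.sort(df.loc[df[event_col].astype(bool), duration_col].unique())
    dur = df[duration_col].to_numpy(dtype=float)
    evt = df[event_col].to_numpy(dtype=bool)
    n = len(df)
    cuts = np.searchsorted(times, dur, side="left")  # event times < duration
    n_rows = cuts + 1
    ids = np.repeat(np.arange(n), n_rows)
    pos = np.arange(n_rows.sum()) - np.repeat(np.cumsum(n_rows) - n_rows, n_rows)
    start = np.where(pos == 0, 0.0, times[np.clip(pos - 1, 0, None)])
    last = pos == cuts[ids]
    stop = np.where(last, dur[ids], times[np.minimum(pos, len(times) - 1)])
    long = pd.DataFrame({"_id": ids, "start": start, "stop": stop,
                         "event": last & evt[ids]})
    return long.join(terms.reset_index(drop=True), on="_id")


def test_ph(df: pd.DataFrame, covariates: list[str],
            exposure_df: pd.DataFrame | None = None,
            duration_col: str = DURATION_COL, event_col: str = EVENT_COL,
            ) -> pd.Series:
    """Time-dependent-covariate PH check.

    Each term in turn is augmented with a term x log(time) interaction in a
    time-varying Cox model; the Wald p of the interaction is returned per
    term (small p flags a PH violation for that term).
    """
    if int(df[event_col].sum()) < 2:
        raise SampleSizeError("PH check needs at least 2 events")
    terms = _encode(df, covariates)
    if exposure_df is not None:
        terms = pd.concat([exposure_df.astype(float), terms], axis=1)
    terms = terms.loc[:, terms.nunique() > 1]
    long = _episode_split(df, terms, duration_col, event_col)
    pvals = {}
    for c in terms.columns:
        aug = long.copy()
        aug[f"{c}_x_logt"] = aug[c] * np.log(aug["stop"])
        ctv = CoxTimeVaryingFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ctv.fit(aug, id_col="_id", start_col="start", stop_col="stop",
                    event_col="event")
        pvals[c] = float(ctv.summary.loc[f"{c}_x_logt", "p"])
    return pd.Series(pvals, name="p_ph")


# ---------------------------------------------------------------------------
# Stratified analyses
# ---------------------------------------------------------------------------
def stratified_analysis(df: pd.DataFrame, quintile_medians: pd.Series,
                        covariates: list[str], strata: str = "age",
                        age_cut: float = 55.0) -> dict[str, dict]:
    """Quintile HRs and p-trend within sex or age strata.

    Exposure quintiles are NOT recomputed within strata: the categories fixed
    on the parent sample keep strata comparable.  Strata with fewer than two
    events are skipped with a warning.
    """
    if strata == "sex":
        groups = {"male": df["sex"] == 1, "female": df["sex"] == 0}
        cov = [c for c in covariates if c != "sex"]
    elif strata == "age":
        groups = {f"age<{age_cut:g}": df["age"] < age_cut,
                  f"age>={age_cut:g}": df["age"] >= age_cut}
        cov = covariates
    else:
        raise ValueError("strata must be 'sex' or 'age'")

    results: dict[str, dict] = {}
    for name, mask in groups.items():
        sub = df.loc[mask]
        if int(sub["event"].sum()) < 2:
            warnings.warn(f"stratum {name!r} has <2 events; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        fit = fit_cox(sub, cov, _exposure_columns(sub, "quintile"))
        trend = trend_test(sub, quintile_medians, cov)
        results[name] = {"n": len(sub), "n_events": int(sub["event"].sum()),
                         "quintile_hr": hr_quintiles(fit), "p_trend": trend.p}
    return results
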