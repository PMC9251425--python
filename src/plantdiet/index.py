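"""Plant-based diet index construction.

The overall plant-based diet index (PDI) and the healthful plant-based diet
index (hPDI) are built from per-participant food-group intakes in four steps:

1. each food group's intake (g/day) is adjusted for total energy intake with
   the residual method: intake is regressed on energy by OLS across the
   analysis sample and the adjusted value is the residual plus the predicted
   intake at the sample-mean energy (units and sample mean are preserved);
2. participants are ranked into quintiles of each adjusted group intake,
   with midranks for ties so equal intakes never straddle a quintile
   boundary (many groups are zero-inflated);
3. each quintile is converted to a 1-5 score: positively scored groups get
   score = quintile, negatively scored groups get score = 6 - quintile;
4. the 17 group scores are summed, giving a total in [17, 85], which is then
   itself divided into exposure quintiles (Q1..Q5) for analysis.

Under the PDI all plant groups are scored positively and animal groups
negatively; under the hPDI only healthy plant groups are positive while
less-healthy plant and animal groups are reverse-scored.

The scoring pipeline is exposed both as sklearn-style transformers
(:class:`ResidualEnergyAdjuster`, :class:`PlantDietIndexScorer`) and as thin
module-level functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import SampleSizeError
from .food_groups import ANIMAL, HEALTHY_PLANT, FoodGroupMap

POSITIVE = 1
NEGATIVE = -1

ENERGY_COL = "total_energy"


# ---------------------------------------------------------------------------
# Scoring schemes
# ---------------------------------------------------------------------------
@dataclass
class IndexScheme:
    """A named diet-index scoring scheme: per-group scoring direction."""

    name: str
    directions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        bad = {g: d for g, d in self.directions.items() if d not in (POSITIVE, NEGATIVE)}
        if bad:
            raise ValueError(f"directions must be +1 or -1, got {bad}")

    @classmethod
    def pdi(cls, food_group_map: FoodGroupMap | None = None) -> "IndexScheme":
        """All plant groups positive, animal groups negative."""
        fmap = food_group_map or FoodGroupMap.default()
        return cls("PDI", {
            g: (POSITIVE if c != ANIMAL else NEGATIVE)
            for g, c in fmap.groups.items()
        })

    @classmethod
    def hpdi(cls, food_group_map: FoodGroupMap | None = None) -> "IndexScheme":
        """Only healthy plant groups positive; everything else reverse-scored."""
        fmap = food_group_map or FoodGroupMap.default()
        return cls("hPDI", {
            g: (POSITIVE if c == HEALTHY_PLANT else NEGATIVE)
            for g, c in fmap.groups.items()
        })

    def flipped(self) -> "IndexScheme":
        return IndexScheme(f"{self.name}-flipped",
                           {g: -d for g, d in self.directions.items()})


def get_scheme(name: str, food_group_map: FoodGroupMap | None = None) -> IndexScheme:
    key = name.lower()
    if key == "pdi":
        return IndexScheme.pdi(food_group_map)
    if key == "hpdi":
        return IndexScheme.hpdi(food_group_map)
    raise ValueError(f"unknown index scheme {name!r}; use 'pdi' or 'hpdi'")


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------
def residual_energy_adjust(intakes, energy) -> np.ndarray:
    """Energy-adjust one food group's intakes with the residual method.

    OLS of intake on total energy across the sample; returns
    ``residual + prediction at mean(energy)``, i.e. ``intake - b*(E - mean(E))``.
    With zero energy variance the regression is degenerate: raw intakes are
    returned and a warning is emitted.
    """
    y = np.asarray(intakes, dtype=float)
    e = np.asarray(energy, dtype=float)
    if y.shape != e.shape:
        raise ValueError("intakes and energy must have equal length")
    if y.size < 3:
        raise SampleSizeError("residual adjustment needs at least 3 participants")
    e_centred = e - e.mean()
    var = np.dot(e_centred, e_centred)
    if var == 0.0:
        warnings.warn("zero energy variance; residual adjustment skipped",
                      RuntimeWarning, stacklevel=2)
        return y.copy()
    slope = np.dot(e_centred, y) / var
    return y - slope * e_centred


def _midrank_against(sorted_ref: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Midrank of each value within a sorted reference sample.

    For a value present in the reference this equals the usual midrank;
    unseen values fall between the flanking ranks.
    """
    lo = np.searchsorted(sorted_ref, values, side="left")
    hi = np.searchsorted(sorted_ref, values, side="right")
    return np.where(hi > lo, (lo + hi + 1) / 2.0, lo + 0.5)


def quintile_from_rank(ranks, n: int) -> np.ndarray:
    """Map (mid)ranks in a sample of size n to quintiles 1..5."""
    f = (np.asarray(ranks, dtype=float) - 0.5) / n
    return np.minimum(np.floor(5.0 * f).astype(int) + 1, 5)


def assign_quintiles(values) -> np.ndarray:
    """Rank a sample into quintiles 1..5 with midranks for ties.

    fractional rank f = (midrank - 0.5)/n; quintile = floor(5 f) + 1, clamped
    to 5.  Identical values always share a quintile.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise SampleSizeError(f"quintile assignment needs n >= 5, got {x.size}")
    return quintile_from_rank(rankdata(x, method="average"), x.size)


def score_group(quintile, direction) -> np.ndarray | int:
    """Convert a group quintile to its 1-5 score under a scoring direction."""
    q = np.asarray(quintile)
    if np.any((q < 1) | (q > 5)):
        raise ValueError("quintile must be in 1..5")
    if isinstance(direction, str):
        direction = POSITIVE if direction == "positive" else NEGATIVE
    if direction not in (POSITIVE, NEGATIVE):
        raise ValueError("direction must be 'positive'/'negative' or +-1")
    out = q if direction == POSITIVE else 6 - q
    return out if out.ndim else int(out)


# ---------------------------------------------------------------------------
# sklearn-style transformers
# ---------------------------------------------------------------------------
class ResidualEnergyAdjuster(TransformerMixin, BaseEstimator):
    """Residual-method energy adjustment for a table of group intakes.

    Fitting learns, for every intake column, the OLS slope on the energy
    column and the training-sample mean energy; transforming returns
    ``intake - slope_ * (energy - mean_energy_)`` so adjusted intakes keep
    their original units and (training) mean.
    """

    def __init__(self, energy_col: str = ENERGY_COL):
        self.energy_col = energy_col

    def fit(self, X: pd.DataFrame, y=None):
        if self.energy_col not in X.columns:
            raise ValueError(f"energy column {self.energy_col!r} not in X")
        if len(X) < 3:
            raise SampleSizeError("residual adjustment needs at least 3 participants")
        e = X[self.energy_col].to_numpy(dtype=float)
        self.mean_energy_ = float(e.mean())
        e_c = e - self.mean_energy_
        var = float(np.dot(e_c, e_c))
        self.degenerate_ = var == 0.0
        if self.degenerate_:
            warnings.warn("zero energy variance; residual adjustment skipped",
                          RuntimeWarning, stacklevel=2)
        cols = [c for c in X.columns if c != self.energy_col]
        self.intake_columns_ = cols
        if self.degenerate_:
            self.slopes_ = pd.Series(0.0, index=cols)
        else:
            mat = X[cols].to_numpy(dtype=float)
            self.slopes_ = pd.Series(e_c @ mat / var, index=cols)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "slopes_")
        e_c = X[self.energy_col].to_numpy(dtype=float) - self.mean_energy_
        out = X[self.intake_columns_].astype(float).copy()
        out -= np.outer(e_c, self.slopes_.to_numpy())
        return out


class PlantDietIndexScorer(TransformerMixin, BaseEstimator):
    """Compute a plant-based diet index for a sample of intake profiles.

    Parameters
    ----------
    scheme :
        ``"pdi"``, ``"hpdi"`` or an :class:`IndexScheme`.
    food_group_map :
        Taxonomy used to build named schemes; defaults to the 17-group map.
    adjust_energy :
        Apply residual-method energy adjustment before ranking (default).
    energy_col :
        Name of the total-energy column in the profile table.

    ``fit`` learns the energy regression, the per-group quintile ranking
    reference, and the index-total mean/SD and exposure-quintile reference
    from the training sample (the analysis sample).  ``transform`` returns a
    DataFrame with per-group scores, the index total, its z-score and the
    exposure quintile Q1..Q5.
    """

    def __init__(self, scheme="pdi", food_group_map: FoodGroupMap | None = None,
                 adjust_energy: bool = True, energy_col: str = ENERGY_COL):
        self.scheme = scheme
        self.food_group_map = food_group_map
        self.adjust_energy = adjust_energy
        self.energy_col = energy_col

    def _resolve_scheme(self) -> IndexScheme:
        if isinstance(self.scheme, IndexScheme):
            return self.scheme
        return get_scheme(self.scheme, self.food_group_map)

    def fit(self, X: pd.DataFrame, y=None):
        scheme = self._resolve_scheme()
        self.scheme_ = scheme
        missing = [g for g in scheme.directions if g not in X.columns]
        if missing:
            raise ValueError(f"profile table lacks food-group columns: {missing}")
        if len(X) < 5:
            raise SampleSizeError(f"index scoring needs n >= 5, got {len(X)}")
        self.n_ = len(X)

        cols = list(scheme.directions)
        if self.adjust_energy:
            self.adjuster_ = ResidualEnergyAdjuster(self.energy_col)
            adjusted = self.adjuster_.fit_transform(X[cols + [self.energy_col]])
        else:
            self.adjuster_ = None
            adjusted = X[cols].astype(float)
        # sorted per-group reference samples for midranking
        self.reference_ = {g: np.sort(adjusted[g].to_numpy()) for g in cols}

        totals = self._totals(adjusted)
        self.total_reference_ = np.sort(totals)
        self.total_mean_ = float(totals.mean())
        self.total_sd_ = float(totals.std(ddof=1))
        quint = quintile_from_rank(rankdata(totals, method="average"), len(totals))
        self.quintile_medians_ = pd.Series(
            {q: float(np.median(totals[quint == q])) for q in np.unique(quint)},
            name="median_total",
        )
        return self

    def _totals(self, adjusted: pd.DataFrame) -> np.ndarray:
        """Sum directional scores over groups for a table of adjusted intakes."""
        total = np.zeros(len(adjusted), dtype=int)
        for g, d in self.scheme_.directions.items():
            ranks = _midrank_against(self.reference_[g], adjusted[g].to_numpy())
            q = quintile_from_rank(ranks, self.n_)
            total += np.asarray(score_group(q, d))
        return total

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "reference_")
        scheme = self.scheme_
        cols = list(scheme.directions)
        if self.adjuster_ is not None:
            adjusted = self.adjuster_.transform(X[cols + [self.energy_col]])
        else:
            adjusted = X[cols].astype(float)

        out = pd.DataFrame(index=X.index)
        total = np.zeros(len(X), dtype=int)
        for g, d in scheme.directions.items():
            ranks = _midrank_against(self.reference_[g], adjusted[g].to_numpy())
            q = quintile_from_rank(ranks, self.n_)
            s = np.asarray(score_group(q, d))
            out[f"q_{g}"] = q
            out[f"score_{g}"] = s
            total += s
        out["total"] = total
        out["z"] = (total - self.total_mean_) / self.total_sd_ if self.total_sd_ > 0 \
            else np.zeros(len(X))
        ranks = _midrank_against(self.total_reference_, total.astype(float))
        out["quintile"] = quintile_from_rank(ranks, len(self.total_reference_))
        return out


# ---------------------------------------------------------------------------
# Functional API
# ---------------------------------------------------------------------------
def compute_index(profiles: pd.DataFrame, scheme="pdi",
                  food_group_map: FoodGroupMap | None = None,
                  adjust_energy: bool = True) -> pd.DataFrame:
    """Score every participant in ``profiles`` under ``scheme``.

    ``profiles`` holds one row per participant with the 17 food-group g/day
    columns plus ``total_energy``. Returns per-group quintiles/scores, the
    index ``total`` (range 17-85), its sample ``z`` score and the exposure
    ``quintile``.
    """
    scorer = PlantDietIndexScorer(scheme, food_group_map, adjust_energy)
    return scorer.fit(profiles).transform(profiles)


def index_quintiles(totals) -> tuple[np.ndarray, pd.Series]:
    """Exposure quintiles of index totals plus each quintile's median total."""
    totals = np.asarray(totals, dtype=float)
    quint = assign_quintiles(totals)
    medians = pd.Series({q: float(np.median(totals[quint == q]))
                         for q in np.unique(quint)}, name="median_total")
    return quint, medians
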