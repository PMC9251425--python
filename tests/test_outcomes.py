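import numpy as np
import pandas as pd
import pytest

from plantdiet import (build_analysis_sample, classify_hypertension,
                       classify_overweight, classify_t2d, compute_bmi,
                       compute_follow_up, person_years)
from plantdiet.errors import ChronologyError
from plantdiet.food_groups import DEFAULT_GROUPS
from plantdiet.outcomes import BASELINE_COLUMNS, OUTCOMES, WAVE_COLUMNS


# ---------------------------------------------------------------------------
# fixture builders
# ---------------------------------------------------------------------------
def make_baseline(n, **overrides):
    base = pd.DataFrame({
        "participant_id": np.arange(1, n + 1),
        "baseline_year": 2004, "age": 45.0, "sex": 1, "urban": 0,
        "education": 1, "met_per_day": 150.0, "smoker": 0, "drinker": 0,
        "height_m": 1.60, "weight_kg": 56.3,  # BMI 22.0
        "sbp": 118.0, "dbp": 76.0, "self_report_htn": 0, "on_bp_medication": 0,
        "self_report_t2d": 0, "on_glucose_medication": 0, "cvd_or_cancer": 0,
    })
    for col, values in overrides.items():
        base[col] = values
    return base[BASELINE_COLUMNS]


def make_recalls(pids, kcal):
    rows = []
    for pid, e in zip(pids, kcal):
        for day in (1, 2, 3):
            for j, g in enumerate(DEFAULT_GROUPS):
                rows.append((pid, 2004, day, g, 50.0 + 10.0 * j + pid, e))
    return pd.DataFrame(rows, columns=["participant_id", "year", "day",
                                       "group_id", "grams", "kcal"])


def make_wave(pid, wave_year, bmi=22.0, sbp=118.0, dbp=76.0, fpg=5.0,
              hba1c=5.3, rep_htn=0, med_htn=0, rep_t2d=0, med_t2d=0,
              height=1.60, missing_anthro=False):
    row = {"participant_id": pid, "wave_year": wave_year,
           "weight_kg": np.nan if missing_anthro else round(bmi * height ** 2, 1),
           "height_m": np.nan if missing_anthro else height,
           "sbp": sbp, "dbp": dbp, "fpg": fpg, "hba1c": hba1c,
           "self_report_htn": rep_htn, "on_bp_medication": med_htn,
           "self_report_t2d": rep_t2d, "on_glucose_medication": med_t2d}
    return row


# ---------------------------------------------------------------------------
# classification primitives
# ---------------------------------------------------------------------------
class TestClassification:
    def test_bmi_arithmetic_and_threshold(self):
        assert compute_bmi(76.8, 1.60) == pytest.approx(30.0)
        assert classify_overweight(24.0) is True
        assert classify_overweight(23.9) is False
        with pytest.raises(ValueError):
            compute_bmi(-70.0, 1.6)

    @pytest.mark.parametrize("sbp,dbp,rep,med,expected", [
        (140.0, 80.0, 0, 0, True),   # SBP at threshold
        (120.0, 70.0, 1, 0, True),   # self-report alone
        (120.0, 70.0, 0, 1, True),   # medication counts as disease
        (139.0, 89.0, 0, 0, False),  # just below both thresholds
        (100.0, 90.0, 0, 0, True),   # DBP at threshold
    ])
    def test_hypertension_criteria(self, sbp, dbp, rep, med, expected):
        assert classify_hypertension(sbp, dbp, rep, med) is expected

    def test_hypertension_all_missing_is_undeterminable(self):
        assert classify_hypertension(np.nan, np.nan, None, None) is None

    @pytest.mark.parametrize("year,fpg,hba1c,rep,expected", [
        (2009, 7.0, np.nan, 0, True),    # FPG at threshold
        (2009, 6.0, 6.5, 0, True),       # HbA1c at threshold
        (2009, 6.0, 6.0, 0, False),
        (2015, 8.0, np.nan, 0, False),   # biomarkers ignored at 2015
        (2015, np.nan, np.nan, 1, True),  # self-report rule at 2015
    ])
    def test_t2d_wave_specific_rules(self, year, fpg, hba1c, rep, expected):
        assert classify_t2d(year, fpg, hba1c, rep, 0) is expected

    def test_classification_monotone_in_biomarkers(self):
        rng = np.random.default_rng(0)
        sbp = rng.uniform(100, 180, 200)
        dbp = rng.uniform(60, 110, 200)
        before = classify_hypertension(sbp, dbp, np.zeros(200), np.zeros(200))
        after = classify_hypertension(sbp + 15.0, dbp, np.zeros(200), np.zeros(200))
        assert np.all(after >= before)


# ---------------------------------------------------------------------------
# follow-up accounting
# ---------------------------------------------------------------------------
class TestFollowUp:
    def test_event_and_censor_arithmetic(self):
        assert compute_follow_up(2004, event_wave_year=2009) == 5.0
        assert compute_follow_up(2006, censor_wave_year=2015) == 9.0

    def test_additivity(self):
        sample = pd.DataFrame({"follow_up_years": [5.0, 9.0]})
        assert person_years(sample) == 14.0

    def test_event_before_baseline_rejected(self):
        with pytest.raises(ChronologyError):
            compute_follow_up(2006, event_wave_year=2004)


# ---------------------------------------------------------------------------
# exclusion flow
# ---------------------------------------------------------------------------
class TestExclusionFlow:
    def test_five_row_fixture_ledger(self):
        """Manual enumeration: one energy exclusion, one prevalent case,
        one all-waves-missing, two clean participants retained."""
        baseline = make_baseline(5)
        baseline.loc[1, "weight_kg"] = 64.0  # BMI 25: prevalent overweight
        recalls = make_recalls([1, 2, 3, 4, 5],
                               [400.0, 2000.0, 2100.0, 2200.0, 2300.0])
        waves = pd.DataFrame([
            make_wave(2, 2009), make_wave(3, 2009, missing_anthro=True),
            make_wave(4, 2009, bmi=26.0),          # incident event at 2009
            make_wave(5, 2015, bmi=22.0),          # censored at 2015
        ])[WAVE_COLUMNS]
        with pytest.warns(RuntimeWarning, match="n=2"):
            sample = build_analysis_sample(baseline, recalls, waves,
                                           "overweight_obesity")
        assert sample.ledger == {"input": 5, "missing_diet": 0, "energy": 1,
                                 "prevalent_cvd_cancer": 0,
                                 "lost_to_followup": 0, "prevalent_outcome": 1,
                                 "missing_outcome": 1, "retained": 2}
        assert sample.n == 2
        d = sample.data
        assert bool(d.loc[4, "event"]) and d.loc[4, "follow_up_years"] == 5.0
        assert not bool(d.loc[5, "event"]) and d.loc[5, "follow_up_years"] == 11.0

    def test_prevalent_case_excluded_per_outcome_not_globally(self):
        baseline = make_baseline(7)
        baseline.loc[0, "sbp"] = 150.0  # participant 1 hypertensive at baseline
        recalls = make_recalls(range(1, 8), [2000.0] * 7)
        waves = pd.DataFrame([make_wave(pid, 2009) for pid in range(1, 8)]
                             )[WAVE_COLUMNS]
        htn = build_analysis_sample(baseline, recalls, waves, "hypertension")
        t2d = build_analysis_sample(baseline, recalls, waves, "t2d")
        assert 1 not in htn.data.index
        assert 1 in t2d.data.index
        assert htn.ledger["prevalent_outcome"] == 1
        assert t2d.ledger["prevalent_outcome"] == 0

    def test_empty_input_gives_empty_sample_with_zero_ledger(self):
        baseline = make_baseline(5)
        recalls = make_recalls(range(1, 6), [2000.0] * 5)
        waves = pd.DataFrame([], columns=WAVE_COLUMNS)
        with pytest.warns(RuntimeWarning):
            sample = build_analysis_sample(baseline, recalls, waves, "t2d")
        assert sample.n == 0
        assert sample.ledger["lost_to_followup"] == 5

    def test_ledger_conservation_on_synthetic_cohort(self, small_dataset):
        for outcome in OUTCOMES:
            s = build_analysis_sample(small_dataset.baseline,
                                      small_dataset.recalls,
                                      small_dataset.waves, outcome)
            excluded = sum(v for k, v in s.ledger.items()
                           if k not in ("input", "retained"))
            assert excluded + s.ledger["retained"] == s.ledger["input"]
            assert s.ledger["retained"] == s.n

    def test_row_order_invariance(self, small_dataset):
        s1 = build_analysis_sample(small_dataset.baseline,
                                   small_dataset.recalls,
                                   small_dataset.waves, "hypertension")
        shuffled = small_dataset.baseline.sample(frac=1.0, random_state=9)
        s2 = build_analysis_sample(shuffled, small_dataset.recalls,
                                   small_dataset.waves, "hypertension")
        pd.testing.assert_frame_equal(s1.data.sort_index(),
                                      s2.data.sort_index())
        assert s1.ledger == s2.ledger
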