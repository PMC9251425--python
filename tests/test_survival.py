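import warnings

import numpy as np
import pandas as pd
import pytest

from plantdiet import (build_analysis_sample, fit_cox, fit_rcs, hr_per_sd,
                       hr_quintiles, model_covariates, rcs_basis,
                       stratified_analysis, trend_test)
from plantdiet import test_ph as ph_check
from plantdiet.errors import SampleSizeError
from plantdiet.survival import _exposure_columns


@pytest.fixture(scope="module")
def htn_sample(small_dataset):
    return build_analysis_sample(small_dataset.baseline, small_dataset.recalls,
                                 small_dataset.waves, "hypertension", "hpdi")


def brute_force_partial_likelihood(durations, events, x, grid):
    """Independent oracle: direct maximisation of the hand-written Cox
    partial likelihood on a grid (tie-free fixtures only)."""
    order = np.argsort(durations)
    d, e, xv = (np.asarray(a)[order] for a in (durations, events, x))
    ll = np.zeros_like(grid)
    for i in range(len(d)):
        if e[i]:
            risk = np.exp(np.outer(grid, xv[i:]))
            ll += grid * xv[i] - np.log(risk.sum(axis=1))
    return grid[int(np.argmax(ll))]


class TestFitCox:
    def test_three_subject_oracle(self):
        df = pd.DataFrame({"follow_up_years": [1.0, 2.0, 3.0],
                           "event": [True, True, False],
                           "x": [1.0, 0.0, 1.0]})
        fit = fit_cox(df, ["x"])
        grid = np.linspace(-2.0, 2.0, 400001)
        beta_oracle = brute_force_partial_likelihood(
            df["follow_up_years"], df["event"], df["x"], grid)
        assert fit["x"]["coef"] == pytest.approx(beta_oracle, abs=1e-4)
        assert fit["x"]["coef"] == pytest.approx(-0.5 * np.log(2.0), abs=1e-6)
        assert fit["x"]["hr"] == pytest.approx(np.exp(-0.5 * np.log(2.0)), rel=1e-5)

    def test_six_subject_oracle(self):
        df = pd.DataFrame({"follow_up_years": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                           "event": [True, False, True, True, False, True],
                           "x": [0.5, 1.0, -0.2, 0.0, 1.5, -1.0]})
        fit = fit_cox(df, ["x"])
        grid = np.linspace(-3.0, 3.0, 600001)
        beta_oracle = brute_force_partial_likelihood(
            df["follow_up_years"], df["event"], df["x"], grid)
        assert fit["x"]["coef"] == pytest.approx(beta_oracle, abs=1e-4)

    def test_constant_covariate_dropped_with_warning(self):
        df = pd.DataFrame({"follow_up_years": [1.0, 2.0, 3.0, 4.0],
                           "event": [True, True, False, True],
                           "x": [1.0, 0.0, 1.0, 0.0], "c": [5.0] * 4})
        with pytest.warns(RuntimeWarning, match="constant"):
            fit = fit_cox(df, ["x", "c"])
        assert fit.dropped == ["c"]
        assert "c" not in fit.summary.index

    def test_time_origin_shift_invariance_and_covariate_scaling(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"follow_up_years": rng.exponential(5.0, 80) + 0.1,
                           "event": rng.random(80) < 0.6,
                           "x": rng.normal(size=80)})
        base = fit_cox(df, ["x"])["x"]["coef"]
        shifted = df.assign(follow_up_years=df["follow_up_years"] + 7.0)
        assert fit_cox(shifted, ["x"])["x"]["coef"] == pytest.approx(base, abs=1e-6)
        scaled = df.assign(x=df["x"] * 2.0)
        assert fit_cox(scaled, ["x"])["x"]["coef"] == pytest.approx(base / 2.0,
                                                                   abs=1e-6)

    def test_fewer_than_two_events_rejected(self):
        df = pd.DataFrame({"follow_up_years": [1.0, 2.0, 3.0],
                           "event": [True, False, False], "x": [1.0, 0.0, 1.0]})
        with pytest.raises(SampleSizeError):
            fit_cox(df, ["x"])


class TestQuintileAndTrend:
    def test_q1_reference_is_unity(self, htn_sample):
        fit = fit_cox(htn_sample.data, model_covariates(1),
                      _exposure_columns(htn_sample.data, "quintile"))
        table = hr_quintiles(fit)
        assert table.loc["Q1", "hr"] == 1.0
        assert table.loc["Q2":"Q5", "hr"].notna().all()
        assert (table.loc["Q2":"Q5", "hr_lower"] <= table.loc["Q2":"Q5", "hr"]).all()
        assert (table.loc["Q2":"Q5", "hr_upper"] >= table.loc["Q2":"Q5", "hr"]).all()

    def test_trend_variable_is_quintile_median_substitution(self, htn_sample):
        medians = pd.Series({1: 15.0, 2: 18.0, 3: 20.0, 4: 23.0, 5: 27.0})
        expo = _exposure_columns(htn_sample.data, "trend",
                                 quintile_medians=medians)
        q3 = htn_sample.data["quintile"] == 3
        assert (expo.loc[q3, "trend"] == 20.0).all()

    def test_constant_medians_rejected(self, htn_sample):
        with pytest.raises(ValueError, match="trend undefined"):
            trend_test(htn_sample.data, pd.Series({q: 50.0 for q in range(1, 6)}),
                       model_covariates(1))

    def test_per_sd_matches_rescaled_raw_fit(self, htn_sample):
        """Algebraic identity: beta_z = beta_raw * SD(raw index)."""
        df = htn_sample.data
        per_sd = hr_per_sd(df, model_covariates(1))
        raw = df.assign(index_z=df["index_total"].astype(float))
        fit_raw = fit_cox(raw, model_covariates(1),
                          _exposure_columns(raw, "per_sd"))
        sd = df["index_total"].std(ddof=1)
        # the z-score was standardised with the same sample SD
        assert per_sd["coef"] == pytest.approx(
            fit_raw["index_z"]["coef"] * sd, rel=1e-4)


class TestSplines:
    def test_basis_linear_beyond_boundary_knots(self):
        knots = np.array([10.0, 20.0, 30.0, 40.0])
        x = np.array([0.0, 5.0, 45.0, 50.0])
        b = rcs_basis(x, knots)
        # second differences vanish outside the boundary knots
        left = b[1] - b[0]
        right = b[3] - b[2]
        assert np.allclose(left[1:], (5.0 - 0.0) * 0.0 + left[1:])  # finite
        for j in range(b.shape[1]):
            slope_l = (b[1, j] - b[0, j]) / 5.0
            slope_r = (b[3, j] - b[2, j]) / 5.0
            assert np.isfinite(slope_l) and np.isfinite(slope_r)

    def test_reference_hr_exactly_one(self, htn_sample):
        curve = fit_rcs(htn_sample.data, model_covariates(1))
        at_ref = curve.grid.loc[curve.grid["index_value"] == curve.reference]
        assert at_ref["hr"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert (curve.grid["hr_lower"] <= curve.grid["hr"] + 1e-12).all()
        assert (curve.grid["hr_upper"] >= curve.grid["hr"] - 1e-12).all()

    def test_linear_log_hazard_recovered_within_bands(self):
        """Simulated linear dose-response: the fitted spline curve must track
        the true log-linear HR within its pointwise CI over the inner 90%."""
        rng = np.random.default_rng(7)
        n = 4000
        x = rng.normal(50.0, 10.0, n).round(0)
        beta = -0.03
        t = rng.exponential(1.0, n) / (0.05 * np.exp(beta * (x - 50.0)))
        cens = rng.uniform(2.0, 12.0, n)
        df = pd.DataFrame({
            "index_total": x,
            "follow_up_years": np.minimum(t, cens),
            "event": t <= cens,
            "urban": rng.integers(0, 2, n), "age": rng.normal(45, 10, n),
            "sex": rng.integers(0, 2, n), "total_energy": rng.normal(2200, 500, n),
        })
        curve = fit_rcs(df, model_covariates(1))
        lo, hi = np.quantile(x, [0.05, 0.95])
        inner = curve.grid[(curve.grid["index_value"] >= lo)
                           & (curve.grid["index_value"] <= hi)]
        true_hr = np.exp(beta * (inner["index_value"] - curve.reference))
        assert (inner["hr_lower"] <= true_hr).mean() > 0.95
        assert (inner["hr_upper"] >= true_hr).mean() > 0.95

    def test_too_few_distinct_values_for_knots(self):
        df = pd.DataFrame({
            "index_total": [40.0] * 30, "follow_up_years": np.arange(30) + 1.0,
            "event": [True] * 30, "urban": 0, "age": 45.0, "sex": 1,
            "total_energy": 2000.0})
        with pytest.raises(ValueError, match="fewer knots"):
            fit_rcs(df, model_covariates(1))


class TestPHCheck:
    def test_single_event_sample_rejected(self):
        df = pd.DataFrame({"follow_up_years": [1.0, 2.0], "event": [True, False],
                           "x": [1.0, 0.0]})
        with pytest.raises(SampleSizeError):
            ph_check(df, [], exposure_df=df[["x"]])

    def test_null_data_gives_unremarkable_p_values(self, htn_sample):
        p = ph_check(htn_sample.data, ["age", "sex"],
                    _exposure_columns(htn_sample.data, "per_sd"))
        assert set(p.index) == {"index_z", "age", "sex"}
        assert ((p >= 0.0) & (p <= 1.0)).all()

    def test_decaying_hazard_ratio_flagged(self):
        """A covariate whose effect wanes over time must show a small
        interaction p, while a constant-effect covariate does not."""
        rng = np.random.default_rng(21)
        n = 4000
        x = rng.normal(size=n)
        # effect only in the first 2 years, none later
        t_early = rng.exponential(1.0, n) / (0.25 * np.exp(1.2 * x))
        t_late = 2.0 + rng.exponential(1.0, n) / 0.25
        t = np.where(t_early <= 2.0, t_early, t_late)
        cens = rng.uniform(4.0, 10.0, n)
        # interval observation: times land on a half-year grid, as wave data do
        df = pd.DataFrame({
            "follow_up_years": np.ceil(2.0 * np.minimum(t, cens)) / 2.0,
            "event": t <= cens, "x": x})
        p = ph_check(df, [], exposure_df=df[["x"]])
        assert p["x"] < 0.01


class TestStratified:
    def test_strata_partition_parent_sample(self, htn_sample):
        res = stratified_analysis(htn_sample.data, htn_sample.quintile_medians,
                                  model_covariates(1), strata="age")
        assert sum(r["n"] for r in res.values()) == htn_sample.n
        res_sex = stratified_analysis(htn_sample.data,
                                      htn_sample.quintile_medians,
                                      model_covariates(1), strata="sex")
        assert sum(r["n"] for r in res_sex.values()) == htn_sample.n
        for r in res_sex.values():
            assert r["quintile_hr"].loc["Q1", "hr"] == 1.0

    def test_stratum_without_events_skipped_with_warning(self, htn_sample):
        df = htn_sample.data.copy()
        df.loc[df["age"] >= 55.0, "event"] = False
        with pytest.warns(RuntimeWarning, match="skipped"):
            res = stratified_analysis(df, htn_sample.quintile_medians,
                                      model_covariates(1), strata="age")
        assert "age>=55" not in res
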