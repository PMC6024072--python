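"""Exposure models: design exclusions, GEE fitting, percent-change transform."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from campm import (ModelSpec, TrueParameters, build_design, fit_gamma_repeated,
                   fit_hourly_selfreport, percent_change)
from campm.models import build_hourly_design
from campm.simulate import simulate_hourly, simulate_intervals


class TestPercentChange:
    def test_zero_beta_is_zero_percent(self):
        pct, lo, hi = percent_change(0.0, 0.0)
        assert pct == 0.0 and lo == 0.0 and hi == 0.0

    def test_log_two_is_plus_100(self):
        pct, _, _ = percent_change(math.log(2), 0.1)
        assert pct == pytest.approx(100.0)

    def test_negative_beta_closed_form_degenerate_ci(self):
        pct, lo, hi = percent_change(-0.5, 0.0)
        assert pct == pytest.approx((math.exp(-0.5) - 1) * 100, abs=1e-9)
        assert pct == pytest.approx(-39.3469, abs=1e-3)
        assert lo == pct and hi == pct

    def test_strictly_monotone_in_beta(self):
        grid = np.linspace(-2, 2, 41)
        vals = [percent_change(b, 0.0)[0] for b in grid]
        assert np.all(np.diff(vals) > 0)

    def test_ci_brackets_point(self):
        pct, lo, hi = percent_change(0.66, 0.09)
        assert lo < pct < hi
        # asymmetry of the transformed interval: upper arm is wider
        assert (hi - pct) > (pct - lo)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.1, -0.01)


class TestBuildDesign:
    def _intervals(self):
        rng = np.random.default_rng(0)
        n = 50
        df = pd.DataFrame({
            "participant_day": "P1_S1",
            "interval_index": np.arange(n),
            "pm_mean_5min": rng.gamma(10, 4, n),
            "kitchen": rng.random(n).round(),
            "smoking": rng.random(n).round(),
            "indoors": 1.0,
            "road": 0.0,
        })
        return df

    def test_infrequent_concept_dropped_with_reason(self):
        counts = {"kitchen": 500, "smoking": 99, "indoors": 500, "road": 500}
        design, excl = build_design(self._intervals(), counts)
        reasons = {e["concept"]: e["reason"] for e in excl}
        assert reasons["smoking"] == "infrequent"
        assert "smoking" not in design.columns

    def test_location_concepts_dropped_for_collinearity(self):
        counts = {"kitchen": 500, "smoking": 500, "indoors": 500, "road": 500}
        design, excl = build_design(self._intervals(), counts)
        reasons = {e["concept"]: e["reason"] for e in excl}
        assert reasons["indoors"] == "location/collinearity"

    def test_zero_threshold_and_no_location_excludes_nothing_present(self):
        counts = {"kitchen": 1, "smoking": 1, "indoors": 1, "road": 1}
        design, excl = build_design(self._intervals(), counts, photo_threshold=0,
                                    location_concepts=())
        kept = [c for c in ("kitchen", "smoking", "indoors") if c in design.columns]
        assert kept == ["kitchen", "smoking", "indoors"]
        # 'road' never occurs in the intervals, so it still goes
        assert {e["concept"] for e in excl} == {"road"}

    def test_all_excluded_raises(self):
        counts = {"kitchen": 0, "smoking": 0, "indoors": 0, "road": 0}
        with pytest.raises(ValueError, match="excluded"):
            build_design(self._intervals(), counts)


class TestFitGammaRepeated:
    def test_intercept_only_equals_log_mean(self):
        """Closed form: intercept-only Gamma/log fit is log of the sample mean."""
        rng = np.random.default_rng(1)
        n = 10_000
        y = rng.gamma(4.0, 10.0, n)
        df = pd.DataFrame({
            "participant_day": np.repeat([f"d{i}" for i in range(10)], n // 10),
            "interval_index": np.tile(np.arange(n // 10), 10),
            "pm_mean_5min": y,
        })
        res = fit_gamma_repeated(df, ModelSpec(predictors=(),
                                               correlation="independence"))
        assert res.exp_alpha == pytest.approx(y.mean(), rel=1e-4)
        assert res.exp_alpha == pytest.approx(40.0, rel=0.01)

    def test_reduction_to_independence_glm(self):
        """With sigma_u = rho = 0 the fit coincides with a plain Gamma GLM."""
        params = TrueParameters(
            beta={"kitchen": math.log(1.4), "smoking": math.log(1.8)},
            sigma_u=0.0, rho=0.0, sigma_eps=0.0, gamma_shape=8.0)
        df = simulate_intervals(15, 2, params, seed=3)
        predictors = ("kitchen", "smoking", "biomass_cooking_unit")
        res = fit_gamma_repeated(df, ModelSpec(predictors=predictors,
                                               correlation="independence"))
        X = sm.add_constant(df[list(predictors)].to_numpy())
        glm = sm.GLM(df["pm_mean_5min"].to_numpy(), X,
                     family=sm.families.Gamma(link=sm.families.links.Log())).fit()
        mine = np.r_[res.alpha_hat, res.terms["beta"].to_numpy()]
        assert np.max(np.abs(mine - glm.params)) < 1e-6

    def test_ar1_structure_estimated_near_truth(self, recovery_params):
        df = simulate_intervals(40, 4, recovery_params, seed=19)
        res = fit_gamma_repeated(df, ModelSpec(
            predictors=("biomass_cooking_unit", "smoking", "kitchen")))
        assert res.rho_hat == pytest.approx(0.5, abs=0.1)
        assert res.sigma_u_hat == pytest.approx(0.3, abs=0.1)
        assert res.converged and "ar1" in res.algorithm or "exchangeable" in res.algorithm

    def test_fixed_zero_correlation_matches_independence(self, recovery_params):
        df = simulate_intervals(8, 2, recovery_params, seed=23)
        spec_fix = ModelSpec(predictors=("kitchen",), correlation="ar1",
                             fixed_corr={"tau": 0.0, "psi": 0.0, "rho": 0.0})
        spec_ind = ModelSpec(predictors=("kitchen",), correlation="independence")
        a = fit_gamma_repeated(df, spec_fix)
        b = fit_gamma_repeated(df, spec_ind)
        assert a.alpha_hat == pytest.approx(b.alpha_hat, abs=1e-8)
        assert a.terms["beta"].iloc[0] == pytest.approx(b.terms["beta"].iloc[0], abs=1e-8)

    def test_nonpositive_response_names_rows(self, recovery_params):
        df = simulate_intervals(3, 2, recovery_params, seed=4)
        df.loc[7, "pm_mean_5min"] = 0.0
        with pytest.raises(ValueError, match="non-positive response"):
            fit_gamma_repeated(df, ModelSpec(predictors=("kitchen",)))

    def test_too_few_clusters_rejected(self, recovery_params):
        df = simulate_intervals(1, 1, recovery_params, seed=5)
        with pytest.raises(ValueError, match="participant-days"):
            fit_gamma_repeated(df, ModelSpec(predictors=("kitchen",)))


class TestHourlyModel:
    def test_split_rule_weights_half(self):
        diary = pd.DataFrame({
            "participant_id": ["P1", "P1"],
            "participant_day": ["P1_S1", "P1_S1"],
            "hour": [0, 1],
            "pm_hourly": [30.0, 40.0],
            "activity1": ["sleeping", "cooking"],
            "activity2": ["", "sedentary"],
        })
        design, non_ref = build_hourly_design(diary)
        row = design.loc[design["hour"] == 1].iloc[0]
        assert row["cooking"] == pytest.approx(0.5)
        assert row["sedentary"] == pytest.approx(0.5)

    def test_duplicate_row_encoding(self):
        diary = pd.DataFrame({
            "participant_id": ["P1"], "participant_day": ["P1_S1"], "hour": [1],
            "pm_hourly": [40.0],
            "activity1": ["cooking"], "activity2": ["sedentary"],
        })
        with pytest.raises(ValueError, match="reference activity"):
            build_hourly_design(diary, encoding="duplicate")
        diary2 = pd.concat([diary, diary.assign(hour=2, activity1="sleeping",
                                                activity2="")], ignore_index=True)
        design, _ = build_hourly_design(diary2, encoding="duplicate")
        assert len(design) == 3  # the two-activity hour appears twice

    def test_all_sleeping_reduces_to_intercept_model(self):
        rng = np.random.default_rng(6)
        n_days, n_h = 12, 24
        rows = []
        for d in range(n_days):
            for h in range(n_h):
                rows.append({"participant_id": f"P{d % 4}",
                             "participant_day": f"P{d % 4}_S{d}",
                             "hour": h, "pm_hourly": rng.gamma(8.0, 5.0),
                             "activity1": "sleeping", "activity2": ""})
        diary = pd.DataFrame(rows)
        diary.loc[0, "activity2"] = "cooking"  # one non-reference indicator
        res = fit_hourly_selfreport(diary)
        assert res.exp_alpha == pytest.approx(diary["pm_hourly"].mean(), rel=0.02)

    def test_known_activity_effect_recovered(self):
        effects = {"cooking": math.log(1.4), "working": math.log(1.1),
                   "travel": 0.0, "sedentary": 0.0, "household_chores": 0.0}
        df = simulate_hourly(40, 4, effects, seed=31)
        res = fit_hourly_selfreport(df)
        b = res.term("cooking")
        assert b["beta"] == pytest.approx(math.log(1.4), abs=0.1)
        assert b["ci_low"] < (1.4 - 1) * 100 < b["ci_high"]

    def test_missing_reference_activity_raises(self):
        diary = pd.DataFrame({
            "participant_id": ["P1"], "participant_day": ["P1_S1"], "hour": [1],
            "pm_hourly": [40.0], "activity1": ["cooking"], "activity2": [""],
        })
        with pytest.raises(ValueError, match="sleeping"):
            fit_hourly_selfreport(diary)
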