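"""Generator correctness: schedules, the PM process, rendering, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from campm import ArtifactSpec, TrueParameters
from campm.simulate import (DayInfo, render_observed, simulate_intervals,
                            simulate_pm, simulate_schedule, simulate_study)


def single_state_params(dwell=math.inf, overlays_off=True, **kw):
    sched = {"female": {"dwell": {"kitchen": dwell}, "weight": {"kitchen": 1.0}}}
    ov = {"female": {"rate": {c: 0.0 for c in
                              ("smoking", "lpg_stove", "biomass_cooking_unit",
                               "visible_flame_smoke", "food_preparation", "eating")},
                     "duration": {c: 5.0 for c in
                                  ("smoking", "lpg_stove", "biomass_cooking_unit",
                                   "visible_flame_smoke", "food_preparation", "eating")}}}
    return TrueParameters(schedule_rates=sched, overlay_rates=ov, **kw)


class TestSchedule:
    def test_zero_overlay_rates_only_base_concepts(self, small_config):
        params = TrueParameters()
        for sex_cfg in params.overlay_rates.values():
            sex_cfg["rate"] = {k: 0.0 for k in sex_cfg["rate"]}
        res = simulate_schedule(small_config, params, "P1_S1", sex="male")
        overlays = ["smoking", "lpg_stove", "biomass_cooking_unit",
                    "visible_flame_smoke", "food_preparation", "eating"]
        assert not res.timeline[overlays].any().any()
        assert res.timeline["kitchen"].any() or res.timeline["road"].any() \
            or res.timeline["indoors"].any()

    def test_infinite_dwell_single_state(self, small_config):
        params = single_state_params()
        res = simulate_schedule(small_config, params, "P1_S1", apply_night=False)
        assert res.timeline["kitchen"].all()
        assert res.n_completed_dwells == 0

    def test_renewal_expectation(self, small_config):
        """Mean dwell 30 min over 12 h: E[completed dwells] = 720/30 = 24."""
        params = single_state_params(dwell=30.0)
        counts = []
        for i in range(500):
            res = simulate_schedule(small_config, params, f"P1_S{i}",
                                    duration_min=720, apply_night=False)
            counts.append(res.n_completed_dwells)
        mean = np.mean(counts)
        mc_err = 3 * np.std(counts) / math.sqrt(len(counts))
        assert mean == pytest.approx(24.0, abs=max(mc_err, 0.7))

    def test_unknown_concept_rejected(self, small_config):
        params = TrueParameters()
        params.overlay_rates["female"]["rate"]["not_a_concept"] = 1.0
        params.overlay_rates["female"]["duration"]["not_a_concept"] = 5.0
        with pytest.raises(ValueError, match="unknown overlay concept"):
            simulate_schedule(small_config, params, "P1_S1", sex="female")

    def test_night_hours_forced_indoors(self, small_config):
        res = simulate_schedule(small_config, TrueParameters(), "P2_S1", sex="male")
        tl = res.timeline
        clock = (small_config.session_start_hour + tl.index / 60.0) % 24
        night = (clock >= 22) | (clock < 6)
        assert (tl.loc[night, "base_state"] == "indoors_other").all()


class TestPmProcess:
    def _flat_timeline(self, n_min, config, params):
        return simulate_schedule(config, params, "X", apply_night=False,
                                 duration_min=n_min).timeline

    def test_closed_form_marginal_mean(self, small_config):
        """beta=0, sigma_u=0, rho=0: mean = exp(alpha) * exp(sigma_eps^2/2)."""
        params = single_state_params(beta={}, sigma_u=0.0, rho=0.0, sigma_eps=0.4,
                                     gamma_shape=25.0)
        tl = self._flat_timeline(20000, small_config, params)
        rng = np.random.default_rng(1)
        y, _ = simulate_pm(tl, params, small_config, rng)
        expected = math.exp(params.alpha) * math.exp(params.sigma_eps**2 / 2)
        assert len(y) >= 1e5
        assert y.mean() == pytest.approx(expected, rel=0.02)

    def test_concept_on_off_mean_ratio(self, small_config):
        """beta = ln 2 for an always-on concept doubles the mean."""
        base = dict(sigma_u=0.0, rho=0.0, sigma_eps=0.3, gamma_shape=25.0)
        p_on = single_state_params(beta={"kitchen": math.log(2)}, **base)
        p_off = single_state_params(beta={}, **base)
        tl = self._flat_timeline(5000, small_config, p_on)
        y_on, _ = simulate_pm(tl, p_on, small_config, np.random.default_rng(2))
        y_off, _ = simulate_pm(tl, p_off, small_config, np.random.default_rng(2))
        ratio = y_on.mean() / y_off.mean()
        assert ratio == pytest.approx(2.0, rel=0.03)

    def test_lag1_autocorrelation(self, small_config):
        params = single_state_params(beta={}, sigma_u=0.0, rho=0.8, sigma_eps=0.5,
                                     gamma_shape=1e7)
        tl = self._flat_timeline(2000, small_config, params)
        y, _ = simulate_pm(tl, params, small_config, np.random.default_rng(3))
        ly = np.log(y)
        r = np.corrcoef(ly[:-1], ly[1:])[0, 1]
        assert r == pytest.approx(0.8, abs=0.05)

    def test_strictly_positive(self, small_config):
        params = TrueParameters()
        tl = self._flat_timeline(500, small_config, params)
        y, _ = simulate_pm(tl, params, small_config, np.random.default_rng(4))
        assert (y > 0).all()


class TestRenderObserved:
    def _day(self):
        start = pd.Timestamp("2015-06-01 08:00:00")
        return DayInfo("P1_S1", "P001", "D2", "female", start,
                       start + pd.Timedelta(hours=24))

    def _inputs(self, config, params, seed=9):
        tl = simulate_schedule(config, params, "P1_S1", sex="female").timeline
        rng = np.random.default_rng(seed)
        y, _ = simulate_pm(tl, params, config, rng)
        return tl, y, rng

    def test_clean_artifacts_identity(self, small_config):
        params = TrueParameters()
        tl, y, rng = self._inputs(small_config, params)
        sensor, photos, meta, diary = render_observed(
            y, tl, ArtifactSpec(), small_config, self._day(), rng)
        assert np.allclose(sensor["neph"].to_numpy(), y)
        assert meta["grav_ref"] == pytest.approx(float(np.mean(y)))

    def test_temperature_drift_is_linear_in_excess(self, small_config):
        params = TrueParameters()
        tl, y, rng = self._inputs(small_config, params)
        art = ArtifactSpec(temp_slope=2.0, temp_affected_devices=("D2",))
        sensor, *_ = render_observed(y, tl, art, small_config, self._day(), rng)
        excess = np.clip(sensor["temperature"].to_numpy() - 30.0, 0, None)
        assert np.allclose(sensor["neph"].to_numpy() - y, 2.0 * excess)

    def test_photos_only_in_wear_window(self, small_config):
        params = TrueParameters()
        tl, y, rng = self._inputs(small_config, params)
        _, photos, _, _ = render_observed(y, tl, ArtifactSpec(), small_config,
                                          self._day(), rng)
        hours = photos["timestamp"].dt.hour
        w0, w1 = small_config.wear_window
        assert hours.between(w0, w1 - 1).all()
        cadence = photos["timestamp"].diff().dt.total_seconds().dropna()
        assert abs(cadence.mean() - small_config.photo_interval_s) < 2.0

    def test_diary_hourly_with_one_or_two_tuples(self, small_config):
        params = TrueParameters()
        tl, y, rng = self._inputs(small_config, params)
        *_, diary = render_observed(y, tl, ArtifactSpec(), small_config,
                                    self._day(), rng)
        assert len(diary) == 24
        assert (diary["activity1"] != "").all()
        night = diary["hour_start"].dt.hour.isin([22, 23, 0, 1, 2, 3, 4, 5])
        assert (diary.loc[night, "activity1"] == "sleeping").all()


class TestDeterminism:
    def test_study_reproducible(self, small_config):
        a = simulate_study(small_config, TrueParameters())
        b = simulate_study(small_config, TrueParameters())
        pd.testing.assert_frame_equal(a.photos, b.photos)
        pd.testing.assert_frame_equal(a.sensor, b.sensor)
        pd.testing.assert_frame_equal(a.sessions, b.sessions)
        pd.testing.assert_frame_equal(a.diary, b.diary)

    def test_adding_participants_leaves_others_untouched(self, recovery_params):
        d3 = simulate_intervals(3, 2, recovery_params, seed=11)
        d4 = simulate_intervals(4, 2, recovery_params, seed=11)
        keep = d4["participant_id"].isin(d3["participant_id"].unique())
        pd.testing.assert_frame_equal(
            d3.reset_index(drop=True),
            d4[keep].reset_index(drop=True))

    def test_different_seed_differs(self, recovery_params):
        d1 = simulate_intervals(2, 1, recovery_params, seed=1)
        d2 = simulate_intervals(2, 1, recovery_params, seed=2)
        assert not np.allclose(d1["pm_mean_5min"], d2["pm_mean_5min"])


class TestIntervalFastPath:
    def test_marginal_mean_tracks_model(self, recovery_params):
        """Interval means with no concept active match exp(alpha) * lognormal lift."""
        df = simulate_intervals(30, 3, recovery_params, seed=21)
        concepts = [c for c in df.columns if c in
                    ("kitchen", "smoking", "biomass_cooking_unit")]
        none_active = df.loc[(df[["kitchen", "smoking", "biomass_cooking_unit"]]
                              .sum(axis=1) == 0), "pm_mean_5min"]
        expected = math.exp(recovery_params.alpha) * recovery_params.marginal_mean_factor()
        assert none_active.mean() == pytest.approx(expected, rel=0.05)
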