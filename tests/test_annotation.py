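"""Inter-rater agreement and annotation aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score

from campm import (AggregationConfig, cohens_kappa, concept_frequency,
                   gate_annotator, minutes_to_intervals, photos_to_minutes)

from conftest import brute_force_intervals, brute_force_minutes, random_photo_table

CONCEPTS = ["kitchen", "smoking", "road"]


class TestCohensKappa:
    def test_perfect_agreement(self):
        a = [True, False, True, False]
        assert cohens_kappa(a, a).kappa == pytest.approx(1.0)

    def test_hand_computed_2x2_table(self):
        # 45 both-true, 45 both-false, 5+5 discordant: p_o=0.9, p_e=0.5
        a = [True] * 45 + [False] * 45 + [True] * 5 + [False] * 5
        b = [True] * 45 + [False] * 45 + [False] * 5 + [True] * 5
        r = cohens_kappa(a, b)
        assert r.p_observed == pytest.approx(0.9)
        assert r.p_expected == pytest.approx(0.5)
        assert r.kappa == pytest.approx(0.8)

    def test_degenerate_marginals_undefined(self):
        r = cohens_kappa([True] * 10, [True] * 10)
        assert r.kappa is None and not r.defined
        assert r.p_expected == pytest.approx(1.0)

    @pytest.mark.parametrize("a,b,err", [
        ([True], [True, False], "length mismatch"),
        ([], [], "empty"),
    ])
    def test_input_errors(self, a, b, err):
        with pytest.raises(ValueError, match=err):
            cohens_kappa(a, b)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=2, max_size=60))
    def test_matches_sklearn(self, pairs):
        """Independent library oracle on arbitrary paired boolean vectors."""
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        r = cohens_kappa(a, b)
        if r.defined:
            expected = cohen_kappa_score(a, b)
            assert r.kappa == pytest.approx(expected, abs=1e-12)


class TestGate:
    def _frames(self, kappa_target: dict[str, float], n=200, seed=0):
        """Construct rating pairs with a controlled disagreement rate."""
        rng = np.random.default_rng(seed)
        a = pd.DataFrame({c: rng.random(n) < 0.5 for c in kappa_target})
        b = a.copy()
        for c, k in kappa_target.items():
            # flipping a fraction f of balanced ratings gives kappa ~= 1-2f
            f = (1 - k) / 2
            flip = rng.random(n) < f
            b[c] = np.where(flip, ~a[c], a[c])
        return a, b

    def test_all_perfect_passes(self):
        a, b = self._frames({"kitchen": 1.0, "smoking": 1.0})
        assert gate_annotator(a, b).passed

    def test_low_category_named(self):
        a, b = self._frames({"kitchen": 1.0, "smoking": 0.5}, n=2000)
        res = gate_annotator(a, b, threshold=0.85)
        assert not res.passed
        assert res.failing == ("smoking",)

    def test_threshold_inclusive(self):
        res = gate_annotator(*self._frames({"kitchen": 1.0}))
        k = res.kappas["kitchen"]
        assert k.kappa >= 0.85 and res.passed
        # exactly at the bar passes: attainment, not exceedance
        from campm.annotation import KappaResult
        exact = KappaResult("kitchen", 0.85, 100, 0.9, 1 / 3)
        assert exact.kappa >= 0.85

    def test_missing_concept_fails_incomplete(self):
        a, b = self._frames({"kitchen": 1.0, "smoking": 1.0})
        res = gate_annotator(a, b.drop(columns=["smoking"]))
        assert not res.passed and res.missing == ("smoking",)

    def test_undefined_reported_not_failed(self):
        a = pd.DataFrame({"kitchen": [True] * 10, "smoking": [True, False] * 5})
        res = gate_annotator(a, a)
        assert res.passed and res.undefined == ("kitchen",)

    def test_category_grouping(self):
        a, b = self._frames({"kitchen": 1.0, "lpg_stove": 1.0, "road": 1.0})
        res = gate_annotator(a, b, by="category")
        assert set(res.kappas) == {"cooking", "travel"}


class TestPhotosToMinutes:
    def test_any_codeable_photo_sets_flag(self):
        t0 = pd.Timestamp("2015-06-01 09:00:00")
        df = pd.DataFrame({
            "photo_id": ["a", "b"],
            "participant_day": "P1_S1",
            "timestamp": [t0, t0 + pd.Timedelta(seconds=35)],
            "codeable": [True, True],
            "annotator_id": "A1",
            "kitchen": [False, True], "smoking": [False, False], "road": [False, False],
        })
        out = photos_to_minutes(df)
        assert len(out) == 1
        assert bool(out.loc[0, "kitchen"]) is True
        assert bool(out.loc[0, "smoking"]) is False

    def test_uncodeable_only_minute(self):
        t0 = pd.Timestamp("2015-06-01 09:00:00")
        df = pd.DataFrame({
            "photo_id": ["a"], "participant_day": "P1_S1", "timestamp": [t0],
            "codeable": [False], "annotator_id": "A1",
            "kitchen": [False], "smoking": [False], "road": [False],
        })
        out = photos_to_minutes(df)
        assert len(out) == 1 and int(out.loc[0, "n_codeable"]) == 0
        assert not out[CONCEPTS].any().any()
        out2 = photos_to_minutes(df, AggregationConfig(uncodeable="as_missing"))
        assert out2.empty

    def test_duplicate_photo_id_rejected(self):
        rng = np.random.default_rng(0)
        df = random_photo_table(rng, 10, CONCEPTS)
        df.loc[5, "photo_id"] = df.loc[4, "photo_id"]
        with pytest.raises(ValueError, match="duplicate photo_id"):
            photos_to_minutes(df)

    def test_empty_input(self):
        df = random_photo_table(np.random.default_rng(0), 3, CONCEPTS).iloc[:0]
        assert photos_to_minutes(df).empty

    def test_monotone_in_added_true_photo(self):
        """Adding a TRUE codeable photo never lowers any flag or proportion."""
        rng = np.random.default_rng(42)
        for trial in range(20):
            df = random_photo_table(rng, 40, CONCEPTS)
            new = df.iloc[[0]].copy()
            new["photo_id"] = "extra"
            new["codeable"] = True
            new["timestamp"] = df["timestamp"].iloc[int(rng.integers(len(df)))]
            for c in CONCEPTS:
                new[c] = True
            aug = pd.concat([df, new], ignore_index=True)
            m0 = photos_to_minutes(df).set_index("minute")
            m1 = photos_to_minutes(aug).set_index("minute")
            joint = m0.join(m1, lsuffix="_0", rsuffix="_1")
            for c in CONCEPTS:
                assert (joint[f"{c}_1"] >= joint[f"{c}_0"]).all()
            i0 = minutes_to_intervals(m0.reset_index()).set_index("interval_start")
            i1 = minutes_to_intervals(m1.reset_index()).set_index("interval_start")
            ji = i0.join(i1, lsuffix="_0", rsuffix="_1", how="inner")
            for c in CONCEPTS:
                assert (ji[f"{c}_1"] >= ji[f"{c}_0"] - 1e-12).all()


class TestMinutesToIntervals:
    def _minutes(self, flags, start="2015-06-01 09:00:00"):
        t0 = pd.Timestamp(start)
        return pd.DataFrame({
            "minute": [t0 + pd.Timedelta(minutes=i) for i in range(len(flags))],
            "kitchen": flags,
            "smoking": [False] * len(flags),
            "road": [False] * len(flags),
            "n_photos": 1, "n_codeable": 1,
        })

    def test_present_all_five_minutes_is_one(self):
        out = minutes_to_intervals(self._minutes([True] * 5, "2015-06-01 09:00:00"))
        assert out.loc[0, "kitchen"] == pytest.approx(1.0)

    def test_three_of_five(self):
        out = minutes_to_intervals(self._minutes([True, True, True, False, False]))
        assert out.loc[0, "kitchen"] == pytest.approx(0.6)

    def test_observed_minute_denominator(self):
        m = self._minutes([True, False])  # only 2 observed minutes in the interval
        out = minutes_to_intervals(m)
        assert out.loc[0, "kitchen"] == pytest.approx(0.5)
        assert int(out.loc[0, "n_minutes_observed"]) == 2

    def test_alignment_to_five_minute_wall_clock(self):
        m = self._minutes([True] * 3, start="2015-06-01 09:03:00")  # crosses 09:05
        out = minutes_to_intervals(m)
        assert list(out["interval_start"]) == [
            pd.Timestamp("2015-06-01 09:00:00"), pd.Timestamp("2015-06-01 09:05:00")]

    def test_brute_force_oracle(self, vocab):
        rng = np.random.default_rng(7)
        for trial in range(50):
            df = random_photo_table(rng, int(rng.integers(5, 60)), CONCEPTS)
            minutes = photos_to_minutes(df)
            oracle_m = brute_force_minutes(df, CONCEPTS)
            assert len(minutes) == len(oracle_m)
            for _, row in minutes.iterrows():
                om = oracle_m[row["minute"]]
                for c in CONCEPTS:
                    assert bool(row[c]) == om[c]
            intervals = minutes_to_intervals(minutes)
            oracle_i = brute_force_intervals(oracle_m, CONCEPTS)
            assert len(intervals) == len(oracle_i)
            for _, row in intervals.iterrows():
                oi = oracle_i[row["interval_start"]]
                for c in CONCEPTS:
                    assert row[c] == pytest.approx(oi[c], abs=1e-12)


class TestConceptFrequency:
    def test_counts_and_invariance(self):
        rng = np.random.default_rng(3)
        df = random_photo_table(rng, 50, CONCEPTS)
        counts = concept_frequency(df)
        shuffled = concept_frequency(df.sample(frac=1, random_state=1))
        assert counts.equals(shuffled)
        df["road"] = False
        assert concept_frequency(df)["road"] == 0
        # direct count oracle
        assert counts["kitchen"] == int(df["kitchen"].sum())
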