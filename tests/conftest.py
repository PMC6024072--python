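import math

import numpy as np
import pandas as pd
import pytest

from campm import SimulationConfig, TrueParameters
from campm.concepts import DEFAULT_VOCABULARY


@pytest.fixture
def vocab():
    return DEFAULT_VOCABULARY


@pytest.fixture
def small_config():
    return SimulationConfig(n_participants=3, sessions_per_participant=2, random_seed=5)


@pytest.fixture
def recovery_params():
    """Generative parameters used throughout the recovery experiments."""
    return TrueParameters(
        beta={"biomass_cooking_unit": math.log(1.6),
              "smoking": math.log(1.9),
              "kitchen": math.log(1.3)},
        sigma_u=0.3, rho=0.5,
    )


def random_photo_table(rng: np.random.Generator, n_photos: int, concepts,
                       start="2015-06-01 08:00:00", span_min: int = 30,
                       p_flag: float = 0.3, p_codeable: float = 0.8) -> pd.DataFrame:
    """Small randomized photo-annotation table for oracle comparisons."""
    t0 = pd.Timestamp(start)
    offsets = np.sort(rng.integers(0, span_min * 60, size=n_photos))
    codeable = rng.random(n_photos) < p_codeable
    rows = {
        "photo_id": [f"ph{i}" for i in range(n_photos)],
        "participant_day": "P1_S1",
        "timestamp": [t0 + pd.Timedelta(seconds=int(s)) for s in offsets],
        "codeable": codeable,
        "annotator_id": "A1",
    }
    df = pd.DataFrame(rows)
    for c in concepts:
        df[c] = np.where(codeable, rng.random(n_photos) < p_flag, False)
    return df


def brute_force_minutes(records: pd.DataFrame, concepts) -> dict:
    """Nested-loop oracle: minute -> {concept: flag, n_photos, n_codeable}."""
    out: dict = {}
    for _, row in records.iterrows():
        minute = pd.Timestamp(row["timestamp"]).floor("min")
        entry = out.setdefault(minute, {c: False for c in concepts})
        entry.setdefault("n_photos", 0)
        entry.setdefault("n_codeable", 0)
        entry["n_photos"] += 1
        if row["codeable"]:
            entry["n_codeable"] += 1
            for c in concepts:
                entry[c] = entry[c] or bool(row[c])
    return out


def brute_force_intervals(minute_oracle: dict, concepts, interval_min: int = 5) -> dict:
    """Nested-loop oracle for 5-min proportions over observed minutes."""
    out: dict = {}
    for minute, entry in minute_oracle.items():
        iv = minute.floor(f"{interval_min}min")
        agg = out.setdefault(iv, {c: 0 for c in concepts} | {"n": 0})
        agg["n"] += 1
        for c in concepts:
            agg[c] += int(entry[c])
    return {
        iv: {c: agg[c] / agg["n"] for c in concepts} | {"n": agg["n"]}
        for iv, agg in out.items()
    }
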