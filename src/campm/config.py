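"""Configuration objects for the simulator, QC and pipeline.

All knobs the analysis depends on live here as dataclasses with defaults that
describe a peri-urban Indian panel study: ~45 participants wearing a chest
camera (one photo every ~35 s, daytime only) and a nephelometer-based PM2.5
monitor logging every 10 s over repeated 24-h sessions.  Configs round-trip
through plain dicts and YAML so a run is fully described by one file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .concepts import BASE_STATES, OVERLAY_CONCEPTS


@dataclass
class SimulationConfig:
    """Study layout: who is monitored, when, and at what cadence."""

    n_participants: int = 45
    sessions_per_participant: int = 4
    session_start_hour: int = 8
    session_length_h: float = 24.0
    #: camera-on clock hours [start, end); photos exist only inside this window
    wear_window: tuple[int, int] = (8, 20)
    #: sleep clock hours [start, end) wrapping midnight; schedule forced indoors
    night_hours: tuple[int, int] = (22, 6)
    photo_interval_s: float = 35.0
    photo_interval_jitter_s: float = 3.0
    pm_sample_interval_s: float = 10.0
    prop_female: float = 23 / 45
    uncodeable_rate: float = 0.19
    n_devices: int = 4
    flow_nominal: float = 0.5  # L/min
    base_date: str = "2015-06-01"
    session_spacing_days: int = 2
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0 or self.sessions_per_participant <= 0:
            raise ValueError("participant and session counts must be positive")
        if not 1 <= self.sessions_per_participant <= 6:
            raise ValueError("sessions_per_participant must be in 1..6")
        if self.photo_interval_s <= 0 or self.pm_sample_interval_s <= 0:
            raise ValueError("sampling intervals must be positive")
        w0, w1 = self.wear_window
        if not (0 <= w0 < w1 <= 24):
            raise ValueError("wear_window must be an increasing clock interval")
        if not 0 <= self.prop_female <= 1:
            raise ValueError("prop_female must be a proportion")


def _default_beta() -> dict[str, float]:
    # Multiplicative exposure effects, log scale.  Chosen to span the range of
    # effect sizes seen in household-air-pollution panel data: strong combustion
    # sources roughly double exposure, locations shift it by tens of percent.
    return {
        "smoking": math.log(1.9),
        "biomass_cooking_unit": math.log(1.6),
        "visible_flame_smoke": math.log(1.6),
        "kitchen": math.log(1.3),
        "lpg_stove": math.log(1.15),
        "food_preparation": math.log(1.10),
        "eating": math.log(1.05),
        "road": math.log(1.10),
        "industry": math.log(1.15),
        "work_field": math.log(0.85),
        "office_shop": 0.0,
    }


def _default_schedule() -> dict[str, dict[str, dict[str, float]]]:
    # mean dwell (minutes) and relative entry weights per base state, by sex.
    # Women's days are kitchen/indoor-heavy, men's road/work-heavy.
    return {
        "female": {
            "dwell": {"kitchen": 45, "road": 15, "work_field": 60,
                      "office_shop": 20, "industry": 10, "indoors_other": 40},
            "weight": {"kitchen": 0.30, "road": 0.15, "work_field": 0.20,
                       "office_shop": 0.05, "industry": 0.02, "indoors_other": 0.28},
        },
        "male": {
            "dwell": {"kitchen": 10, "road": 20, "work_field": 40,
                      "office_shop": 30, "industry": 40, "indoors_other": 30},
            "weight": {"kitchen": 0.08, "road": 0.25, "work_field": 0.15,
                       "office_shop": 0.15, "industry": 0.12, "indoors_other": 0.25},
        },
    }


def _default_overlays() -> dict[str, dict[str, dict[str, float]]]:
    # episodes per hour (while in a compatible state) and mean episode length.
    return {
        "female": {
            "rate": {"smoking": 0.06, "lpg_stove": 0.50, "biomass_cooking_unit": 0.35,
                     "visible_flame_smoke": 0.30, "food_preparation": 0.50, "eating": 0.30},
            "duration": {"smoking": 6, "lpg_stove": 12, "biomass_cooking_unit": 15,
                         "visible_flame_smoke": 5, "food_preparation": 15, "eating": 20},
        },
        "male": {
            "rate": {"smoking": 0.30, "lpg_stove": 0.25, "biomass_cooking_unit": 0.20,
                     "visible_flame_smoke": 0.25, "food_preparation": 0.20, "eating": 0.30},
            "duration": {"smoking": 6, "lpg_stove": 12, "biomass_cooking_unit": 12,
                         "visible_flame_smoke": 5, "food_preparation": 10, "eating": 20},
        },
    }


@dataclass
class TrueParameters:
    """Ground-truth generative parameters for the exposure process.

    The 10-s (or 5-min) log-mean is ``alpha + sum_c beta[c] * x_c(t) + u``
    with a participant-day random intercept ``u ~ N(0, sigma_u^2)`` and
    stationary lag-1 autoregressive log-scale noise (marginal SD ``sigma_eps``,
    per-step correlation ``rho``); observations are Gamma with shape
    ``gamma_shape`` around the resulting mean.
    """

    alpha: float = math.log(35.0)  # log(ug/m3) background
    beta: dict[str, float] = field(default_factory=_default_beta)
    sigma_u: float = 0.3
    rho: float = 0.5
    sigma_eps: float = 0.4
    gamma_shape: float = 25.0
    schedule_rates: dict = field(default_factory=_default_schedule)
    overlay_rates: dict = field(default_factory=_default_overlays)

    def __post_init__(self) -> None:
        if self.sigma_u < 0 or self.sigma_eps < 0:
            raise ValueError("noise SDs must be nonnegative")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        for sex_cfg in self.schedule_rates.values():
            for state, dwell in sex_cfg["dwell"].items():
                if state not in BASE_STATES:
                    raise ValueError(f"unknown base state in schedule_rates: {state!r}")
                if dwell <= 0:
                    raise ValueError("dwell times must be positive")
        for sex_cfg in self.overlay_rates.values():
            for concept in sex_cfg["rate"]:
                if concept not in OVERLAY_CONCEPTS:
                    raise ValueError(f"unknown overlay concept: {concept!r}")

    def marginal_mean_factor(self) -> float:
        """E[exp(u)] * E[exp(eps)] — lognormal lift of the marginal mean."""
        return math.exp(self.sigma_u**2 / 2) * math.exp(self.sigma_eps**2 / 2)


@dataclass
class ArtifactSpec:
    """Sensor imperfections injected into the rendered observations.

    All rates default to zero (a clean instrument); :func:`study_artifacts`
    returns a preset with every failure mode switched on.
    """

    outlier_rate_per_h: float = 0.0
    outlier_magnitude: float = 300.0  # median spike height, ug/m3
    temp_threshold: float = 30.0  # degC
    temp_slope: float = 0.0  # ug/m3 per degC above threshold
    temp_affected_devices: tuple[str, ...] = ()
    flow_drift_prob: float = 0.0
    flow_drift_range: tuple[float, float] = (0.10, 0.35)
    gap_rate_per_h: float = 0.0
    gap_mean_min: float = 4.0
    neph_mult: float = 1.0
    neph_add: float = 0.0
    ref_error_sd: float = 0.0  # SD of gravimetric reference error, ug/m3

    def __post_init__(self) -> None:
        for r in (self.outlier_rate_per_h, self.flow_drift_prob, self.gap_rate_per_h):
            if r < 0:
                raise ValueError("artifact rates must be nonnegative")

    @property
    def is_clean(self) -> bool:
        return (
            self.outlier_rate_per_h == 0
            and self.temp_slope == 0
            and self.flow_drift_prob == 0
            and self.gap_rate_per_h == 0
            and self.neph_mult == 1.0
            and self.neph_add == 0.0
            and self.ref_error_sd == 0.0
        )


def study_artifacts() -> ArtifactSpec:
    """A realistically dirty instrument: spikes, heat drift, flow drift, gaps."""
    return ArtifactSpec(
        outlier_rate_per_h=0.2,
        outlier_magnitude=300.0,
        temp_slope=2.0,
        temp_affected_devices=("D2", "D4"),
        flow_drift_prob=0.08,
        gap_rate_per_h=0.10,
        gap_mean_min=4.0,
        neph_mult=0.85,
        neph_add=3.0,
        ref_error_sd=2.0,
    )


@dataclass
class QCConfig:
    """Thresholds for the sensor QC pipeline."""

    flow_tolerance: float = 0.20  # discard when |pre-post|/pre exceeds this
    outlier_window: int = 361  # samples (~1 h at 10 s), centered
    outlier_k: float = 5.0
    outlier_scale: str = "log"  # "log" or "linear" deviation scale
    outlier_mad_floor_log: float = 0.025  # ~2.5% relative
    outlier_mad_floor_linear: float = 1.0  # ug/m3
    gap_limit_min: int = 5  # runs of >= this many missing minutes stay missing
    negative_floor: float = 0.0
    baseline_shift_check: bool = False
    baseline_shift_threshold: float = 50.0  # ug/m3 between consecutive 1-h medians


@dataclass
class AggregationConfig:
    """Photo -> minute -> 5-min aggregation options."""

    uncodeable: str = "as_absent"  # or "as_missing"
    min_minutes_per_interval: int = 1
    interval_min: int = 5

    def __post_init__(self) -> None:
        if self.uncodeable not in ("as_absent", "as_missing"):
            raise ValueError("uncodeable must be 'as_absent' or 'as_missing'")


@dataclass
class RunConfig:
    """Everything one end-to-end pipeline run needs."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    parameters: TrueParameters = field(default_factory=TrueParameters)
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    qc: QCConfig = field(default_factory=QCConfig)
    aggregation: AggregationConfig = field(default_factory=AggregationConfig)
    photo_threshold: int = 100
    seed: int = 0
    output_dir: str = "campm_run"
    #: when set, load photos/sensor/sessions/diary CSVs from here instead of simulating
    input_dir: str | None = None


_SECTIONS = {
    "simulation": SimulationConfig,
    "parameters": TrueParameters,
    "artifacts": ArtifactSpec,
    "qc": QCConfig,
    "aggregation": AggregationConfig,
}


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_to_dict(config: RunConfig) -> dict:
    return _to_plain(config)


def _build(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ValueError(f"unknown {cls.__name__} field: {key!r}")
        if isinstance(fields[key].default, tuple) or (
            fields[key].type.startswith("tuple") if isinstance(fields[key].type, str) else False
        ):
            if isinstance(value, list):
                value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def config_from_dict(data: dict) -> RunConfig:
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build(cls, data[name])
    for key in ("photo_threshold", "seed", "output_dir", "input_dir"):
        if key in data:
            kwargs[key] = data[key]
    extra = set(data) - set(_SECTIONS) - {"photo_threshold", "seed", "output_dir", "input_dir"}
    if extra:
        raise ValueError(f"unknown config sections: {sorted(extra)}")
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def config_hash(config: RunConfig) -> str:
    canon = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
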