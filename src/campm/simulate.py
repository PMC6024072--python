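"""Synthetic panel-study generator with known ground truth.

Emulates the data structure of a wearable-camera + personal-PM2.5 panel
study: participants move through mutually exclusive microenvironment base
states (a semi-Markov chain with exponential dwell times), episodic overlay
concepts (smoking, stoves, flame, food preparation, eating) switch on and off
over compatible states, and personal PM2.5 follows a log-linear model of the
active concepts,

    log mean(t) = alpha + sum_c beta_c x_c(t) + u,   u ~ N(0, sigma_u^2)

with stationary AR(1) log-scale noise (marginal SD ``sigma_eps``, lag-1
correlation ``rho`` per step) multiplied into the mean and Gamma-distributed
observations around it.  The marginal mean at time t is therefore
``exp(alpha + sum beta_c x_c) * exp(sigma_u^2/2) * exp(sigma_eps^2/2)``
(the Gamma observation step is mean-preserving).

Four observable tables are rendered from the truth — photo annotations,
10-second sensor logs, session metadata with a collocated gravimetric
reference, and hourly activity diaries — optionally degraded by configurable
sensor artifacts (spikes, heat drift, flow drift, gaps, miscalibration).

Randomness: one master seed; each participant-day draws from an independent
substream keyed by its identifier, so adding participants or sessions never
perturbs existing ones.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .concepts import ConceptVocabulary, DEFAULT_VOCABULARY
from .config import ArtifactSpec, SimulationConfig, TrueParameters

__all__ = [
    "simulate_schedule",
    "simulate_pm",
    "render_observed",
    "simulate_study",
    "simulate_intervals",
    "simulate_hourly",
    "StudyData",
    "write_study_csvs",
]


def _stable_int(key: str) -> int:
    return int.from_bytes(hashlib.sha256(key.encode()).digest()[:4], "little")


def substream(master_seed: int, *keys: str) -> np.random.Generator:
    """Independent generator keyed by (master seed, string keys)."""
    entropy = [int(master_seed)] + [_stable_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

@dataclass
class ScheduleResult:
    """Minute-resolution timeline of one participant-day.

    ``timeline`` has one row per minute of the session: a ``base_state``
    column plus one boolean column per visual concept.
    """

    timeline: pd.DataFrame
    n_completed_dwells: int
    sex: str


def _draw_state(rng: np.random.Generator, states: list[str], weights: np.ndarray,
                exclude: str | None = None) -> str:
    w = weights.copy()
    if exclude is not None and len(states) > 1:
        w[states.index(exclude)] = 0.0
    w = w / w.sum()
    return states[rng.choice(len(states), p=w)]


def simulate_schedule(
    config: SimulationConfig,
    params: TrueParameters,
    participant_day: str,
    sex: str = "female",
    duration_min: int | None = None,
    apply_night: bool = True,
    rng: np.random.Generator | None = None,
    vocabulary: ConceptVocabulary = DEFAULT_VOCABULARY,
) -> ScheduleResult:
    """Simulate the minute-resolution concept timeline for one participant-day.

    Base states follow a semi-Markov chain (exponential dwell times, entry
    weights from ``params.schedule_rates[sex]``); overlay episodes arrive as a
    Poisson process per concept and switch the concept on over minutes whose
    base state is compatible.  Deterministic given (config seed,
    participant_day): the substream is derived by hashing the identifier.
    """
    if sex not in params.schedule_rates:
        raise ValueError(f"no schedule rates for sex {sex!r}")
    sched = params.schedule_rates[sex]
    states = list(sched["dwell"])
    for s in states:
        if s not in vocabulary.base_states:
            raise ValueError(f"unknown base state {s!r}")
    if rng is None:
        rng = substream(config.random_seed, "schedule", participant_day)
    n_min = duration_min if duration_min is not None else int(round(config.session_length_h * 60))

    dwell = np.array([float(sched["dwell"][s]) for s in states])
    weight = np.array([float(sched["weight"].get(s, 0.0)) for s in states])
    if weight.sum() <= 0:
        raise ValueError("schedule weights must have positive sum")

    base = np.empty(n_min, dtype=object)
    t = 0.0
    state = _draw_state(rng, states, weight)
    n_dwells = 0
    while t < n_min:
        mean = dwell[states.index(state)]
        length = n_min - t if np.isinf(mean) else rng.exponential(mean)
        lo, hi = int(math.floor(t)), min(n_min, int(math.ceil(t + length)))
        base[lo:hi] = state
        t += length
        if t < n_min:
            n_dwells += 1
            state = _draw_state(rng, states, weight, exclude=state)

    minutes = np.arange(n_min)
    clock_h = (config.session_start_hour + minutes / 60.0) % 24.0
    if apply_night:
        h0, h1 = config.night_hours
        night = (clock_h >= h0) | (clock_h < h1) if h0 > h1 else (clock_h >= h0) & (clock_h < h1)
        base[night] = "indoors_other"
    else:
        night = np.zeros(n_min, dtype=bool)

    concepts = list(vocabulary.concepts)
    col = {c: i for i, c in enumerate(concepts)}
    flag_arr = np.zeros((n_min, len(concepts)), dtype=bool)
    for state_name, implied in vocabulary.state_concepts.items():
        mask = base == state_name
        for c in implied:
            flag_arr[mask, col[c]] = True

    ov = params.overlay_rates[sex]
    day_minutes = np.flatnonzero(~night)
    day_hours = len(day_minutes) / 60.0
    for concept, rate in ov["rate"].items():
        if concept not in vocabulary.overlays:
            raise ValueError(f"unknown overlay concept {concept!r}")
        if rate <= 0 or day_hours <= 0:
            continue
        mean_dur = float(ov["duration"][concept])
        compat = np.isin(base, list(vocabulary.compatibility.get(concept, ())))
        n_ep = rng.poisson(rate * day_hours)
        starts = np.sort(rng.choice(day_minutes, size=n_ep)) if n_ep else []
        for s0 in starts:
            dur = max(1, int(round(rng.exponential(mean_dur))))
            hi = min(s0 + dur, n_min)
            seg = compat[s0:hi]
            flag_arr[s0:hi, col[concept]] |= seg

    timeline = pd.DataFrame(flag_arr, index=minutes, columns=concepts)
    timeline.insert(0, "base_state", base)
    timeline.index.name = "minute"
    return ScheduleResult(timeline=timeline, n_completed_dwells=n_dwells, sex=sex)


# ---------------------------------------------------------------------------
# PM process
# ---------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, n: int, sigma: float, rho: float) -> np.ndarray:
    """Stationary AR(1) path with marginal SD sigma and lag-1 correlation rho."""
    if sigma == 0 or n == 0:
        return np.zeros(n)
    innov = rng.normal(0.0, sigma * math.sqrt(1 - rho**2), size=n)
    innov[0] = rng.normal(0.0, sigma)
    return lfilter([1.0], [1.0, -rho], innov)


def _log_mu(timeline: pd.DataFrame, params: TrueParameters) -> np.ndarray:
    mu = np.full(len(timeline), params.alpha)
    for concept, b in params.beta.items():
        if b != 0.0:
            if concept not in timeline.columns:
                raise ValueError(f"beta refers to unknown concept {concept!r}")
            mu = mu + b * timeline[concept].to_numpy(dtype=float)
    return mu


def simulate_pm(
    timeline: pd.DataFrame,
    params: TrueParameters,
    config: SimulationConfig,
    rng: np.random.Generator,
    u: float | None = None,
) -> tuple[np.ndarray, float]:
    """True 10-s PM2.5 series over the session covered by ``timeline``.

    Returns ``(series, u)`` where ``series`` has ``60/pm_sample_interval_s``
    samples per timeline minute and ``u`` is the participant-day random
    intercept actually drawn.
    """
    per_min = int(round(60.0 / config.pm_sample_interval_s))
    log_mu_min = _log_mu(timeline, params)
    log_mu = np.repeat(log_mu_min, per_min)
    if u is None:
        u = float(rng.normal(0.0, params.sigma_u))
    eps = _ar1(rng, len(log_mu), params.sigma_eps, params.rho)
    mean = np.exp(log_mu + u + eps)
    shape = params.gamma_shape
    y = rng.gamma(shape, mean / shape)
    return y, u


# ---------------------------------------------------------------------------
# rendering observations
# ---------------------------------------------------------------------------

@dataclass
class DayInfo:
    participant_day: str
    participant_id: str
    device_id: str
    sex: str
    session_start: pd.Timestamp
    session_end: pd.Timestamp


def _temperature(clock_hours: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # diurnal cycle peaking mid-afternoon; exceeds 30 degC for several hours
    return 29.0 + 7.0 * np.cos(2 * np.pi * (clock_hours - 14.0) / 24.0) + rng.normal(0, 0.3, len(clock_hours))


def render_observed(
    true_series: np.ndarray,
    timeline: pd.DataFrame,
    artifacts: ArtifactSpec,
    config: SimulationConfig,
    day: DayInfo,
    rng: np.random.Generator,
    vocabulary: ConceptVocabulary = DEFAULT_VOCABULARY,
) -> tuple[pd.DataFrame, pd.DataFrame, dict, pd.DataFrame]:
    """Render (sensor log, photo table, session metadata, hourly diary).

    The sensor log carries the nephelometer reading (miscalibrated, heat-
    drifted, spiked and gapped per ``artifacts``), temperature, RH and flow.
    Photos exist only inside the wear window at ~35 s cadence; uncodeable
    photos carry all-false flags.  The gravimetric reference is the session
    time-weighted true mean plus configurable reference error.
    """
    per_min = int(round(60.0 / config.pm_sample_interval_s))
    n = len(true_series)
    ts = day.session_start + pd.to_timedelta(
        np.arange(n) * config.pm_sample_interval_s, unit="s")
    clock_h = (ts.hour + ts.minute / 60.0 + ts.second / 3600.0).to_numpy()

    temp = _temperature(clock_h, rng)
    rh = np.clip(55 + 15 * np.sin(2 * np.pi * (clock_h - 4) / 24.0) + rng.normal(0, 2, n), 0, 100)
    flow = np.full(n, config.flow_nominal)

    neph = artifacts.neph_mult * true_series + artifacts.neph_add
    if artifacts.temp_slope and day.device_id in artifacts.temp_affected_devices:
        excess = np.clip(temp - artifacts.temp_threshold, 0.0, None)
        neph = neph + artifacts.temp_slope * excess

    n_spikes = rng.poisson(artifacts.outlier_rate_per_h * n * config.pm_sample_interval_s / 3600.0)
    if n_spikes:
        idx = rng.choice(n, size=n_spikes, replace=False)
        neph[idx] += artifacts.outlier_magnitude * rng.lognormal(0.0, 0.5, n_spikes)

    sensor = pd.DataFrame({
        "participant_day": day.participant_day,
        "timestamp": ts,
        "neph": neph,
        "temperature": temp,
        "rh": rh,
        "flow": flow,
    })

    # gaps: whole minutes dropped so injected gap length equals missing minutes
    n_gaps = rng.poisson(artifacts.gap_rate_per_h * n * config.pm_sample_interval_s / 3600.0)
    if n_gaps:
        drop = np.zeros(n, dtype=bool)
        n_minutes = n // per_min
        for _ in range(n_gaps):
            g0 = int(rng.integers(0, n_minutes))
            glen = max(1, int(rng.geometric(1.0 / artifacts.gap_mean_min)))
            drop[g0 * per_min:(g0 + glen) * per_min] = True
        sensor = sensor.loc[~drop].reset_index(drop=True)

    # photos within the wear window
    w0, w1 = config.wear_window
    day0 = day.session_start.normalize()
    wear_start = max(day.session_start, day0 + pd.Timedelta(hours=w0))
    wear_end = min(day.session_end, day0 + pd.Timedelta(hours=w1))
    concepts = list(vocabulary.concepts)
    flag_arr = timeline[concepts].to_numpy(dtype=bool)
    jitter = config.photo_interval_jitter_s
    photo_times = []
    t = wear_start
    while t < wear_end:
        photo_times.append(t.floor("s"))
        t = t + pd.Timedelta(seconds=config.photo_interval_s + rng.uniform(-jitter, jitter))
    n_ph = len(photo_times)
    codeable = rng.random(n_ph) >= config.uncodeable_rate
    minute_idx = np.array([
        int((pt - day.session_start).total_seconds() // 60) for pt in photo_times])
    valid = (minute_idx >= 0) & (minute_idx < len(flag_arr))
    ph_flags = np.zeros((n_ph, len(concepts)), dtype=bool)
    ok = codeable & valid
    ph_flags[ok] = flag_arr[minute_idx[ok]]
    photos = pd.DataFrame({
        "photo_id": [f"{day.participant_day}_P{i:05d}" for i in range(n_ph)],
        "participant_day": day.participant_day,
        "timestamp": photo_times,
        "codeable": codeable,
        "annotator_id": "A1",
    })
    for j, c in enumerate(concepts):
        photos[c] = ph_flags[:, j]

    flow_pre = config.flow_nominal
    if rng.random() < artifacts.flow_drift_prob:
        lo, hi = artifacts.flow_drift_range
        flow_post = flow_pre * (1.0 - rng.uniform(lo, hi))
    else:
        flow_post = flow_pre * (1.0 + rng.normal(0.0, 0.01))
    grav_ref = float(np.mean(true_series)) + float(rng.normal(0.0, artifacts.ref_error_sd))
    meta = {
        "participant_day": day.participant_day,
        "participant_id": day.participant_id,
        "device_id": day.device_id,
        "sex": day.sex,
        "session_start": day.session_start,
        "session_end": day.session_end,
        "flow_pre": round(flow_pre, 4),
        "flow_post": round(float(flow_post), 4),
        "grav_ref": grav_ref,
    }

    diary = _render_diary(timeline, config, day)
    return sensor, photos, meta, diary


_STATE_DIARY = {
    "kitchen": ("cooking", "indoor_home"),
    "road": ("travel", "outdoor_village"),
    "work_field": ("working", "outdoor_field"),
    "office_shop": ("working", "indoor_other"),
    "industry": ("working", "indoor_other"),
    "indoors_other": ("sedentary", "indoor_home"),
}


def _render_diary(timeline: pd.DataFrame, config: SimulationConfig, day: DayInfo) -> pd.DataFrame:
    """Hourly recall: 1-2 modal activity-location tuples per hour.

    Coarsens the true minute timeline the way a post-session interview does:
    only the dominant one or two states of each hour survive, with no
    within-hour proportions.
    """
    h0, h1 = config.night_hours
    rows = []
    n_hours = int(len(timeline) // 60)
    base = timeline["base_state"].to_numpy()
    for h in range(n_hours):
        start = day.session_start + pd.Timedelta(hours=h)
        clock = start.hour
        night = (clock >= h0 or clock < h1) if h0 > h1 else (h0 <= clock < h1)
        if night:
            tuples = [("sleeping", "indoor_home")]
        else:
            seg = base[h * 60:(h + 1) * 60]
            states, counts = np.unique(seg, return_counts=True)
            order = np.argsort(counts)[::-1]
            tuples = [_STATE_DIARY[states[order[0]]]]
            if len(order) > 1 and counts[order[1]] >= 15:
                second = _STATE_DIARY[states[order[1]]]
                if second != tuples[0]:
                    tuples.append(second)
        rows.append({
            "participant_day": day.participant_day,
            "participant_id": day.participant_id,
            "hour_start": start,
            "activity1": tuples[0][0],
            "location1": tuples[0][1],
            "activity2": tuples[1][0] if len(tuples) > 1 else "",
            "location2": tuples[1][1] if len(tuples) > 1 else "",
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole-study generation
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """All simulator outputs for one synthetic study."""

    photos: pd.DataFrame
    sensor: pd.DataFrame
    sessions: pd.DataFrame
    diary: pd.DataFrame
    true_minutes: pd.DataFrame  # participant_day, minute, pm_true
    truth: dict = field(default_factory=dict)


def participant_roster(config: SimulationConfig) -> pd.DataFrame:
    n_female = int(round(config.prop_female * config.n_participants))
    rows = []
    for i in range(config.n_participants):
        rows.append({
            "participant_id": f"P{i + 1:03d}",
            "sex": "female" if i < n_female else "male",
        })
    return pd.DataFrame(rows)


def simulate_study(
    config: SimulationConfig,
    params: TrueParameters,
    artifacts: ArtifactSpec | None = None,
    vocabulary: ConceptVocabulary = DEFAULT_VOCABULARY,
) -> StudyData:
    """Generate the four observable tables plus ground truth for a study."""
    artifacts = artifacts or ArtifactSpec()
    vocabulary.validate()
    roster = participant_roster(config)
    base_date = pd.Timestamp(config.base_date)
    per_min = int(round(60.0 / config.pm_sample_interval_s))

    all_sensor, all_photos, all_meta, all_diary, all_true = [], [], [], [], []
    u_by_day = {}
    for _, prow in roster.iterrows():
        pid, sex = prow["participant_id"], prow["sex"]
        for s in range(config.sessions_per_participant):
            day_id = f"{pid}_S{s + 1}"
            start = (base_date + pd.Timedelta(days=s * config.session_spacing_days)
                     + pd.Timedelta(hours=config.session_start_hour))
            end = start + pd.Timedelta(hours=config.session_length_h)
            dev = f"D{(_stable_int(day_id) % config.n_devices) + 1}"
            day = DayInfo(day_id, pid, dev, sex, start, end)

            rng = substream(config.random_seed, "day", day_id)
            sched = simulate_schedule(config, params, day_id, sex=sex, rng=rng,
                                      vocabulary=vocabulary)
            true_series, u = simulate_pm(sched.timeline, params, config, rng)
            u_by_day[day_id] = u
            sensor, photos, meta, diary = render_observed(
                true_series, sched.timeline, artifacts, config, day, rng, vocabulary)

            minute_true = true_series.reshape(-1, per_min).mean(axis=1)
            minutes = start + pd.to_timedelta(np.arange(len(minute_true)), unit="min")
            all_true.append(pd.DataFrame({
                "participant_day": day_id, "minute": minutes, "pm_true": minute_true}))
            all_sensor.append(sensor)
            all_photos.append(photos)
            all_meta.append(meta)
            all_diary.append(diary)

    truth = {
        "alpha": params.alpha,
        "beta": dict(params.beta),
        "sigma_u": params.sigma_u,
        "rho": params.rho,
        "sigma_eps": params.sigma_eps,
        "gamma_shape": params.gamma_shape,
        "marginal_mean_factor": params.marginal_mean_factor(),
        "concept_true_means": {
            c: math.exp(params.alpha + params.beta.get(c, 0.0)) * params.marginal_mean_factor()
            for c in vocabulary.concepts
        },
        "u_by_participant_day": u_by_day,
    }
    return StudyData(
        photos=pd.concat(all_photos, ignore_index=True),
        sensor=pd.concat(all_sensor, ignore_index=True),
        sessions=pd.DataFrame(all_meta),
        diary=pd.concat(all_diary, ignore_index=True),
        true_minutes=pd.concat(all_true, ignore_index=True),
        truth=truth,
    )


def write_study_csvs(data: StudyData, outdir: str | Path) -> dict[str, Path]:
    """Write the four observable CSVs plus the ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [("photos", data.photos), ("sensor", data.sensor),
                     ("sessions", data.sessions), ("diary", data.diary),
                     ("true_minutes", data.true_minutes)]:
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    p = outdir / "truth.json"
    with open(p, "w") as fh:
        json.dump(data.truth, fh, indent=1, default=float)
    paths["truth"] = p
    return paths


# ---------------------------------------------------------------------------
# model-scale fast paths
# ---------------------------------------------------------------------------

def simulate_intervals(
    n_participants: int,
    sessions_per_participant: int,
    params: TrueParameters,
    seed: int,
    wear_minutes: int = 780,
    interval_min: int = 5,
    prop_female: float = 23 / 45,
    vocabulary: ConceptVocabulary = DEFAULT_VOCABULARY,
) -> pd.DataFrame:
    """Simulate 5-min interval data directly at the analysis resolution.

    Here ``params.rho`` and ``params.sigma_eps`` describe the interval-level
    log-scale noise (one AR(1) step per 5-min interval), which is the scale at
    which the exposure model operates; the schedule is still simulated at
    minute resolution and averaged into concept proportions.  Used for
    statistical calibration experiments where running the 10-s sensor chain
    would only add averaging noise.
    """
    cfg = SimulationConfig(
        n_participants=n_participants,
        sessions_per_participant=min(sessions_per_participant, 6),
        prop_female=prop_female,
        random_seed=seed,
    )
    per = interval_min
    n_iv = wear_minutes // per
    concepts = list(vocabulary.concepts)
    frames = []
    n_female = int(round(prop_female * n_participants))
    for i in range(n_participants):
        pid = f"P{i + 1:03d}"
        sex = "female" if i < n_female else "male"
        for s in range(sessions_per_participant):
            day_id = f"{pid}_S{s + 1}"
            rng = substream(seed, "ivday", day_id)
            sched = simulate_schedule(
                cfg, params, day_id, sex=sex, duration_min=n_iv * per,
                apply_night=False, rng=rng, vocabulary=vocabulary)
            flags = sched.timeline[concepts].to_numpy(dtype=float)
            props = flags.reshape(n_iv, per, len(concepts)).mean(axis=1)
            betavec = np.array([params.beta.get(c, 0.0) for c in concepts])
            log_mu = params.alpha + props @ betavec
            u = rng.normal(0.0, params.sigma_u)
            eps = _ar1(rng, n_iv, params.sigma_eps, params.rho)
            mean = np.exp(log_mu + u + eps)
            y = rng.gamma(params.gamma_shape, mean / params.gamma_shape)
            df = pd.DataFrame(props, columns=concepts)
            df.insert(0, "participant_day", day_id)
            df.insert(1, "participant_id", pid)
            df.insert(2, "sex", sex)
            df.insert(3, "interval_index", np.arange(n_iv))
            df["pm_mean_5min"] = y
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


_DIARY_ACTIVITIES = ("cooking", "working", "travel", "sedentary", "household_chores")


def simulate_hourly(
    n_participants: int,
    days_per_participant: int,
    effects: dict[str, float],
    seed: int,
    alpha: float = math.log(35.0),
    sigma_participant: float = 0.2,
    sigma_day: float = 0.25,
    gamma_shape: float = 10.0,
    two_activity_prob: float = 0.3,
    night_hours: tuple[int, int] = (22, 6),
) -> pd.DataFrame:
    """Hourly self-report data: sleeping at night, drawn activities by day.

    ``effects`` maps activity name -> log-scale effect relative to sleeping
    (the reference).  Hours with two activities weight each indicator 0.5.
    Log-mean gets nested random intercepts: participant and participant-day.
    """
    acts = [a for a in _DIARY_ACTIVITIES if a in effects] or list(effects)
    for a in effects:
        if a == "sleeping":
            raise ValueError("sleeping is the reference; give no effect for it")
    rng = np.random.default_rng(np.random.SeedSequence([seed, _stable_int("hourly")]))
    h0, h1 = night_hours
    rows = []
    for i in range(n_participants):
        pid = f"P{i + 1:03d}"
        up = rng.normal(0.0, sigma_participant)
        for d in range(days_per_participant):
            day_id = f"{pid}_S{d + 1}"
            ud = rng.normal(0.0, sigma_day)
            for h in range(24):
                night = (h >= h0 or h < h1) if h0 > h1 else (h0 <= h < h1)
                if night:
                    chosen = ["sleeping"]
                else:
                    k = 2 if rng.random() < two_activity_prob else 1
                    chosen = list(rng.choice(acts, size=k, replace=False))
                w = 1.0 / len(chosen)
                log_mu = alpha + sum(effects.get(a, 0.0) * w for a in chosen) + up + ud
                mean = math.exp(log_mu)
                y = rng.gamma(gamma_shape, mean / gamma_shape)
                row = {"participant_id": pid, "participant_day": day_id,
                       "hour": h, "pm_hourly": y,
                       "activity1": chosen[0],
                       "activity2": chosen[1] if len(chosen) > 1 else ""}
                rows.append(row)
    return pd.DataFrame(rows)
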