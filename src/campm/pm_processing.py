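"""Quality control of raw 10-second nephelometer logs into 1-minute PM2.5.

Pipeline order is fixed: flow-drift screening -> outlier removal ->
temperature correction -> gravimetric correction -> minute averaging ->
short-gap interpolation.  Outlier removal precedes the corrections so that a
spike does not leak into session means used for the gravimetric fit.

The outlier rule is a rolling robust filter: a sample is removed when its
deviation from the centered rolling median exceeds ``k`` times the scaled
rolling MAD (median absolute deviation, scaled by 1.4826 to estimate a
normal SD), with a floor on the MAD so constant stretches do not flag
everything.  Because nephelometer noise is multiplicative — concentration
fluctuations scale with the level — the deviations are measured on the log
scale by default, which keeps genuine lognormal-tail excursions while still
catching instrument spikes an order of magnitude above the local level; a
linear-scale variant is available for additive-noise instruments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import QCConfig

__all__ = [
    "FlowVerdict",
    "check_flow_drift",
    "remove_outliers",
    "DeviceTempCorrection",
    "correct_temperature",
    "GravimetricFit",
    "fit_gravimetric",
    "apply_gravimetric",
    "to_minutes",
    "process_session",
    "SessionQCReport",
]

MAD_SCALE = 1.4826


@dataclass(frozen=True)
class FlowVerdict:
    keep: bool
    drift_fraction: float | None
    reason: str


def check_flow_drift(meta, tolerance: float = 0.20) -> FlowVerdict:
    """Keep/discard a session from its pre/post pump-flow measurements.

    Discards when |pre - post| / pre strictly exceeds ``tolerance`` (a drift
    of exactly the tolerance keeps the session); a missing post-sampling flow
    is unverifiable and discards.
    """
    pre = meta["flow_pre"] if not hasattr(meta, "flow_pre") else meta.flow_pre
    post = meta["flow_post"] if not hasattr(meta, "flow_post") else meta.flow_post
    if pre is None or not np.isfinite(pre) or pre <= 0:
        raise ValueError("flow_pre must be positive")
    if post is None or not np.isfinite(post):
        return FlowVerdict(False, None, "unverifiable: missing post-sampling flow")
    drift = abs(pre - post) / pre
    if drift > tolerance:
        return FlowVerdict(False, drift, f"flow drift {drift:.1%} > {tolerance:.0%}")
    return FlowVerdict(True, drift, f"flow drift {drift:.1%} within tolerance")


def _rolling_median(x: pd.Series, window: int) -> pd.Series:
    return x.rolling(window, center=True, min_periods=1).median()


def remove_outliers(
    pm: pd.Series,
    window: int = 361,
    k: float = 5.0,
    scale: str = "log",
    mad_floor: float | None = None,
) -> tuple[pd.Series, int]:
    """Set rolling-robust outliers to missing; return (series, count removed).

    ``scale="log"`` (default) measures deviations on log-transformed values;
    nonpositive samples cannot be genuine concentrations and are removed
    outright.  ``scale="linear"`` uses raw deviations.  The MAD gets an
    epsilon floor (log: 0.025 ~ 2.5% relative; linear: 1 ug/m3) so constant
    stretches produce no false outliers.  A window larger than the series
    falls back to the global median/MAD with a warning.  Idempotent: removed
    values stay missing and do not shift the medians of a second pass enough
    to flag survivors (medians are recomputed on the thinned series).
    """
    if scale not in ("log", "linear"):
        raise ValueError("scale must be 'log' or 'linear'")
    if mad_floor is None:
        mad_floor = 0.025 if scale == "log" else 1.0
    x = pm.astype(float).copy()
    n_valid = int(x.notna().sum())
    if n_valid == 0:
        return x, 0
    if window > n_valid:
        warnings.warn(
            f"outlier window {window} exceeds series length {n_valid}; "
            "using global median/MAD", stacklevel=2)

    bad_nonpos = pd.Series(False, index=x.index)
    if scale == "log":
        bad_nonpos = x.notna() & (x <= 0)
        work = np.log(x.where(x > 0))
    else:
        work = x
    if window > n_valid:
        med = pd.Series(np.nanmedian(work), index=work.index)
        dev = (work - med).abs()
        mad = pd.Series(np.nanmedian(dev), index=work.index)
    else:
        med = _rolling_median(work, window)
        dev = (work - med).abs()
        mad = _rolling_median(dev, window)
    sigma = np.maximum(MAD_SCALE * mad, mad_floor)
    out = (dev > k * sigma) | bad_nonpos
    out = out.fillna(False)
    x[out] = np.nan
    return x, int(out.sum())


@dataclass(frozen=True)
class DeviceTempCorrection:
    """Device-specific linear heat-drift correction above a threshold."""

    device_id: str
    threshold: float = 30.0
    slope: float = 0.0  # ug/m3 per degC above threshold
    intercept: float = 0.0  # ug/m3


def correct_temperature(
    pm: pd.Series,
    temperature: pd.Series,
    correction: DeviceTempCorrection,
) -> pd.Series:
    """Subtract the device's heat artifact where temperature > threshold.

    pm <- pm - (intercept + slope * (T - threshold)) for samples above the
    threshold; samples at or below it are untouched.  No clipping is applied
    here; negative values are floored (and counted) downstream.
    """
    hot = temperature > correction.threshold
    adj = correction.intercept + correction.slope * (temperature - correction.threshold)
    return pm.where(~hot, pm - adj)


@dataclass(frozen=True)
class GravimetricFit:
    """OLS of gravimetric reference on nephelometer session means."""

    slope: float
    intercept: float
    n_sessions: int
    r2: float

    def apply(self, pm: pd.Series) -> pd.Series:
        return self.intercept + self.slope * pm


IDENTITY_FIT = GravimetricFit(1.0, 0.0, 0, 1.0)


def fit_gravimetric(session_means: pd.DataFrame) -> GravimetricFit:
    """Fit the nephelometer-to-gravimetric calibration line.

    ``session_means`` needs columns ``neph_mean`` and ``grav_ref``; the
    reference concentration is regressed on the nephelometer session mean
    (prediction form), and the fitted line is later applied to every sample.
    """
    d = session_means[["neph_mean", "grav_ref"]].dropna()
    if len(d) < 2:
        raise ValueError(f"need >= 2 sessions with both values, got {len(d)}")
    x = d["neph_mean"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in nephelometer session means")
    res = sm.OLS(d["grav_ref"].to_numpy(float), sm.add_constant(x)).fit()
    return GravimetricFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        n_sessions=len(d),
        r2=float(res.rsquared),
    )


def apply_gravimetric(
    pm: pd.Series,
    fit: GravimetricFit,
    floor: float = 0.0,
) -> tuple[pd.Series, int]:
    """Apply the calibration line; floor negatives and count them."""
    out = fit.apply(pm.astype(float))
    below = out.notna() & (out < floor)
    out[below] = floor
    return out, int(below.sum())


def to_minutes(
    pm: pd.Series,
    timestamps: pd.Series,
    gap_limit_min: int = 5,
) -> pd.DataFrame:
    """Average 10-s samples to calendar minutes and fill short gaps.

    Runs of wholly missing minutes shorter than ``gap_limit_min`` are filled
    by linear interpolation between the flanking minute means and flagged
    ``interpolated``; runs of ``gap_limit_min`` or more (and runs touching
    either end of the session) are left missing.  The output covers every
    minute from the first to the last observed sample.
    """
    ts = pd.to_datetime(timestamps)
    minute = ts.dt.floor("min")
    df = pd.DataFrame({"minute": minute, "pm": pm.to_numpy(float)})
    g = df.groupby("minute")["pm"]
    means = g.mean()
    counts = g.count()
    full = pd.date_range(means.index.min(), means.index.max(), freq="min")
    means = means.reindex(full)
    counts = counts.reindex(full, fill_value=0)

    filled = means.copy()
    interpolated = pd.Series(False, index=full)
    isna = means.isna().to_numpy()
    i = 0
    n = len(full)
    while i < n:
        if isna[i]:
            j = i
            while j < n and isna[j]:
                j += 1
            run = j - i
            if 0 < i and j < n and run < gap_limit_min:
                left, right = means.iloc[i - 1], means.iloc[j]
                frac = np.arange(1, run + 1) / (run + 1)
                filled.iloc[i:j] = left + frac * (right - left)
                interpolated.iloc[i:j] = True
            i = j
        else:
            i += 1
    return pd.DataFrame({
        "minute": full,
        "pm": filled.to_numpy(),
        "n_samples": counts.to_numpy(int),
        "interpolated": interpolated.to_numpy(),
    })


@dataclass
class SessionQCReport:
    participant_day: str
    kept: bool
    reason: str
    flow_drift: float | None = None
    n_samples: int = 0
    n_outliers_removed: int = 0
    n_floored: int = 0
    n_minutes: int = 0
    n_minutes_missing: int = 0
    n_minutes_interpolated: int = 0
    baseline_shift: bool = False
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "participant_day", "kept", "reason", "flow_drift", "n_samples",
            "n_outliers_removed", "n_floored", "n_minutes", "n_minutes_missing",
            "n_minutes_interpolated", "baseline_shift")}
        d.update(self.extra)
        return d


def _baseline_shift(minutes: pd.DataFrame, threshold: float) -> bool:
    pm = minutes.set_index("minute")["pm"]
    hourly = pm.resample("1h").median().dropna()
    if len(hourly) < 2:
        return False
    return bool((hourly.diff().abs() > threshold).any())


def preclean_session(
    raw: pd.DataFrame,
    correction: DeviceTempCorrection,
    qc: QCConfig,
) -> tuple[pd.Series, int]:
    """Outlier removal then temperature correction on one raw session log."""
    pm, n_out = remove_outliers(
        raw["neph"], window=qc.outlier_window, k=qc.outlier_k,
        scale=qc.outlier_scale,
        mad_floor=(qc.outlier_mad_floor_log if qc.outlier_scale == "log"
                   else qc.outlier_mad_floor_linear))
    pm = correct_temperature(pm, raw["temperature"], correction)
    return pm, n_out


def process_session(
    raw: pd.DataFrame,
    meta,
    correction: DeviceTempCorrection,
    grav_fit: GravimetricFit,
    qc: QCConfig | None = None,
) -> tuple[pd.DataFrame, SessionQCReport]:
    """Run the full per-session chain and return (minute table, QC report).

    The session is assumed to have already passed flow screening; the
    gravimetric fit is estimated across sessions beforehand (see
    :func:`fit_gravimetric`) and applied here.
    """
    qc = qc or QCConfig()
    day = meta["participant_day"] if not hasattr(meta, "participant_day") else meta.participant_day
    pm, n_out = preclean_session(raw, correction, qc)
    pm, n_floor = apply_gravimetric(pm, grav_fit, floor=qc.negative_floor)
    minutes = to_minutes(pm, raw["timestamp"], gap_limit_min=qc.gap_limit_min)
    minutes.insert(0, "participant_day", day)
    shift = _baseline_shift(minutes, qc.baseline_shift_threshold) if qc.baseline_shift_check else False
    kept = not shift
    report = SessionQCReport(
        participant_day=str(day),
        kept=kept,
        reason="abrupt baseline shift" if shift else "passed sensor QC",
        n_samples=int(raw["neph"].notna().sum()),
        n_outliers_removed=n_out,
        n_floored=n_floor,
        n_minutes=len(minutes),
        n_minutes_missing=int(minutes["pm"].isna().sum()),
        n_minutes_interpolated=int(minutes["interpolated"].sum()),
        baseline_shift=shift,
    )
    return minutes, report
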