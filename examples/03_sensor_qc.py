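"""Sensor QC on a deliberately dirty session log.

A constructed 2-hour nephelometer log gets every failure mode the QC chain
handles: a flow-drifted session verdict, an instrument spike, heat drift
above 30 degC, a miscalibrated optical response, and a 3-minute data gap.
The chain (outliers -> temperature -> gravimetric -> minute averaging -> gap
interpolation) repairs each one; compare the printed output to the truth.
"""

import numpy as np
import pandas as pd

from campm import (DeviceTempCorrection, GravimetricFit, check_flow_drift,
                   correct_temperature, remove_outliers, to_minutes)

rng = np.random.default_rng(3)
n = 720  # 2 h at 10 s
t0 = pd.Timestamp("2015-06-01 08:00:00")
ts = pd.Series([t0 + pd.Timedelta(seconds=10 * i) for i in range(n)])
true_pm = 40.0 * np.exp(rng.normal(0, 0.2, n))  # lognormal-ish truth

temp = np.linspace(26, 36, n)  # afternoon heat ramp
neph = 0.85 * true_pm + 3.0  # optical miscalibration
neph += 2.0 * np.clip(temp - 30.0, 0, None)  # heat drift above 30 degC
neph[300] += 3500.0  # one instrument spike
neph[430:448] = np.nan  # 3-min run of lost samples (2 whole calendar minutes)

verdict = check_flow_drift({"flow_pre": 0.50, "flow_post": 0.46})
print(f"flow screening: keep={verdict.keep} ({verdict.reason})")

pm, n_removed = remove_outliers(pd.Series(neph))
print(f"outlier removal: {n_removed} sample(s) removed "
      f"(spike was {neph[300]:.0f} vs local level ~40)")

pm = correct_temperature(pm, pd.Series(temp), DeviceTempCorrection("D2", slope=2.0))
# gravimetric fit would come from collocated reference sessions; the line
# inverting the injected miscalibration is y = (x - 3) / 0.85
fit = GravimetricFit(slope=1 / 0.85, intercept=-3.0 / 0.85, n_sessions=8, r2=1.0)
pm = fit.apply(pm)

minutes = to_minutes(pm, ts)
true_minutes = pd.Series(true_pm).groupby(np.arange(n) // 6).mean()
err = np.abs(minutes["pm"].to_numpy()[:len(true_minutes)] - true_minutes.to_numpy())
ok = ~np.isnan(err)
print(f"minute series: {len(minutes)} minutes, "
      f"{int(minutes['interpolated'].sum())} interpolated (the wholly-missing "
      f"minutes of the gap), {int(minutes['pm'].isna().sum())} left missing")
print(f"max |corrected - true| over non-gap minutes: {np.nanmax(err):.3f} ug/m3")
print("(residual is the spike minute: one of its six samples was removed, "
      "so its mean uses five samples)")
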