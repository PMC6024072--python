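# Methods

This note records the statistical model behind `campm`, the generative
model of the synthetic-data module, the defaults and why they were chosen,
and the numerical decisions a maintainer would otherwise have to rediscover.

## The exposure model

The target of inference is the multiplicative effect of a visual concept
(a camera-derived microenvironment/activity flag) on short-term personal
PM2.5.  For 5-minute interval *t* of participant-day *i*, with
x_cit ∈ [0, 1] the proportion of observed minutes in the interval carrying
concept *c*:

    Y_it ~ Gamma,   log E[Y_it] = α + Σ_c β_c x_cit

- β_c is the log contrast between an interval fully covered by concept *c*
  and one without it, other concepts held fixed; reported as percent change
  (e^{β_c} − 1)·100.
- α is the log 5-minute mean when no concept is present.  Because the
  random effects below act multiplicatively, the marginal intercept absorbs
  their lognormal lift (σ_u²/2 + σ_ε²/2 on the log scale); the β_c are
  unaffected, which is why a marginal (GEE) fit is consistent for them.
- Dependence within a participant-day has two sources: a day-level random
  intercept (everything shifting a whole day — instrument, weather,
  household fuel) and serial correlation between neighbouring intervals.

Fits are stratified by sex throughout: activity patterns differ so strongly
between women and men in the study population this package models that a
pooled fit would mostly estimate the sex contrast.

### Estimation

`fit_gamma_repeated` solves the Gamma/log quasi-score by Fisher scoring
under a working within-cluster correlation

    R_jk = τ + ψ·ρ^{|t_j − t_k|}   (j ≠ k),  R_jj = 1,

where τ captures the exchangeable (random-intercept) share of the Pearson
residual correlation, and ψ·ρ^d its autoregressive decay with integer lag
distance d (missing intervals advance the lag; non-equidistant decay is not
modelled).  For the Gamma family with log link the estimating equations
reduce to Σ_i X_i'R_i⁻¹z_i = 0 with z = (y − μ)/μ, so the scoring matrix
Σ X_i'R_i⁻¹X_i is free of μ and can be factorized once per correlation
update — this is what makes replicate studies cheap.

Between scoring passes (τ, ψ, ρ) are moment-estimated: residual
autocovariances c_k at lags k = 1…10 are fit to c_k = τ + ψρ^k by
weighted least squares, profiling ρ over (0, 0.99).  Because independent
observation noise (the Gamma shape component) dilutes all c_k equally, ρ is
identified from the *decay* of c_k and is therefore robust to that
dilution; τ and ψ estimate shares of the response-scale residual variance.
`sigma_u_hat = sqrt(τ·φ)` (φ the Pearson scale) is a small-variance
approximation to the log-scale random-intercept SD — adequate at the
variance levels this design targets (σ_u ≈ 0.3), documented as approximate.

Standard errors are cluster-robust (sandwich over participant-days), so
confidence intervals remain valid if the working correlation is wrong.
Wald intervals are formed on the log scale and transformed, preserving the
asymmetry of multiplicative effects.  No multiple-testing adjustment is
applied; the concept contrasts are reported as a mutually adjusted panel.

Whether the serial correlation "really" lives on a latent Gaussian process
(GLMM reading) or on working residuals (GEE reading) is deliberately left
open: the implementation commits only to the contract that marginal effects
are recovered without material bias, intervals are calibrated, and the
dependence parameters are recovered — properties the test suite checks by
simulation rather than by algebraic identity with any one mixed-model
formulation.

The hourly self-report variant swaps the correlation model for a nested
exchangeable one (participant and participant-day components), uses
sleeping as the reference activity, and weights each of two reported
activities 0.5 within an hour (the diary records no within-hour
proportions; a duplicate-row encoding is available as a switch).

### Exclusion rules

Before fitting, `build_design` drops (with a reason string per concept):
location concepts (`indoors`, `in_vehicle`, `mixed`) — collinear with the
activities that define them; concepts flagged in fewer than 100 photographs
in the stratum — too thin to estimate; concepts never present in the
interval data.  Rows with missing response are dropped and counted.

## Annotation processing

Cohen's kappa is computed from the 2×2 agreement table per concept (or per
category, pooling member concepts by OR).  When chance agreement p_e = 1
(both raters constant and identical) κ is undefined and reported as such —
not failed, since a concept absent from a training set carries no evidence
either way.  The gate is inclusive: κ = 0.85 exactly passes, reading the
threshold as attainment.

Aggregation conventions (the protocol leaves these open; all are config
switches):

- 5-minute intervals are half-open [t, t+5) aligned to wall-clock minutes
  divisible by 5 — deterministic and session-independent.
- A minute whose photos are all uncodeable counts as observed with no
  concepts (default `as_absent`) rather than missing; with ~19% of images
  uncodeable this choice keeps wear time honest while never inventing a
  concept.  `as_missing` drops such minutes instead.
- Interval proportions divide by *observed* minutes (not 5), with a
  configurable minimum coverage (default ≥ 1 observed minute).

## Sensor QC

Order is fixed and matters: outlier removal → temperature correction →
gravimetric correction → minute averaging → gap interpolation.  Spikes must
go first or they contaminate the session means the gravimetric line is fit
on.

- **Flow screening**: discard a session when |pre − post|/pre > 0.20,
  strictly greater — a drift of exactly 20% keeps.  Missing post-flow is
  unverifiable and discards.
- **Outliers**: a sample is removed when its deviation from the centered
  rolling median (window 361 samples ≈ 1 h) exceeds 5 × the scaled rolling
  MAD (1.4826·MAD), computed on the **log** scale by default.  Nephelometer
  noise is multiplicative — fluctuations scale with the concentration — so
  a linear-scale threshold keyed to the local MAD would flag the genuine
  right tail of high-exposure episodes at a rate of order 10⁻³ per sample;
  on the log scale the same 5-MAD rule keeps lognormal-tail excursions
  (≈ 3×10⁻⁷ per side) while still catching order-of-magnitude instrument
  spikes.  The MAD gets an ε-floor (0.025 log units ≈ 2.5% relative; 1 μg/m³
  in the linear variant) so constant stretches flag nothing.  Nonpositive
  readings cannot be concentrations and are removed outright in log mode.
  The rolling MAD is computed as the rolling median of |x − rolling median|
  (two passes), the standard fast approximation to a windowed MAD.
- **Temperature**: pm ← pm − (intercept + slope·(T − 30)) only where
  T > 30 °C, with per-device coefficients from a config table (zeros by
  default; the simulator's injected slopes play the role of the bench-derived
  equations).
- **Gravimetric**: OLS of the collocated reference concentration on the
  nephelometer session mean (prediction direction), one global line applied
  to every sample; a per-device option exists.  Needs ≥ 2 sessions and
  nonzero variance.  Negative corrected values are floored at 0 and counted.
- **Minutes and gaps**: minute means over available 10-s samples; runs of
  wholly missing minutes shorter than 5 are linearly interpolated between
  flanking minute means and flagged; runs of exactly 5 or more — and runs
  touching either end of a session — stay missing.  The exactly-5 case is
  resolved conservatively (not interpolated).  Minute averaging conserves
  the session sum: Σ(mean·n_samples) over non-interpolated minutes equals
  the sum of surviving samples to numerical precision.
- **Baseline shifts**: an optional session-level screen (difference of
  consecutive 1-h medians above a threshold) ships disabled — in practice
  this failure mode needs eyes on the trace, so the default mirrors manual
  review.

## The synthetic-data generator

The generator exists so every stage can be validated against known truth
with no external data.  One master seed; each participant-day draws from a
substream keyed by hashing its identifier, so adding participants or
sessions never perturbs existing ones, and reruns are bit-identical.

**Schedules.** Base microenvironments (kitchen, road, field, office/shop,
industry, other-indoors) are mutually exclusive and follow a semi-Markov
chain: exponential dwell times (means per state and sex; women's defaults
are kitchen-heavy, men's road/work-heavy) and entry weights.  Overlay
concepts (smoking, LPG stove, biomass stove, visible flame, food
preparation, eating) arrive as Poisson episodes and switch on only over
compatible base states, so concepts co-occur the way annotations do.  Night
hours (22:00–06:00) force the other-indoors state.  The real annotation
data have no such exclusive/overlay structure — it is a modelling choice
needed to *generate* concept timelines at all.

**Exposure.** True 10-s PM2.5 follows the exposure model exactly:
log mean = α + Σβ_c x_c(t) + u with u ~ N(0, σ_u²) per participant-day,
times stationary AR(1) lognormal noise (marginal SD σ_ε, per-step
correlation ρ), with Gamma(shape) observations around the resulting mean.
The marginal mean is exp(α + Σβx)·exp(σ_u²/2)·exp(σ_ε²/2); the Gamma step
is mean-preserving.  Defaults: α = log 35 μg/m³ (a plausible rural-South-Asia
personal background), β spanning ×0.85–×1.9 with combustion sources
strongest, σ_u = 0.3, σ_ε = 0.4, ρ = 0.5, shape 25 (≈ 20% observation CV —
short-term optical noise).  The within-concept concentration spread of real
data is heavier-tailed than this lognormal-Gamma mix; the shape parameter
is a free knob, not an empirical estimate.

`simulate_intervals` generates 5-minute data directly at the analysis
resolution (ρ and σ_ε then describe interval-level noise), which is the
correct scale for calibration experiments on the *model*; the 10-s path
feeds the sensor-QC validation, where its ρ describes 10-s noise.

**Rendering and artifacts.** Photos appear only inside the wear window
(08:00–20:00 by default, ~35 s cadence with ±3 s jitter, 19% uncodeable);
the sensor log carries a diurnal temperature cycle peaking at 36 °C,
humidity and pump flow; the gravimetric reference is the session
time-weighted true mean plus optional error.  Artifact knobs — spike rate
and magnitude, heat-drift slope above 30 °C on designated devices,
pre/post flow drift probability, whole-minute gaps, multiplicative/additive
miscalibration — default to zero; `study_artifacts()` switches all of them
on.  Hourly diaries coarsen the true timeline to the modal one or two
states per hour (sleeping at night), reproducing exactly the information
loss that makes diary-based models blunter than camera-based ones.

**What passing tests do not show.** The generator's schedules are
stationary within a day, annotations are error-free given codeability,
there is no ambient-PM seasonality, no GPS, no images.  Recovery and
calibration results therefore validate the *pipeline machinery* under the
model's own assumptions, not the behaviour of any real population.

## Validation design and problem sizes

The statistical checks run at 40 participants × 4 days (~156 intervals per
day): 100-replicate recovery of β = {log 1.6, log 1.9, log 1.3} with
σ_u = 0.3, ρ = 0.5 (relative bias and 95% CI coverage), 200-replicate
type-I error under all-β = 0 with the dependence intact, single-fit recovery
of ρ and σ_u, and exact reduction to an independence Gamma GLM (cross-checked
against `statsmodels`) when the data carry no dependence.  Deterministic
rules are checked against hand-computed constructions (flow drift 22%,
4-minute gap fills, a lone 4000 μg/m³ spike, the 45/45/5/5 kappa table) and
brute-force recounts on 1000 randomized annotation sets; the clean-instrument
round trip requires the QC output to equal true minute means to < 10⁻⁹
relative.  These sizes keep the full suite to a few minutes while leaving
Monte-Carlo error well inside the asserted bands.

## Known limitations

- σ_u is reported via a small-variance moment approximation, not a
  likelihood estimate; at σ_u ≫ 0.5 it will drift from the log-scale truth.
- The AR lag uses interval *indices*; irregular true spacing within a day
  (beyond missingness) is not modelled.
- The gravimetric line assumes a stable instrument response across
  sessions; drifting calibration would need a per-device or per-period fit.
- Interval proportions enter linearly on the log scale; within-interval
  mixing of concepts is approximated (Jensen gap) whenever a concept covers
  part of an interval.
- The hourly model ignores serial correlation between adjacent hours beyond
  the two nested intercepts.
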