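# Methods

## Preprocessing

A raw CGM export is delimited text with ISO-8601 `timestamp` and `glucose`
columns on a nominal 5-minute grid; clock jitter up to 1 s is snapped to
the grid, anything larger is rejected rather than resampled. The analysis
window is the first admissible 24-hour block (288 samples), preferring the
block that starts at 08:00 the day after the recording begins so that the
in-clinic insertion hours are excluded. A block is admissible when every
run of consecutive missing samples has length ≤ 2 and its endpoints are
present; qualifying gaps are filled by linear interpolation between the
flanking observations (the simplest rule consistent with ≤ 2-point gaps —
no extrapolation, so edge gaps disqualify a block). When the preferred
block is inadmissible the candidate start slides forward in 5-minute
steps, wrapping to the earlier part of the recording before the whole
trace is declared unsuitable. The sliding order is this package's
convention; any deterministic order would do, and on gap-free traces the
selection is value-independent.

## Fluctuation analysis

The fluctuation function is computed directly on the glucose values, not
on the cumulative-sum profile. This departs from the usual random-walk
framing of DFA deliberately: integrating smooths the trace and pushes
every exponent up by one, while the raw-series residuals retain the
short-window information the crossover lives in. The cumulative-sum
pre-treatment is kept as an option (`integrate_first=True`) for
sensitivity comparisons; with it, i.i.d. noise yields the textbook
exponent 0.5, which the test suite verifies as a calibration of the
machinery.

Windows are non-overlapping and tile the series exactly — every member of
the window sequence divides 288, which is why that particular sequence is
used. Detrending is order-1 (a straight line per window); windows of
fewer than 3 points are rejected since a line through two points has zero
residual by construction. Logarithms are natural throughout; only the
overall slope and intersection abscissa are base-dependent quantities,
and the minutes conversion `5·e^x` assumes base e.

F(n) values at or below machine precision relative to the signal are
floored to exactly zero and excluded from the log–log coordinates with a
warning; this occurs only for degenerate input (e.g. an exactly linear
series, whose per-window lines fit perfectly).

## Crossover fitting

All splits with at least 4 points in the first limb and 5 in the second
are enumerated (k = 4 … 11 on the 16-point curve). "Combined weighted R²"
is implemented as the point-count-weighted mean of the limb R² values; it
reduces to the plain mean for equal limbs and is maximized exactly at a
true two-line break. Ties break toward the smaller split index. Slopes
equal up to 1e−12 (relative) are treated as parallel: the intersection is
then meaningless, `crossover_of` raises, and `fit_split` records NaN.
The angle is `arctan(slope1) − arctan(slope2)`: of the candidate readings
of "angle from the difference between the slopes", only this one is
consistent with limb exponents ≈ 1.5 / 0.36 producing an angle ≈ 0.64 rad,
so it is adopted and documented as a derived disambiguation. Intersections
falling outside the observed window span (ln 3 … ln 288) are returned
with an `out_of_range` flag instead of being rejected; the cohort pipeline
maps flagged values to missing, because a near-parallel limb pair can
place its intersection arbitrarily far away (including at numerical
infinity) and such values are estimator artefacts, not physiology.

## Glycemic covariates

Mean, sample SD (n−1) and CV = 100·SD/mean are the conventional
sequence-blind summaries. MAGE is computed in its classical form: turning
points of the raw trace (no pre-smoothing; plateaus collapse to their
first sample), amplitudes between successive alternating extrema, a
qualifying threshold of one within-day SD, and averaging in the direction
of the first qualifying excursion. With no qualifying excursion MAGE is
reported as missing, never zero. MAGE is translation invariant and scale
equivariant, which the property tests exercise.

## Synthetic traces

A generated 24-h trace is baseline + circadian sinusoid + meal train +
fast regulatory component + sensor noise, clipped to the sensor range
2.2–22.2 mmol/L (with a warning) only in pathological parameter regimes.
Defaults describe an at-risk, non-diabetic population:

| parameter | default | rationale |
|---|---|---|
| baseline | 5.5 mmol/L | normal-range mean interstitial glucose |
| meal times | 08:00, 13:00, 20:00 | three daily meals |
| meal amplitude | 1.8 mmol/L | non-diabetic postprandial rise |
| meal rise / decay | 30′ / 90′ | difference-of-exponentials excursion ~2 h long |
| circadian amplitude | 0.3 mmol/L | dawn-phenomenon-scale drift, trough ~03:00 |
| ou_tau_minutes | 40′ | fast-regulation relaxation time |
| ou_sigma | 0.5 mmol/L | stationary SD of the fast component |
| noise_sd | 0.05 mmol/L | white residual of device-filtered output |

These combine to a within-day SD of ~0.8–0.9 mmol/L, the scale observed
in at-risk cohorts.

The fast component deserves its own paragraph. It is a *second-order*
relaxation process: white noise passed through two cascaded exponential
(discrete AR(1)) filters with a common pole, normalized analytically to
stationary SD `ou_sigma` (stationary variance of the double-pole cascade:
(1+ρ²)/(1−ρ²)³ for unit white input). A first-order Ornstein–Uhlenbeck
process was evaluated first and rejected on measurement: its log–log
scaling break is spread over more than a decade and sits 3–5× above the
relaxation time, so for timescales beyond ~1 h the break leaves the span
the 16-window two-limb estimator can represent within a single 24-h trace,
and the detected crossover stops tracking the timescale (it was
non-monotone over 20–160 min in 50-seed median). The second filtering
stage makes the path differentiable at short lags — as device-filtered
interstitial glucose is, and as the steep observed short-window exponents
(≈ 1–1.5) require — and the break sharp. The internal stage timescale is
`ou_tau_minutes / 2`, chosen so the *induced crossover* lands near
`ou_tau_minutes` itself; with this construction the detected-crossover
median increases strictly over timescales 20 → 160 min, the package's
central recovery property. Burn-in of 1024 samples precedes the retained
288 so the filters start effectively stationary.

What the generator does *not* emulate: glucose–insulin feedback dynamics
(no Bergman-style ODEs), meal-size and meal-time variability, sensor
dropout and compression artefacts, day-to-day nonstationarity, or skewed
glucose distributions. Passing recovery tests on these traces therefore
demonstrates that the estimator tracks a known correlation timescale
embedded in realistic amplitude structure — not that it is unbiased on
real patient data.

## Synthetic cohorts

Each patient's timescale is drawn log-uniformly over 20–120 min; traces
use per-patient substreams of a single seed (`default_rng([seed, i])`), so
patient i's data never depend on cohort size or order. The diabetes-onset
hazard is exponential with
`baseline_hazard · exp(hazard_link · z) / E[exp(hazard_link · z)]`, where
z is the log-timescale standardized against its sampling distribution and
the closed-form normalizer (sinh(a√3)/(a√3) for uniform z) makes
`baseline_hazard` the cohort-average rate regardless of link strength.
Onset is recorded at the first 6-monthly visit after the latent event;
follow-up otherwise ends at a per-patient administrative visit drawn
uniformly from {6, 12, 18, 24, 30} months (mean 18). Visit-grid rounding
produces tied event times on purpose — the tie regime the Breslow
likelihood is meant for.

Two calibration choices: `baseline_hazard = 0.067`/year makes the
*observed* crude incidence (after grid rounding and censoring losses)
come out near 58 events per 1000 patient-years, i.e. ~18 events in a
206-patient cohort over ~1.5 years; and `hazard_link = 1.5` per SD of
log-timescale yields, after the attenuation introduced by estimating the
crossover from a single noisy trace (corr ≈ 0.45 between detected
crossover and latent timescale), an observed per-minute coefficient on
the detected crossover of the order 0.01 — the magnitude regime the
method is intended to flag — with ≥ 80% power at 500 patients.

## Survival stage

The Cox model is fitted from the partial likelihood directly, not through
a survival library. Ties are handled by Breslow (full risk set shared by
tied events), the natural companion to visit-grid diagnosis times.
Covariates are standardized internally for conditioning; coefficients,
standard errors (inverse observed information), Wald z and two-sided p are
reported on the original scale. Newton–Raphson starts at β = 0 with
step-halving, converges on gradient ∞-norm < 1e−9 within 50 iterations,
and reports monotone likelihood (separation) or non-convergence via a
diagnostic rather than silently. Records with a missing covariate are
excluded listwise with a logged count. Degenerate designs (constant or
collinear columns) raise. An independent implementation (lifelines) is
used in the tests as a cross-check on tie-free data, where Efron and
Breslow coincide; the two agree to 1e−6 in coefficients and standard
errors and ~1e−10 in log-likelihood.

Incidence is the crude rate 1000·events/(patients·mean follow-up years).
Significance is read at two-sided 0.05, with 0.05–0.10 reportable as a
trend.

## Problem sizes in the test suite

Simulation-backed tests use 50 seeds per timescale for crossover
recovery, 200 replicates at n = 500 for the type-I error of the Cox Wald
test, 20 replicates at n = 1000 for coefficient recovery, and 20
replicates of 500-patient cohorts for end-to-end power; the whole suite
runs in well under a minute on one core, and `scripts/acceptance.py` in a
few seconds.

## Known limitations

- The two-limb fit cannot place a break beyond the 11th curve point
  (180 min window); very delayed crossovers are extrapolated from the limb
  intersection and flagged when outside the observed span.
- The crossover estimate from a single 24-h trace is noisy (IQR of ~60–80
  min at fixed timescale); cohort-level associations are attenuated
  accordingly, and per-patient values should not be over-read clinically.
- MAGE follows one (the original ascending-direction) of several variants
  in circulation; implementations differ in smoothing and direction rules.
- The incidence and hazard calibrations are tied to the default follow-up
  design; changing the visit grid changes the observed event yield.
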