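"""Synthetic CGM traces and cohorts with known ground truth.

A generated 24-hour trace is the sum of
  * a constant baseline glucose level,
  * a circadian sinusoid (trough in the early morning),
  * a meal pulse train (one difference-of-exponentials excursion per meal),
  * a smooth mean-reverting stochastic component standing in for the fast
    insulin-driven counter-regulation, whose relaxation timescale is the
    quantity the crossover analysis should recover, and
  * i.i.d. Gaussian measurement noise.

The fast component is a second-order relaxation process: white noise
passed twice through an exponential filter (two cascaded AR(1) stages with
a common pole), normalized to a chosen stationary SD.  A single
first-order Ornstein-Uhlenbeck stage produces a scaling break that is too
gradual, and located too far above its relaxation time, for the 16-window
two-limb estimator to place reproducibly within a single 24-h trace; the
second filtering stage makes the trace differentiable at short lags (as
device-filtered interstitial glucose is) and the break sharp.  The
internal stage timescale is ``ou_tau_minutes / 2``, which places the
induced log-log break near ``ou_tau_minutes`` itself.

The relaxation timescale controls where the short-window scaling regime
ends, so longer ``ou_tau_minutes`` shifts the detected crossover to larger
windows — a sluggish counter-regulation delays the crossover.  A generated
cohort links each patient's timescale to an exponential diabetes-onset
hazard on the log scale, with visit-grid censoring, so the survival stage
can be tested end to end against a known effect.

Default magnitudes target an at-risk, non-diabetic population: baseline
5.5 mmol/L, within-day SD of order 0.8 mmol/L, and about 58 events per
1000 patient-years at the default hazard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime

import numpy as np
from scipy.signal import lfilter

from .preprocess import DT_MINUTES, SAMPLES_PER_DAY, GlucoseSeries

#: physiological sensor range, mmol/L (40-400 mg/dL)
CLIP_RANGE = (2.2, 22.2)

_DEFAULT_START = datetime(2016, 1, 2, 8, 0)


@dataclass
class GeneratorParams:
    """Parameters of one synthetic 24-h trace (concentrations in mmol/L)."""

    baseline: float = 5.5
    ou_tau_minutes: float = 40.0
    ou_sigma: float = 0.5
    meal_times: tuple = (480.0, 780.0, 1200.0)  # minutes of day: 08h, 13h, 20h
    meal_amplitude: float = 1.8
    meal_rise_minutes: float = 30.0
    meal_decay_minutes: float = 90.0
    circadian_amplitude: float = 0.3
    noise_sd: float = 0.05
    start_hour: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        for name in ("ou_tau_minutes", "meal_rise_minutes", "meal_decay_minutes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("ou_sigma", "meal_amplitude", "circadian_amplitude", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.meal_rise_minutes >= self.meal_decay_minutes:
            raise ValueError("meal rise time must be shorter than decay time")


@dataclass
class CohortParams:
    """Parameters of a synthetic cohort with a timescale-linked hazard."""

    n_patients: int = 206
    tau_range_minutes: tuple = (20.0, 120.0)  # log-uniform across patients
    hazard_link: float = 1.5  # log-hazard slope per SD of log-timescale
    # cohort-average latent events per patient-year; 0.067 makes the
    # *observed* crude incidence (after visit-grid rounding and censoring)
    # come out near 58 per 1000 patient-years at the default follow-up
    baseline_hazard: float = 0.067
    followup_months_mean: float = 18.0
    admin_censor_months: float = 30.0
    visit_interval_months: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        lo, hi = self.tau_range_minutes
        if not (0 < lo < hi):
            raise ValueError("tau_range_minutes must be an increasing positive pair")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.visit_interval_months <= 0 or self.admin_censor_months < self.visit_interval_months:
            raise ValueError("censoring grid is degenerate")


@dataclass
class CohortPatient:
    """One simulated patient: trace, follow-up, outcome and ground truth."""

    patient_id: int
    series: GlucoseSeries
    followup_months: float
    event: bool
    ou_tau_minutes: float


def _meal_pulse(t_min: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials pulse, normalized to unit peak height."""
    h = np.where(t_min >= 0, np.exp(-t_min / decay) - np.exp(-t_min / rise), 0.0)
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    return h / peak


#: samples discarded so the recursive filters reach stationarity
_BURN_IN = 1024


def _fast_component(rng, n: int, tau_minutes: float, sigma: float, dt: float) -> np.ndarray:
    """Smooth mean-reverting path: white noise through two cascaded
    exponential (AR(1)) stages with common pole, unit-variance normalized.

    The stage timescale is tau/2 so the induced DFA crossover falls near
    ``tau_minutes``; the stationary SD is exactly ``sigma``.
    """
    if sigma == 0.0:
        return np.zeros(n)
    rho = np.exp(-dt / (0.5 * tau_minutes))
    w = rng.standard_normal(n + _BURN_IN)
    y = lfilter([1.0], [1.0, -rho], lfilter([1.0], [1.0, -rho], w))[_BURN_IN:]
    # stationary variance of the double-pole cascade driven by unit white
    # noise: sum_k ((k+1) rho^k)^2 = (1 + rho^2) / (1 - rho^2)^3
    var = (1.0 + rho**2) / (1.0 - rho**2) ** 3
    return sigma * y / np.sqrt(var)


def generate_trace(params: GeneratorParams | None = None, **overrides) -> GlucoseSeries:
    """Generate one deterministic 288-point synthetic glucose trace."""
    if params is None:
        params = GeneratorParams(**overrides)
    elif overrides:
        raise TypeError("pass either params or keyword overrides, not both")
    params.validate()
    rng = np.random.default_rng(params.seed)

    n, dt = SAMPLES_PER_DAY, DT_MINUTES
    t = np.arange(n) * dt  # minutes since window start
    minutes_of_day = params.start_hour * 60.0 + t

    # circadian trough at ~03:00
    circ = params.circadian_amplitude * np.sin(
        2.0 * np.pi * (minutes_of_day - 540.0) / 1440.0
    )

    meals = np.zeros(n)
    for m in params.meal_times:
        # a meal from the previous day can still tail into the window
        for day_shift in (-1440.0, 0.0, 1440.0):
            meals += params.meal_amplitude * _meal_pulse(
                minutes_of_day - (m + day_shift),
                params.meal_rise_minutes,
                params.meal_decay_minutes,
            )

    fast = _fast_component(rng, n, params.ou_tau_minutes, params.ou_sigma, dt)
    noise = params.noise_sd * rng.standard_normal(n)

    values = params.baseline + circ + meals + fast + noise
    lo, hi = CLIP_RANGE
    if np.any(values < lo) or np.any(values > hi):
        warnings.warn("synthetic trace clipped to the sensor range", stacklevel=2)
        values = np.clip(values, lo, hi)

    start = _DEFAULT_START.replace(hour=params.start_hour)
    return GlucoseSeries(values=values, start_time=start, unit="mmol_L")


def generate_cohort(params: CohortParams | None = None, **overrides) -> list[CohortPatient]:
    """Generate a cohort of traces with timescale-linked diabetes onset.

    Each patient's relaxation timescale is drawn log-uniformly over
    ``tau_range_minutes``; the onset hazard is
    ``baseline_hazard * exp(hazard_link * z) / E[exp(hazard_link * z)]``
    with z the standardized log-timescale (standardized against the
    sampling distribution, so one patient's outcome never depends on the
    rest of the cohort).  The normalizing constant makes ``baseline_hazard``
    the cohort-average event rate whatever the link strength, so the
    expected event count stays calibrated when the link is varied.  Onset
    is observed at the first 6-monthly visit after the latent event time;
    follow-up ends at a per-patient administrative censoring visit.
    """
    if params is None:
        params = CohortParams(**overrides)
    elif overrides:
        raise TypeError("pass either params or keyword overrides, not both")
    params.validate()

    lo, hi = params.tau_range_minutes
    log_lo, log_hi = np.log(lo), np.log(hi)
    z_mean = 0.5 * (log_lo + log_hi)
    z_sd = (log_hi - log_lo) / np.sqrt(12.0)
    # E[exp(a z)] for z ~ Uniform(-sqrt(3), sqrt(3)): sinh(a sqrt(3)) / (a sqrt(3))
    a = params.hazard_link * np.sqrt(3.0)
    normalizer = float(np.sinh(a) / a) if a != 0.0 else 1.0

    visit = params.visit_interval_months
    n_visits = int(round(params.admin_censor_months / visit))
    # uniform over the visit grid; symmetric about followup_months_mean
    # when admin_censor = 2*mean - visit (default 30 = 2*18 - 6)

    patients = []
    for i in range(params.n_patients):
        rng = np.random.default_rng([params.seed, i])
        tau = float(np.exp(rng.uniform(log_lo, log_hi)))
        z = (np.log(tau) - z_mean) / z_sd if z_sd > 0 else 0.0
        hazard_per_month = (
            params.baseline_hazard * np.exp(params.hazard_link * z) / normalizer / 12.0
        )

        censor_months = visit * rng.integers(1, n_visits + 1)
        latent_months = rng.exponential(1.0 / hazard_per_month)
        event_visit = visit * np.ceil(latent_months / visit)
        if event_visit <= censor_months:
            followup, event = float(event_visit), True
        else:
            followup, event = float(censor_months), False

        trace_seed = int(rng.integers(0, 2**31 - 1))
        series = generate_trace(
            GeneratorParams(ou_tau_minutes=tau, seed=trace_seed)
        )
        patients.append(
            CohortPatient(
                patient_id=i,
                series=series,
                followup_months=followup,
                event=event,
                ou_tau_minutes=tau,
            )
        )
    return patients
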