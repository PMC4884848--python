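"""Non-integrated detrended fluctuation analysis of 24-h glucose traces.

The fluctuation function is computed directly on the glucose series (no
cumulative-sum pre-treatment by default): the series is partitioned into
non-overlapping windows of n points, an ordinary least-squares line is
fitted within each window, and

    F(n) = sqrt( (1/N) * sum_k (y_k - yhat_n(k))^2 )

is the root-mean-square residual over all N points.  Repeating this over a
fixed windowing sequence whose every member divides N = 288 yields a 16-point
log-log curve; its overall slope is the global scaling exponent, and the
two-limb piecewise fit of :mod:`cgmdfa.crossover` locates the crossover.

Cumulative-sum pre-treatment (the conventional random-walk profile) is
retained as an option for sensitivity comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocess import GlucoseSeries

#: window sizes, in points, used for the 16-point fluctuation curve;
#: every entry divides 288, so windows tile the series exactly
WINDOW_POINTS = (3, 4, 6, 8, 9, 12, 16, 18, 24, 32, 36, 48, 72, 96, 144, 288)


@dataclass
class IntegratedSeries:
    """Cumulative deviations y(k) = sum_{i<=k} (G_i - mean(G))."""

    values: np.ndarray
    source_mean: float


@dataclass
class FluctuationCurve:
    """The (window size, F(n)) pairs of a DFA run, with log-log coordinates.

    ``valid`` marks points with F(n) > 0; log coordinates are NaN elsewhere
    (F(n) = 0 only for degenerate, e.g. exactly linear, input).
    """

    window_points: np.ndarray
    fn: np.ndarray
    dt_minutes: float = 5.0

    def __post_init__(self) -> None:
        self.window_points = np.asarray(self.window_points, dtype=int)
        self.fn = np.asarray(self.fn, dtype=float)
        if self.window_points.shape != self.fn.shape:
            raise ValueError("window_points and fn differ in shape")
        if np.any(self.fn < 0):
            raise ValueError("fluctuation values must be non-negative")

    @property
    def window_minutes(self) -> np.ndarray:
        return self.window_points * self.dt_minutes

    @property
    def valid(self) -> np.ndarray:
        return self.fn > 0

    @property
    def log_x(self) -> np.ndarray:
        return np.log(self.window_points.astype(float))

    @property
    def log_y(self) -> np.ndarray:
        out = np.full(self.fn.shape, np.nan)
        out[self.valid] = np.log(self.fn[self.valid])
        return out

    def __len__(self) -> int:
        return len(self.window_points)


def _values(series) -> np.ndarray:
    if isinstance(series, (GlucoseSeries, IntegratedSeries)):
        return np.asarray(series.values, dtype=float)
    return np.asarray(series, dtype=float)


def integrate(series) -> IntegratedSeries:
    """Cumulative-sum profile of deviations from the series mean.

    The last element is zero up to rounding (the deviations telescope).
    """
    x = _values(series)
    if x.size < 2:
        raise ValueError("need at least 2 points to integrate")
    mean = float(x.mean())
    return IntegratedSeries(values=np.cumsum(x - mean), source_mean=mean)


def fluctuation_function(series, window_points: int) -> float:
    """Root-mean-square residual around per-window OLS lines.

    The series is split into N / n consecutive non-overlapping windows of
    ``window_points`` samples; a straight line is fitted to each window by
    ordinary least squares against the within-window index, and the RMS of
    the residuals over all N points is returned.

    ``window_points`` must divide the series length and be at least 3 (a
    line through two points has zero residual by construction).
    """
    y = _values(series)
    n = int(window_points)
    N = y.size
    if n < 3:
        raise ValueError("window must contain at least 3 points")
    if N % n != 0:
        raise ValueError(f"window size {n} does not divide series length {N}")

    windows = y.reshape(N // n, n)
    t = np.arange(n, dtype=float)
    t_c = t - t.mean()
    denom = float(t_c @ t_c)
    slopes = windows @ t_c / denom
    resid = windows - windows.mean(axis=1, keepdims=True) - slopes[:, None] * t_c
    return float(np.sqrt(np.mean(resid**2)))


def fluctuation_curve(
    series,
    integrate_first: bool = False,
    window_points: Sequence[int] = WINDOW_POINTS,
    dt_minutes: float | None = None,
) -> FluctuationCurve:
    """Fluctuation function over the full windowing sequence.

    Parameters
    ----------
    series : GlucoseSeries or array-like
        The 24-h glucose trace (or any uniformly sampled series whose
        length every window size divides).
    integrate_first : bool
        Apply the cumulative-sum pre-treatment before detrending.  The
        main analysis mode is ``False`` (detrending the raw series).
    window_points : sequence of int
        Window sizes in points; defaults to the 16-member sequence.
    """
    if dt_minutes is None:
        dt_minutes = getattr(series, "dt_minutes", 5.0)
    y = _values(series)
    if integrate_first:
        y = integrate(y).values
    fn = np.array([fluctuation_function(y, n) for n in window_points])
    # residuals at machine precision relative to the signal are degenerate
    # (an exactly linear series leaves rounding dust, not fluctuation)
    fn[fn <= 1e-12 * max(1.0, float(np.abs(y).max()))] = 0.0
    if np.any(fn == 0):
        warnings.warn(
            "fluctuation is exactly zero for some window sizes "
            "(degenerate input); those points are excluded from the "
            "log-log coordinates",
            stacklevel=2,
        )
    return FluctuationCurve(
        window_points=np.asarray(window_points, dtype=int),
        fn=fn,
        dt_minutes=dt_minutes,
    )


def global_dfa(curve: FluctuationCurve) -> float:
    """OLS slope of log F(n) against log n over all valid curve points.

    This is the whole-series scaling exponent, ignoring any crossover.
    """
    m = curve.valid
    if m.sum() < 2:
        raise ValueError("need at least 2 valid log-log points")
    slope, _ = np.polyfit(curve.log_x[m], curve.log_y[m], 1)
    return float(slope)
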