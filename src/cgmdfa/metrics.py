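"""Conventional glycemic-variability summaries: mean, SD, CV and MAGE.

These are the standard covariates a CGM analysis adjusts for.  MAGE (mean
amplitude of glycaemic excursions) averages the peak-to-nadir amplitudes of
excursions larger than one within-day standard deviation, counted in one
consistent direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocess import GlucoseSeries


@dataclass
class GlycemicSummary:
    mean_glucose: float
    sd_glucose: float
    cv_percent: float
    mage: float  # NaN when no qualifying excursion exists


def _values(series) -> np.ndarray:
    if isinstance(series, GlucoseSeries):
        return series.values
    return np.asarray(series, dtype=float)


def summary_stats(series) -> GlycemicSummary:
    """Arithmetic mean, sample SD (n-1 denominator) and CV = 100*SD/mean."""
    x = _values(series)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return GlycemicSummary(
        mean_glucose=mean,
        sd_glucose=sd,
        cv_percent=100.0 * sd / mean,
        mage=mage(x),
    )


def mage(series) -> float:
    """Mean amplitude of glycaemic excursions.

    Turning points of the raw trace are located (no smoothing); the
    amplitudes between successive extrema that exceed one within-day sample
    SD qualify, and their mean is taken in the direction of the first
    qualifying excursion.  Returns NaN when no excursion qualifies
    (e.g. a constant trace).
    """
    x = _values(series)
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return math.nan
    extrema = _turning_points(x)
    amps = np.diff(x[extrema])  # signed amplitude between successive extrema
    qualifying = amps[np.abs(amps) > sd]
    if qualifying.size == 0:
        return math.nan
    direction = np.sign(qualifying[0])
    same_dir = qualifying[np.sign(qualifying) == direction]
    return float(np.mean(np.abs(same_dir)))


def _turning_points(x: np.ndarray) -> np.ndarray:
    """Indices of alternating local extrema, endpoints included.

    Plateaus are collapsed to their first sample so consecutive extrema
    strictly alternate in direction.
    """
    # drop repeats so sign changes of the diff locate extrema
    keep = np.concatenate(([True], np.diff(x) != 0))
    idx = np.flatnonzero(keep)
    xs = x[idx]
    if xs.size < 2:
        return idx[:1]
    d = np.sign(np.diff(xs))
    interior = np.flatnonzero(d[1:] != d[:-1]) + 1
    return idx[np.concatenate(([0], interior, [xs.size - 1]))]
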