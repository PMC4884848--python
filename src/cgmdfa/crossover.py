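"""Two-limb piecewise regression of the log-log fluctuation curve.

The 16-point log-log curve is fitted with every admissible pair of straight
limbs: the first limb over points 1..k and the second over points k+1..16,
for k = 4, 5, ..., 11.  Each pair gets a combined weighted R^2 (the
point-count-weighted mean of the two limbs' R^2) and the best pair is kept.
The limb slopes are the short- and long-window scaling exponents (dfa1,
dfa2); the abscissa of the limb intersection, converted to minutes, is the
crossover point, and arctan(slope1) - arctan(slope2) is the crossover angle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dfa import FluctuationCurve

#: log-window-size span of the default curve, for the out-of-range flag
_DEFAULT_RANGE = (np.log(3.0), np.log(288.0))


class NoCrossoverError(ValueError):
    """The two limbs are parallel; the intersection is undefined."""


@dataclass
class PiecewiseFit:
    """A two-limb fit of a log-log fluctuation curve at a given split.

    Attributes
    ----------
    split_index : int
        k: the first limb covers curve points 1..k (1-based), the second
        covers k+1..n.
    slope1, slope2 : float
        Limb slopes: the short-window (dfa1) and long-window (dfa2)
        scaling exponents.
    intercept1, intercept2 : float
        Limb intercepts in log-log coordinates.
    r2_combined : float
        Point-count-weighted mean of the two limbs' R^2.
    crossover_x : float
        Abscissa of the limb intersection, in log(points per window);
        NaN when the limbs are parallel.
    crossover_minutes : float
        dt_minutes * exp(crossover_x).
    angle_rad : float
        arctan(slope1) - arctan(slope2); positive when the short-window
        limb is steeper.
    out_of_range : bool
        True when crossover_x falls outside the observed window span.
    """

    split_index: int
    slope1: float
    slope2: float
    intercept1: float
    intercept2: float
    r2_combined: float
    crossover_x: float = np.nan
    crossover_minutes: float = np.nan
    angle_rad: float = np.nan
    out_of_range: bool = False


def candidate_splits(
    n_points: int = 16, min_first: int = 4, min_second: int = 5
) -> list[int]:
    """Admissible split indices: first limb >= min_first points, second
    limb >= min_second.  For the default 16-point curve: [4, 5, ..., 11]."""
    if n_points < min_first + min_second:
        raise ValueError(
            f"curve of {n_points} points is too short for limbs of "
            f">= {min_first} and >= {min_second} points"
        )
    return list(range(min_first, n_points - min_second + 1))


def _limb_ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and R^2 of one limb by ordinary least squares."""
    if len(x) < 2:
        raise ValueError("a limb needs at least 2 valid points")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_res = float(np.sum((y - slope * x - intercept) ** 2))
    ss_tot = float(np.sum((y - ym) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res <= 1e-24 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return slope, intercept, r2


def fit_split(curve: FluctuationCurve, k: int) -> PiecewiseFit:
    """Fit the limb pair (points 1..k | k+1..n) at a fixed split index.

    Invalid curve points (F(n) = 0) are dropped from their limb; each limb
    must retain at least two points.
    """
    x, y, valid = curve.log_x, curve.log_y, curve.valid
    m1, m2 = valid[:k], valid[k:]
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"split {k} leaves a limb with < 2 valid points")
    s1, b1, r21 = _limb_ols(x[:k][m1], y[:k][m1])
    s2, b2, r22 = _limb_ols(x[k:][m2], y[k:][m2])
    r2c = (n1 * r21 + n2 * r22) / (n1 + n2)
    fit = PiecewiseFit(
        split_index=k,
        slope1=s1,
        slope2=s2,
        intercept1=b1,
        intercept2=b2,
        r2_combined=r2c,
        angle_rad=angle_of_slopes(s1, s2),
    )
    if not _parallel(s1, s2):
        fit = _with_crossover(fit, curve.dt_minutes)
    return fit


def _parallel(s1: float, s2: float) -> bool:
    # slopes equal up to float noise: the intersection is meaningless
    return abs(s1 - s2) <= 1e-12 * max(1.0, abs(s1), abs(s2))


def best_fit(curve: FluctuationCurve) -> PiecewiseFit:
    """Exhaustively evaluate all candidate splits; keep the pair with the
    highest combined weighted R^2, ties broken toward the smaller split."""
    best = None
    for k in candidate_splits(len(curve)):
        fit = fit_split(curve, k)
        if best is None or fit.r2_combined > best.r2_combined:
            best = fit
    return best


def _with_crossover(fit: PiecewiseFit, dt_minutes: float) -> PiecewiseFit:
    x = (fit.intercept2 - fit.intercept1) / (fit.slope1 - fit.slope2)
    lo, hi = _DEFAULT_RANGE
    with np.errstate(over="ignore"):  # near-parallel limbs: inf, flagged below
        minutes = dt_minutes * float(np.exp(x))
    return replace(
        fit,
        crossover_x=x,
        crossover_minutes=minutes,
        out_of_range=not (lo <= x <= hi),
    )


def crossover_of(fit: PiecewiseFit, dt_minutes: float = 5.0) -> float:
    """Crossover point in minutes: dt * exp(x) at the limb intersection
    x = (intercept2 - intercept1) / (slope1 - slope2).

    Raises :class:`NoCrossoverError` when the limbs are parallel.  A
    crossover outside the observed window span is returned as-is; the
    ``out_of_range`` flag on the fit marks it.
    """
    if _parallel(fit.slope1, fit.slope2):
        raise NoCrossoverError("no crossover: parallel limbs")
    x = (fit.intercept2 - fit.intercept1) / (fit.slope1 - fit.slope2)
    with np.errstate(over="ignore"):
        return dt_minutes * float(np.exp(x))


def angle_of_slopes(slope1: float, slope2: float) -> float:
    """Angle between two limbs of given slopes, in radians:
    arctan(slope1) - arctan(slope2)."""
    if not (np.isfinite(slope1) and np.isfinite(slope2)):
        raise ValueError("slopes must be finite")
    return float(np.arctan(slope1) - np.arctan(slope2))


def angle_of(fit: PiecewiseFit) -> float:
    """Crossover angle of a fitted limb pair, in radians."""
    return angle_of_slopes(fit.slope1, fit.slope2)
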