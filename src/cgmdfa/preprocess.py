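"""Reading raw CGM exports and selecting a clean 24-hour analysis window.

A continuous glucose monitor samples interstitial glucose every 5 minutes
for about 3 days.  The analysis operates on a single clean 24-hour block of
288 samples.  The preferred block starts at 08:00 the morning after the
recording begins (to skip the in-clinic insertion hours); short gaps of at
most two consecutive missing samples are linearly interpolated, and a block
containing any longer gap is inadmissible.  If no admissible 24-hour block
exists anywhere in the trace the recording is unsuitable.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, time, timedelta

import numpy as np
import pandas as pd

#: samples per 24-hour window at 5-minute spacing
SAMPLES_PER_DAY = 288
#: nominal sampling interval in minutes
DT_MINUTES = 5.0

VALID_UNITS = ("mmol_L", "mg_dL")


class UnsuitableTraceError(ValueError):
    """No admissible 24-hour window exists in the trace."""


@dataclass
class RawTrace:
    """A raw CGM recording on a uniform 5-minute grid, gaps kept as NaN.

    Parameters
    ----------
    timestamps : pandas.DatetimeIndex
        Sample times, strictly increasing, on a uniform grid.
    glucose : numpy.ndarray
        Glucose concentrations; missing samples are ``nan``.
    unit : str
        ``"mmol_L"`` or ``"mg_dL"``.
    device_interval : float
        Sampling period in minutes (expected 5).
    """

    timestamps: pd.DatetimeIndex
    glucose: np.ndarray
    unit: str
    device_interval: float = DT_MINUTES

    def __post_init__(self) -> None:
        self.glucose = np.asarray(self.glucose, dtype=float)
        if len(self.timestamps) != len(self.glucose):
            raise ValueError("timestamps and glucose differ in length")
        if len(self.timestamps) > 1:
            diffs = np.diff(self.timestamps.view("int64"))
            if np.any(diffs <= 0):
                raise ValueError("timestamps must be strictly increasing")
        present = self.glucose[np.isfinite(self.glucose)]
        if np.any(present <= 0):
            raise ValueError("glucose values must be positive")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}")

    def __len__(self) -> int:
        return len(self.glucose)


@dataclass
class GlucoseSeries:
    """A gap-free 24-hour glucose trace: 288 samples at 5-minute spacing."""

    values: np.ndarray
    start_time: datetime
    unit: str
    dt_minutes: float = DT_MINUTES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (SAMPLES_PER_DAY,):
            raise ValueError(
                f"GlucoseSeries requires exactly {SAMPLES_PER_DAY} values, "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GlucoseSeries values must all be finite")
        if self.dt_minutes * SAMPLES_PER_DAY != 1440:
            raise ValueError("dt_minutes x 288 must span 24 h")

    def __len__(self) -> int:
        return SAMPLES_PER_DAY

    def to_frame(self) -> pd.DataFrame:
        idx = pd.date_range(self.start_time, periods=len(self), freq=f"{int(self.dt_minutes)}min")
        return pd.DataFrame({"timestamp": idx, "glucose": self.values})


def read_cgm(path, unit: str = "mmol_L") -> RawTrace:
    """Read a delimited CGM export into a :class:`RawTrace`.

    The file must have a ``timestamp`` column (ISO-8601) and a ``glucose``
    column; missing glucose is an empty field or ``NA``.  Timestamp jitter
    up to 1 second is snapped to the 5-minute grid; larger deviations from
    uniform sampling are an error.
    """
    if unit not in VALID_UNITS:
        raise ValueError(f"unit must be one of {VALID_UNITS}")
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    if "timestamp" not in cols or "glucose" not in cols:
        raise ValueError("file must have 'timestamp' and 'glucose' columns")
    try:
        ts = pd.to_datetime(df[cols["timestamp"]], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable timestamp in {path}: {exc}") from exc
    glucose = pd.to_numeric(df[cols["glucose"]], errors="coerce").to_numpy(float)
    bad = np.isfinite(glucose) & (glucose <= 0)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # 1-based, after header
        raise ValueError(f"non-positive glucose value at line {line}")
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValueError("timestamps are not strictly increasing")

    # snap <=1 s jitter onto the uniform grid anchored at the first sample
    dt = timedelta(minutes=DT_MINUTES)
    offsets = (ts - ts.iloc[0]) / dt
    snapped = offsets.round()
    jitter_s = np.abs((offsets - snapped) * DT_MINUTES * 60.0)
    if np.any(jitter_s > 1.0):
        line = int(np.flatnonzero(jitter_s > 1.0)[0]) + 2
        raise ValueError(
            f"non-uniform sampling beyond 1-second jitter at line {line}"
        )
    if snapped.duplicated().any():
        raise ValueError("two samples snap to the same grid slot")
    grid = pd.DatetimeIndex(ts.iloc[0] + snapped * dt)
    return RawTrace(timestamps=grid, glucose=glucose, unit=unit)


def interpolate_gaps(values, max_gap: int = 2) -> np.ndarray:
    """Fill short missing runs by linear interpolation.

    Every missing run must have length <= ``max_gap`` and the first and last
    samples must be present (no extrapolation).  Present values are returned
    unchanged; the operation is idempotent on gap-free input.
    """
    values = np.asarray(values, dtype=float)
    missing = ~np.isfinite(values)
    if not missing.any():
        return values.copy()
    if missing[0] or missing[-1]:
        raise ValueError("cannot interpolate a missing endpoint")
    run = _longest_missing_run(missing)
    if run > max_gap:
        raise ValueError(
            f"missing run of length {run} exceeds max_gap={max_gap}"
        )
    idx = np.arange(len(values))
    out = values.copy()
    out[missing] = np.interp(idx[missing], idx[~missing], values[~missing])
    return out


def _longest_missing_run(missing: np.ndarray) -> int:
    longest = cur = 0
    for m in missing:
        cur = cur + 1 if m else 0
        longest = max(longest, cur)
    return longest


def select_window(
    trace: RawTrace,
    preferred_start_hour: int = 8,
    max_gap: int = 2,
) -> GlucoseSeries:
    """Select the first admissible 24-hour block of a raw trace.

    The preferred block starts at ``preferred_start_hour`` (08:00 by
    default) on the day after the trace begins.  A block is admissible when
    every run of consecutive missing values has length <= ``max_gap`` and
    its endpoints are present.  If the preferred block is inadmissible the
    candidate start slides forward in 5-minute steps to the end of the
    trace, then over the earlier starts from the beginning of the trace.

    Raises
    ------
    UnsuitableTraceError
        If no 24-hour block anywhere in the trace satisfies the gap rule.
    """
    n = len(trace)
    if n < SAMPLES_PER_DAY:
        raise UnsuitableTraceError("trace shorter than 24 h")

    first = trace.timestamps[0]
    preferred = datetime.combine(
        (first + timedelta(days=1)).date(), time(hour=preferred_start_hour)
    )
    dt = timedelta(minutes=trace.device_interval)
    pref_idx = int(round((preferred - first.to_pydatetime()) / dt))
    pref_idx = min(max(pref_idx, 0), n - SAMPLES_PER_DAY)

    order = list(range(pref_idx, n - SAMPLES_PER_DAY + 1)) + list(range(0, pref_idx))
    for start in order:
        block = trace.glucose[start : start + SAMPLES_PER_DAY]
        if _admissible(block, max_gap):
            return GlucoseSeries(
                values=interpolate_gaps(block, max_gap=max_gap),
                start_time=trace.timestamps[start].to_pydatetime(),
                unit=trace.unit,
                dt_minutes=trace.device_interval,
            )
    raise UnsuitableTraceError("unsuitable: no admissible 24-h window")


def _admissible(block: np.ndarray, max_gap: int) -> bool:
    missing = ~np.isfinite(block)
    if missing[0] or missing[-1]:
        return False
    return _longest_missing_run(missing) <= max_gap
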