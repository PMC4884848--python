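import sys
from datetime import datetime
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from cgmdfa import GlucoseSeries


@pytest.fixture
def make_series():
    """Wrap a 288-vector as a GlucoseSeries starting 08:00."""

    def _make(values, unit="mmol_L"):
        return GlucoseSeries(
            values=np.asarray(values, dtype=float),
            start_time=datetime(2016, 1, 2, 8, 0),
            unit=unit,
        )

    return _make


@pytest.fixture
def write_cgm_csv(tmp_path):
    """Write (timestamp, glucose) rows to a temp CSV; None means missing."""

    def _write(rows, name="trace.csv"):
        path = tmp_path / name
        lines = ["timestamp,glucose"]
        for ts, g in rows:
            lines.append(f"{ts.isoformat()},{'' if g is None else g}")
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


def grid_rows(start, n, glucose, gaps=()):
    """n rows at 5-min spacing from start; indices in `gaps` are missing."""
    from datetime import timedelta

    rows = []
    for i in range(n):
        g = None if i in gaps else (glucose(i) if callable(glucose) else glucose)
        rows.append((start + timedelta(minutes=5 * i), g))
    return rows
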