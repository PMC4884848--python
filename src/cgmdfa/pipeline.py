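"""End-to-end per-patient analysis: trace -> fluctuation curve -> crossover
fit -> glycemic summaries -> a flat covariate row ready for survival
modelling."""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .crossover import best_fit
from .dfa import fluctuation_curve, global_dfa
from .metrics import summary_stats
from .preprocess import GlucoseSeries
from .survival import CohortRecord


def analyze_series(series: GlucoseSeries, integrate_first: bool = False) -> dict:
    """All per-patient covariates the survival model consumes."""
    curve = fluctuation_curve(series, integrate_first=integrate_first)
    fit = best_fit(curve)
    stats = summary_stats(series)
    return {
        "crossover_minutes": fit.crossover_minutes,
        "angle_rad": fit.angle_rad,
        "dfa1": fit.slope1,
        "dfa2": fit.slope2,
        "global_dfa": global_dfa(curve),
        "split_index": fit.split_index,
        "r2_combined": fit.r2_combined,
        "crossover_out_of_range": fit.out_of_range,
        "mean_glucose": stats.mean_glucose,
        "sd_glucose": stats.sd_glucose,
        "cv_percent": stats.cv_percent,
        "mage": stats.mage,
    }


def cohort_records(
    patients: Iterable,
    integrate_first: bool = False,
    drop_out_of_range: bool = True,
) -> list[CohortRecord]:
    """Analyze each simulated patient and wrap the result for the Cox fit.

    Crossovers flagged as falling outside the observed window span are
    implausible limb intersections (near-parallel limbs can place them
    anywhere); with ``drop_out_of_range`` they are recorded as missing, so
    the survival stage excludes those patients listwise.
    """
    records = []
    for pat in patients:
        cov = analyze_series(pat.series, integrate_first=integrate_first)
        if drop_out_of_range and cov["crossover_out_of_range"]:
            cov["crossover_minutes"] = float("nan")
        records.append(
            CohortRecord(
                patient_id=pat.patient_id,
                covariates=cov,
                followup_time=pat.followup_months,
                event=pat.event,
            )
        )
    return records


def records_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {"patient_id": rec.patient_id, **rec.covariates}
        row["followup_months"] = rec.followup_time
        row["event"] = int(rec.event)
        rows.append(row)
    return pd.DataFrame(rows)
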