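"""Inclusion/exclusion cascade and 28-day data truncation.

The analysis cohort is restricted to adults with baseline and ventilation
data available, on their first ICU admission and first ventilation episode,
ventilated for at least 72 hours; chart data beyond day 28 of ventilation
are discarded. Each step's exclusion count is recorded in a
:class:`FilterReport` so a selection flowchart can be reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FilterReport", "apply_inclusion_exclusion", "truncate_to_28_days",
           "MIN_MV_HOURS", "TRUNCATION_DAYS"]

#: minimum ventilation duration retained (inclusive)
MIN_MV_HOURS = 72.0
#: chart data after this many days of ventilation are discarded
TRUNCATION_DAYS = 28.0

_BASELINE_COLS = ("age", "gender", "sofa", "saps2", "outcome_28d")
_REQUIRED_COLS = ("patient_id", "age", "gender", "sofa", "saps2",
                  "mv_start", "mv_end", "outcome_28d")


@dataclass
class FilterReport:
    """Ordered record of the selection cascade: (label, excluded, remaining)."""

    initial: int
    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, label: str, excluded: int, remaining: int) -> None:
        if self.steps and remaining > self.steps[-1][2]:
            raise ValueError("remaining counts must be non-increasing")
        self.steps.append((label, excluded, remaining))

    @property
    def final(self) -> int:
        return self.steps[-1][2] if self.steps else self.initial

    def validate(self) -> None:
        total_excluded = sum(e for _, e, _ in self.steps)
        if self.final != self.initial - total_excluded:
            raise ValueError("final remaining != initial - sum of exclusions")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["criterion", "excluded", "remaining"]
        )


def apply_inclusion_exclusion(
    patients: pd.DataFrame, events: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, FilterReport]:
    """Apply the selection cascade; return filtered tables and the report.

    Steps, in order: baseline data available; ventilation data available
    (at least two chart timepoints); age >= 18; not a second ventilation
    episode; not a second ICU admission; ventilation duration >= 72 h
    (inclusive). Episode/admission indices are read from optional
    ``mv_episode_seq`` / ``icu_admission_seq`` columns (absent = first).
    No chart event survives for an excluded patient.
    """
    missing = [c for c in _REQUIRED_COLS if c not in patients.columns]
    if missing:
        raise ValueError(f"patient table missing required columns: {missing}")
    if not {"patient_id", "timestamp"}.issubset(events.columns):
        raise ValueError("event table must have patient_id and timestamp columns")

    pts = patients.copy()
    report = FilterReport(initial=len(pts))

    def step(label: str, keep: pd.Series) -> None:
        nonlocal pts
        excluded = int((~keep).sum())
        pts = pts[keep]
        report.add(label, excluded, len(pts))

    step("baseline data available",
         pts[list(_BASELINE_COLS)].notna().all(axis=1))

    n_timepoints = (
        events.drop_duplicates(["patient_id", "timestamp"])
        .groupby("patient_id")
        .size()
    )
    step("MV data available (>= 2 chart timepoints)",
         pts["patient_id"].map(n_timepoints).fillna(0).ge(2))

    step("age >= 18", pts["age"] >= 18)

    if "mv_episode_seq" in pts.columns:
        step("first MV episode", pts["mv_episode_seq"].fillna(1) <= 1)
    else:
        report.add("first MV episode", 0, len(pts))
    if "icu_admission_seq" in pts.columns:
        step("first ICU admission", pts["icu_admission_seq"].fillna(1) <= 1)
    else:
        report.add("first ICU admission", 0, len(pts))

    mv_hours = (
        pd.to_datetime(pts["mv_end"]) - pd.to_datetime(pts["mv_start"])
    ).dt.total_seconds() / 3600.0
    step(f"MV duration >= {MIN_MV_HOURS:g} h", mv_hours >= MIN_MV_HOURS)

    report.validate()
    events_f = events[events["patient_id"].isin(pts["patient_id"])].copy()
    return pts.reset_index(drop=True), events_f.reset_index(drop=True), report


def truncate_to_28_days(
    events: pd.DataFrame, patients: pd.DataFrame
) -> pd.DataFrame:
    """Drop chart events recorded strictly after day 28 of ventilation.

    Events at exactly ``mv_start + 28 d`` are kept; no patient is removed.
    """
    cutoff = (
        pd.to_datetime(patients.set_index("patient_id")["mv_start"])
        + pd.Timedelta(days=TRUNCATION_DAYS)
    )
    limit = events["patient_id"].map(cutoff)
    keep = pd.to_datetime(events["timestamp"]) <= limit
    return events[keep.fillna(False) | limit.isna()].reset_index(drop=True)
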