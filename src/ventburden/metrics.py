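"""Chart-series cleaning and per-interval power and energy computation.

Cleaning order: nearest-time imputation, then 1%/99% winsorizing, then
derivation of dynamic driving pressure and dynamic mechanical power.

Formulas (units: pressures cm H2O, RR breaths/min, VT litres):

    dynamic driving pressure  dp = Ppeak - PEEP
    dynamic mechanical power  mp = 0.098 * RR * VT * (Ppeak - 0.5 * dp)   [J/min]
    mechanical energy         E  = mp * interval duration in minutes      [J]

Tidal volume is charted in mL and converted to litres before the power
formula, which puts mp on the familiar clinical scale (cohort medians
around 12 J/min). Each recorded timepoint opens an exposure interval that
lasts until the next recorded timepoint; the final interval is clipped at
``min(mv_end, mv_start + 28 d)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import CHART_VARIABLES

__all__ = [
    "POWER_COEFFICIENT",
    "events_to_wide",
    "impute_missing",
    "winsorize",
    "clean_chart_events",
    "build_intervals",
    "compute_power",
    "summarize_energy",
]

POWER_COEFFICIENT = 0.098
WINSOR_LIMITS = (1.0, 99.0)  # percentiles


def events_to_wide(events: pd.DataFrame) -> pd.DataFrame:
    """Pivot long-format chart events to one row per (patient, timestamp).

    Missing (patient, timestamp, variable) cells become NaN. The row index
    is sorted by patient then time.
    """
    wide = events.pivot_table(
        index=["patient_id", "timestamp"],
        columns="variable",
        values="value",
        aggfunc="first",
    ).reset_index()
    wide.columns.name = None
    for var in CHART_VARIABLES:
        if var not in wide.columns:
            wide[var] = np.nan
    return (
        wide[["patient_id", "timestamp", *CHART_VARIABLES]]
        .sort_values(["patient_id", "timestamp"], kind="mergesort")
        .reset_index(drop=True)
    )


def _nearest_fill(wide: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Fill NaNs from the nearest-in-time observation of the same patient
    and variable; ties between an equally near earlier and later observation
    go to the earlier one. Cells with no within-patient value stay NaN."""
    out = wide.copy()
    t = pd.to_datetime(out["timestamp"]).astype("int64")
    grp = out.groupby("patient_id", sort=False)
    for col in columns:
        valid = out[col].notna()
        t_obs = t.where(valid)
        prev_v = grp[col].ffill()
        prev_t = t_obs.groupby(out["patient_id"], sort=False).ffill()
        next_v = grp[col].bfill()
        next_t = t_obs.groupby(out["patient_id"], sort=False).bfill()
        d_prev = (t - prev_t).abs()
        d_next = (next_t - t).abs()
        # earlier wins ties; either side may be missing
        use_prev = prev_v.notna() & (next_v.isna() | (d_prev <= d_next))
        filled = prev_v.where(use_prev, next_v)
        out[col] = out[col].where(valid, filled)
    return out


def impute_missing(events: pd.DataFrame) -> pd.DataFrame:
    """Populate every (patient, timepoint, variable) cell.

    Missing cells take the value at the nearest-in-time available timepoint
    of the same patient and variable (earlier wins ties); a patient with no
    value at all for a variable receives the cohort median for that
    variable. Returns a wide table with columns ppeak/peep/rr/vt.

    Raises ``ValueError`` if a variable is entirely missing cohort-wide.
    """
    wide = events_to_wide(events)
    cols = list(CHART_VARIABLES)
    wide = _nearest_fill(wide, cols)
    for col in cols:
        if wide[col].isna().all():
            raise ValueError(f"variable {col!r} entirely missing cohort-wide")
        if wide[col].isna().any():
            wide[col] = wide[col].fillna(wide[col].median())
    return wide


def winsorize(values: pd.Series | np.ndarray, limits=WINSOR_LIMITS) -> np.ndarray:
    """Clip values below the 1st percentile / above the 99th to those
    percentiles (linear-interpolation quantiles, cohort-wide)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot winsorize an empty array")
    lo, hi = np.nanpercentile(arr, limits)
    return np.clip(arr, lo, hi)


def clean_chart_events(events: pd.DataFrame) -> pd.DataFrame:
    """Impute, winsorize per variable, and resolve Ppeak < PEEP rows.

    A row where the cleaned Ppeak falls below PEEP cannot yield a
    non-negative driving pressure; the pair is treated as missing and
    re-imputed from the nearest valid timepoint (cohort medians as a last
    resort). Any remaining inversion is clamped to zero driving pressure.
    """
    wide = impute_missing(events)
    for col in CHART_VARIABLES:
        wide[col] = winsorize(wide[col])

    bad = wide["ppeak"] < wide["peep"]
    if bad.any():
        wide.loc[bad, ["ppeak", "peep"]] = np.nan
        wide = _nearest_fill(wide, ["ppeak", "peep"])
        for col in ("ppeak", "peep"):
            wide[col] = wide[col].fillna(wide[col].median())
        still = wide["ppeak"] < wide["peep"]
        if still.any():
            wide.loc[still, "peep"] = wide.loc[still, "ppeak"]
    return wide


def compute_power(ppeak, peep, rr, vt_l):
    """Dynamic driving pressure and dynamic mechanical power.

    ``dp = ppeak - peep``; ``mp = 0.098 * rr * vt_l * (ppeak - 0.5 * dp)``
    with VT in litres, giving J/min. Inputs may be scalars or arrays.
    Raises ``ValueError`` if any ppeak < peep (should not survive cleaning).
    """
    ppeak = np.asarray(ppeak, dtype=float)
    peep = np.asarray(peep, dtype=float)
    dp = ppeak - peep
    if np.any(dp < 0):
        raise ValueError("ppeak < peep encountered; clean the series first")
    mp = POWER_COEFFICIENT * np.asarray(rr, float) * np.asarray(vt_l, float) * (
        ppeak - 0.5 * dp
    )
    return dp, mp


def build_intervals(
    clean_wide: pd.DataFrame, patients: pd.DataFrame, truncate_days: float = 28.0
) -> pd.DataFrame:
    """One exposure interval per timepoint, with derived power and energy.

    Each interval spans from its timepoint to the next; the final interval
    spans to ``min(mv_end, mv_start + truncate_days)``. Parameters of an
    interval are those recorded at its start. Zero-length intervals (a
    timepoint exactly at the clipped end) are dropped.

    Returns columns: patient_id, start, duration_min, ppeak, peep, rr,
    vt_ml, dp, mp, energy_j.
    """
    df = clean_wide.sort_values(["patient_id", "timestamp"], kind="mergesort")
    if df.duplicated(["patient_id", "timestamp"]).any():
        raise ValueError("duplicate timestamps within a patient")

    counts = df.groupby("patient_id").size()
    if (counts < 2).any():
        few = counts[counts < 2].index.tolist()
        raise ValueError(f"patients with fewer than 2 timepoints: {few[:5]}")

    pinfo = patients.set_index("patient_id")
    mv_start = df["patient_id"].map(pd.to_datetime(pinfo["mv_start"]))
    mv_end = df["patient_id"].map(pd.to_datetime(pinfo["mv_end"]))
    clip_end = np.minimum(
        mv_end, mv_start + pd.Timedelta(days=truncate_days)
    )

    ts = pd.to_datetime(df["timestamp"])
    next_ts = ts.groupby(df["patient_id"], sort=False).shift(-1)
    end = next_ts.fillna(clip_end)
    duration_min = (end - ts).dt.total_seconds() / 60.0
    if (duration_min < 0).any():
        raise ValueError("non-monotone timestamps or events beyond mv_end")

    dp, mp = compute_power(df["ppeak"], df["peep"], df["rr"], df["vt"] / 1000.0)
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"].to_numpy(),
            "start": ts.to_numpy(),
            "duration_min": duration_min.to_numpy(),
            "ppeak": df["ppeak"].to_numpy(),
            "peep": df["peep"].to_numpy(),
            "rr": df["rr"].to_numpy(),
            "vt_ml": df["vt"].to_numpy(),
            "dp": dp,
            "mp": mp,
        }
    )
    out = out[out["duration_min"] > 0].reset_index(drop=True)
    out["energy_j"] = out["mp"] * out["duration_min"]
    return out


def summarize_energy(intervals: pd.DataFrame) -> pd.DataFrame:
    """Per-patient totals: total mechanical energy (J), total ventilation
    minutes, and whole-course average power ``avg_mp = energy / minutes``."""
    g = intervals.groupby("patient_id")
    total_energy = g["energy_j"].sum()
    total_min = g["duration_min"].sum()
    if (total_min <= 0).any():
        raise ValueError("patient with zero total ventilation duration")
    return pd.DataFrame(
        {
            "patient_id": total_energy.index,
            "total_energy_j": total_energy.to_numpy(),
            "total_mv_min": total_min.to_numpy(),
            "avg_mp": (total_energy / total_min).to_numpy(),
        }
    ).reset_index(drop=True)
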