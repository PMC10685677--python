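"""Odds-ratio-deviation risk surfaces and fitted iso-risk contours.

For every lattice cell the event counts are normalised to events per
patient in each outcome group; the cell OR is the survivor-to-non-survivor
ratio of those averages, and the *deviation* is the cell OR minus the
cohort-wide overall OR. Negative deviation marks duration-intensity
combinations seen disproportionately in non-survivors (-0.1 is read as a
10% mortality-risk increase, -0.2 as 20%). Cells whose non-survivor
average is zero have an undefined OR; they are flagged, excluded from
contour fitting, and rendered neutral.

Contours are located column-by-column (linear interpolation of the first
level crossing along the intensity axis) and smoothed with a constrained
monotone power-law fit ``i(t) = a + b * t**(-c)`` with b, c >= 0, which
reproduces hyperbolic iso-risk fronts exactly and matches the roughly
exponential decay seen in cohort surfaces. A constrained exponential
``a + b * exp(-c t)`` is available as an alternative form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .events import EventCountGrid, GridSpec

__all__ = ["ORGrid", "ContourCurve", "compute_or_grid", "fit_contour",
           "or_grid_to_frame", "contours_to_frame"]

DEFAULT_CONTOUR_LEVELS = (0.0, -0.1, -0.2)


@dataclass
class ORGrid:
    """OR, overall OR and deviation surfaces over a duration-intensity grid."""

    spec: GridSpec
    avg_survivor: np.ndarray
    avg_nonsurvivor: np.ndarray
    or_matrix: np.ndarray
    overall_or: float
    deviation: np.ndarray
    pct_deviation: np.ndarray
    defined: np.ndarray  # bool mask; False where the OR denominator is zero


def compute_or_grid(grid: EventCountGrid, normalized: bool = True) -> ORGrid:
    """Turn an event-count grid into OR and deviation surfaces.

    ``normalized=True`` (default) computes the overall OR from per-patient
    averaged totals, (sum survivor counts / n_survivor) /
    (sum non-survivor counts / n_nonsurvivor), so it is commensurate with
    the cell ORs; ``normalized=False`` uses the raw total-count ratio.
    """
    if grid.n_survivor <= 0 or grid.n_nonsurvivor <= 0:
        raise ValueError("both outcome groups must be non-empty")
    tot_s = grid.counts_survivor.sum()
    tot_ns = grid.counts_nonsurvivor.sum()
    if tot_s == 0 or tot_ns == 0:
        raise ValueError("zero total event counts in a group; overall OR undefined")

    avg_s = grid.counts_survivor / grid.n_survivor
    avg_ns = grid.counts_nonsurvivor / grid.n_nonsurvivor
    defined = avg_ns > 0
    or_matrix = np.full(grid.spec.shape, np.nan)
    np.divide(avg_s, avg_ns, out=or_matrix, where=defined)
    if normalized:
        overall = (tot_s / grid.n_survivor) / (tot_ns / grid.n_nonsurvivor)
    else:
        overall = tot_s / tot_ns
    deviation = or_matrix - overall
    pct = 100.0 * deviation / overall
    return ORGrid(
        spec=grid.spec,
        avg_survivor=avg_s,
        avg_nonsurvivor=avg_ns,
        or_matrix=or_matrix,
        overall_or=float(overall),
        deviation=deviation,
        pct_deviation=pct,
        defined=defined,
    )


@dataclass
class ContourCurve:
    """An iso-deviation contour: raw column crossings plus a monotone fit.

    ``points`` holds one (duration_h, intensity) pair per lattice column
    where the deviation surface crosses ``level``; ``fit_params`` is None
    when fewer than three crossings were available to fit.
    """

    level: float
    points: pd.DataFrame
    fit_params: dict | None = None
    form: str = "power"

    def predict(self, durations) -> np.ndarray:
        """Fitted intensity at the given durations (hours)."""
        if self.fit_params is None:
            raise ValueError("contour has no fitted curve (too few crossings)")
        t = np.asarray(durations, dtype=float)
        a, b, c = (self.fit_params[k] for k in ("a", "b", "c"))
        if self.form == "power":
            return a + b * np.power(t, -c)
        return a + b * np.exp(-c * t)


def _column_crossings(
    or_grid: ORGrid, level: float, mode: str = "absolute"
) -> pd.DataFrame:
    surface = or_grid.deviation if mode == "absolute" else or_grid.pct_deviation
    intens = or_grid.spec.intensities
    rows = []
    for jt, t in enumerate(or_grid.spec.durations):
        col = surface[:, jt]
        ok = or_grid.defined[:, jt]
        idx = np.flatnonzero(ok)
        for lo, hi in zip(idx[:-1], idx[1:]):
            d0, d1 = col[lo] - level, col[hi] - level
            if d0 == 0.0:
                rows.append((t, intens[lo]))
                break
            if d0 * d1 < 0 or d1 == 0.0:
                # linear interpolation between adjacent defined cells
                frac = d0 / (d0 - d1)
                rows.append((t, intens[lo] + frac * (intens[hi] - intens[lo])))
                break  # lowest crossing only
    return pd.DataFrame(rows, columns=["duration_h", "intensity"])


def fit_contour(
    or_grid: ORGrid,
    level: float,
    mode: str = "absolute",
    form: str = "power",
) -> ContourCurve:
    """Locate and fit the iso-deviation contour at ``level``.

    Columns without a crossing contribute no point; if fewer than three
    crossings exist the raw points are returned without a fitted curve.
    """
    if form not in ("power", "exp"):
        raise ValueError(f"unknown contour form {form!r}")
    pts = _column_crossings(or_grid, level, mode)
    curve = ContourCurve(level=level, points=pts, form=form)
    if len(pts) < 3:
        return curve

    t = pts["duration_h"].to_numpy(float)
    y = pts["intensity"].to_numpy(float)
    if form == "power":
        f = lambda t, a, b, c: a + b * np.power(t, -c)
        p0 = (max(y.min(), 0.0), max(y.max() - y.min(), 1e-3), 1.0)
    else:
        f = lambda t, a, b, c: a + b * np.exp(-c * t)
        p0 = (max(y.min(), 0.0), max(y.max() - y.min(), 1e-3), 0.05)
    try:
        popt, _ = curve_fit(
            f, t, y, p0=p0,
            bounds=([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        curve.fit_params = {"a": float(popt[0]), "b": float(popt[1]),
                            "c": float(popt[2])}
    except RuntimeError:
        curve.fit_params = None
    return curve


def or_grid_to_frame(or_grid: ORGrid) -> pd.DataFrame:
    """Long-format export: one row per lattice cell."""
    ii, jt = np.meshgrid(
        np.arange(len(or_grid.spec.intensities)),
        np.arange(len(or_grid.spec.durations)),
        indexing="ij",
    )
    return pd.DataFrame(
        {
            "intensity": or_grid.spec.intensities[ii.ravel()],
            "duration_h": or_grid.spec.durations[jt.ravel()],
            "avg_survivor": or_grid.avg_survivor.ravel(),
            "avg_nonsurvivor": or_grid.avg_nonsurvivor.ravel(),
            "or": or_grid.or_matrix.ravel(),
            "deviation": or_grid.deviation.ravel(),
            "pct_deviation": or_grid.pct_deviation.ravel(),
            "defined": or_grid.defined.ravel(),
        }
    )


def contours_to_frame(contours: list[ContourCurve]) -> pd.DataFrame:
    frames = []
    for c in contours:
        df = c.points.copy()
        df.insert(0, "level", c.level)
        df = df.rename(columns={"intensity": "raw_intensity"})
        df["fitted_intensity"] = (
            c.predict(df["duration_h"]) if c.fit_params is not None else np.nan
        )
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["level", "duration_h", "raw_intensity", "fitted_intensity"]
        )
    return pd.concat(frames, ignore_index=True)
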