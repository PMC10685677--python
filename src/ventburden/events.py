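"""Supra-threshold exposure episodes and the duration-intensity count grid.

An *episode* at intensity threshold I is a maximal run of consecutive
exposure intervals whose dynamic mechanical power is strictly above I; its
duration is the sum of the member interval durations. The lattice cell
(I, t) counts, over all patients in an outcome group, the episodes at
threshold I lasting at least t hours — so one 8-hour episode above
10 J/min contributes to every cell (10, t) with t <= 8.

Episodes are detected independently at every threshold; no nesting
shortcut is used, so the counting path can be checked cell-for-cell
against a naive enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GridSpec", "ExposureEpisode", "EventCountGrid",
           "detect_episodes", "count_events"]


@dataclass(frozen=True)
class GridSpec:
    """The duration-intensity lattice: default 5..30 J/min x 1..72 h."""

    intensities: np.ndarray = field(
        default_factory=lambda: np.arange(5.0, 31.0)
    )
    durations: np.ndarray = field(
        default_factory=lambda: np.arange(1.0, 73.0)
    )

    def __post_init__(self):
        object.__setattr__(self, "intensities", np.asarray(self.intensities, float))
        object.__setattr__(self, "durations", np.asarray(self.durations, float))
        for name in ("intensities", "durations"):
            arr = getattr(self, name)
            if arr.size == 0 or np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be non-empty and strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.intensities), len(self.durations)


@dataclass(frozen=True)
class ExposureEpisode:
    patient_id: str
    intensity_threshold: float
    start: object
    duration_h: float


def _episode_durations(
    mp: np.ndarray, duration_h: np.ndarray, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Durations and start indices of maximal runs with mp strictly above
    the threshold, for one contiguous interval sequence."""
    above = mp > threshold
    edges = np.diff(np.concatenate(([0], above.astype(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    cum = np.concatenate(([0.0], np.cumsum(duration_h)))
    return cum[ends] - cum[starts], starts


def detect_episodes(
    intervals: pd.DataFrame, intensity_threshold: float
) -> list[ExposureEpisode]:
    """Detect supra-threshold episodes in one patient's interval sequence.

    ``intervals`` must be the contiguous, time-ordered sequence for a single
    patient with ``mp`` (J/min) and ``duration_min`` columns. Exceedance is
    strict: an interval exactly at the threshold breaks a run.
    """
    if len(intervals) == 0:
        raise ValueError("empty interval sequence")
    if intervals["patient_id"].nunique() > 1:
        raise ValueError("detect_episodes expects a single patient")
    pid = intervals["patient_id"].iloc[0]
    mp = intervals["mp"].to_numpy(float)
    dur_min = intervals["duration_min"].to_numpy(float)
    durations_min, starts = _episode_durations(mp, dur_min, intensity_threshold)
    start_ts = intervals["start"].to_numpy()
    return [
        ExposureEpisode(pid, float(intensity_threshold), start_ts[s], float(d) / 60.0)
        for d, s in zip(durations_min, starts)
    ]


@dataclass
class EventCountGrid:
    """Per-outcome-group episode counts over the lattice.

    ``counts_survivor[i, t]`` is the number of episodes at intensity
    ``spec.intensities[i]`` with duration >= ``spec.durations[t]`` hours,
    summed over survivors; likewise for non-survivors. Counts are
    non-increasing along the duration axis by construction. They are *not*
    monotone along the intensity axis in general: raising the threshold can
    split one long episode into several shorter qualifying ones.
    """

    spec: GridSpec
    counts_survivor: np.ndarray
    counts_nonsurvivor: np.ndarray
    n_survivor: int
    n_nonsurvivor: int

    def __post_init__(self):
        for m in (self.counts_survivor, self.counts_nonsurvivor):
            if m.shape != self.spec.shape:
                raise ValueError("count matrix shape does not match grid spec")
            if np.any(m < 0):
                raise ValueError("negative counts")
            if np.any(np.diff(m, axis=1) > 0):
                raise ValueError("counts must be non-increasing along duration")


def _all_episode_durations(intervals: pd.DataFrame, thresholds: np.ndarray):
    """For each threshold: (episode durations in hours, owning patient codes),
    across all patients at once. Patient boundaries break runs."""
    df = intervals.sort_values(["patient_id", "start"], kind="mergesort")
    codes, uniques = pd.factorize(df["patient_id"], sort=True)
    mp = df["mp"].to_numpy(float)
    # accumulate in minutes: charted at minute resolution, so sums of
    # integral floats stay exact and threshold comparisons are stable
    dur_min = df["duration_min"].to_numpy(float)
    cum = np.concatenate(([0.0], np.cumsum(dur_min)))
    boundary = np.concatenate(([True], codes[1:] != codes[:-1]))
    out = {}
    for thr in thresholds:
        above = mp > thr
        # a run starts where the interval is above and the previous interval
        # of the same patient is not
        prev_above = np.concatenate(([False], above[:-1])) & ~boundary
        run_start = above & ~prev_above
        next_above = np.concatenate((above[1:], [False])) & np.concatenate(
            (~boundary[1:], [False])
        )
        run_end = above & ~next_above
        s = np.flatnonzero(run_start)
        e = np.flatnonzero(run_end)
        out[float(thr)] = (cum[e + 1] - cum[s], codes[s])  # minutes
    return out, uniques


def count_events(
    intervals: pd.DataFrame,
    outcomes: pd.Series,
    spec: GridSpec | None = None,
) -> EventCountGrid:
    """Populate the duration-intensity event-count lattice by outcome group.

    Parameters
    ----------
    intervals : contiguous per-patient interval table with ``patient_id``,
        ``start``, ``duration_min`` and ``mp`` columns.
    outcomes : Series indexed by patient_id with values ``"survivor"`` /
        ``"non-survivor"``; every patient in ``intervals`` must be present.
    """
    spec = spec or GridSpec()
    bad = set(outcomes.dropna().unique()) - {"survivor", "non-survivor"}
    if bad:
        raise ValueError(f"unknown outcome labels: {sorted(bad)}")

    episodes, uniques = _all_episode_durations(intervals, spec.intensities)
    pids = intervals["patient_id"].unique()
    missing = [p for p in pids if p not in outcomes.index or pd.isna(outcomes[p])]
    if missing:
        raise ValueError(f"patients with unknown outcome: {missing[:5]}")

    is_surv = (outcomes.reindex(uniques) == "survivor").to_numpy()
    n_i, n_t = spec.shape
    counts = {
        True: np.zeros((n_i, n_t), dtype=np.int64),
        False: np.zeros((n_i, n_t), dtype=np.int64),
    }
    thresholds_min = spec.durations * 60.0
    for ii, thr in enumerate(spec.intensities):
        durs_min, who = episodes[float(thr)]
        for grp in (True, False):
            d = np.sort(durs_min[is_surv[who] == grp])
            # number of episodes with duration >= t (inclusive); compared in
            # minutes where sums are exact
            counts[grp][ii, :] = d.size - np.searchsorted(d, thresholds_min, "left")
    n_surv = int(is_surv.sum())
    return EventCountGrid(
        spec=spec,
        counts_survivor=counts[True],
        counts_nonsurvivor=counts[False],
        n_survivor=n_surv,
        n_nonsurvivor=len(uniques) - n_surv,
    )
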