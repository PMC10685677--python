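"""Model/Results interface tying the whole analysis together.

:class:`VentilationBurdenModel` is built from a patient table and a
long-format chart-event table (or a directory of CSVs); ``fit()`` runs the
full analysis - selection cascade, 28-day truncation, series cleaning,
interval power/energy computation, duration-intensity event counting, OR
deviation surface with iso-risk contours, average-power quartile
Kaplan-Meier and univariate/stepwise Cox models - and returns a
:class:`VentilationBurdenResults` carrying every intermediate product, a
``summary()`` table, plotting helpers and a ``save()`` exporter.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import filtering, metrics, plotting, surface, survival
from .events import EventCountGrid, GridSpec, count_events
from .filtering import FilterReport
from .simulate import COMORBIDITIES, read_cohort
from .surface import DEFAULT_CONTOUR_LEVELS, ContourCurve, ORGrid

__all__ = ["VentilationBurdenModel", "VentilationBurdenResults"]

#: Cox covariates screened univariately (avg_mp is appended at fit time)
BASE_COVARIATES = ["age", "male", "sofa", "saps2", "avg_mp", *COMORBIDITIES]

_SUBSETS = {"all": np.inf, "lt300": 300.0, "lt200": 200.0, "lt100": 100.0}


class VentilationBurdenModel:
    """Duration-intensity mortality-burden analysis of one cohort.

    Parameters
    ----------
    patients, chartevents : the raw cohort tables (see
        :mod:`ventburden.simulate` for the schemas).
    grid : duration-intensity lattice; default 5-30 J/min x 1-72 h.
    contour_levels : OR-deviation levels at which contours are fitted.
    subset : restrict the analysis to a P/F stratum
        (``all``/``lt300``/``lt200``/``lt100``).
    normalized_overall_or : per-patient-normalised overall OR (default) or
        the raw total-count ratio.
    deviation_mode : ``absolute`` or ``percentage`` deviation for contour
        fitting and heatmaps.
    """

    def __init__(
        self,
        patients: pd.DataFrame,
        chartevents: pd.DataFrame,
        grid: GridSpec | None = None,
        contour_levels=DEFAULT_CONTOUR_LEVELS,
        subset: str = "all",
        normalized_overall_or: bool = True,
        deviation_mode: str = "absolute",
    ):
        if subset not in _SUBSETS:
            raise ValueError(f"subset must be one of {sorted(_SUBSETS)}")
        if len(set(contour_levels)) != len(tuple(contour_levels)):
            raise ValueError("contour levels must be distinct")
        self.patients = patients
        self.chartevents = chartevents
        self.grid = grid or GridSpec()
        self.contour_levels = tuple(contour_levels)
        self.subset = subset
        self.normalized_overall_or = normalized_overall_or
        self.deviation_mode = deviation_mode

    @classmethod
    def from_csv(cls, directory: str, **kwargs) -> "VentilationBurdenModel":
        patients, events = read_cohort(directory)
        return cls(patients, events, **kwargs)

    def fit(self) -> "VentilationBurdenResults":
        patients, events, report = filtering.apply_inclusion_exclusion(
            self.patients, self.chartevents
        )
        if self.subset != "all":
            keep = patients["pf_ratio"] < _SUBSETS[self.subset]
            patients = patients[keep].reset_index(drop=True)
            events = events[
                events["patient_id"].isin(patients["patient_id"])
            ].reset_index(drop=True)
        events = filtering.truncate_to_28_days(events, patients)

        clean = metrics.clean_chart_events(events)
        intervals = metrics.build_intervals(clean, patients)
        summaries = metrics.summarize_energy(intervals)

        outcomes = patients.set_index("patient_id")["outcome_28d"]
        grid_counts = count_events(intervals, outcomes, self.grid)
        or_grid = surface.compute_or_grid(
            grid_counts, normalized=self.normalized_overall_or
        )
        contours = [
            surface.fit_contour(or_grid, lvl, mode=self.deviation_mode)
            for lvl in self.contour_levels
        ]

        analysis = patients.merge(summaries, on="patient_id")
        analysis["event"] = (analysis["outcome_28d"] == "non-survivor").astype(int)
        analysis["male"] = (analysis["gender"] == "male").astype(int)

        quartiles = survival.assign_quartiles(summaries)
        km_data = analysis.merge(
            quartiles[["patient_id", "quartile"]], on="patient_id"
        )
        km = survival.km_logrank(km_data)

        covariates = [c for c in BASE_COVARIATES if c in analysis.columns]
        cox_uni = survival.cox_univariate(analysis, covariates)
        try:
            cox_final, cox_full = survival.cox_stepwise(cox_uni, analysis)
        except ValueError:
            cox_final = cox_uni.iloc[0:0].copy()
            cox_full = cox_uni.iloc[0:0].copy()

        table1 = survival.descriptive_tables(
            analysis,
            continuous=["age", "weight", "height", "sofa", "saps2"],
            categorical=["male", *COMORBIDITIES],
        )
        table2 = survival.descriptive_tables(
            analysis,
            continuous=["pf_ratio", "avg_mp", "total_energy_j"],
            categorical=[],
        )

        return VentilationBurdenResults(
            model=self,
            filter_report=report,
            patients=patients,
            analysis=analysis,
            intervals=intervals,
            summaries=summaries,
            event_grid=grid_counts,
            or_grid=or_grid,
            contours=contours,
            quartiles=quartiles,
            km=km,
            cox_univariate=cox_uni,
            cox_multivariate=cox_final,
            cox_full_model=cox_full,
            table1=table1,
            table2=table2,
        )


@dataclass
class VentilationBurdenResults:
    """Everything the fitted analysis produced."""

    model: VentilationBurdenModel
    filter_report: FilterReport
    patients: pd.DataFrame
    analysis: pd.DataFrame
    intervals: pd.DataFrame
    summaries: pd.DataFrame
    event_grid: EventCountGrid
    or_grid: ORGrid
    contours: list[ContourCurve]
    quartiles: pd.DataFrame
    km: survival.KMResult
    cox_univariate: pd.DataFrame
    cox_multivariate: pd.DataFrame
    cox_full_model: pd.DataFrame
    table1: pd.DataFrame = field(repr=False, default=None)
    table2: pd.DataFrame = field(repr=False, default=None)

    @property
    def mortality_28d(self) -> float:
        """28-day mortality fraction in the analysis cohort."""
        return float((self.patients["outcome_28d"] == "non-survivor").mean())

    def contour_at(self, level: float) -> ContourCurve:
        for c in self.contours:
            if c.level == level:
                return c
        raise KeyError(f"no contour fitted at level {level}")

    def summary(self) -> str:
        g = self.event_grid
        lines = [
            "Ventilation duration-intensity burden analysis",
            "=" * 54,
            f"patients analysed      {len(self.patients):>8d}",
            f"  survivors            {g.n_survivor:>8d}",
            f"  non-survivors        {g.n_nonsurvivor:>8d}",
            f"28-day mortality       {100 * self.mortality_28d:>7.1f}%",
            f"median avg power       "
            f"{self.summaries['avg_mp'].median():>7.1f} J/min",
            f"overall OR             {self.or_grid.overall_or:>8.3f}",
            f"log-rank (quartiles)   chi2={self.km.statistic:.1f}, "
            f"p={self.km.p_value:.2g}",
            "",
            "Selection cascade:",
        ]
        for label, excl, rem in self.filter_report.steps:
            lines.append(f"  {label:<42s} -{excl:<6d} -> {rem}")
        fitted = [c for c in self.contours if c.fit_params is not None]
        if fitted:
            lines += ["", "Iso-risk intensity bounds (J/min):",
                      "  level      24 h    48 h    72 h"]
            for c in fitted:
                v = c.predict([24.0, 48.0, 72.0])
                lines.append(
                    f"  {c.level:>5.2f}   {v[0]:>6.1f}  {v[1]:>6.1f}  {v[2]:>6.1f}"
                )
        if len(self.cox_multivariate):
            lines += ["", "Multivariate Cox model (28-day mortality):",
                      "  variable        HR    95% CI          p"]
            for _, r in self.cox_multivariate.iterrows():
                if not r.get("retained", True) or pd.isna(r["hr"]):
                    continue
                lines.append(
                    f"  {r['variable']:<12s} {r['hr']:>6.2f}  "
                    f"({r['ci_lower']:.2f}, {r['ci_upper']:.2f})  {r['p']:.2g}"
                )
        return "\n".join(lines)

    # ------------------------------------------------------------------ plots
    def plot_heatmap(self, path: str, mode: str | None = None) -> str:
        return plotting.render_heatmap(
            self.or_grid, path, mode=mode or self.model.deviation_mode,
            contours=self.contours,
        )

    def plot_contour_grid(self, path: str) -> str:
        return plotting.grid_plot(self.contours, path, spec=self.or_grid.spec)

    def plot_km(self, path: str) -> str:
        return plotting.km_plot(self.km, path)

    # ------------------------------------------------------------------ export
    def save(self, directory: str) -> dict:
        """Write all tabular outputs as CSV plus a JSON manifest; returns
        the manifest dictionary."""
        os.makedirs(directory, exist_ok=True)
        tables = {
            "filter_report.csv": self.filter_report.to_frame(),
            "intervals.csv": self.intervals,
            "summaries.csv": self.summaries,
            "event_grid.csv": _event_grid_frame(self.event_grid),
            "or_grid.csv": surface.or_grid_to_frame(self.or_grid),
            "contours.csv": surface.contours_to_frame(self.contours),
            "quartiles.csv": self.quartiles,
            "cox_results.csv": pd.concat(
                [self.cox_univariate, self.cox_multivariate], ignore_index=True
            ),
            "km_curves.csv": _km_frame(self.km),
            "table1.csv": self.table1,
            "table2.csv": self.table2,
        }
        manifest = {
            "n_patients": len(self.patients),
            "n_survivor": self.event_grid.n_survivor,
            "n_nonsurvivor": self.event_grid.n_nonsurvivor,
            "overall_or": self.or_grid.overall_or,
            "files": {},
        }
        for name, df in tables.items():
            path = os.path.join(directory, name)
            df.to_csv(path, index=False)
            manifest["files"][name] = len(df)
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest


def _event_grid_frame(grid: EventCountGrid) -> pd.DataFrame:
    frames = []
    for label, counts in (
        ("survivor", grid.counts_survivor),
        ("non-survivor", grid.counts_nonsurvivor),
    ):
        ii, jt = np.meshgrid(
            np.arange(len(grid.spec.intensities)),
            np.arange(len(grid.spec.durations)),
            indexing="ij",
        )
        frames.append(
            pd.DataFrame(
                {
                    "intensity": grid.spec.intensities[ii.ravel()],
                    "duration_h": grid.spec.durations[jt.ravel()],
                    "group": label,
                    "count": counts.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _km_frame(km: survival.KMResult) -> pd.DataFrame:
    frames = []
    for label, sf in km.survival_functions.items():
        df = sf.reset_index()
        df.columns = ["time", "survival"]
        df.insert(0, "group", label)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
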