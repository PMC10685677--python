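"""Synthetic ICU cohort generator with a known ventilation dose-response effect.

Emulates the structure of an electronic-chart extract for invasively
ventilated ICU patients: a patient table (demographics, severity scores,
comorbidities, ventilation episode bounds, 28-day outcome) and a long-format
chart-event table with peak inspiratory pressure (``ppeak``, cm H2O), PEEP
(cm H2O), measured respiratory rate (``rr``, min^-1) and tidal volume
(``vt``, mL) recorded roughly every four hours.

The injected harm model is explicit and configurable, so downstream risk
surfaces and survival models can be validated against a known truth: each
day's death hazard is the baseline daily hazard multiplied by
``rho ** (min(E_d, cap) / 24)``, where ``E_d`` is the cumulative number of
hours spent with true dynamic mechanical power above ``intensity_threshold``
beyond the first ``duration_threshold`` hours, and optionally by
``exp(beta * (avg_mp - 11.8))`` for a log-linear effect of the whole-course
average power. With ``rho = 1`` and ``beta = 0`` the outcome is independent
of ventilation, giving an exact null for calibration checks.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "VariableParams",
    "HarmModel",
    "SimulationConfig",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "PATIENT_COLUMNS",
    "EVENT_COLUMNS",
]

#: chart variables, charted units: cm H2O, cm H2O, breaths/min, mL
CHART_VARIABLES = ("ppeak", "peep", "rr", "vt")

COMORBIDITIES = ("chf", "cvd", "cpd", "diabetes", "cancer", "renal", "liver")

PATIENT_COLUMNS = [
    "patient_id", "age", "gender", "weight", "height", "sofa", "saps2",
    "pf_ratio", *COMORBIDITIES, "mv_start", "mv_end", "outcome_28d",
    "survival_time_days",
]

EVENT_COLUMNS = ["patient_id", "timestamp", "variable", "value"]

#: first-day P/F strata bounds (mmHg), most to least oxygenated
PF_STRATA_BOUNDS = ((300.0, 450.0), (200.0, 300.0), (100.0, 200.0), (40.0, 100.0))

_BASE_DATE = pd.Timestamp("2138-01-01")

#: centring constant for the log-linear average-power effect (J/min); the
#: cohort-median average dynamic mechanical power in adult MV cohorts.
MP_REFERENCE = 11.8


@dataclass(frozen=True)
class VariableParams:
    """Per-stratum generation parameters for one chart variable.

    ``means`` are ordered by P/F stratum from best (> 300 mmHg) to worst
    (<= 100 mmHg) oxygenation; ``within_sd`` is the record-to-record SD
    around the patient mean. Patient means scatter around the stratum mean
    either additively (normal with SD ``between_sd``) or, when
    ``lognormal_between`` is set, multiplicatively (lognormal with log-SD
    ``between_sd``), which reproduces the right-skew of charted airway
    pressures.
    """

    means: tuple[float, float, float, float]
    between_sd: float
    within_sd: float
    lognormal_between: bool = False


def _default_baseline() -> dict[str, VariableParams]:
    # Stratum medians follow the clinical gradient: worse oxygenation ->
    # higher pressures and respiratory rate, near-constant tidal volume.
    # Dispersions chosen so the cleaned cohort reproduces the charted
    # quartiles of a large adult MV cohort (see docs/methods.md).
    return {
        "ppeak": VariableParams((17.7, 18.7, 20.6, 23.1), 0.27, 1.5,
                                lognormal_between=True),
        "peep": VariableParams((5.3, 5.7, 7.0, 8.8), 0.33, 0.8,
                               lognormal_between=True),
        "rr": VariableParams((19.9, 19.9, 21.1, 22.8), 3.4, 2.0),
        "vt": VariableParams((455.0, 461.0, 468.0, 457.0), 68.0, 30.0),
    }


@dataclass(frozen=True)
class HarmModel:
    """Parameters of the injected exposure-mortality effect.

    intensity_threshold : J/min power level above which exposure is harmful.
    duration_threshold : hours of supra-threshold exposure tolerated before
        the hazard starts rising.
    rho : hazard multiplier per 24 excess hours (>= 1; the default 1 injects
        no effect).
    excess_cap_h : excess hours beyond which risk saturates.
    beta_avg_mp : optional log-linear daily-hazard coefficient per J/min of
        whole-course average dynamic mechanical power (0 = off).
    """

    intensity_threshold: float = 15.0
    duration_threshold: float = 24.0
    rho: float = 1.0
    excess_cap_h: float = 72.0
    beta_avg_mp: float = 0.0

    def validate(self) -> None:
        if self.rho < 1.0:
            raise ValueError(f"rho must be >= 1, got {self.rho}")
        if self.intensity_threshold <= 0 or self.duration_threshold < 0:
            raise ValueError("harm thresholds must be positive")
        if self.excess_cap_h <= 0:
            raise ValueError("excess_cap_h must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic cohort.

    Identical config + seed reproduces the output tables exactly.
    """

    n_patients: int = 500
    seed: int = 0
    recording_interval_h: float = 4.0
    jitter_frac: float = 0.25
    mv_duration_median_d: float = 6.0
    mv_duration_sigma: float = 0.55
    mv_duration_range_d: tuple[float, float] = (1.0, 45.0)
    severity_mix: tuple[float, float, float, float] = (0.392, 0.153, 0.278, 0.177)
    baseline_params: dict[str, VariableParams] = field(default_factory=_default_baseline)
    missing_rate: float = 0.008
    extreme_rate: float = 0.002
    effect: HarmModel = field(default_factory=HarmModel)
    #: baseline daily death hazard, calibrated so that 28-day mortality is
    #: close to 30% at the default (no injected effect) configuration
    baseline_daily_hazard: float = 0.0126

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError(f"n_patients must be positive, got {self.n_patients}")
        if abs(sum(self.severity_mix) - 1.0) > 1e-9:
            raise ValueError(
                f"severity_mix must sum to 1, got {sum(self.severity_mix)!r}"
            )
        if not 0.0 <= self.missing_rate <= 0.05:
            raise ValueError(f"missing_rate must be in [0, 0.05], got {self.missing_rate}")
        if not 0.0 <= self.extreme_rate <= 0.02:
            raise ValueError(f"extreme_rate must be in [0, 0.02], got {self.extreme_rate}")
        if self.recording_interval_h <= 0:
            raise ValueError("recording_interval_h must be positive")
        if not 0.0 <= self.jitter_frac < 1.0:
            raise ValueError("jitter_frac must be in [0, 1)")
        if set(self.baseline_params) != set(CHART_VARIABLES):
            raise ValueError(f"baseline_params must cover {CHART_VARIABLES}")
        self.effect.validate()

    def with_effect(self, **kwargs) -> "SimulationConfig":
        """Return a copy with harm-model fields replaced."""
        return replace(self, effect=replace(self.effect, **kwargs))


def _minutes(hours: np.ndarray) -> np.ndarray:
    return np.rint(hours * 60.0).astype(np.int64)


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (patient table, chart-event table) for one synthetic cohort.

    Returns
    -------
    patients : DataFrame with :data:`PATIENT_COLUMNS`.
    events : long-format DataFrame with :data:`EVENT_COLUMNS`; a missing
        measurement is an absent row.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    eff = config.effect

    stratum = rng.choice(4, size=n, p=np.asarray(config.severity_mix))

    age = np.clip(np.rint(rng.normal(64.0, 15.0, n)), 18, 95).astype(int)
    gender = np.where(rng.random(n) < 0.578, "male", "female")
    weight = np.round(np.clip(rng.normal(84.0, 20.0, n), 40.0, 180.0), 1)
    height = np.round(np.clip(rng.normal(170.0, 9.0, n), 140.0, 205.0), 0)
    sofa = np.clip(
        np.rint(np.array([4.0, 5.5, 9.0, 10.5])[stratum] + rng.normal(0, 2.5, n)),
        0, 24,
    ).astype(int)
    saps2 = np.clip(
        np.rint(np.array([38.0, 44.0, 48.0, 52.0])[stratum] + rng.normal(0, 10.0, n)),
        0, 120,
    ).astype(int)
    lo = np.array([b[0] for b in PF_STRATA_BOUNDS])[stratum]
    hi = np.array([b[1] for b in PF_STRATA_BOUNDS])[stratum]
    pf_ratio = np.round(lo + (hi - lo) * rng.random(n), 0)
    comorb = {
        name: rng.random(n) < p
        for name, p in zip(
            COMORBIDITIES, (0.323, 0.202, 0.287, 0.255, 0.120, 0.231, 0.093)
        )
    }

    dur_lo, dur_hi = config.mv_duration_range_d
    dur_d = np.clip(
        np.exp(math.log(config.mv_duration_median_d)
               + rng.normal(0.0, config.mv_duration_sigma, n)),
        dur_lo, dur_hi,
    )
    mv_start = _BASE_DATE + pd.to_timedelta(
        _minutes(rng.random(n) * 365.0 * 24.0), unit="m"
    )
    mv_end = mv_start + pd.to_timedelta(_minutes(dur_d * 24.0), unit="m")
    dur_h = (mv_end - mv_start).total_seconds().to_numpy() / 3600.0

    # patient-level means per variable, then per-record values
    pmeans = {}
    for var in CHART_VARIABLES:
        vp = config.baseline_params[var]
        centre = np.asarray(vp.means)[stratum]
        if vp.lognormal_between:
            pmeans[var] = centre * np.exp(rng.normal(0, vp.between_sd, n))
        else:
            pmeans[var] = centre + rng.normal(0, vp.between_sd, n)
    pmeans["peep"] = np.clip(pmeans["peep"], 2.0, None)
    pmeans["ppeak"] = np.maximum(pmeans["ppeak"], pmeans["peep"] + 2.0)
    pmeans["rr"] = np.clip(pmeans["rr"], 8.0, None)
    pmeans["vt"] = np.clip(pmeans["vt"], 200.0, None)

    # recording grid: steps of recording_interval_h with uniform jitter
    step_h = config.recording_interval_h
    max_steps = int(np.ceil(dur_h.max() / (step_h * (1.0 - config.jitter_frac)))) + 2
    steps = step_h * (
        1.0 + rng.uniform(-config.jitter_frac, config.jitter_frac, (n, max_steps))
    )
    offsets_h = np.concatenate([np.zeros((n, 1)), np.cumsum(steps, axis=1)], axis=1)
    valid = offsets_h < dur_h[:, None]  # timepoints strictly inside the episode

    pid = np.array([f"P{i:05d}" for i in range(n)])
    rows_pid, rows_off = np.nonzero(valid)
    offs_min = _minutes(offsets_h[rows_pid, rows_off])
    n_obs = len(rows_pid)

    true_vals = np.empty((n_obs, 4))
    for k, var in enumerate(CHART_VARIABLES):
        vp = config.baseline_params[var]
        true_vals[:, k] = pmeans[var][rows_pid] + rng.normal(0, vp.within_sd, n_obs)
    true_vals[:, 1] = np.clip(true_vals[:, 1], 1.0, None)              # peep
    true_vals[:, 0] = np.maximum(true_vals[:, 0], true_vals[:, 1] + 0.5)  # ppeak
    true_vals[:, 2] = np.clip(true_vals[:, 2], 5.0, None)              # rr
    true_vals[:, 3] = np.clip(true_vals[:, 3], 100.0, None)            # vt

    # --- outcome from the true (uncorrupted) power series -------------------
    ppeak_t, peep_t, rr_t, vt_t = true_vals.T
    mp_true = 0.098 * rr_t * (vt_t / 1000.0) * (ppeak_t - 0.5 * (ppeak_t - peep_t))

    # interval duration: until next recorded timepoint, last one to mv_end
    t_off = offs_min / 60.0
    next_off = np.empty_like(t_off)
    next_off[:-1] = t_off[1:]
    last_of_patient = np.empty(n_obs, dtype=bool)
    last_of_patient[:-1] = rows_pid[1:] != rows_pid[:-1]
    last_of_patient[-1] = True
    next_off[last_of_patient] = dur_h[rows_pid[last_of_patient]]
    int_dur_h = next_off - t_off

    excess, avg_mp_true = _daily_excess_hours(
        rows_pid, t_off, int_dur_h, mp_true, n,
        eff.intensity_threshold, eff.duration_threshold,
    )
    excess = np.minimum(excess, eff.excess_cap_h)
    log_mult = (excess / 24.0) * math.log(eff.rho)
    if eff.beta_avg_mp != 0.0:
        log_mult = log_mult + eff.beta_avg_mp * (avg_mp_true - MP_REFERENCE)[:, None]
    daily_hazard = config.baseline_daily_hazard * np.exp(log_mult)
    p_death = 1.0 - np.exp(-daily_hazard)

    u = rng.random((n, 28))
    died_day = u < p_death
    any_death = died_day.any(axis=1)
    first_day = np.where(any_death, died_day.argmax(axis=1), 27)  # 0-based day index
    frac = rng.random(n)
    survival_time = np.where(any_death, np.minimum(first_day + frac, 27.999), 28.0)
    outcome = np.where(any_death, "non-survivor", "survivor")

    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "age": age,
            "gender": gender,
            "weight": weight,
            "height": height,
            "sofa": sofa,
            "saps2": saps2,
            "pf_ratio": pf_ratio,
            **{k: v.astype(int) for k, v in comorb.items()},
            "mv_start": mv_start,
            "mv_end": mv_end,
            "outcome_28d": outcome,
            "survival_time_days": np.round(survival_time, 3),
        }
    )

    # --- charted (observed) values: corruption applied to the truth ---------
    charted = true_vals.copy()
    if config.extreme_rate > 0:
        extreme = rng.random((n_obs, 4)) < config.extreme_rate
        factors = rng.uniform(3.0, 5.0, (n_obs, 4))
        charted = np.where(extreme, charted * factors, charted)
    keep_mask = (
        rng.random((n_obs, 4)) >= config.missing_rate
        if config.missing_rate > 0
        else np.ones((n_obs, 4), dtype=bool)
    )

    ts = mv_start.to_numpy()[rows_pid] + offs_min * np.timedelta64(60, "s")
    events = pd.DataFrame(
        {
            "patient_id": np.repeat(pid[rows_pid], 4),
            "timestamp": np.repeat(ts, 4),
            "variable": np.tile(np.array(CHART_VARIABLES), n_obs),
            "value": np.round(charted, 2).ravel(),
        }
    )
    events = events[keep_mask.ravel()]
    events = events.sort_values(
        ["patient_id", "timestamp", "variable"], kind="mergesort"
    ).reset_index(drop=True)
    return patients, events


def _daily_excess_hours(
    rows_pid: np.ndarray,
    t_off_h: np.ndarray,
    int_dur_h: np.ndarray,
    mp: np.ndarray,
    n_patients: int,
    intensity_threshold: float,
    duration_threshold: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative supra-threshold excess hours at each day boundary.

    Returns an (n_patients, 28) array whose [i, d] entry is the number of
    hours patient i has spent with power above ``intensity_threshold`` beyond
    the first ``duration_threshold`` such hours, as of the end of day d+1,
    plus the per-patient true whole-course average power.
    """
    above = mp > intensity_threshold
    t_end = t_off_h + int_dur_h

    day_edges = np.arange(1, 29) * 24.0
    # overlap of each supra-threshold interval with [0, edge] for every edge
    overlap = np.clip(
        np.minimum(t_end[:, None], day_edges[None, :]) - t_off_h[:, None], 0.0, None
    )
    overlap[~above] = 0.0
    cum = np.zeros((n_patients, 28))
    np.add.at(cum, rows_pid, overlap)
    excess = np.clip(cum - duration_threshold, 0.0, None)

    # true average power over the first 28 days (the outcome window, which
    # is also the window the downstream analysis measures)
    dur_28 = np.clip(np.minimum(t_end, 28.0 * 24.0) - t_off_h, 0.0, None)
    energy = np.zeros(n_patients)
    minutes = np.zeros(n_patients)
    np.add.at(energy, rows_pid, mp * dur_28 * 60.0)
    np.add.at(minutes, rows_pid, dur_28 * 60.0)
    avg_mp = np.divide(energy, minutes, out=np.zeros(n_patients), where=minutes > 0)
    return excess, avg_mp


def write_cohort(
    patients: pd.DataFrame, events: pd.DataFrame, directory: str | os.PathLike
) -> dict[str, str]:
    """Write the cohort as ``patients.csv`` and ``chartevents.csv``.

    Timestamps are ISO-8601; a missing chart value is an empty field. The
    files round-trip losslessly through :func:`read_cohort`.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {
        "patients": os.path.join(directory, "patients.csv"),
        "chartevents": os.path.join(directory, "chartevents.csv"),
    }
    out = patients.copy()
    for col in ("mv_start", "mv_end"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(paths["patients"], index=False)

    ev = events.copy()
    ev["timestamp"] = pd.to_datetime(ev["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    ev.to_csv(paths["chartevents"], index=False)
    return paths


def read_cohort(directory: str | os.PathLike) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load a cohort written by :func:`write_cohort` (or any conformant CSVs)."""
    ppath = os.path.join(directory, "patients.csv")
    epath = os.path.join(directory, "chartevents.csv")
    for p in (ppath, epath):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    patients = pd.read_csv(ppath, parse_dates=["mv_start", "mv_end"])
    events = pd.read_csv(
        epath,
        parse_dates=["timestamp"],
        dtype={"patient_id": str, "variable": str, "value": float},
    )
    if patients.empty:
        patients = patients.astype({"patient_id": str}, errors="ignore")
    return patients, events
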