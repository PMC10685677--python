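import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import ventburden as vb

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_cohort():
    """A moderately sized cohort with the harmful exposure effect injected."""
    config = vb.SimulationConfig(n_patients=400, seed=3).with_effect(rho=2.0)
    patients, events = vb.generate_cohort(config)
    return config, patients, events


@pytest.fixture(scope="session")
def fitted_results(default_cohort):
    _, patients, events = default_cohort
    return vb.VentilationBurdenModel(patients, events).fit()


def make_patient_row(
    pid,
    age=60,
    mv_hours=120.0,
    outcome="survivor",
    survival=28.0,
    admission_seq=1,
    episode_seq=1,
    pf_ratio=250.0,
):
    start = pd.Timestamp("2140-01-01 08:00")
    return {
        "patient_id": pid,
        "age": age,
        "gender": "male",
        "weight": 80.0,
        "height": 170.0,
        "sofa": 6,
        "saps2": 40,
        "pf_ratio": pf_ratio,
        "chf": 0, "cvd": 0, "cpd": 0, "diabetes": 0,
        "cancer": 0, "renal": 0, "liver": 0,
        "mv_start": start,
        "mv_end": start + pd.Timedelta(hours=mv_hours),
        "outcome_28d": outcome,
        "survival_time_days": survival,
        "icu_admission_seq": admission_seq,
        "mv_episode_seq": episode_seq,
    }


def make_events(patients, spacing_h=4.0):
    """Regularly spaced chart events for each patient, all four variables."""
    rows = []
    for _, p in patients.iterrows():
        t = p["mv_start"]
        while t < p["mv_end"]:
            for var, val in [("ppeak", 20.0), ("peep", 5.0), ("rr", 20.0),
                             ("vt", 500.0)]:
                rows.append((p["patient_id"], t, var, val))
            t = t + pd.Timedelta(hours=spacing_h)
    return pd.DataFrame(rows, columns=["patient_id", "timestamp", "variable", "value"])


@pytest.fixture
def hand_cohort():
    """Ten hand-built patients: 2 second admissions, 1 second episode,
    3 with MV shorter than 72 h, 4 that pass every criterion."""
    rows = [
        make_patient_row("A1"),
        make_patient_row("A2", mv_hours=200.0),
        make_patient_row("A3", outcome="non-survivor", survival=10.0),
        make_patient_row("A4", mv_hours=96.0),
        make_patient_row("B1", admission_seq=2),
        make_patient_row("B2", admission_seq=2),
        make_patient_row("C1", episode_seq=2),
        make_patient_row("D1", mv_hours=24.0),
        make_patient_row("D2", mv_hours=71.0),
        make_patient_row("D3", mv_hours=48.0),
    ]
    patients = pd.DataFrame(rows)
    events = make_events(patients)
    return patients, events


def intervals_from_mp(mp_values, duration_h=4.0, pid="P1"):
    """A contiguous interval table with the given power sequence."""
    start = pd.Timestamp("2140-01-01")
    mp = np.asarray(mp_values, dtype=float)
    starts = [start + pd.Timedelta(hours=duration_h * i) for i in range(len(mp))]
    return pd.DataFrame(
        {
            "patient_id": pid,
            "start": starts,
            "duration_min": duration_h * 60.0,
            "mp": mp,
        }
    )
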