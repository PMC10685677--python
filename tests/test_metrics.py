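"""Series cleaning and per-interval power/energy computation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ventburden as vb
from tests.conftest import make_patient_row


def long_events(pid, hours, variable, values):
    start = pd.Timestamp("2140-01-01")
    return pd.DataFrame(
        {
            "patient_id": pid,
            "timestamp": [start + pd.Timedelta(hours=h) for h in hours],
            "variable": variable,
            "value": values,
        }
    )


def full_events(pid, hours, **series):
    frames = [
        long_events(pid, hours, var, vals) for var, vals in series.items()
    ]
    return pd.concat(frames, ignore_index=True).dropna(subset=["value"])


class TestImputation:
    def test_equidistant_tie_breaks_toward_earlier_value(self):
        ev = full_events(
            "P1", [0, 4, 8],
            ppeak=[10.0, np.nan, 14.0],
            peep=[5.0, 5.0, 5.0], rr=[20.0] * 3, vt=[500.0] * 3,
        )
        wide = vb.impute_missing(ev)
        assert wide["ppeak"].tolist() == [10.0, 10.0, 14.0]

    def test_single_neighbor_fills_backward(self):
        ev = full_events(
            "P1", [0, 4],
            ppeak=[np.nan, 12.0], peep=[5.0, 5.0], rr=[20.0] * 2, vt=[500.0] * 2,
        )
        wide = vb.impute_missing(ev)
        assert wide["ppeak"].tolist() == [12.0, 12.0]

    def test_patient_with_no_values_gets_cohort_median(self):
        a = full_events("A", [0, 4], ppeak=[20.0, 20.0], peep=[5.0, 5.0],
                        rr=[18.0, 22.0], vt=[500.0] * 2)
        b = full_events("B", [0, 4], ppeak=[20.0, 20.0], peep=[5.0, 5.0],
                        rr=[np.nan, np.nan], vt=[500.0] * 2)
        wide = vb.impute_missing(pd.concat([a, b], ignore_index=True))
        assert (wide.loc[wide["patient_id"] == "B", "rr"] == 20.0).all()

    def test_nearest_in_time_not_nearest_in_index(self):
        ev = full_events(
            "P1", [0, 6, 8],
            ppeak=[10.0, np.nan, 14.0],
            peep=[5.0] * 3, rr=[20.0] * 3, vt=[500.0] * 3,
        )
        wide = vb.impute_missing(ev)
        assert wide["ppeak"].tolist() == [10.0, 14.0, 14.0]

    def test_variable_missing_cohort_wide_raises(self):
        ev = full_events("P1", [0, 4], ppeak=[20.0, 20.0], peep=[5.0, 5.0],
                         rr=[20.0, 20.0], vt=[np.nan, np.nan])
        with pytest.raises(ValueError, match="entirely missing"):
            vb.impute_missing(ev)


class TestWinsorize:
    def test_outlier_pulled_to_99th_percentile(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(0, 1, 1000)
        vals[0] = 10.0
        out = vb.winsorize(vals)
        assert out[0] == pytest.approx(np.percentile(vals, 99))
        assert out[0] < 1.1

    def test_identical_values_unchanged(self):
        assert (vb.winsorize(np.full(50, 7.0)) == 7.0).all()

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            vb.winsorize(np.array([]))

    @settings(deadline=None, max_examples=40)
    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=200
        )
    )
    def test_output_bounded_by_percentiles(self, values):
        arr = np.asarray(values)
        out = vb.winsorize(arr)
        p1, p99 = np.percentile(arr, [1, 99])
        assert out.min() >= p1 - 1e-9 and out.max() <= p99 + 1e-9

    def test_near_idempotent_on_own_output(self):
        # a second pass can move clipped values only by the interpolation
        # gap between adjacent order statistics at the 1%/99% positions
        vals = np.random.default_rng(5).normal(size=2000)
        once = vb.winsorize(vals)
        np.testing.assert_allclose(vb.winsorize(once), once, atol=1e-2)


class TestIntervals:
    def _patients(self, pid="P1", mv_hours=12.0):
        return pd.DataFrame([make_patient_row(pid, mv_hours=mv_hours)])

    def _wide(self, pid, hours, mv_hours=12.0):
        start = pd.Timestamp("2140-01-01 08:00")
        return pd.DataFrame(
            {
                "patient_id": pid,
                "timestamp": [start + pd.Timedelta(hours=h) for h in hours],
                "ppeak": 20.0, "peep": 5.0, "rr": 20.0, "vt": 500.0,
            }
        )

    def test_durations_span_to_next_timepoint_then_mv_end(self):
        iv = vb.build_intervals(self._wide("P1", [0, 4, 10]), self._patients())
        assert iv["duration_min"].tolist() == [240.0, 360.0, 120.0]

    def test_final_interval_clipped_at_day_28(self):
        pts = self._patients(mv_hours=31 * 24.0)
        iv = vb.build_intervals(self._wide("P1", [0, 4]), pts)
        assert iv["duration_min"].sum() == pytest.approx(28 * 24 * 60.0)

    def test_total_duration_equals_truncated_mv_duration(self, default_cohort):
        _, patients, events = default_cohort
        pts, evs, _ = vb.apply_inclusion_exclusion(patients, events)
        evs = vb.truncate_to_28_days(evs, pts)
        iv = vb.build_intervals(vb.clean_chart_events(evs), pts)
        total = iv.groupby("patient_id")["duration_min"].sum()
        mv_min = (
            (pts["mv_end"] - pts["mv_start"]).dt.total_seconds() / 60.0
        ).clip(upper=28 * 24 * 60.0)
        expected = pd.Series(mv_min.to_numpy(), index=pts["patient_id"])
        pd.testing.assert_series_equal(
            total, expected.sort_index(), check_names=False
        )

    def test_duplicate_timestamps_raise(self):
        with pytest.raises(ValueError, match="duplicate"):
            vb.build_intervals(self._wide("P1", [0, 0, 4]), self._patients())

    def test_single_timepoint_raises(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            vb.build_intervals(self._wide("P1", [0]), self._patients())


class TestPower:
    def test_worked_example(self):
        dp, mp = vb.compute_power(20.0, 5.0, 20.0, 0.5)
        assert dp == 15.0
        assert mp == pytest.approx(0.098 * 20 * 0.5 * 12.5) == pytest.approx(12.25)

    def test_zero_driving_pressure(self):
        dp, mp = vb.compute_power(18.0, 18.0, 20.0, 0.5)
        assert dp == 0.0
        assert mp == pytest.approx(0.098 * 20.0 * 0.5 * 18.0)

    def test_zero_tidal_volume_gives_zero_power(self):
        _, mp = vb.compute_power(20.0, 5.0, 20.0, 0.0)
        assert mp == 0.0

    def test_inverted_pressures_raise(self):
        with pytest.raises(ValueError, match="ppeak < peep"):
            vb.compute_power(4.0, 5.0, 20.0, 0.5)


class TestEnergySummary:
    def test_worked_example(self):
        iv = pd.DataFrame(
            {
                "patient_id": "P1",
                "duration_min": [240.0, 240.0],
                "mp": [10.0, 14.0],
            }
        )
        iv["energy_j"] = iv["mp"] * iv["duration_min"]
        s = vb.summarize_energy(iv)
        assert s.loc[0, "total_energy_j"] == pytest.approx(5760.0)
        assert s.loc[0, "avg_mp"] == pytest.approx(12.0)

    def test_constant_power_average_is_invariant_to_interval_structure(self):
        iv = pd.DataFrame(
            {
                "patient_id": "P1",
                "duration_min": [60.0, 300.0, 15.0],
                "mp": [8.5, 8.5, 8.5],
            }
        )
        iv["energy_j"] = iv["mp"] * iv["duration_min"]
        assert vb.summarize_energy(iv).loc[0, "avg_mp"] == pytest.approx(8.5)

    def test_average_power_bounded_by_interval_powers(self, fitted_results):
        merged = fitted_results.summaries.set_index("patient_id")
        per_patient = fitted_results.intervals.groupby("patient_id")["mp"]
        assert (merged["avg_mp"] >= per_patient.min() - 1e-9).all()
        assert (merged["avg_mp"] <= per_patient.max() + 1e-9).all()

    def test_energy_consistency_on_fitted_cohort(self, fitted_results):
        iv = fitted_results.intervals
        np.testing.assert_allclose(
            iv["energy_j"], iv["mp"] * iv["duration_min"], rtol=1e-9
        )

    def test_cleaning_enforces_nonnegative_driving_pressure(self, default_cohort):
        _, _, events = default_cohort
        ev = events.copy()
        # force an inversion at one timepoint
        first = ev[(ev["variable"] == "ppeak")].index[0]
        ev.loc[first, "value"] = 0.5
        wide = vb.clean_chart_events(ev)
        assert (wide["ppeak"] >= wide["peep"]).all()
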