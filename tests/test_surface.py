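"""OR-deviation surfaces, iso-risk contours, and their figures."""

import numpy as np
import pytest

import ventburden as vb
from ventburden.events import EventCountGrid, GridSpec
from ventburden.plotting import grid_plot, render_heatmap
from ventburden.surface import ORGrid, fit_contour


def tiny_grid(counts_s, counts_ns, n_s=2, n_ns=2, spec=None):
    spec = spec or GridSpec(intensities=[10.0], durations=[1.0])
    return EventCountGrid(
        spec=spec,
        counts_survivor=np.asarray(counts_s),
        counts_nonsurvivor=np.asarray(counts_ns),
        n_survivor=n_s,
        n_nonsurvivor=n_ns,
    )


def analytic_or_grid(deviation_fn, spec, overall=1.0):
    """An ORGrid with a prescribed deviation surface (all cells defined)."""
    i, t = np.meshgrid(spec.intensities, spec.durations, indexing="ij")
    dev = deviation_fn(i, t)
    return ORGrid(
        spec=spec,
        avg_survivor=np.ones_like(dev),
        avg_nonsurvivor=np.ones_like(dev),
        or_matrix=dev + overall,
        overall_or=overall,
        deviation=dev,
        pct_deviation=100.0 * dev / overall,
        defined=np.ones_like(dev, dtype=bool),
    )


class TestORGrid:
    def test_worked_arithmetic(self):
        og = vb.compute_or_grid(tiny_grid([[4]], [[6]]))
        assert og.avg_survivor[0, 0] == 2.0
        assert og.avg_nonsurvivor[0, 0] == 3.0
        assert og.or_matrix[0, 0] == pytest.approx(2 / 3)

    def test_symmetric_groups_give_zero_deviation(self):
        spec = GridSpec(intensities=[10.0, 12.0], durations=[1.0, 2.0])
        counts = [[6, 4], [3, 1]]
        og = vb.compute_or_grid(tiny_grid(counts, counts, spec=spec))
        np.testing.assert_allclose(og.or_matrix, 1.0)
        assert og.overall_or == pytest.approx(1.0)
        np.testing.assert_allclose(og.deviation, 0.0)

    def test_scale_invariance_under_count_doubling(self):
        spec = GridSpec(intensities=[10.0, 12.0], durations=[1.0, 2.0])
        cs, cns = [[6, 4], [3, 1]], [[8, 2], [2, 1]]
        og1 = vb.compute_or_grid(tiny_grid(cs, cns, spec=spec))
        og2 = vb.compute_or_grid(
            tiny_grid(2 * np.asarray(cs), 2 * np.asarray(cns), spec=spec)
        )
        np.testing.assert_allclose(og1.or_matrix, og2.or_matrix)
        assert og1.overall_or == pytest.approx(og2.overall_or)
        np.testing.assert_allclose(og1.deviation, og2.deviation)

    def test_zero_denominator_cells_flagged_undefined(self):
        spec = GridSpec(intensities=[10.0], durations=[1.0, 2.0])
        og = vb.compute_or_grid(tiny_grid([[3, 2]], [[4, 0]], spec=spec))
        assert og.defined.tolist() == [[True, False]]
        assert np.isnan(og.or_matrix[0, 1])

    def test_unnormalized_overall_or_differs_by_group_ratio(self):
        spec = GridSpec(intensities=[10.0], durations=[1.0])
        g = tiny_grid([[6]], [[4]], n_s=3, n_ns=1, spec=spec)
        norm = vb.compute_or_grid(g, normalized=True)
        raw = vb.compute_or_grid(g, normalized=False)
        assert norm.overall_or == pytest.approx((6 / 3) / (4 / 1))
        assert raw.overall_or == pytest.approx(6 / 4)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            vb.compute_or_grid(tiny_grid([[1]], [[1]], n_ns=0))
        with pytest.raises(ValueError, match="zero total"):
            vb.compute_or_grid(tiny_grid([[0]], [[5]]))


class TestContours:
    def test_zero_level_contour_tracks_analytic_line(self):
        spec = GridSpec()
        og = analytic_or_grid(
            lambda i, t: (i - 17.5) / 12.5 - t / 36.0, spec
        )
        curve = vb.fit_contour(og, 0.0)
        pts = curve.points.set_index("duration_h")["intensity"]
        for t, raw in pts.items():
            analytic = 17.5 + 12.5 * t / 36.0
            assert abs(raw - analytic) <= 1.0  # within one lattice step

    def test_no_crossing_returns_no_points_and_no_fit(self):
        og = analytic_or_grid(lambda i, t: 0.1 + 0 * i, GridSpec())
        curve = vb.fit_contour(og, -0.1)
        assert len(curve.points) == 0
        assert curve.fit_params is None
        with pytest.raises(ValueError, match="no fitted curve"):
            curve.predict([10.0])

    def test_power_fit_recovers_hyperbolic_contour(self):
        spec = GridSpec(
            intensities=np.arange(0.5, 30.5, 0.5), durations=np.arange(1.0, 73.0)
        )
        og = analytic_or_grid(lambda i, t: -0.002 * i * t, spec)
        curve = vb.fit_contour(og, -0.1)
        t = np.arange(4.0, 73.0)
        rel = np.abs(curve.predict(t) - 50.0 / t) / (50.0 / t)
        assert rel.max() < 0.05

    def test_fitted_curve_is_monotone_non_increasing(self, fitted_results):
        for c in fitted_results.contours:
            if c.fit_params is None:
                continue
            t = np.linspace(1, 72, 144)
            y = c.predict(t)
            assert (np.diff(y) <= 1e-9).all()

    def test_contours_ordered_by_level_do_not_cross(self):
        spec = GridSpec(
            intensities=np.arange(0.25, 30.25, 0.25),
            durations=np.arange(1.0, 73.0),
        )
        og = analytic_or_grid(lambda i, t: -0.002 * i * t, spec)
        curves = [vb.fit_contour(og, lvl) for lvl in (-0.05, -0.1, -0.2)]
        t = np.linspace(4, 72, 50)
        y = [c.predict(t) for c in curves]
        assert (y[1] >= y[0] - 1e-6).all() and (y[2] >= y[1] - 1e-6).all()

    def test_unknown_form_rejected(self):
        og = analytic_or_grid(lambda i, t: -0.002 * i * t, GridSpec())
        with pytest.raises(ValueError, match="form"):
            vb.fit_contour(og, -0.1, form="spline")


class TestFigures:
    def test_heatmap_written_for_zero_surface(self, tmp_path):
        og = analytic_or_grid(lambda i, t: 0.0 * i, GridSpec())
        path = render_heatmap(og, str(tmp_path / "h.png"))
        assert (tmp_path / "h.png").stat().st_size > 0

    def test_percentage_mode_uses_pct_surface(self, tmp_path):
        og = analytic_or_grid(lambda i, t: -0.001 * i * t, GridSpec())
        render_heatmap(og, str(tmp_path / "pct.png"), mode="percentage")
        assert (tmp_path / "pct.png").exists()
        with pytest.raises(ValueError, match="mode"):
            render_heatmap(og, str(tmp_path / "x.png"), mode="relative")

    def test_harmful_cohort_surface_has_expected_sign_structure(
        self, fitted_results
    ):
        """High-intensity/long-duration cells carry lower (more negative)
        deviation than low-intensity/short-duration cells under harm."""
        og = fitted_results.or_grid
        i, t = np.meshgrid(og.spec.intensities, og.spec.durations, indexing="ij")
        top_right = og.defined & (i >= 20) & (t >= 36)
        bottom_left = og.defined & (i <= 12) & (t <= 24)
        assert og.deviation[top_right].mean() < og.deviation[bottom_left].mean()

    def test_grid_plot_requires_fitted_contours(self, tmp_path):
        with pytest.raises(ValueError, match="no fitted contours"):
            grid_plot([], str(tmp_path / "g.png"))

    def test_grid_plot_written(self, tmp_path):
        spec = GridSpec()
        og = analytic_or_grid(lambda i, t: -0.002 * i * t, spec)
        curve = fit_contour(og, -0.1)
        grid_plot([curve], str(tmp_path / "g.png"), spec=spec)
        assert (tmp_path / "g.png").stat().st_size > 0
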