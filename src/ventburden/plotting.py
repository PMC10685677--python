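"""Heatmaps, contour grid plots and Kaplan-Meier figures."""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .surface import ContourCurve, ORGrid

__all__ = ["render_heatmap", "grid_plot", "km_plot"]

_LEVEL_COLORS = {0.0: "0.45", -0.1: "purple", -0.2: "black"}


def _level_color(level: float) -> str:
    return _LEVEL_COLORS.get(round(level, 3), "tab:green")


def render_heatmap(
    or_grid: ORGrid,
    path: str,
    mode: str = "absolute",
    contours: list[ContourCurve] | None = None,
) -> str:
    """Diverging blue-red heatmap of the (percentage) OR deviation.

    Duration runs along the horizontal axis, intensity along the vertical;
    the colour scale is symmetric about zero (blue = favourable, red =
    unfavourable); undefined cells are neutral grey.
    """
    if mode not in ("absolute", "percentage"):
        raise ValueError(f"unknown heatmap mode {mode!r}")
    surface = or_grid.deviation if mode == "absolute" else or_grid.pct_deviation
    data = np.ma.masked_invalid(np.where(or_grid.defined, surface, np.nan))
    vmax = float(np.abs(data).max()) if data.count() else 1.0
    vmax = vmax or 1.0

    spec = or_grid.spec
    fig, ax = plt.subplots(figsize=(8, 4.5))
    cmap = plt.get_cmap("RdBu").copy()
    cmap.set_bad("0.85")
    extent = (
        spec.durations[0] - 0.5, spec.durations[-1] + 0.5,
        spec.intensities[0] - 0.5, spec.intensities[-1] + 0.5,
    )
    im = ax.imshow(
        data, origin="lower", aspect="auto", cmap=cmap,
        vmin=-vmax, vmax=vmax, extent=extent,
    )
    for curve in contours or []:
        if curve.fit_params is not None:
            t = np.linspace(spec.durations[0], spec.durations[-1], 200)
            ax.plot(t, curve.predict(t), color=_level_color(curve.level), lw=2)
    ax.set_xlabel("exposure duration (h)")
    ax.set_ylabel("dynamic mechanical power (J/min)")
    ax.set_ylim(extent[2], extent[3])
    label = "OR deviation" if mode == "absolute" else "OR deviation (%)"
    fig.colorbar(im, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def grid_plot(contours: list[ContourCurve], path: str, spec=None) -> str:
    """Iso-risk contour curves on a labelled duration-intensity grid."""
    fitted = [c for c in contours if c.fit_params is not None]
    if not fitted:
        raise ValueError("no fitted contours to plot")
    fig, ax = plt.subplots(figsize=(8, 4.5))
    tmin = min(c.points["duration_h"].min() for c in fitted)
    tmax = max(c.points["duration_h"].max() for c in fitted)
    if spec is not None:
        tmin, tmax = spec.durations[0], spec.durations[-1]
    t = np.linspace(tmin, tmax, 300)
    for c in sorted(fitted, key=lambda c: -c.level):
        ax.plot(t, c.predict(t), color=_level_color(c.level),
                lw=2, label=f"deviation {c.level:g}")
        ax.plot(c.points["duration_h"], c.points["intensity"], ".",
                color=_level_color(c.level), ms=4, alpha=0.5)
    if spec is not None:
        ax.set_ylim(spec.intensities[0], spec.intensities[-1])
    ax.set_xlim(tmin, tmax)
    ax.grid(True, which="both", alpha=0.4)
    ax.set_xlabel("exposure duration (h)")
    ax.set_ylabel("dynamic mechanical power (J/min)")
    ax.legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def km_plot(km_result, path: str) -> str:
    """Kaplan-Meier survival curves per average-power quartile."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, sf in km_result.survival_functions.items():
        ax.step(sf.index, sf.iloc[:, 0], where="post", label=f"quartile {label}")
    ax.set_xlabel("days since start of ventilation")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(title=f"log-rank p = {km_result.p_value:.2g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
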