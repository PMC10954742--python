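"""Matplotlib views of the fitted analysis (heatmaps, densities, curves, maps).

Display-only: density curves use a Gaussian KDE purely for visual
smoothing, while all inference elsewhere runs on the exact eCDF medians.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .momentum import MomentumHeatmap
from .spatial import EntryPoint, TrajectoryPoint, build_trajectory
from .temporal import CumulativeCurve, DeltaDistribution


def _save(fig, path: Optional[Path | str]):
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_heatmap(heatmap: MomentumHeatmap, path: Optional[Path | str] = None):
    """Region × momentum species-count heatmap (regions east→west top-down)."""
    fig, ax = plt.subplots(figsize=(8, 0.5 * len(heatmap.counts) + 2))
    data = heatmap.counts.to_numpy()
    im = ax.imshow(data, aspect="auto", cmap="viridis")
    ax.set_xticks(range(data.shape[1]), [f"t{t}" for t in heatmap.counts.columns])
    ax.set_yticks(range(data.shape[0]), list(heatmap.counts.index))
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            if data[i, j]:
                ax.text(j, i, str(data[i, j]), ha="center", va="center", color="w", fontsize=7)
    ax.set_xlabel("momentum")
    ax.set_ylabel(heatmap.level)
    fig.colorbar(im, ax=ax, label="species")
    return _save(fig, path)


def plot_delta_densities(
    dists: Sequence[DeltaDistribution], path: Optional[Path | str] = None
):
    """Stacked KDE density curves of the per-step year-gap samples, median marked."""
    from scipy.stats import gaussian_kde

    fig, axes = plt.subplots(len(dists), 1, figsize=(7, 1.2 * len(dists)), sharex=True)
    axes = np.atleast_1d(axes)
    for ax, d in zip(axes, dists):
        vals = np.asarray(d.values, dtype=float)
        if vals.size > 1 and vals.std() > 0:
            xs = np.linspace(vals.min() - 1, vals.max() + 1, 200)
            ax.fill_between(xs, gaussian_kde(vals)(xs), alpha=0.5)
        else:
            ax.hist(vals, bins=5, density=True, alpha=0.5)
        ax.axvline(d.median, color="red")
        ax.set_ylabel(d.label, rotation=0, ha="right", fontsize=8)
    axes[-1].set_xlabel("years")
    return _save(fig, path)


def plot_cumulative_curves(
    curve_all: CumulativeCurve,
    curve_dom: Optional[CumulativeCurve] = None,
    path: Optional[Path | str] = None,
):
    """Cumulative median years vs momentum for both scenarios."""
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(1, curve_all.n_steps + 1)
    ax.plot(x, curve_all.cumulative, "o-", color="tab:blue", label="scenario 1: all cases")
    if curve_dom is not None:
        xd = np.arange(1, curve_dom.n_steps + 1)
        ax.plot(xd, curve_dom.cumulative, "s--", color="tab:red", label="scenario 2: dominant hotspots")
    ax.set_xticks(x, [f"t{k}" for k in x])
    ax.set_xlabel("momentum reached")
    ax.set_ylabel("cumulative median years since entry")
    ax.legend()
    return _save(fig, path)


def plot_trajectory_map(
    points: Sequence[TrajectoryPoint],
    polygons: Optional[dict] = None,
    entry: EntryPoint = EntryPoint(),
    path: Optional[Path | str] = None,
):
    """Hotspot polygons, centroids and the entry-anchored trajectory."""
    fig, ax = plt.subplots(figsize=(9, 5))
    if polygons:
        for geom in polygons.values():
            for part in getattr(geom, "geoms", [geom]):
                ax.plot(*part.exterior.xy, color="lightsteelblue", lw=0.7)
    for p in points:
        for part in getattr(p.hotspot_polygon, "geoms", [p.hotspot_polygon]):
            ax.fill(*part.exterior.xy, color="tomato", alpha=0.15)
    line = build_trajectory(points, entry)
    ax.plot(*line.xy, "k--", lw=1)
    ax.plot(entry.lon, entry.lat, "k*", ms=12)
    for p in points:
        ax.plot(*p.centroid, "ko", ms=4)
        ax.annotate(f"t{p.momentum_index}", p.centroid, fontsize=7, xytext=(3, 3),
                    textcoords="offset points")
    ax.set_xlabel("lon (°E)")
    ax.set_ylabel("lat (°N)")
    return _save(fig, path)
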