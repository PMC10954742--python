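"""Hotspot selection, buffered unions, centroids and the trajectory."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from nispread.momentum import MomentumHeatmap
from nispread.spatial import (
    BufferRangeWarning,
    EntryPoint,
    TrajectoryPoint,
    buffered_union,
    build_trajectory,
    load_polygons,
    polygon_centroid,
    select_dominant_hotspot,
    trajectory_geojson,
)


def heatmap_from_counts(counts: dict, momentum: int = 0) -> MomentumHeatmap:
    frame = pd.DataFrame({momentum: counts}).astype(int)
    return MomentumHeatmap(level="country", counts=frame)


def minimal_prefix_oracle(counts: dict) -> list[str]:
    """Exhaustive scan: shortest rank-ordered prefix strictly above half."""
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(counts.values())
    for k in range(1, len(ranked) + 1):
        if sum(n for _, n in ranked[:k]) * 2 > total:
            return [c for c, _ in ranked[:k]]
    return [c for c, _ in ranked]


def test_dominant_hotspot_worked_example():
    sel = select_dominant_hotspot(heatmap_from_counts({"A": 63, "B": 37, "C": 30}), 0)
    assert [c for c, _, _ in sel.ranked] == ["A", "B", "C"]
    assert sel.ranked[0][2] == pytest.approx(100 * 63 / 130, abs=0.05)
    assert sel.selected == ("A", "B")
    assert sel.cumulative_share_pct == pytest.approx(100 * 100 / 130)


def test_single_country_above_half_suffices():
    sel = select_dominant_hotspot(heatmap_from_counts({"A": 51, "B": 49}), 0)
    assert sel.selected == ("A",)


def test_exact_half_needs_second_country_tie_alphabetical():
    sel = select_dominant_hotspot(heatmap_from_counts({"B": 50, "A": 50}), 0)
    assert sel.selected == ("A", "B")  # strict >50; tie ranked alphabetically


def test_hotspot_errors():
    hm = heatmap_from_counts({"A": 0})
    with pytest.raises(ValueError):
        select_dominant_hotspot(hm, 0)
    with pytest.raises(ValueError):
        select_dominant_hotspot(hm, 3)


def test_hotspot_minimality_matches_exhaustive_scan():
    rng = np.random.default_rng(7)
    for _ in range(100):
        n = int(rng.integers(1, 8))
        counts = {f"C{i}": int(rng.integers(0, 40)) for i in range(n)}
        if sum(counts.values()) == 0:
            counts["C0"] = 1
        sel = select_dominant_hotspot(heatmap_from_counts(counts), 0)
        assert list(sel.selected) == minimal_prefix_oracle(
            {c: v for c, v in counts.items() if v > 0}
        )
        # removing the last selected country drops the share to <= 50%
        total = sum(v for v in counts.values())
        kept = sum(counts[c] for c in sel.selected[:-1])
        assert kept * 2 <= total


def unit_square(x0=0.0, y0=0.0, side=1.0) -> Polygon:
    return box(x0, y0, x0 + side, y0 + side)


def rasterized_dilation_area(buffer_deg: float, cell: float = 0.01) -> float:
    """Brute-force area of the unit square dilated by ``buffer_deg``.

    Cell centers within Euclidean distance of the square are counted; the
    distance uses plain coordinate clamping, independent of shapely.
    """
    pad = buffer_deg + 2 * cell
    xs = np.arange(-pad, 1 + pad, cell) + cell / 2
    ys = xs
    X, Y = np.meshgrid(xs, ys)
    dx = np.maximum(np.maximum(-X, X - 1.0), 0.0)
    dy = np.maximum(np.maximum(-Y, Y - 1.0), 0.0)
    inside = np.hypot(dx, dy) <= buffer_deg
    return float(inside.sum()) * cell * cell


def test_buffered_union_area_matches_rasterized_dilation():
    geom = buffered_union([unit_square()], 1.0)
    oracle = rasterized_dilation_area(1.0)
    assert geom.area == pytest.approx(oracle, rel=0.01)


def test_buffer_bridges_a_one_degree_gap():
    a, b = unit_square(0, 0), unit_square(2, 0)  # 1 degree apart
    merged = buffered_union([a, b], 1.0)
    assert merged.geom_type == "Polygon"


def test_buffer_outside_range_warns_or_raises():
    with pytest.warns(BufferRangeWarning):
        buffered_union([unit_square()], 0.5)
    with pytest.raises(ValueError):
        buffered_union([unit_square()], 0.5, strict=True)
    with pytest.raises(ValueError):
        buffered_union([], 1.0)


def test_buffer_monotone_in_radius():
    polys = [unit_square(), unit_square(3, 1)]
    assert buffered_union(polys, 3.0).area >= buffered_union(polys, 1.0).area


def shoelace_centroid(coords) -> tuple[float, float]:
    """Green's-theorem centroid of a simple ring, independent of shapely."""
    x, y = np.asarray(coords).T
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = cross.sum() / 2.0
    cx = ((x + x1) * cross).sum() / (6.0 * a)
    cy = ((y + y1) * cross).sum() / (6.0 * a)
    return float(cx), float(cy)


def random_convex_polygon(rng) -> Polygon:
    pts = rng.uniform(-5, 5, size=(int(rng.integers(4, 12)), 2))
    from scipy.spatial import ConvexHull

    hull = ConvexHull(pts)
    return Polygon(pts[hull.vertices])


def test_centroid_examples_and_errors():
    assert polygon_centroid(unit_square()) == pytest.approx((0.5, 0.5))
    two = unit_square(-0.5, -0.5).union(unit_square(3.5, -0.5))
    assert polygon_centroid(two) == pytest.approx((2.0, 0.0))
    with pytest.raises(ValueError):
        polygon_centroid(Polygon())


def test_centroid_matches_shoelace_oracle():
    rng = np.random.default_rng(11)
    for _ in range(50):
        poly = random_convex_polygon(rng)
        assert polygon_centroid(poly) == pytest.approx(
            shoelace_centroid(poly.exterior.coords[:-1]), abs=1e-9
        )


def test_centroid_translation_equivariance():
    rng = np.random.default_rng(5)
    poly = random_convex_polygon(rng)
    from shapely.affinity import translate

    cx, cy = polygon_centroid(poly)
    tx, ty = polygon_centroid(translate(poly, xoff=2.5, yoff=-1.25))
    assert (tx, ty) == pytest.approx((cx + 2.5, cy - 1.25))


def traj_points(centroids):
    return [
        TrajectoryPoint(i, unit_square(cx - 0.5, cy - 0.5), (cx, cy), 1.0)
        for i, (cx, cy) in enumerate(centroids)
    ]


def test_trajectory_has_momenta_plus_one_vertices():
    entry = EntryPoint()
    line = build_trajectory(traj_points([(30, 33), (28, 35), (25, 36)]), entry)
    assert len(line.coords) == 4
    assert line.coords[0] == (entry.lon, entry.lat)


def test_trajectory_with_identical_centroids_keeps_vertices():
    pts = traj_points([(30, 33), (30, 33)])
    assert len(build_trajectory(pts).coords) == 3


def test_trajectory_rejects_index_gaps():
    pts = traj_points([(30, 33), (28, 35)])
    gappy = [pts[0], TrajectoryPoint(2, pts[1].hotspot_polygon, pts[1].centroid, 1.0)]
    with pytest.raises(ValueError, match="gapless"):
        build_trajectory(gappy)


def test_trajectory_geojson_is_reproducible_bytes():
    pts = traj_points([(30, 33), (28, 35)])
    a = json.dumps(trajectory_geojson(pts), sort_keys=True)
    b = json.dumps(trajectory_geojson(pts), sort_keys=True)
    assert a == b
    roles = {f["properties"]["role"] for f in trajectory_geojson(pts)["features"]}
    assert roles == {"entry_point", "hotspot_polygon", "centroid", "trajectory"}


def test_packaged_polygon_fixture_covers_region_table():
    from nispread.regions import RegionTable

    polys = load_polygons()
    assert set(RegionTable.default().countries()) <= set(polys)
    for geom in polys.values():
        assert geom.is_valid and geom.area > 0
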