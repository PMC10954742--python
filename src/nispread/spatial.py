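"""Dominant-hotspot geometry and the entry-anchored spread trajectory.

At each momentum the countries are ranked by species count and the minimal
prefix whose cumulative share strictly exceeds 50% is the *dominant
hotspot*. The hotspot countries' EEZ polygons, each dilated by a 1°–3°
buffer and unioned, form the momentum's range polygon; its area-weighted
planar centroid is the momentum's location. Aligning the centroids of
t_0..t_max behind the entry point (the Mediterranean mouth of the Suez
Canal by default) yields the spread trajectory polyline.

All geometry is planar in WGS84 degree space, matching a GIS workflow over
lon/lat layers; at Mediterranean latitudes the departure from geodesic
centroids is small.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

from shapely.geometry import LineString, Point, mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .momentum import MomentumHeatmap

BUFFER_MIN_DEG = 1.0
BUFFER_MAX_DEG = 3.0


class BufferRangeWarning(UserWarning):
    """Buffer outside the 1°–3° range the method calls for."""


@dataclass(frozen=True)
class EntryPoint:
    """Anchor of every trajectory; defaults to the Suez Canal's Mediterranean mouth."""

    name: str = "Suez Canal"
    lon: float = 32.32
    lat: float = 31.28


@dataclass(frozen=True)
class HotspotSelection:
    """Ranked countries at one momentum and the minimal >50% prefix."""

    momentum_index: int
    ranked: tuple[tuple[str, int, float], ...]  # (country, count, share %)
    selected: tuple[str, ...]

    @property
    def cumulative_share_pct(self) -> float:
        shares = dict((c, s) for c, _, s in self.ranked)
        return sum(shares[c] for c in self.selected)


@dataclass(frozen=True)
class TrajectoryPoint:
    """One momentum's buffered hotspot polygon and its centroid."""

    momentum_index: int
    hotspot_polygon: BaseGeometry
    centroid: tuple[float, float]  # (lon, lat)
    buffer_deg: float
    countries: tuple[str, ...] = ()


def select_dominant_hotspot(
    heatmap: MomentumHeatmap, momentum_index: int
) -> HotspotSelection:
    """Pick the minimal country prefix holding >50% of a momentum's records.

    Countries are ranked by species count descending, ties broken
    alphabetically by code; the selection is the shortest prefix whose
    cumulative share strictly exceeds half the column total.
    """
    if momentum_index not in heatmap.counts.columns:
        raise ValueError(f"momentum {momentum_index} not tabulated")
    col = heatmap.counts[momentum_index]
    col = col[col > 0]
    total = int(col.sum())
    if total < 1:
        raise ValueError(f"no records at momentum {momentum_index}")
    ranked = sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))
    shares = [(c, int(n), 100.0 * n / total) for c, n in ranked]
    selected: list[str] = []
    cum = 0
    for c, n, _ in shares:
        selected.append(c)
        cum += n
        if 100.0 * cum / total > 50.0:
            break
    return HotspotSelection(
        momentum_index=momentum_index, ranked=tuple(shares), selected=tuple(selected)
    )


def buffered_union(
    polygons: Sequence[BaseGeometry],
    buffer_deg: float,
    clip: Optional[BaseGeometry] = None,
    strict: bool = False,
) -> BaseGeometry:
    """Dilate each polygon by ``buffer_deg`` (planar degrees) and union.

    The result may be multi-part. A buffer outside [1°, 3°] warns by
    default or raises with ``strict=True``. ``clip`` optionally intersects
    the union with a mask (e.g. a sea polygon).
    """
    polys = [p for p in polygons if p is not None and not p.is_empty]
    if not polys:
        raise ValueError("buffered_union requires at least one non-empty polygon")
    if not (BUFFER_MIN_DEG <= buffer_deg <= BUFFER_MAX_DEG):
        msg = f"buffer {buffer_deg}° outside the [{BUFFER_MIN_DEG}°, {BUFFER_MAX_DEG}°] expansion range"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, BufferRangeWarning, stacklevel=2)
    out = unary_union([p.buffer(buffer_deg) for p in polys])
    if clip is not None:
        out = out.intersection(clip)
    return out


def polygon_centroid(polygon: BaseGeometry) -> tuple[float, float]:
    """Area-weighted planar centroid (lon, lat) of a (multi)polygon."""
    if polygon is None or polygon.is_empty or polygon.area == 0.0:
        raise ValueError("degenerate zero-area geometry has no area centroid")
    c = polygon.centroid
    return (float(c.x), float(c.y))


def load_polygons(path: Optional[Path | str] = None) -> dict[str, BaseGeometry]:
    """Load country-keyed EEZ polygons from a GeoJSON FeatureCollection.

    Features must carry a ``country`` property. With no path, the packaged
    synthetic simplified fixture is loaded (coarse boxes for tests and
    examples — substitute real EEZ GeoJSON for faithful geography).
    """
    if path is None:
        raw = json.loads(
            resources.files("nispread.data").joinpath("eez_synthetic.geojson").read_text()
        )
    else:
        raw = json.loads(Path(path).read_text())
    out = {}
    for feat in raw["features"]:
        out[feat["properties"]["country"]] = shape(feat["geometry"])
    return out


def momentum_trajectory_points(
    heatmap: MomentumHeatmap,
    polygons: Mapping[str, BaseGeometry],
    buffer_deg: float = 1.0,
    max_momentum: int = 10,
    clip: Optional[BaseGeometry] = None,
) -> tuple[list[TrajectoryPoint], list[HotspotSelection]]:
    """Hotspot polygon + centroid per momentum with any data, in order.

    Stops at the first momentum with an empty column, so the returned
    indices are gapless 0..k.
    """
    if heatmap.level != "country":
        raise ValueError("trajectory hotspots are selected on the country-level heatmap")
    points, selections = [], []
    for t in range(max_momentum + 1):
        if t not in heatmap.counts.columns or heatmap.column_total(t) < 1:
            break
        sel = select_dominant_hotspot(heatmap, t)
        missing = [c for c in sel.selected if c not in polygons]
        if missing:
            raise KeyError(f"no polygon for hotspot countries {missing} at momentum {t}")
        poly = buffered_union([polygons[c] for c in sel.selected], buffer_deg, clip=clip)
        points.append(
            TrajectoryPoint(
                momentum_index=t,
                hotspot_polygon=poly,
                centroid=polygon_centroid(poly),
                buffer_deg=buffer_deg,
                countries=sel.selected,
            )
        )
        selections.append(sel)
    return points, selections


def build_trajectory(
    points: Sequence[TrajectoryPoint], entry: EntryPoint = EntryPoint()
) -> LineString:
    """Polyline from the entry point through every momentum centroid.

    Vertices are ``[entry, centroid(t_0), …, centroid(t_max)]`` — one more
    vertex than there are momenta. Momentum indices must be gapless from 0.
    """
    if not points:
        raise ValueError("build_trajectory requires at least one trajectory point")
    indices = [p.momentum_index for p in points]
    if indices != list(range(len(points))):
        raise ValueError(f"momentum indices must be gapless from 0, got {indices}")
    coords = [(entry.lon, entry.lat)] + [p.centroid for p in points]
    return LineString(coords)


def trajectory_geojson(
    points: Sequence[TrajectoryPoint],
    entry: EntryPoint = EntryPoint(),
    path: Optional[Path | str] = None,
) -> dict:
    """GeoJSON FeatureCollection: hotspot polygons, centroids, trajectory line."""
    line = build_trajectory(points, entry)
    features = [
        {
            "type": "Feature",
            "properties": {"role": "entry_point", "name": entry.name},
            "geometry": mapping(Point(entry.lon, entry.lat)),
        }
    ]
    for p in points:
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "role": "hotspot_polygon",
                    "momentum": p.momentum_index,
                    "buffer_deg": p.buffer_deg,
                    "countries": list(p.countries),
                },
                "geometry": mapping(p.hotspot_polygon),
            }
        )
        features.append(
            {
                "type": "Feature",
                "properties": {"role": "centroid", "momentum": p.momentum_index},
                "geometry": mapping(Point(*p.centroid)),
            }
        )
    features.append(
        {
            "type": "Feature",
            "properties": {"role": "trajectory", "n_momenta": len(points)},
            "geometry": mapping(line),
        }
    )
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(fc, sort_keys=True))
    return fc
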