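"""Model/Results objects tying the momentum framework together.

:class:`MomentumSpreadModel` is built from a detection-record table (a
DataFrame or a CSV path); ``fit()`` runs the whole analysis — momentum
sequencing, establishment classification, region heatmaps, per-step delta
distributions and cumulative median curves for the all-cases and
dominant-hotspot scenarios, hotspot geometry and the entry-anchored
trajectory — and returns a :class:`SpreadResults` carrying every
intermediate product plus ``summary()``, validation and export helpers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import momentum as mcore
from . import spatial, temporal
from .records import DetectionRecord, CleanReport, parse_records
from .regions import RegionTable
from .spatial import EntryPoint, HotspotSelection, TrajectoryPoint
from .temporal import CumulativeCurve, DeltaDistribution
from .validation import PointTrack, ValidationReport, validate_species


class MomentumSpreadModel:
    """Spatio-temporal spread model over first-detection records.

    Parameters
    ----------
    records
        Cleaned detection records (see :func:`nispread.records.parse_records`).
    region_table
        Country → MSFD mapping; packaged Mediterranean table by default.
    max_momentum
        Truncation of the analysis window (default t_0..t_10).
    buffer_deg
        Planar dilation, in degrees, applied to hotspot polygons (1°–3°).
    entry_point
        Trajectory anchor; Suez Canal Mediterranean mouth by default.
    polygons
        Country-keyed EEZ polygons; the packaged synthetic simplified
        fixture by default.
    """

    def __init__(
        self,
        records: Sequence[DetectionRecord],
        region_table: Optional[RegionTable] = None,
        max_momentum: int = mcore.DEFAULT_MAX_MOMENTUM,
        buffer_deg: float = 1.0,
        entry_point: Optional[EntryPoint] = None,
        polygons: Optional[Mapping] = None,
        clean_report: Optional[CleanReport] = None,
    ):
        if not records:
            raise ValueError("no detection records given")
        self.records = list(records)
        self.region_table = region_table or RegionTable.default()
        self.max_momentum = int(max_momentum)
        self.buffer_deg = float(buffer_deg)
        self.entry_point = entry_point or EntryPoint()
        self.polygons = dict(polygons) if polygons is not None else spatial.load_polygons()
        self.clean_report = clean_report

    @classmethod
    def from_csv(
        cls,
        path: Path | str,
        region_table: Optional[RegionTable] = None,
        columns: Optional[Mapping[str, str]] = None,
        **kwargs,
    ) -> "MomentumSpreadModel":
        """Parse + clean a record CSV and build the model from the survivors."""
        table = region_table or RegionTable.default()
        records, report = parse_records(path, table, columns=columns)
        return cls(records, region_table=table, clean_report=report, **kwargs)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        region_table: Optional[RegionTable] = None,
        **kwargs,
    ) -> "MomentumSpreadModel":
        """Build from an in-memory record table (runs the same cleaning)."""
        import tempfile

        with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
            df.to_csv(fh, index=False)
            tmp = fh.name
        try:
            return cls.from_csv(tmp, region_table=region_table, **kwargs)
        finally:
            Path(tmp).unlink(missing_ok=True)

    def fit(self) -> "SpreadResults":
        """Run the full momentum analysis."""
        series = mcore.build_all_series(self.records, self.region_table)
        heat_country = mcore.heatmap_counts(
            series, "country", self.region_table, self.max_momentum
        )
        heat_msfd = mcore.heatmap_counts(series, "msfd", self.region_table, self.max_momentum)

        points, selections = spatial.momentum_trajectory_points(
            heat_country, self.polygons, self.buffer_deg, self.max_momentum
        )

        # scenario-2 gate: a species contributes the Δt_k–t_(k-1) gap iff
        # its momentum-k country is inside that momentum's dominant hotspot
        sel_by_momentum = {s.momentum_index: set(s.selected) for s in selections}
        step_filters: dict[int, set[str]] = {}
        for step in range(1, self.max_momentum + 1):
            allowed = sel_by_momentum.get(step)
            if allowed is None:
                continue
            step_filters[step] = {
                s.species
                for s in series
                if len(s.steps) > step and s.country_at(step) in allowed
            }

        curve_all = temporal.cumulative_median_curve(
            series, "all", max_momentum=self.max_momentum
        )
        try:
            curve_dom = temporal.cumulative_median_curve(
                series, "dominant", step_filters=step_filters,
                max_momentum=curve_all.n_steps,
            )
        except temporal.EmptyDistributionError:
            curve_dom = None
        deviation = None
        if curve_dom is not None and curve_dom.n_steps == curve_all.n_steps:
            deviation = temporal.scenario_deviation(curve_all, curve_dom)

        deltas_all = [
            temporal.step_deltas(series, k) for k in range(1, curve_all.n_steps + 1)
        ]
        return SpreadResults(
            model=self,
            series=series,
            heatmap_country=heat_country,
            heatmap_msfd=heat_msfd,
            deltas_all=deltas_all,
            curve_all=curve_all,
            curve_dominant=curve_dom,
            deviation=deviation,
            hotspots=selections,
            trajectory_points=points,
        )


@dataclass
class SpreadResults:
    """Everything the fitted momentum analysis produced."""

    model: MomentumSpreadModel
    series: list[mcore.MomentumSeries]
    heatmap_country: mcore.MomentumHeatmap
    heatmap_msfd: mcore.MomentumHeatmap
    deltas_all: list[DeltaDistribution]
    curve_all: CumulativeCurve
    curve_dominant: Optional[CumulativeCurve]
    deviation: Optional[list[temporal.DeviationEntry]]
    hotspots: list[HotspotSelection]
    trajectory_points: list[TrajectoryPoint]

    # -- headline quantities -------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.series)

    @property
    def n_records(self) -> int:
        return len(self.model.records)

    @property
    def established_fraction(self) -> float:
        return mcore.established_fraction(self.series)

    @property
    def entry_share_pct(self) -> float:
        """Share of species whose first record (t_0) lies in the modal t_0 region."""
        sel = spatial.select_dominant_hotspot(self.heatmap_country, 0)
        return sel.ranked[0][2]

    def trajectory_line(self):
        return spatial.build_trajectory(self.trajectory_points, self.model.entry_point)

    # -- validation ----------------------------------------------------------
    def validate_track(self, track: PointTrack, window: int = 5) -> ValidationReport:
        """Ground-truth one invasive species against the fitted framework.

        Temporal information is read off the all-cases (scenario 1)
        cumulative curve.
        """
        return validate_species(
            track,
            self.trajectory_points,
            self.curve_all,
            window=window,
            entry=self.model.entry_point,
        )

    # -- presentation ---------------------------------------------------------
    def steps_table(self) -> pd.DataFrame:
        """Per-step medians, sample sizes, cumulative years and deviation."""
        rows = []
        for k in range(curve_len := self.curve_all.n_steps):
            row = {
                "step": f"dt{k + 1}-t{k}",
                "n": self.curve_all.ns[k],
                "median_all": self.curve_all.step_medians[k],
                "cumulative_all": self.curve_all.cumulative[k],
            }
            if self.curve_dominant is not None and k < self.curve_dominant.n_steps:
                row["median_dominant"] = self.curve_dominant.step_medians[k]
                row["cumulative_dominant"] = self.curve_dominant.cumulative[k]
            if self.deviation is not None:
                dev = self.deviation[k].deviation_pct
                row["deviation_pct"] = np.nan if dev is None else dev
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text overview in the spirit of a fitted-model summary table."""
        buf = io.StringIO()
        w = buf.write
        w("Momentum spread analysis\n")
        w("=" * 64 + "\n")
        w(f"species: {self.n_species:>6d}    records: {self.n_records}\n")
        est = self.established_fraction
        w(
            f"established (>= 3 momenta): {int(round(est * self.n_species))} "
            f"({100 * est:.1f}% of species)\n"
        )
        sel0 = spatial.select_dominant_hotspot(self.heatmap_country, 0)
        top0, n0, share0 = sel0.ranked[0]
        w(f"modal entry country at t0: {top0} ({n0} species, {share0:.1f}%)\n")
        w(f"analysis window: t0..t{self.model.max_momentum}; buffer {self.model.buffer_deg} deg\n\n")
        w(self.steps_table().to_string(index=False, float_format=lambda v: f"{v:.2f}"))
        w("\n\n")
        if self.curve_all.n_steps >= 2:
            w(
                f"mean step after dt1-t0 (all cases): "
                f"{self.curve_all.mean_step_after_first:.2f} years\n"
            )
        w(
            f"inferred time entry -> t{self.curve_all.n_steps}: "
            f"{self.curve_all.cumulative[-1]:.1f} years\n"
        )
        return buf.getvalue()

    # -- export ---------------------------------------------------------------
    def export(self, outdir: Path | str) -> list[Path]:
        """Write every tabular/geometric product; returns the paths written."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []

        def w(path: Path, text: str) -> None:
            path.write_text(text)
            written.append(path)

        w(outdir / "heatmap_country.csv", self.heatmap_country.to_long().to_csv(index=False))
        w(outdir / "heatmap_msfd.csv", self.heatmap_msfd.to_long().to_csv(index=False))
        long_deltas = pd.DataFrame(
            [(d.step, d.label, v) for d in self.deltas_all for v in d.values],
            columns=["step", "label", "delta_years"],
        )
        w(outdir / "step_deltas.csv", long_deltas.to_csv(index=False))
        w(outdir / "curves.csv", self.steps_table().to_csv(index=False))
        import json

        medians = {
            "all": {
                "step_medians": list(self.curve_all.step_medians),
                "cumulative": list(self.curve_all.cumulative),
                "n": list(self.curve_all.ns),
            }
        }
        if self.curve_dominant is not None:
            medians["dominant"] = {
                "step_medians": list(self.curve_dominant.step_medians),
                "cumulative": list(self.curve_dominant.cumulative),
                "n": list(self.curve_dominant.ns),
            }
        w(outdir / "medians.json", json.dumps(medians, indent=2, sort_keys=True))
        hot = pd.DataFrame(
            [
                (s.momentum_index, c, n, share, c in s.selected)
                for s in self.hotspots
                for c, n, share in s.ranked
            ],
            columns=["momentum", "country", "count", "share_pct", "selected"],
        )
        w(outdir / "hotspots.csv", hot.to_csv(index=False))
        fc = spatial.trajectory_geojson(self.trajectory_points, self.model.entry_point)
        w(outdir / "trajectory.geojson", json.dumps(fc, sort_keys=True))
        w(outdir / "summary.txt", self.summary())
        return written
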