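"""End-to-end orchestration with a reproducible run manifest.

``run_pipeline`` executes parse → clean → momenta → heatmaps → deltas →
cumulative curves (both scenarios) → hotspots → trajectory →
(optionally) per-species validation, writes every module's outputs under
one directory, and finishes with ``manifest.json`` recording the config
echo, package version, input SHA-256 hashes and output checksums. The same
inputs and config always yield byte-identical outputs; plots are opt-in
because raster output is presentation, not analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import __version__
from .model import MomentumSpreadModel
from .regions import RegionTable
from .spatial import EntryPoint, load_polygons
from .validation import PointTrack

log = logging.getLogger("nispread")


class PipelineError(RuntimeError):
    """An analysis stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything one reproducible run needs.

    ``records_csv`` is the cleaned-or-raw detection table;
    ``validation_csv`` (species, year, lon, lat) switches on the
    ground-truth stage, with ``validation_exclusions`` as
    ``{species: [[year, reason], ...]}``.
    """

    records_csv: str
    out_dir: str
    columns: Optional[Mapping[str, str]] = None
    msfd_defaults: Optional[Mapping[str, str]] = None
    max_momentum: int = 10
    buffer_deg: float = 1.0
    entry_point: tuple[float, float] = (32.32, 31.28)
    dominant_threshold_pct: float = 50.0
    window: int = 5
    polygons_geojson: Optional[str] = None
    validation_csv: Optional[str] = None
    validation_exclusions: Mapping[str, Sequence[Sequence]] = field(default_factory=dict)
    plots: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 < self.dominant_threshold_pct < 100.0):
            raise ValueError("dominant threshold must be in (0, 100)")

    @classmethod
    def from_json(cls, path: Path | str) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name: str, fn, *args, **kwargs):
        log.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, exc) from exc

    table = stage(
        "regions", RegionTable.default, defaults_override=config.msfd_defaults
    )
    polygons = stage("polygons", load_polygons, config.polygons_geojson)
    entry = EntryPoint(lon=config.entry_point[0], lat=config.entry_point[1])
    model = stage(
        "ingest",
        MomentumSpreadModel.from_csv,
        config.records_csv,
        region_table=table,
        columns=config.columns,
        max_momentum=config.max_momentum,
        buffer_deg=config.buffer_deg,
        entry_point=entry,
        polygons=polygons,
    )
    results = stage("fit", model.fit)
    written = stage("export", results.export, outdir)
    if model.clean_report is not None:
        p = outdir / "clean_report.json"
        model.clean_report.to_json(p)
        written.append(p)

    if config.validation_csv:
        import pandas as pd

        vdf = stage("validation-read", pd.read_csv, config.validation_csv)
        reports = {}
        for species in sorted(vdf["species"].unique()):
            excl = tuple(
                (int(y), str(r)) for y, r in config.validation_exclusions.get(species, [])
            )
            track = stage(
                f"validation:{species}", PointTrack.from_frame, vdf, species, excl
            )
            reports[species] = stage(
                f"validate:{species}", results.validate_track, track, config.window
            ).to_dict()
        p = outdir / "validation.json"
        p.write_text(json.dumps(reports, indent=2, sort_keys=True))
        written.append(p)

    if config.plots:
        from . import plotting

        stage("plot-heatmap", plotting.plot_heatmap, results.heatmap_country,
              outdir / "heatmap_country.png")
        stage("plot-densities", plotting.plot_delta_densities, results.deltas_all,
              outdir / "step_deltas.png")
        stage("plot-curves", plotting.plot_cumulative_curves, results.curve_all,
              results.curve_dominant, outdir / "curves.png")
        stage("plot-map", plotting.plot_trajectory_map, results.trajectory_points,
              polygons, entry, outdir / "trajectory.png")
        written += [outdir / n for n in
                    ("heatmap_country.png", "step_deltas.png", "curves.png", "trajectory.png")]

    inputs = {config.records_csv: _sha256(Path(config.records_csv))}
    if config.validation_csv:
        inputs[config.validation_csv] = _sha256(Path(config.validation_csv))
    if config.polygons_geojson:
        inputs[config.polygons_geojson] = _sha256(Path(config.polygons_geojson))
    manifest = {
        "package": {"name": "nispread", "version": __version__},
        "config": dataclasses.asdict(config),
        "inputs_sha256": inputs,
        "outputs_sha256": {
            p.name: _sha256(Path(p)) for p in sorted(written, key=lambda q: Path(q).name)
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
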