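"""Model/Results surface, pipeline orchestration and the CLI."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import pytest
from click.testing import CliRunner

from nispread.cli import main as cli_main
from nispread.model import MomentumSpreadModel
from nispread.pipeline import PipelineError, RunConfig, run_pipeline
from nispread.simulate import IntervalDist, SpreadConfig, generate_spread_dataset, write_spread_csv


@pytest.fixture(scope="module")
def spread_df():
    cfg = SpreadConfig(
        n_species=25,
        step_interval=IntervalDist("geometric", p=0.4),
        established_fraction=0.6,
        max_steps=8,
        seed=17,
    )
    df, truth = generate_spread_dataset(cfg)
    return df, truth


@pytest.fixture(scope="module")
def fitted(spread_df):
    df, _ = spread_df
    return MomentumSpreadModel.from_dataframe(df).fit()


def test_fit_produces_coherent_results(fitted, spread_df):
    _, truth = spread_df
    assert fitted.n_species == 25
    assert fitted.established_fraction == truth.established_fraction
    # both scenario curves cover the same steps and deviation is defined
    assert fitted.curve_dominant is not None
    assert fitted.curve_dominant.n_steps == fitted.curve_all.n_steps
    assert fitted.deviation is not None
    # trajectory has one vertex per momentum plus the entry anchor
    line = fitted.trajectory_line()
    assert len(line.coords) == len(fitted.trajectory_points) + 1


def test_generated_westward_chain_yields_northwest_net_displacement(fitted):
    first = fitted.trajectory_points[0].centroid
    last = fitted.trajectory_points[-1].centroid
    assert last[0] < first[0]  # net westward along the east→west chain
    assert last[1] > first[1]  # and net northward


def test_summary_reports_headline_numbers(fitted):
    text = fitted.summary()
    assert "species:     25" in text
    assert "established" in text and "%" in text
    assert "dt1-t0" in text


def test_steps_table_has_scenarios_and_deviation(fitted):
    table = fitted.steps_table()
    assert {"step", "n", "median_all", "cumulative_all"} <= set(table.columns)
    assert "deviation_pct" in table.columns
    assert (table["cumulative_all"].diff().dropna() >= 0).all()


def test_export_writes_expected_files(fitted, tmp_path):
    written = fitted.export(tmp_path / "out")
    names = {p.name for p in written}
    assert {
        "heatmap_country.csv",
        "heatmap_msfd.csv",
        "step_deltas.csv",
        "curves.csv",
        "medians.json",
        "hotspots.csv",
        "trajectory.geojson",
        "summary.txt",
    } <= names


def test_from_csv_and_dataframe_agree(spread_df, tmp_path):
    df, _ = spread_df
    path = tmp_path / "records.csv"
    write_spread_csv(df, path)
    a = MomentumSpreadModel.from_csv(path).fit()
    b = MomentumSpreadModel.from_dataframe(df).fit()
    assert a.curve_all == b.curve_all
    assert a.heatmap_country.counts.equals(b.heatmap_country.counts)


def make_run_config(tmp_path, df, **overrides) -> RunConfig:
    records = tmp_path / "records.csv"
    write_spread_csv(df, records)
    kwargs = dict(records_csv=str(records), out_dir=str(tmp_path / "out"))
    kwargs.update(overrides)
    return RunConfig(**kwargs)


def test_run_pipeline_manifest_lists_outputs_and_hashes(tmp_path, spread_df):
    df, _ = spread_df
    manifest = run_pipeline(make_run_config(tmp_path, df))
    assert manifest["package"]["name"] == "nispread"
    outs = manifest["outputs_sha256"]
    assert "curves.csv" in outs and "trajectory.geojson" in outs and "clean_report.json" in outs
    for name, digest in outs.items():
        assert (Path(tmp_path) / "out" / name).exists()
        assert len(digest) == 64
    # input hash present and correct length
    assert all(len(h) == 64 for h in manifest["inputs_sha256"].values())


def test_run_pipeline_momentum_cap_bounds_heatmap_columns(tmp_path, spread_df):
    df, _ = spread_df
    run_pipeline(make_run_config(tmp_path, df, max_momentum=10))
    hm = pd.read_csv(tmp_path / "out" / "heatmap_country.csv")
    assert hm["momentum"].nunique() <= 11
    assert hm["momentum"].max() <= 10


def test_run_pipeline_validation_stage(tmp_path, spread_df):
    from nispread.simulate import generate_point_tracks

    df, _ = spread_df
    track, _ = generate_point_tracks(
        n_years=6, start_lonlat=(33.5, 31.5), drift_per_year=(-0.8, 0.5),
        scatter_sd=0.1, points_per_year=15, seed=6, species="ias-a",
    )
    vcsv = tmp_path / "points.csv"
    pd.DataFrame(track.points, columns=["year", "lon", "lat"]).assign(species="ias-a").to_csv(
        vcsv, index=False
    )
    cfg = make_run_config(tmp_path, df, validation_csv=str(vcsv))
    run_pipeline(cfg)
    reports = json.loads((tmp_path / "out" / "validation.json").read_text())
    rep = reports["ias-a"]
    assert rep["trajectory_validated"] is True
    assert rep["actual_duration"] == 6
    assert 0 < rep["temporal_validation_pct"] <= 100


def test_pipeline_error_names_failed_stage(tmp_path):
    cfg = RunConfig(records_csv=str(tmp_path / "missing.csv"), out_dir=str(tmp_path / "o"))
    with pytest.raises(PipelineError, match="ingest"):
        run_pipeline(cfg)


def test_run_config_threshold_bounds(tmp_path):
    with pytest.raises(ValueError):
        RunConfig(records_csv="x", out_dir="y", dominant_threshold_pct=0.0)


def test_cli_simulate_then_run_all_and_rerun_identical(tmp_path, spread_df):
    runner = CliRunner()
    sim_dir = tmp_path / "sim"
    r = runner.invoke(
        cli_main,
        ["simulate", "--out", str(sim_dir), "--n-species", "20", "--seed", "3",
         "--established-fraction", "0.5"],
    )
    assert r.exit_code == 0, r.output
    cfg = {
        "records_csv": str(sim_dir / "records_synthetic.csv"),
        "out_dir": str(tmp_path / "run1"),
    }
    cfg_path = tmp_path / "config.json"
    cfg_path.write_text(json.dumps(cfg))
    r1 = runner.invoke(cli_main, ["run-all", "--config", str(cfg_path)])
    assert r1.exit_code == 0, r1.output
    snapshot = {
        p.name: p.read_bytes() for p in sorted((tmp_path / "run1").iterdir())
    }
    r2 = runner.invoke(cli_main, ["run-all", "--config", str(cfg_path)])
    assert r2.exit_code == 0
    for p in sorted((tmp_path / "run1").iterdir()):
        assert p.read_bytes() == snapshot[p.name], f"{p.name} changed between reruns"


def test_cli_stage_commands(tmp_path, spread_df):
    df, _ = spread_df
    records = tmp_path / "records.csv"
    write_spread_csv(df, records)
    runner = CliRunner()
    for cmd in (
        ["ingest", str(records), "--out", str(tmp_path / "a")],
        ["momentum", str(records), "--out", str(tmp_path / "b")],
        ["temporal", str(records), "--out", str(tmp_path / "c")],
        ["spatial", str(records), "--out", str(tmp_path / "d")],
    ):
        r = runner.invoke(cli_main, cmd)
        assert r.exit_code == 0, (cmd, r.output)
    assert (tmp_path / "a" / "records_clean.csv").exists()
    assert (tmp_path / "d" / "trajectory.geojson").exists()


def test_cli_run_all_fails_nonzero_on_bad_input(tmp_path):
    cfg_path = tmp_path / "config.json"
    cfg_path.write_text(json.dumps({"records_csv": str(tmp_path / "nope.csv"),
                                    "out_dir": str(tmp_path / "o")}))
    r = CliRunner().invoke(cli_main, ["run-all", "--config", str(cfg_path)])
    assert r.exit_code != 0
    assert "ingest" in r.output


def test_plots_are_written_when_enabled(tmp_path, spread_df):
    df, _ = spread_df
    cfg = make_run_config(tmp_path, df, plots=True)
    manifest = run_pipeline(cfg)
    assert "curves.png" in manifest["outputs_sha256"]
    assert (tmp_path / "out" / "trajectory.png").stat().st_size > 0
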