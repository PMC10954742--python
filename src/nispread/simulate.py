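"""Synthetic first-record datasets and point tracks with known ground truth.

The spread generator emulates the structure of a historical first-record
table: each species enters the basin in a configurable entry region in a
uniform random year, then advances stepwise along an ordered east→west
region chain with inter-record year gaps drawn i.i.d. from a configurable
integer distribution (fixed, geometric on {1, 2, …}, or an explicit
discrete table). Truncation at a maximum step count — or at a configured
established fraction — controls how many species reach three regions and
hence count as established. An optional additive detection lag models
late reporting. Everything is driven by one mandatory seed, so a given
config reproduces its dataset byte for byte.

What this emulates: the sequencing structure (one first record per region,
non-decreasing years, a shared entry region and direction of travel). What
it does not: environmental forcing, species interactions, uneven sampling
effort, or back-and-forth spread — so recovery tests exercise the
numerical pipeline, not ecological realism.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .validation import PointTrack

DEFAULT_CHAIN = ("IL", "LB", "SY", "CY", "TR", "GR", "LY", "MT", "TN", "IT", "DZ", "ES")


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class IntervalDist:
    """Integer step-interval distribution: fixed k, geometric(p), or a table.

    ``kind='fixed'`` uses ``k`` years for every step. ``kind='geometric'``
    draws from the geometric distribution on {1, 2, …} with success
    probability ``p`` (median ⌈ln 0.5 / ln(1−p)⌉). ``kind='table'`` draws
    from explicit ``values`` with ``probs``.
    """

    kind: str = "fixed"
    k: int = 3
    p: float = 0.5
    values: tuple[int, ...] = ()
    probs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "fixed":
            if self.k < 0:
                raise ConfigError("fixed interval must be ≥ 0")
        elif self.kind == "geometric":
            if not (0.0 < self.p < 1.0):
                raise ConfigError(f"geometric p must be in (0,1), got {self.p}")
        elif self.kind == "table":
            if not self.values or len(self.values) != len(self.probs):
                raise ConfigError("table distribution needs matching values/probs")
            if any(v < 0 for v in self.values):
                raise ConfigError("table values must be ≥ 0")
            if not math.isclose(sum(self.probs), 1.0, abs_tol=1e-9):
                raise ConfigError("table probs must sum to 1")
        else:
            raise ConfigError(f"unknown interval distribution kind {self.kind!r}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(size, self.k, dtype=int)
        if self.kind == "geometric":
            return rng.geometric(self.p, size=size)
        return rng.choice(np.asarray(self.values, dtype=int), size=size, p=self.probs)

    @property
    def true_median(self) -> float:
        """Population median of the configured distribution."""
        if self.kind == "fixed":
            return float(self.k)
        if self.kind == "geometric":
            return float(math.ceil(math.log(0.5) / math.log(1.0 - self.p)))
        order = np.argsort(self.values)
        vals = np.asarray(self.values, dtype=float)[order]
        cum = np.cumsum(np.asarray(self.probs, dtype=float)[order])
        lo = vals[np.searchsorted(cum, 0.5, side="left")]
        hi = vals[np.searchsorted(cum, 0.5, side="right")]
        return float((lo + hi) / 2.0)


@dataclass(frozen=True)
class SpreadConfig:
    """Ground-truth parameters of one synthetic spread dataset."""

    n_species: int = 100
    region_chain: tuple[str, ...] = DEFAULT_CHAIN
    entry_region: str = "IL"
    entry_year_range: tuple[int, int] = (1950, 2000)
    step_interval: IntervalDist = field(default_factory=IntervalDist)
    max_steps: int = 8
    established_fraction: Optional[float] = None
    detection_lag: Optional[IntervalDist] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ConfigError("n_species must be ≥ 1")
        if self.entry_region not in self.region_chain:
            raise ConfigError(
                f"entry region {self.entry_region!r} not in chain {self.region_chain}"
            )
        if self.entry_year_range[0] > self.entry_year_range[1]:
            raise ConfigError("entry_year_range reversed")
        if self.max_steps < 1:
            raise ConfigError("max_steps must be ≥ 1")
        if self.established_fraction is not None and not (
            0.0 <= self.established_fraction <= 1.0
        ):
            raise ConfigError("established_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Generator-side truth to score pipeline recovery against."""

    config: SpreadConfig
    sequences: dict[str, list[tuple[int, str, int]]]  # species → [(momentum, country, year)]
    intervals: dict[str, list[int]]  # species → true year gaps (pre-lag)
    established: dict[str, bool]

    @property
    def established_fraction(self) -> float:
        return sum(self.established.values()) / len(self.established)

    def to_json(self, path: Optional[Path] = None) -> str:
        payload = json.dumps(
            {
                "config": dataclasses.asdict(self.config),
                "sequences": self.sequences,
                "intervals": self.intervals,
                "established": self.established,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def generate_spread_dataset(config: SpreadConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a detection-record table plus its ground truth.

    Returns a DataFrame in the record-CSV dialect (species, year, country)
    ordered by species then momentum, and the :class:`GroundTruth`.
    Identical config (seed included) reproduces identical output.
    """
    rng = np.random.default_rng(config.seed)
    chain = list(config.region_chain)
    start = chain.index(config.entry_region)
    reachable = len(chain) - start - 1  # steps available beyond entry

    n = config.n_species
    if config.established_fraction is not None:
        n_est = int(round(n * config.established_fraction))
        if reachable < 2 and n_est > 0:
            raise ConfigError("chain too short for established species (needs ≥ 2 steps)")
        flags = np.zeros(n, dtype=bool)
        flags[rng.choice(n, size=n_est, replace=False)] = True
        # established species get ≥ 2 onward steps (≥ 3 regions), others ≤ 1
        n_steps = np.where(
            flags,
            rng.integers(2, max(min(config.max_steps, reachable), 2) + 1, size=n),
            rng.integers(0, 2, size=n),
        )
    else:
        n_steps = np.full(n, min(config.max_steps, reachable), dtype=int)

    entry_years = rng.integers(
        config.entry_year_range[0], config.entry_year_range[1] + 1, size=n
    )

    rows = []
    sequences: dict[str, list[tuple[int, str, int]]] = {}
    intervals: dict[str, list[int]] = {}
    established: dict[str, bool] = {}
    for i in range(n):
        species = f"sp{i:04d}"
        k = int(n_steps[i])
        gaps = config.step_interval.sample(rng, k) if k else np.empty(0, dtype=int)
        years = [int(entry_years[i])]
        for g in gaps:
            years.append(years[-1] + int(g))
        seq = [
            (m, chain[start + m], years[m])
            for m in range(k + 1)
        ]
        if config.detection_lag is not None:
            lags = config.detection_lag.sample(rng, len(seq))
            seq = [(m, c, y + int(lag)) for (m, c, y), lag in zip(seq, lags)]
        sequences[species] = [list(t) for t in seq]  # json-friendly
        intervals[species] = [int(g) for g in gaps]
        established[species] = len(seq) >= 3
        for m, c, y in seq:
            rows.append({"species": species, "year": y, "country": c})
    df = pd.DataFrame(rows, columns=["species", "year", "country"])
    truth = GroundTruth(
        config=config, sequences=sequences, intervals=intervals, established=established
    )
    return df, truth


def write_spread_csv(df: pd.DataFrame, path: Path | str) -> None:
    df.to_csv(path, index=False)


def generate_point_tracks(
    n_years: int,
    start_lonlat: tuple[float, float],
    drift_per_year: tuple[float, float],
    scatter_sd: float,
    points_per_year: int,
    seed: int,
    species: str = "synthetic-ias",
    start_year: int = 2008,
) -> tuple[PointTrack, tuple[float, float]]:
    """Yearly Gaussian point clouds drifting linearly across the map.

    Returns the track and the true endmost centroid
    ``start + (n_years−1)·drift``. ``scatter_sd`` (degrees) must be
    non-negative; zero gives points exactly on the drift line.
    """
    if n_years < 2:
        raise ConfigError("n_years must be ≥ 2")
    if scatter_sd < 0:
        raise ConfigError("scatter_sd must be ≥ 0")
    if points_per_year < 1:
        raise ConfigError("points_per_year must be ≥ 1")
    rng = np.random.default_rng(seed)
    lon0, lat0 = start_lonlat
    dlon, dlat = drift_per_year
    pts = []
    for j in range(n_years):
        mu = (lon0 + j * dlon, lat0 + j * dlat)
        noise = rng.normal(0.0, scatter_sd, size=(points_per_year, 2)) if scatter_sd else np.zeros((points_per_year, 2))
        for dx, dy in noise:
            pts.append((start_year + j, mu[0] + float(dx), mu[1] + float(dy)))
    true_end = (lon0 + (n_years - 1) * dlon, lat0 + (n_years - 1) * dlat)
    return PointTrack(species=species, points=tuple(pts)), true_end
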