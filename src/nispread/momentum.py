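"""Momentum sequencing of detection records.

A species' *momentum* t_x is its x-th first record in a country it had not
previously been sighted in, taken in ascending temporal order: t_0 is the
first record anywhere in the basin, t_1 the first record in a second
country, and so on. Repeat sightings inside an already-occupied country
never advance the momentum. A species with at least three momenta
(t_x ≥ t_2) is classed as established.

Ties between two first records in the same year are broken by input row
order (``source_rank``), which makes the sequencing deterministic and
permutation-stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, NamedTuple, Optional, Sequence

import pandas as pd

from .records import DetectionRecord
from .regions import RegionTable

DEFAULT_MAX_MOMENTUM = 10


class MomentumStep(NamedTuple):
    index: int
    country: str
    msfd: str
    year: int


@dataclass(frozen=True)
class MomentumSeries:
    """One species' ordered first-records per country, indexed t_0 … t_n."""

    species: str
    steps: tuple[MomentumStep, ...]

    def __len__(self) -> int:
        return len(self.steps)

    def year_at(self, index: int) -> int:
        return self.steps[index].year

    def country_at(self, index: int) -> str:
        return self.steps[index].country


@dataclass(frozen=True)
class MomentumHeatmap:
    """Species counts per region × momentum index (long/wide views).

    ``counts`` is a wide DataFrame: rows are regions in east→west order,
    columns momentum indices 0..max. Cell (r, t) is the number of species
    whose momentum-t first record lies in region r.
    """

    level: Literal["country", "msfd"]
    counts: pd.DataFrame

    def column_total(self, momentum: int) -> int:
        return int(self.counts[momentum].sum())

    def to_long(self) -> pd.DataFrame:
        long = (
            self.counts.rename_axis(index="region", columns="momentum")
            .stack()
            .rename("count")
            .reset_index()
        )
        long["count"] = long["count"].astype(int)
        return long


def assign_momenta(
    records: Sequence[DetectionRecord], region_table: RegionTable
) -> MomentumSeries:
    """Build one species' momentum series from its cleaned records.

    For each country only the earliest record counts (year ties broken by
    smallest ``source_rank``); the survivors sorted by ``(year,
    source_rank)`` define momenta 0..n-1. Same-year transitions between
    different countries are legal and yield a zero year-gap downstream.
    """
    if not records:
        raise ValueError("assign_momenta requires at least one record")
    species = records[0].species
    if any(r.species != species for r in records):
        raise ValueError("assign_momenta expects records of a single species")
    first_per_country: dict[str, DetectionRecord] = {}
    for rec in records:
        cur = first_per_country.get(rec.country)
        if cur is None or (rec.year, rec.source_rank) < (cur.year, cur.source_rank):
            first_per_country[rec.country] = rec
    ordered = sorted(first_per_country.values(), key=lambda r: (r.year, r.source_rank))
    steps = tuple(
        MomentumStep(
            index=i,
            country=r.country,
            msfd=region_table.msfd_for(r.country, r.msfd_override),
            year=r.year,
        )
        for i, r in enumerate(ordered)
    )
    return MomentumSeries(species=species, steps=steps)


def build_all_series(
    records: Iterable[DetectionRecord], region_table: RegionTable
) -> list[MomentumSeries]:
    """Group records by species (first-appearance order) and sequence each."""
    by_species: dict[str, list[DetectionRecord]] = {}
    for rec in records:
        by_species.setdefault(rec.species, []).append(rec)
    return [assign_momenta(recs, region_table) for recs in by_species.values()]


def classify_established(series: MomentumSeries) -> bool:
    """True iff the species has at least three successive momenta."""
    return len(series.steps) >= 3


def established_fraction(all_series: Sequence[MomentumSeries]) -> float:
    """Share of species classed as established, in [0, 1]."""
    if not all_series:
        raise ValueError("no series given")
    return sum(classify_established(s) for s in all_series) / len(all_series)


def heatmap_counts(
    all_series: Sequence[MomentumSeries],
    level: Literal["country", "msfd"],
    region_table: Optional[RegionTable] = None,
    max_momentum: int = DEFAULT_MAX_MOMENTUM,
) -> MomentumHeatmap:
    """Aggregate momenta into a region × momentum species-count matrix.

    Rows cover every region that hosts at least one record (plus, when a
    region table is given, all its regions in east→west order); columns run
    t_0 .. t_max even if empty. Species lacking momentum t contribute
    nothing in column t, so column totals are non-increasing in t.
    """
    if level not in ("country", "msfd"):
        raise ValueError(f"level must be 'country' or 'msfd', got {level!r}")
    if not all_series:
        raise ValueError("heatmap_counts requires at least one series")
    if region_table is not None:
        if level == "msfd":
            regions = list(region_table.msfd_order)
        else:
            regions = list(region_table.countries())
    else:
        regions = []
    counts: dict[str, dict[int, int]] = {r: {} for r in regions}
    for series in all_series:
        for step in series.steps:
            if step.index > max_momentum:
                break
            region = step.country if level == "country" else step.msfd
            counts.setdefault(region, {})[step.index] = (
                counts.setdefault(region, {}).get(step.index, 0) + 1
            )
    frame = pd.DataFrame(
        {t: {r: counts.get(r, {}).get(t, 0) for r in counts} for t in range(max_momentum + 1)},
        index=list(counts),
    ).astype(int)
    # regions with zero records are excluded from tabulations
    frame = frame.loc[frame.sum(axis=1) > 0]
    return MomentumHeatmap(level=level, counts=frame)
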