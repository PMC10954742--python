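"""Reading, validating and cleaning first-detection record tables.

A detection record is one dated, region-tagged sighting of one species:
``(species, year, country[, lon, lat[, msfd]])``. Input CSVs are screened
row by row — unknown country codes, non-integer or out-of-range years and
half-present coordinates are dropped and counted; exact
``(species, country, year)`` duplicates are collapsed to the first
occurrence. Records of the same species in the same country in *different*
years survive cleaning; the momentum sequencing step later keeps only the
earliest per country.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .regions import RegionTable

MIN_YEAR = 1800

DEFAULT_COLUMNS: Mapping[str, str] = {
    "species": "species",
    "year": "year",
    "country": "country",
    "lon": "lon",
    "lat": "lat",
    "msfd": "msfd",
}


class SchemaError(ValueError):
    """A required column is missing from the input CSV."""


class EmptyInputError(ValueError):
    """No record survived cleaning."""


@dataclass(frozen=True)
class DetectionRecord:
    """One cleaned sighting of one species in one country-year.

    ``source_rank`` is the original input-file row index (0-based, header
    excluded); it gives deterministic tie-breaking when two first records
    share a year.
    """

    species: str
    year: int
    country: str
    lon: Optional[float] = None
    lat: Optional[float] = None
    msfd_override: Optional[str] = None
    source_rank: int = 0


@dataclass
class CleanReport:
    """Bookkeeping of the cleaning pass; counts always sum to ``n_input``."""

    n_input: int = 0
    n_dropped_invalid: int = 0
    n_dropped_duplicate: int = 0
    n_kept: int = 0
    messages: list[str] = field(default_factory=list)

    def check(self) -> None:
        assert self.n_input == self.n_dropped_invalid + self.n_dropped_duplicate + self.n_kept

    def to_json(self, path: Optional[Path] = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _max_year() -> int:
    return datetime.date.today().year


def _row_problem(
    species: object,
    year: object,
    country: object,
    lon: object,
    lat: object,
    msfd: object,
    region_table: RegionTable,
) -> Optional[str]:
    """Return a human-readable reason to drop the row, or None if valid."""
    if species is None or (isinstance(species, float) and pd.isna(species)) or str(species).strip() == "":
        return "missing species name"
    try:
        y = int(year)
        if float(year) != y:
            return f"non-integer year {year!r}"
    except (TypeError, ValueError):
        return f"non-integer year {year!r}"
    if not (MIN_YEAR <= y <= _max_year()):
        return f"year {y} outside [{MIN_YEAR}, {_max_year()}]"
    c = str(country).strip()
    if c not in region_table:
        return f"unknown country code {c!r}"
    lon_missing = lon is None or (isinstance(lon, float) and pd.isna(lon))
    lat_missing = lat is None or (isinstance(lat, float) and pd.isna(lat))
    if lon_missing != lat_missing:
        return "only one of lon/lat present"
    if not lon_missing:
        try:
            flon, flat = float(lon), float(lat)
        except (TypeError, ValueError):
            return f"non-numeric coordinates ({lon!r}, {lat!r})"
        if not (-180.0 <= flon <= 180.0 and -90.0 <= flat <= 90.0):
            return f"coordinates ({flon}, {flat}) out of WGS84 range"
    if msfd is not None and not (isinstance(msfd, float) and pd.isna(msfd)):
        m = str(msfd).strip()
        if m and m not in region_table.entries[c].msfd:
            return f"MSFD override {m!r} invalid for country {c}"
    return None


def parse_records(
    path: Path | str,
    region_table: RegionTable,
    columns: Optional[Mapping[str, str]] = None,
) -> tuple[list[DetectionRecord], CleanReport]:
    """Parse and clean a detection-record CSV.

    Parameters
    ----------
    path
        CSV file with at least species / year / country columns.
    region_table
        Valid country codes and their MSFD candidates.
    columns
        Logical-name → CSV-header mapping; defaults to
        ``species, year, country, lon, lat, msfd``. The coordinate and msfd
        columns are optional in the file.

    Returns
    -------
    (records, report)
        Cleaned records in file order with ``source_rank`` set to the
        original row index, and the drop-count report.

    Raises
    ------
    FileNotFoundError, SchemaError, EmptyInputError
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    for logical in ("species", "year", "country"):
        if cols[logical] not in df.columns:
            raise SchemaError(
                f"required column {cols[logical]!r} ({logical}) missing from {path.name}; "
                f"found {list(df.columns)}"
            )

    def col(logical: str, idx: int) -> object:
        name = cols[logical]
        return df.at[idx, name] if name in df.columns else None

    report = CleanReport(n_input=len(df))
    records: list[DetectionRecord] = []
    seen: set[tuple[str, str, int]] = set()
    for idx in df.index:
        species, year, country = col("species", idx), col("year", idx), col("country", idx)
        lon, lat, msfd = col("lon", idx), col("lat", idx), col("msfd", idx)
        problem = _row_problem(species, year, country, lon, lat, msfd, region_table)
        if problem is not None:
            report.n_dropped_invalid += 1
            report.messages.append(f"row {idx}: dropped ({problem})")
            continue
        key = (str(species).strip(), str(country).strip(), int(year))
        if key in seen:
            report.n_dropped_duplicate += 1
            report.messages.append(f"row {idx}: duplicate of earlier {key}")
            continue
        seen.add(key)
        lon_f = None if lon is None or pd.isna(lon) else float(lon)
        lat_f = None if lat is None or pd.isna(lat) else float(lat)
        msfd_s = None if msfd is None or (isinstance(msfd, float) and pd.isna(msfd)) else (str(msfd).strip() or None)
        records.append(
            DetectionRecord(
                species=key[0],
                year=key[2],
                country=key[1],
                lon=lon_f,
                lat=lat_f,
                msfd_override=msfd_s,
                source_rank=int(idx),
            )
        )
    report.n_kept = len(records)
    report.check()
    if not records:
        raise EmptyInputError(f"no valid detection records in {path}")
    return records, report


def records_to_frame(records: Iterable[DetectionRecord]) -> pd.DataFrame:
    """Tabulate records (one row each, in input order)."""
    return pd.DataFrame(
        [
            {
                "species": r.species,
                "year": r.year,
                "country": r.country,
                "lon": r.lon,
                "lat": r.lat,
                "msfd": r.msfd_override,
            }
            for r in records
        ]
    )


def write_records(records: Sequence[DetectionRecord], path: Path | str) -> None:
    """Serialize cleaned records back to the input CSV dialect."""
    records_to_frame(records).to_csv(path, index=False)
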