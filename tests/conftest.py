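from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nispread.records import DetectionRecord
from nispread.regions import RegionTable

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def region_table() -> RegionTable:
    return RegionTable.default()


@pytest.fixture()
def write_csv(tmp_path):
    """Write a record table to a temp CSV and return its path."""

    def _write(rows, name="records.csv", columns=("species", "year", "country", "lon", "lat", "msfd")):
        df = pd.DataFrame(rows, columns=list(columns)[: len(rows[0])] if rows else columns)
        path = tmp_path / name
        df.to_csv(path, index=False)
        return path

    return _write


def make_records(triples):
    """(species, country, year) tuples → DetectionRecords with file-order ranks."""
    return [
        DetectionRecord(species=s, year=y, country=c, source_rank=i)
        for i, (s, c, y) in enumerate(triples)
    ]
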