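"""Country ↔ MSFD subregion mapping for the Mediterranean basin.

The Mediterranean is divided by the Marine Strategy Framework Directive
(MSFD) into four subregions — Eastern Mediterranean (EMED), Central
Mediterranean (CMED), Adriatic Sea (ADRIA) and Western Mediterranean
(WMED). Detection records carry a country (EEZ) code; several countries
(Greece, Italy, Tunisia, Libya) border more than one subregion, so each
country has an ordered list of candidate subregions plus a configurable
default used when a record carries no explicit subregion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

MSFD_CODES = ("EMED", "CMED", "ADRIA", "WMED")


class UnknownCountryError(KeyError):
    """Raised when a country code is not present in the region table."""

    def __init__(self, country: str):
        super().__init__(country)
        self.country = country

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"unknown country code {self.country!r}"


@dataclass(frozen=True)
class CountryEntry:
    """One country's region-table row: name, candidate subregions, default."""

    code: str
    name: str
    msfd: tuple[str, ...]
    default: str

    def __post_init__(self) -> None:
        if self.default not in self.msfd:
            raise ValueError(
                f"{self.code}: default {self.default!r} not among {self.msfd}"
            )
        for m in self.msfd:
            if m not in MSFD_CODES:
                raise ValueError(f"{self.code}: unknown MSFD code {m!r}")


@dataclass(frozen=True)
class RegionTable:
    """Mapping country code → :class:`CountryEntry`, plus east→west display order.

    ``msfd_order`` lists the four MSFD subregions in the east-to-west order
    used throughout outputs and plots.
    """

    entries: Mapping[str, CountryEntry]
    msfd_order: tuple[str, ...] = MSFD_CODES

    @classmethod
    def default(cls, defaults_override: Optional[Mapping[str, str]] = None) -> "RegionTable":
        """Load the packaged Mediterranean region table.

        Parameters
        ----------
        defaults_override
            Optional ``{country_code: msfd_code}`` replacing the shipped
            per-country default subregion (must be one of the country's
            candidate subregions).
        """
        raw = json.loads(
            resources.files("nispread.data").joinpath("msfd_regions.json").read_text()
        )
        entries = {}
        for code, spec in raw["countries"].items():
            default = spec["default"]
            if defaults_override and code in defaults_override:
                default = defaults_override[code]
            entries[code] = CountryEntry(
                code=code, name=spec["name"], msfd=tuple(spec["msfd"]), default=default
            )
        return cls(entries=entries, msfd_order=tuple(raw["msfd_order"]))

    def __contains__(self, country: str) -> bool:
        return country in self.entries

    def countries(self) -> Sequence[str]:
        """Country codes in table (east→west) order."""
        return list(self.entries)

    def msfd_for(self, country: str, override: Optional[str] = None) -> str:
        """Resolve a country code to one MSFD subregion code.

        An explicit per-record ``override`` wins if it is a valid candidate
        subregion for the country; otherwise the configured default applies.
        """
        entry = self.entries.get(country)
        if entry is None:
            raise UnknownCountryError(country)
        if override:
            if override not in entry.msfd:
                raise ValueError(
                    f"MSFD override {override!r} is not a candidate region of {country}"
                )
            return override
        return entry.default


def map_country_to_msfd(
    country: str, region_table: RegionTable, override: Optional[str] = None
) -> str:
    """Functional alias for :meth:`RegionTable.msfd_for`."""
    return region_table.msfd_for(country, override)
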