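"""Core data structures for assemblage time series.

The unit of analysis throughout the package is the *assemblage*: the set of
co-occurring species recorded by one monitoring study at one georeferenced
location, censused repeatedly (not necessarily in consecutive calendar years).
Records are held in long format — one row per (year, plot, species) with a
numerical abundance — which is the shape biodiversity time-series exports
such as BioTIME-style tables arrive in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ConfigurationError",
    "UndefinedComparisonError",
    "RECORD_COLUMNS",
    "AssemblageTimeSeries",
    "SynonymTable",
    "AlienChecklist",
]


class ValidationError(ValueError):
    """Input data violates an invariant (bad coordinates, negative abundance, ...)."""


class ConfigurationError(ValueError):
    """A configuration problem (missing column, missing file) detected before computation."""


class UndefinedComparisonError(ValueError):
    """A pairwise comparison is undefined (e.g. both censuses empty)."""


#: canonical column order of the in-memory record table
RECORD_COLUMNS = ["year", "plot_id", "species", "abundance"]


@dataclass
class AssemblageTimeSeries:
    """One study's plot-level abundance records across censuses.

    Parameters
    ----------
    study_id
        Opaque study identifier.
    records
        Long-format table with columns ``year`` (int), ``plot_id``,
        ``species``, ``abundance`` (> 0).  Zero-abundance rows are dropped on
        construction; negative abundances raise :class:`ValidationError`.
    latitude, longitude
        Study-level location in decimal degrees.
    region
        Named region (country or state) used to key alien-status lookups.
    alien_flag
        Whether any recorded species is alien in ``region``; ``None`` until
        assigned.
    alien_species
        The standardized names found in the checklist (diagnostics, e.g.
        alien relative abundance).
    """

    study_id: str
    records: pd.DataFrame
    latitude: float
    longitude: float
    region: str
    alien_flag: bool | None = None
    alien_species: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValidationError(
                f"study {self.study_id!r}: records table missing column(s) {missing}"
            )
        if not -90.0 <= float(self.latitude) <= 90.0:
            raise ValidationError(
                f"study {self.study_id!r}: latitude {self.latitude} outside [-90, 90]"
            )
        if not -180.0 <= float(self.longitude) <= 180.0:
            raise ValidationError(
                f"study {self.study_id!r}: longitude {self.longitude} outside [-180, 180]"
            )
        ab = self.records["abundance"].to_numpy()
        if np.any(ab < 0):
            raise ValidationError(f"study {self.study_id!r}: negative abundance")
        if np.any(ab == 0):
            self.records = self.records.loc[ab > 0].reset_index(drop=True)

    # ------------------------------------------------------------------ views

    @property
    def years(self) -> list[int]:
        """Ordered distinct census years."""
        return sorted(int(y) for y in self.records["year"].unique())

    @property
    def n_censuses(self) -> int:
        return self.records["year"].nunique()

    @property
    def effort_by_year(self) -> dict[int, int]:
        """Sampling effort: number of distinct plots per census year."""
        g = self.records.groupby("year")["plot_id"].nunique()
        return {int(y): int(n) for y, n in g.items()}

    def species_in_year(self, year: int) -> frozenset:
        """Distinct species with positive abundance recorded in ``year``."""
        if year not in set(self.years):
            raise ValidationError(f"study {self.study_id!r}: {year} is not a census year")
        sel = self.records.loc[self.records["year"] == year, "species"]
        return frozenset(sel.unique())

    def abundance_in_year(self, year: int) -> dict[str, float]:
        """Species -> total abundance (summed over plots) in one census."""
        if year not in set(self.years):
            raise ValidationError(f"study {self.study_id!r}: {year} is not a census year")
        sub = self.records.loc[self.records["year"] == year]
        return sub.groupby("species")["abundance"].sum().to_dict()

    def richness_by_year(self) -> dict[int, int]:
        g = self.records.groupby("year")["species"].nunique()
        return {int(y): int(n) for y, n in g.items()}

    def with_records(self, records: pd.DataFrame) -> "AssemblageTimeSeries":
        """Copy of this series with a new record table and the same metadata."""
        return replace(self, records=records.reset_index(drop=True))

    def subset_period(self, start: int, end: int) -> "AssemblageTimeSeries":
        """Restrict the series to censuses within ``[start, end]`` inclusive."""
        keep = self.records["year"].between(start, end)
        return self.with_records(self.records.loc[keep])


@dataclass(frozen=True)
class SynonymTable:
    """Raw-name -> accepted-name mapping used for offline name standardization.

    The mapping must be a function (one accepted name per raw name) and
    accepted names must map to themselves when they appear as keys.
    """

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        for accepted in set(self.mapping.values()):
            if accepted in self.mapping and self.mapping[accepted] != accepted:
                raise ValidationError(
                    f"synonym table: accepted name {accepted!r} does not map to itself"
                )

    def resolve(self, raw: str) -> str:
        """Accepted name for ``raw``; unmatched names pass through unchanged."""
        return self.mapping.get(raw, raw)

    def __contains__(self, raw: str) -> bool:
        return raw in self.mapping


@dataclass(frozen=True)
class AlienChecklist:
    """Set of (region, standardized species name) pairs defining alien status.

    Region-keyed in the style of naturalized-flora checklists: a species may
    be alien in one country or state and native in another.
    """

    pairs: frozenset

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AlienChecklist":
        return cls(frozenset((str(r), str(s)) for r, s in pairs))

    def is_alien(self, region: str, species: str) -> bool:
        return (region, species) in self.pairs

    def species_for_region(self, region: str) -> frozenset:
        return frozenset(s for r, s in self.pairs if r == region)

    def __len__(self) -> int:
        return len(self.pairs)
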