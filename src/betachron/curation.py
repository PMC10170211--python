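"""Curation: name standardization, alien-status assignment, study-selection filters.

Name standardization is table-driven: a user-supplied synonym table maps raw
names to accepted names, replacing any live taxonomic-backbone lookup so runs
are reproducible offline.  Alien status is assigned per study from a
region-keyed checklist: a study is flagged invaded iff at least one species
recorded at *any* census is listed as alien for the study's region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .core import (
    AlienChecklist,
    AssemblageTimeSeries,
    SynonymTable,
    ValidationError,
)

__all__ = [
    "StandardizationReport",
    "standardize_names",
    "assign_alien_status",
    "filter_studies",
    "MIN_CENSUS_YEARS",
]

#: minimum number of distinct census years for a study to be retained
MIN_CENSUS_YEARS = 3


@dataclass
class StandardizationReport:
    """What happened while standardizing one series' names."""

    n_records_in: int = 0
    n_records_out: int = 0
    n_replaced: int = 0
    n_merged: int = 0
    unmatched: list[str] = field(default_factory=list)


def standardize_names(
    series: AssemblageTimeSeries, syn: SynonymTable
) -> tuple[AssemblageTimeSeries, StandardizationReport]:
    """Replace raw names by accepted names and merge collapsed synonyms.

    Records of synonyms that map to the same accepted name within one
    (year, plot) are merged by summing abundance.  Unmatched raw names pass
    through unchanged and are listed (once each) in the report.
    """
    rec = series.records.copy()
    report = StandardizationReport(n_records_in=len(rec))
    matched = rec["species"].isin(syn.mapping)
    report.n_replaced = int(matched.sum())
    report.unmatched = sorted(rec.loc[~matched, "species"].unique())
    rec["species"] = rec["species"].map(syn.resolve)
    merged = (
        rec.groupby(["year", "plot_id", "species"], as_index=False, sort=True)[
            "abundance"
        ].sum()
    )
    report.n_merged = len(rec) - len(merged)
    report.n_records_out = len(merged)
    return series.with_records(merged[["year", "plot_id", "species", "abundance"]]), report


def assign_alien_status(
    series: AssemblageTimeSeries, checklist: AlienChecklist
) -> AssemblageTimeSeries:
    """Flag the series invaded iff any species, over all censuses, is alien
    for the series' region.

    Expects names already standardized to the checklist's nomenclature.
    The per-species alien marks are retained on the returned series for
    diagnostics (e.g. alien relative abundance).  Idempotent and independent
    of record order; status is study-level and constant across censuses.
    """
    if not series.region or str(series.region).strip() == "" or str(series.region) == "nan":
        raise ValidationError(f"study {series.study_id!r}: region missing")
    regional = checklist.species_for_region(series.region)
    observed = frozenset(series.records["species"].unique())
    aliens = observed & regional
    out = series.with_records(series.records)
    out.alien_flag = bool(aliens)
    out.alien_species = frozenset(aliens)
    return out


def filter_studies(
    series_set: Iterable[AssemblageTimeSeries],
    min_years: int = MIN_CENSUS_YEARS,
) -> tuple[list[AssemblageTimeSeries], dict[str, str]]:
    """Retain studies censused in at least ``min_years`` distinct years.

    Census years need not be consecutive calendar years.  Returns the
    retained series and a per-study map of exclusion reasons; applying the
    filter twice equals applying it once.
    """
    kept: list[AssemblageTimeSeries] = []
    excluded: dict[str, str] = {}
    for s in series_set:
        n = s.n_censuses
        if n >= min_years:
            kept.append(s)
        else:
            excluded[s.study_id] = f"only {n} census year(s); need >= {min_years}"
    return kept, excluded
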