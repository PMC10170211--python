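"""Reading and writing the package's tabular formats.

Occurrence tables are long-format CSV/TSV with one row per
(study, year, plot, species) and a numerical abundance, in the style of
large biodiversity time-series exports.  Column names are configurable via a
*dialect* mapping so differently-headed exports can be ingested without
editing files.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import pandas as pd

from .core import (
    AlienChecklist,
    AssemblageTimeSeries,
    ConfigurationError,
    SynonymTable,
    ValidationError,
)

__all__ = [
    "DEFAULT_DIALECT",
    "read_occurrence_table",
    "write_occurrence_table",
    "read_checklist",
    "write_checklist",
    "read_synonyms",
]

#: internal field -> default file column name
DEFAULT_DIALECT: dict[str, str] = {
    "study_id": "STUDY_ID",
    "year": "YEAR",
    "plot_id": "PLOT",
    "species": "GENUS_SPECIES",
    "abundance": "ABUNDANCE",
    "latitude": "LATITUDE",
    "longitude": "LONGITUDE",
    "region": "REGION",
}

#: stable output column order for occurrence tables
OCCURRENCE_COLUMNS = list(DEFAULT_DIALECT)


def _resolve_sep(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_occurrence_table(
    path: str | os.PathLike,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[AssemblageTimeSeries]:
    """Read a long-format occurrence table into one series per study.

    Parameters
    ----------
    path
        CSV (default) or TSV file; UTF-8.
    dialect
        Partial override of :data:`DEFAULT_DIALECT`, mapping internal field
        names (``study_id``, ``year``, ...) to the file's column headers.
    sep
        Field separator; inferred from the extension when omitted.

    Returns
    -------
    list of AssemblageTimeSeries, one per distinct study id, sorted by id.
    Zero-abundance rows are dropped.

    Raises
    ------
    ConfigurationError
        If the file is missing or a mandatory column cannot be resolved.
    ValidationError
        For non-numeric or negative abundance (with 1-based file line
        numbers) or inconsistent coordinates/region within a study.
    """
    if not os.path.exists(path):
        raise ConfigurationError(f"occurrence table not found: {path}")
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(DEFAULT_DIALECT)
        if unknown:
            raise ConfigurationError(f"unknown dialect field(s): {sorted(unknown)}")
        colmap.update(dialect)

    df = pd.read_csv(path, sep=_resolve_sep(path, sep), dtype=str, encoding="utf-8")
    missing = [file_col for file_col in colmap.values() if file_col not in df.columns]
    if missing:
        raise ConfigurationError(
            f"occurrence table {path}: missing mandatory column(s) {missing}"
        )
    df = df.rename(columns={v: k for k, v in colmap.items()})[OCCURRENCE_COLUMNS]

    # numeric coercion with file line numbers (header is line 1)
    for col in ("abundance", "latitude", "longitude"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if df[col].isna().any():
            bad = bad.union(df.index[df[col].isna()])
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]
            raise ValidationError(
                f"occurrence table {path}: non-numeric {col} at line(s) {lines}"
            )
        df[col] = coerced
    yr = pd.to_numeric(df["year"], errors="coerce")
    bad = df.index[yr.isna()]
    if len(bad):
        raise ValidationError(
            f"occurrence table {path}: non-numeric year at line(s) "
            f"{[int(i) + 2 for i in bad[:5]]}"
        )
    df["year"] = yr.astype(int)
    if (df["abundance"] < 0).any():
        line = int(df.index[df["abundance"] < 0][0]) + 2
        raise ValidationError(f"occurrence table {path}: negative abundance at line {line}")
    df = df.loc[df["abundance"] > 0].reset_index(drop=True)

    out: list[AssemblageTimeSeries] = []
    for study_id, sub in df.groupby("study_id", sort=True):
        loc = sub[["latitude", "longitude", "region"]].drop_duplicates()
        if len(loc) != 1:
            raise ValidationError(
                f"study {study_id!r}: inconsistent coordinates/region within the study "
                f"({len(loc)} distinct (latitude, longitude, region) tuples)"
            )
        lat, lon, region = loc.iloc[0]
        out.append(
            AssemblageTimeSeries(
                study_id=str(study_id),
                records=sub[["year", "plot_id", "species", "abundance"]].reset_index(
                    drop=True
                ),
                latitude=float(lat),
                longitude=float(lon),
                region=str(region),
            )
        )
    return out


def write_occurrence_table(
    series_list: Sequence[AssemblageTimeSeries],
    path: str | os.PathLike,
    dialect: Mapping[str, str] | None = None,
) -> None:
    """Write series back to a long-format CSV in the stable column order."""
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    frames = []
    for s in series_list:
        rec = s.records.copy()
        rec.insert(0, "study_id", s.study_id)
        rec["latitude"] = s.latitude
        rec["longitude"] = s.longitude
        rec["region"] = s.region
        frames.append(rec[OCCURRENCE_COLUMNS])
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=OCCURRENCE_COLUMNS)
    )
    table = table.rename(columns=colmap)
    table.to_csv(path, index=False)


def read_checklist(path: str | os.PathLike) -> AlienChecklist:
    """Read a two-column (region, species) alien checklist CSV."""
    if not os.path.exists(path):
        raise ConfigurationError(f"checklist not found: {path}")
    df = pd.read_csv(path, dtype=str)
    cols = [c.lower() for c in df.columns]
    if "region" not in cols or "species" not in cols:
        raise ConfigurationError(
            f"checklist {path}: expected columns 'region' and 'species', got {list(df.columns)}"
        )
    df.columns = cols
    return AlienChecklist.from_pairs(zip(df["region"], df["species"]))


def write_checklist(checklist: AlienChecklist, path: str | os.PathLike) -> None:
    rows = sorted(checklist.pairs)
    pd.DataFrame(rows, columns=["region", "species"]).to_csv(path, index=False)


def read_synonyms(path: str | os.PathLike) -> SynonymTable:
    """Read a two-column (raw, accepted) synonym CSV into a SynonymTable."""
    if not os.path.exists(path):
        raise ConfigurationError(f"synonym table not found: {path}")
    df = pd.read_csv(path, dtype=str)
    cols = [c.lower() for c in df.columns]
    if "raw" not in cols or "accepted" not in cols:
        raise ConfigurationError(
            f"synonym table {path}: expected columns 'raw' and 'accepted', got {list(df.columns)}"
        )
    df.columns = cols
    dup = df["raw"].duplicated()
    if dup.any():
        raise ValidationError(
            f"synonym table {path}: duplicate raw name(s) {sorted(df.loc[dup, 'raw'].unique()[:5])}"
        )
    return SynonymTable(dict(zip(df["raw"], df["accepted"])))
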