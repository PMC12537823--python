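"""Reading, validating and filtering occurrence records and snapshot tables.

Occurrence records are GBIF-occurrence-download-style delimited text: one row
per preserved-specimen record with columns for the species name, year of
collection, decimal coordinates, contributing institution and basis of
record. Internally every table is a :class:`pandas.DataFrame` with the
canonical column names in :data:`CANONICAL_COLUMNS`; missing values are real
missing values (``NaN`` / ``<NA>``), never sentinel numbers.

Snapshot tables record, for each historical state of the aggregated database,
how many records exist for each collection year (optionally split by
institution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, UndefinedRatioError

logger = logging.getLogger(__name__)

#: Canonical internal column names for occurrence tables.
CANONICAL_COLUMNS = (
    "species",
    "year",
    "latitude",
    "longitude",
    "institution",
    "taxon_group",
    "basis_of_record",
)

#: Default mapping from canonical names to GBIF occurrence-download headers.
GBIF_COLUMNS: Mapping[str, str] = {
    "species": "species",
    "year": "year",
    "latitude": "decimalLatitude",
    "longitude": "decimalLongitude",
    "institution": "institutionCode",
    "taxon_group": "taxonGroup",
    "basis_of_record": "basisOfRecord",
}

#: Columns that must exist in the input file; the rest degrade to missing.
REQUIRED_COLUMNS = ("species", "year")


@dataclass
class Dialect:
    """Delimiter and column-name mapping for one tabular input flavour.

    ``columns`` maps canonical names (keys of :data:`GBIF_COLUMNS`) to the
    header names used in the file. Canonical columns whose mapped header is
    absent from the file are filled with missing values, except the required
    ``species`` and ``year`` columns, whose absence is a configuration error.
    """

    delimiter: str = "\t"
    columns: Mapping[str, str] = field(default_factory=lambda: dict(GBIF_COLUMNS))

    def resolve(self, header: list[str]) -> dict[str, str]:
        """Map canonical names to present file columns, validating required ones."""
        present = {}
        for canonical, name in self.columns.items():
            if name in header:
                present[canonical] = name
            elif canonical in REQUIRED_COLUMNS:
                raise ConfigurationError(
                    f"required column {name!r} (for {canonical!r}) "
                    f"not found in header {header!r}"
                )
        return present


TSV = Dialect(delimiter="\t")
CSV = Dialect(delimiter=",")


def _canonicalise(raw: pd.DataFrame, mapping: dict[str, str]) -> pd.DataFrame:
    """Rename mapped columns, coerce dtypes and count unparseable fields."""
    df = pd.DataFrame(index=raw.index)
    warn_counts: dict[str, int] = {}
    for canonical in CANONICAL_COLUMNS:
        if canonical in mapping:
            col = raw[mapping[canonical]]
        else:
            col = pd.Series(pd.NA, index=raw.index)
        if canonical == "year":
            parsed = pd.to_numeric(col, errors="coerce")
            n_bad = int((parsed.isna() & col.notna()).sum())
            if n_bad:
                warn_counts["year"] = warn_counts.get("year", 0) + n_bad
            df[canonical] = parsed.round().astype("Int64")
        elif canonical in ("latitude", "longitude"):
            parsed = pd.to_numeric(col, errors="coerce")
            n_bad = int((parsed.isna() & col.notna()).sum())
            if n_bad:
                warn_counts[canonical] = warn_counts.get(canonical, 0) + n_bad
            df[canonical] = parsed.astype(float)
        else:
            s = col.astype("string").str.strip()
            df[canonical] = s.replace("", pd.NA)
    if warn_counts:
        logger.warning("unparseable fields treated as missing: %s", warn_counts)
    df.attrs["unparseable"] = warn_counts
    return df


def read_occurrences(
    path: str | Path,
    dialect: Dialect | None = None,
    chunksize: int | None = None,
) -> pd.DataFrame | Iterator[pd.DataFrame]:
    """Read an occurrence table into canonical form.

    Parameters
    ----------
    path
        Delimited text file with a header row (TSV by default).
    dialect
        Delimiter and column mapping; defaults to GBIF download headers.
    chunksize
        If given, return an iterator of canonical DataFrame chunks so that
        arbitrarily large downloads can be streamed with bounded memory.

    Unparseable years or coordinates become missing values (the row is kept
    and the field counted in ``df.attrs['unparseable']``); a missing required
    column raises :class:`ConfigurationError` naming the column.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    dialect = dialect or TSV
    header = list(
        pd.read_csv(path, sep=dialect.delimiter, nrows=0, dtype=str).columns
    )
    mapping = dialect.resolve(header)
    kwargs = dict(sep=dialect.delimiter, dtype=str, keep_default_na=True)
    if chunksize is not None:
        reader = pd.read_csv(path, chunksize=chunksize, **kwargs)
        return (_canonicalise(chunk, mapping) for chunk in reader)
    return _canonicalise(pd.read_csv(path, **kwargs), mapping)


def write_occurrences(
    records: pd.DataFrame, path: str | Path, dialect: Dialect | None = None
) -> None:
    """Write a canonical occurrence table back to delimited text.

    Uses the dialect's column names so a written file round-trips through
    :func:`read_occurrences` field-by-field.
    """
    dialect = dialect or TSV
    out = records.loc[:, list(CANONICAL_COLUMNS)].rename(columns=dict(dialect.columns))
    out.to_csv(path, sep=dialect.delimiter, index=False)


def filter_valid(
    records: pd.DataFrame,
    year_min: int = 1800,
    year_max: int = 2024,
    basis: str | None = "PreservedSpecimen",
) -> pd.DataFrame:
    """Keep records with a non-empty species name and an in-range year.

    ``basis``, if not None, additionally requires a case-insensitive match on
    ``basis_of_record`` (default keeps preserved specimens only; records with
    a missing basis are dropped when the filter is active). Order preserving
    and idempotent.
    """
    species_ok = records["species"].notna() & (records["species"].str.len() > 0)
    year_ok = records["year"].notna() & records["year"].between(year_min, year_max)
    mask = species_ok & year_ok
    if basis is not None:
        basis_col = records["basis_of_record"].str.lower()
        mask &= basis_col.notna() & (basis_col == basis.lower())
    return records.loc[mask.fillna(False)]


def filter_spatial(records: pd.DataFrame) -> pd.DataFrame:
    """Keep records with both coordinates present and physically in range.

    Only spatial analyses consume this subset; count and species metrics run
    on the full valid set. (0, 0) coordinates are retained — only missing or
    out-of-range values are excluded.
    """
    lat, lon = records["latitude"], records["longitude"]
    mask = lat.notna() & lon.notna() & lat.between(-90, 90) & lon.between(-180, 180)
    return records.loc[mask]


def location_coverage(n_total: int, n_with_coords: int) -> float:
    """Percentage of records carrying usable coordinates.

    Returns the exact percentage ``100 * n_with_coords / n_total`` (callers
    report it to one decimal place). Equals 100 exactly iff every record has
    coordinates.
    """
    if n_total <= 0:
        raise UndefinedRatioError("location coverage undefined for n_total = 0")
    if not 0 <= n_with_coords <= n_total:
        raise DataError(
            f"n_with_coords ({n_with_coords}) must lie in [0, n_total={n_total}]"
        )
    return 100.0 * n_with_coords / n_total


SNAPSHOT_COLUMNS = ("snapshot_time", "collection_year", "institution", "count")


def read_snapshots(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    """Read a snapshot table (snapshot_time, collection_year[, institution], count).

    ``snapshot_time`` may be an ISO date or a bare year; it is reduced to an
    integer year. Raises :class:`DataError` on negative counts (naming the
    rows) or duplicate (snapshot_time, collection_year, institution) keys.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"snapshot file not found: {path}")
    raw = pd.read_csv(path, sep=delimiter, dtype=str)
    for col in ("snapshot_time", "collection_year", "count"):
        if col not in raw.columns:
            raise ConfigurationError(f"snapshot table missing column {col!r}")
    df = pd.DataFrame()
    times = pd.to_numeric(raw["snapshot_time"], errors="coerce")
    if times.isna().any():
        # fall back to date parsing for ISO timestamps
        dates = pd.to_datetime(raw["snapshot_time"], errors="coerce")
        times = times.fillna(dates.dt.year)
    if times.isna().any():
        bad = raw.index[times.isna()].tolist()
        raise DataError(f"unparseable snapshot_time in rows {bad}")
    df["snapshot_time"] = times.astype(int)
    df["collection_year"] = pd.to_numeric(raw["collection_year"]).astype(int)
    if "institution" in raw.columns:
        df["institution"] = raw["institution"].astype("string")
    else:
        df["institution"] = pd.NA
    counts = pd.to_numeric(raw["count"], errors="coerce")
    if counts.isna().any():
        bad = raw.index[counts.isna()].tolist()
        raise DataError(f"unparseable count in rows {bad}")
    if (counts < 0).any():
        bad = raw.index[counts < 0].tolist()
        raise DataError(f"negative count in rows {bad}")
    df["count"] = counts.astype(int)
    keys = df[["snapshot_time", "collection_year", "institution"]]
    dup = keys.duplicated(keep=False)
    if dup.any():
        dupes = keys.loc[dup].drop_duplicates().to_dict("records")
        raise DataError(f"duplicate snapshot keys: {dupes}")
    return df


def coverage_summary(records: pd.DataFrame) -> dict:
    """Record counts before/after spatial filtering plus coverage percentage."""
    n_total = len(records)
    n_coords = len(filter_spatial(records))
    return {
        "n_records": n_total,
        "n_with_coordinates": n_coords,
        "location_coverage_pct": round(location_coverage(n_total, n_coords), 1)
        if n_total
        else float("nan"),
    }
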