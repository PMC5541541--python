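"""Tabular input/output for the synchrony pipeline.

All tables are plain :class:`pandas.DataFrame` objects with documented,
validated schemas.  Four inputs drive the analysis:

* **observations** — one row per site visit per species with a 0/1
  detection flag (long format, incidence data from transect walks);
* **weather** — monthly site weather (mean temperature, total precipitation);
* **ssta** — a monthly sea-surface-temperature-anomaly series indexing ENSO
  strength (Nino 3.4 region);
* **traits** — a species table of dispersal-related traits (wingspan,
  geographic range, diet breadth, elevational range, migratory flag).

Column names are configurable through a schema map so that differently
labelled monitoring exports can be read without editing files.  Missing
visits are represented by absent rows, never zero-filled ones, so that
"not visited" stays distinct from "visited, not detected".
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger("lepisync")


class DataError(ValueError):
    """Base class for all input validation failures."""


class SchemaError(DataError):
    """A required column is missing or mis-typed."""


class IntegrityError(DataError):
    """Rows violate a uniqueness or consistency constraint."""


# Default column names; a schema map {canonical: actual} overrides them.
OBSERVATION_COLUMNS = ("site_id", "year", "visit_index", "species_id", "detected")
WEATHER_COLUMNS = ("site_id", "year", "month", "tmean", "precip")
SSTA_COLUMNS = ("year", "month", "ssta")
TRAIT_COLUMNS = (
    "species_id",
    "wingspan",
    "geographic_range",
    "diet_breadth",
    "elevational_range",
    "migratory",
)


def _rename(df: pd.DataFrame, required: Sequence[str], schema: Mapping[str, str] | None,
            optional: Sequence[str] = ()) -> pd.DataFrame:
    """Map actual column names onto canonical ones and check presence."""
    if schema:
        inverse = {actual: canon for canon, actual in schema.items()}
        df = df.rename(columns=inverse)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return df


def _check_duplicates(df: pd.DataFrame, key: Sequence[str], what: str) -> None:
    dup = df.duplicated(subset=list(key), keep=False)
    if dup.any():
        keys = df.loc[dup, list(key)].drop_duplicates().head(20)
        raise IntegrityError(
            f"duplicate {what} rows for key(s): " + keys.to_dict("records").__repr__()
        )


def _coerce_int(df: pd.DataFrame, col: str) -> None:
    try:
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    except (ValueError, TypeError) as exc:
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index.tolist()[:10]
        raise SchemaError(f"column {col!r} is not integer-valued (rows {bad})") from exc


def read_observations(path: str | Path, schema: Mapping[str, str] | None = None,
                      study_window: tuple[int, int] | None = None) -> pd.DataFrame:
    """Read and validate a long-format visit/detection table.

    The file may carry either explicit ``(year, visit_index)`` columns or a
    full ``date`` column; dates are collapsed to ``(year, visit_index)`` by
    within-year rank of the distinct visit dates at each site.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional map from canonical column names to the names used in the
        file, e.g. ``{"site_id": "location"}``.
    study_window
        Optional ``(first_year, last_year)``; rows outside it are rejected.

    Returns
    -------
    DataFrame with columns ``site_id, year, visit_index, species_id, detected``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    if schema:
        raw = raw.rename(columns={v: k for k, v in schema.items()})
    if "date" in raw.columns and "visit_index" not in raw.columns:
        raw = collapse_dates(raw)
    df = _rename(raw, OBSERVATION_COLUMNS, None)
    df = df[list(OBSERVATION_COLUMNS)].copy()
    for col in ("year", "visit_index"):
        _coerce_int(df, col)
    det = pd.to_numeric(df["detected"], errors="coerce")
    bad = ~det.isin([0, 1])
    if bad.any():
        raise SchemaError(
            f"'detected' must be 0/1; offending rows: {df.index[bad].tolist()[:10]}"
        )
    df["detected"] = det.astype(int)
    if study_window is not None:
        lo, hi = study_window
        outside = (df["year"] < lo) | (df["year"] > hi)
        if outside.any():
            raise IntegrityError(
                f"{int(outside.sum())} rows outside study window {lo}-{hi}"
            )
    _check_duplicates(df, ("site_id", "year", "visit_index", "species_id"),
                      "observation")
    logger.info("read %d observation rows from %s", len(df), path)
    return df.reset_index(drop=True)


def collapse_dates(df: pd.DataFrame) -> pd.DataFrame:
    """Convert a ``date`` column to ``(year, visit_index)`` per site.

    Visit index is the within-year rank (1-based) of the distinct visit
    dates at each site, so the analysis sees only yearly visit counts.
    """
    out = df.copy()
    dates = pd.to_datetime(out["date"])
    out["year"] = dates.dt.year
    ranks = (
        dates.groupby([out["site_id"], out["year"]])
        .transform(lambda s: s.rank(method="dense"))
        .astype(int)
    )
    out["visit_index"] = ranks
    return out.drop(columns=["date"])


def read_weather(path: str | Path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read monthly site weather: ``site_id, year, month, tmean, precip``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _rename(pd.read_csv(path), WEATHER_COLUMNS, schema)
    df = df[list(WEATHER_COLUMNS)].copy()
    for col in ("year", "month"):
        _coerce_int(df, col)
    _validate_months(df)
    if (df["precip"] < 0).any():
        rows = df.index[df["precip"] < 0].tolist()[:10]
        raise DataError(f"negative precipitation in rows {rows}")
    _check_duplicates(df, ("site_id", "year", "month"), "weather")
    return df.reset_index(drop=True)


def read_ssta(path: str | Path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a monthly SSTA series: ``year, month, ssta``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _rename(pd.read_csv(path), SSTA_COLUMNS, schema)
    df = df[list(SSTA_COLUMNS)].copy()
    for col in ("year", "month"):
        _coerce_int(df, col)
    _validate_months(df)
    _check_duplicates(df, ("year", "month"), "SSTA")
    return df.reset_index(drop=True)


def read_traits(path: str | Path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read the species trait table.

    All numeric traits must be strictly positive; the migratory flag must be
    present (0/1 or boolean) for every species.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _rename(pd.read_csv(path), TRAIT_COLUMNS, schema)
    df = df[list(TRAIT_COLUMNS)].copy()
    numeric = ["wingspan", "geographic_range", "diet_breadth", "elevational_range"]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals <= 0).any():
            raise DataError(f"trait column {col!r} must be positive and complete")
        df[col] = vals
    mig = df["migratory"]
    if mig.isna().any():
        rows = df.index[mig.isna()].tolist()[:10]
        raise DataError(f"missing migratory flag in rows {rows}")
    if mig.dtype == object:
        mig = mig.map({"True": 1, "False": 0, "true": 1, "false": 0}).fillna(mig)
    mig = pd.to_numeric(mig, errors="coerce")
    if not mig.isin([0, 1]).all():
        raise DataError("migratory flag must be boolean / 0-1")
    df["migratory"] = mig.astype(bool)
    _check_duplicates(df, ("species_id",), "trait")
    return df.reset_index(drop=True)


def _validate_months(df: pd.DataFrame) -> None:
    bad = ~df["month"].between(1, 12)
    if bad.any():
        raise DataError(f"month outside 1-12 in rows {df.index[bad].tolist()[:10]}")


def write_table(table: pd.DataFrame, path: str | Path, format: str = "csv") -> None:
    """Write a result table to CSV or JSON (records orientation).

    Raises on an empty table rather than silently producing a header-only
    file; round-tripping through the matching reader reproduces every value
    to full stored precision.
    """
    if len(table) == 0:
        raise DataError("refusing to write an empty table")
    path = Path(path)
    if format == "csv":
        table.to_csv(path, index=False)
    elif format == "json":
        path.write_text(json.dumps(table.to_dict("records"), indent=1, default=float))
    else:
        raise ValueError(f"unknown format {format!r}")
    logger.info("wrote %d rows to %s", len(table), path)


def setup_logging(level: str = "INFO") -> None:
    """Configure stderr logging for the package (idempotent)."""
    h = logging.StreamHandler()
    h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    log = logging.getLogger("lepisync")
    if not log.handlers:
        log.addHandler(h)
    log.setLevel(level.upper())
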