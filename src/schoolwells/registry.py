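"""Well-registry ingestion and harmonization.

Raw well records arrive from a primary registry (OGIM-style) plus state-agency
supplements. Records missing coordinates or any usable date are excluded, and
each surviving well gets an activity window: it is treated as an active
exposure source from its earliest recorded activity date (minimum of spud,
completion, and first-production dates) until a configurable lifespan later
(default 30 years), approximating the producing lifetime of a site.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DATE_FIELDS = ("spud_date", "completion_date", "first_production_date")

RAW_COLUMNS = (
    "source_id",
    "source_name",
    "longitude",
    "latitude",
    *DATE_FIELDS,
    "production_type",
    "drill_type",
    "state_code",
)

PRODUCTION_TYPES = ("oil", "gas", "oil_and_gas", "other", "unknown")
DRILL_TYPES = ("horizontal", "directional", "vertical", "unknown")

DEFAULT_LIFESPAN_YEARS = 30


@dataclass(frozen=True)
class DateInterval:
    """Closed calendar interval; both endpoints inclusive."""

    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} after end {self.end}")

    def overlaps(self, other: "DateInterval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def contains(self, date) -> bool:
        ts = pd.Timestamp(date)
        return self.start <= ts <= self.end


@dataclass
class MergeLog:
    """Outcome of a date-supplement merge."""

    filled: int = 0
    appended: int = 0
    conflicts: int = 0

    def as_dict(self) -> dict:
        return {"filled": self.filled, "appended": self.appended, "conflicts": self.conflicts}


def school_year_interval(label: str) -> DateInterval:
    """Interval for a school-year label like ``"2022-2023"``.

    Anchored on July 1 of the first year through June 30 of the second, to
    absorb regional differences in academic calendars. The two years must be
    consecutive.
    """
    try:
        first_s, second_s = label.split("-")
        first, second = int(first_s), int(second_s)
    except ValueError as exc:
        raise ValueError(f"school-year label {label!r} must look like '2022-2023'") from exc
    if second != first + 1:
        raise ValueError(f"school-year label {label!r} must span consecutive years")
    return DateInterval(pd.Timestamp(year=first, month=7, day=1), pd.Timestamp(year=second, month=6, day=30))


def _parse_dates(series: pd.Series, date_formats: Sequence[str] | None = None) -> pd.Series:
    """Parse a date column; unparseable values become missing (NaT)."""
    if date_formats:
        out = pd.Series(pd.NaT, index=series.index, dtype="datetime64[ns]")
        remaining = series.astype("string")
        for fmt in date_formats:
            parsed = pd.to_datetime(remaining, format=fmt, errors="coerce")
            out = out.fillna(parsed)
        return out
    return pd.to_datetime(series, errors="coerce", format="ISO8601")


def _validate_coordinates(df: pd.DataFrame) -> None:
    lon, lat = df["longitude"], df["latitude"]
    bad_lon = lon.notna() & ((lon < -180) | (lon > 180))
    bad_lat = lat.notna() & ((lat < -90) | (lat > 90))
    if bad_lon.any() or bad_lat.any():
        n = int(bad_lon.sum() + bad_lat.sum())
        raise ValueError(f"{n} well record(s) carry out-of-range coordinates")


def normalize_raw_wells(df: pd.DataFrame, column_map: Mapping[str, str] | None = None,
                        date_formats: Sequence[str] | None = None) -> pd.DataFrame:
    """Coerce an arbitrary well table onto the canonical raw-record schema.

    ``column_map`` maps canonical names to source column names. Missing
    categorical fields default to ``"unknown"``; unparseable dates become
    missing.
    """
    if column_map:
        df = df.rename(columns={src: canon for canon, src in column_map.items()})
    out = pd.DataFrame(index=df.index)
    for col in RAW_COLUMNS:
        out[col] = df[col] if col in df.columns else np.nan
    out["source_id"] = out["source_id"].astype("string")
    out["source_name"] = out["source_name"].astype("string")
    out["state_code"] = out["state_code"].astype("string")
    for col in ("longitude", "latitude"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    for col in DATE_FIELDS:
        out[col] = _parse_dates(out[col], date_formats)
    for col, allowed in (("production_type", PRODUCTION_TYPES), ("drill_type", DRILL_TYPES)):
        vals = out[col].astype("string").str.lower()
        out[col] = vals.where(vals.isin(allowed), "unknown").fillna("unknown")
    _validate_coordinates(out)
    return out.reset_index(drop=True)


def read_wells_csv(path, column_map: Mapping[str, str] | None = None,
                   date_formats: Sequence[str] | None = None) -> pd.DataFrame:
    return normalize_raw_wells(pd.read_csv(path, dtype={"source_id": str, "state_code": str}),
                               column_map, date_formats)


def read_wells_geojson(path) -> pd.DataFrame:
    """Read raw wells from a GeoJSON FeatureCollection of Point features."""
    with open(path) as fh:
        doc = json.load(fh)
    rows = []
    for feat in doc.get("features", []):
        props = dict(feat.get("properties") or {})
        geom = feat.get("geometry") or {}
        if geom.get("type") == "Point" and geom.get("coordinates"):
            props["longitude"], props["latitude"] = geom["coordinates"][:2]
        rows.append(props)
    return normalize_raw_wells(pd.DataFrame(rows))


def wells_to_geojson(df: pd.DataFrame, path) -> None:
    feats = []
    for _, row in df.iterrows():
        props = {
            k: (None if pd.isna(v) else (v.date().isoformat() if isinstance(v, pd.Timestamp) else v))
            for k, v in row.items()
            if k not in ("longitude", "latitude")
        }
        geom = None
        if pd.notna(row.get("longitude")) and pd.notna(row.get("latitude")):
            geom = {"type": "Point", "coordinates": [float(row["longitude"]), float(row["latitude"])]}
        feats.append({"type": "Feature", "geometry": geom, "properties": props})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def _require_unique_key(df: pd.DataFrame, join_key: str, which: str) -> None:
    dup = df[join_key][df[join_key].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate join key {join_key!r} in {which} collection: {dup.iloc[0]!r}")


def merge_date_supplements(base: pd.DataFrame, supplements: pd.DataFrame,
                           join_key: str = "source_id") -> tuple[pd.DataFrame, MergeLog]:
    """Fill missing dates on base records from state supplements.

    Base dates are never overwritten; a supplement date conflicting with a
    present base date is logged and discarded. Supplement records without a
    base match are appended as new wells when they carry coordinates and at
    least one date.
    """
    for df, which in ((base, "base"), (supplements, "supplement")):
        if join_key not in df.columns:
            raise ValueError(f"join key {join_key!r} missing from {which} collection")
        _require_unique_key(df, join_key, which)

    merged = base.copy().reset_index(drop=True)
    log = MergeLog()
    if len(supplements) == 0:
        return merged, log

    supp = supplements.set_index(join_key)
    matched = merged[join_key].isin(supp.index)
    for col in DATE_FIELDS:
        if col not in supp.columns:
            continue
        supp_vals = merged.loc[matched, join_key].map(supp[col])
        base_vals = merged.loc[matched, col]
        fill = base_vals.isna() & supp_vals.notna()
        conflict = base_vals.notna() & supp_vals.notna() & (base_vals != supp_vals)
        merged.loc[fill[fill].index, col] = supp_vals[fill]
        log.filled += int(fill.sum())
        log.conflicts += int(conflict.sum())

    unmatched = supplements[~supplements[join_key].isin(base[join_key])]
    has_coords = unmatched["longitude"].notna() & unmatched["latitude"].notna()
    has_date = unmatched[list(DATE_FIELDS)].notna().any(axis=1)
    to_append = unmatched[has_coords & has_date]
    if len(to_append):
        merged = pd.concat([merged, to_append], ignore_index=True)
        log.appended = len(to_append)
    return merged, log


def filter_usable(raw: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop records missing coordinates or any usable date.

    Returns the kept records and a rejection log partitioning rejects by
    reason; a record missing both is counted under ``missing_coordinates``.
    """
    has_coords = raw["longitude"].notna() & raw["latitude"].notna()
    has_date = raw[list(DATE_FIELDS)].notna().any(axis=1)
    missing_coords = ~has_coords
    missing_date = has_coords & ~has_date
    kept = raw[has_coords & has_date].reset_index(drop=True)
    log = {
        "missing_coordinates": int(missing_coords.sum()),
        "missing_date": int(missing_date.sum()),
    }
    return kept, log


def earliest_activity_date(record) -> pd.Timestamp:
    """Earliest of the spud / completion / first-production dates.

    Accepts a single record (Series or mapping). Raises if no date is present
    — such a record should have been excluded upstream.
    """
    vals = [pd.Timestamp(record[f]) for f in DATE_FIELDS
            if f in record and pd.notna(record[f])]
    if not vals:
        raise ValueError("record has no usable date; it should have been excluded upstream")
    return min(vals)


def activity_window(earliest, lifespan_years: int = DEFAULT_LIFESPAN_YEARS) -> DateInterval:
    """Closed activity interval: earliest date through its anniversary
    ``lifespan_years`` later (Feb 29 anniversaries fall back to Feb 28)."""
    if lifespan_years < 1:
        raise ValueError("lifespan_years must be >= 1")
    start = pd.Timestamp(earliest)
    return DateInterval(start, start + pd.DateOffset(years=lifespan_years))


def is_active(well, period: DateInterval):
    """Whether a well's activity window overlaps a closed calendar period.

    ``well`` may be a single record with ``activity_start``/``activity_end``
    or a harmonized DataFrame (returns a boolean Series).
    """
    if isinstance(well, pd.DataFrame):
        return (well["activity_start"] <= period.end) & (well["activity_end"] >= period.start)
    return bool(well["activity_start"] <= period.end and well["activity_end"] >= period.start)


def harmonize(raw: pd.DataFrame, lifespan_years: int = DEFAULT_LIFESPAN_YEARS) -> pd.DataFrame:
    """Turn filtered raw records into harmonized wells with activity windows.

    ``well_id`` is ``source_name:source_id`` — cross-source duplicates are
    deliberately not collapsed.
    """
    kept, _ = filter_usable(raw)
    out = kept.copy()
    out["well_id"] = out["source_name"].fillna("unknown").str.cat(out["source_id"].astype("string"), sep=":")
    dup = out["well_id"][out["well_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate well_id after harmonization: {dup.iloc[0]!r}")
    earliest = out[list(DATE_FIELDS)].min(axis=1)
    out["earliest_activity_date"] = earliest
    out["activity_start"] = earliest
    out["activity_end"] = earliest + pd.DateOffset(years=lifespan_years)
    cols = ["well_id", "longitude", "latitude", "earliest_activity_date",
            "activity_start", "activity_end", "production_type", "drill_type", "state_code",
            "source_name", "source_id"]
    return out[cols].reset_index(drop=True)
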