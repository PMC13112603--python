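"""School-roster ingestion, demographic profiles, and urbanicity classes.

Schools come with enrollment and student counts by race/ethnicity (treated as
mutually exclusive: Hispanic of any race vs. non-Hispanic groups) and by
free/reduced-lunch (FRL) eligibility, an income proxy. A school is
"predominantly" of a category when the category share strictly exceeds a
threshold (50% by default; 40%/60% as sensitivity settings). Urbanicity comes
from ZIP-level Rural-Urban Commuting Area (RUCA) codes collapsed to
Metropolitan (1-3), Micropolitan (4-6), and Rural (7-10); schools whose ZIP has
no RUCA assignment are assumed Rural.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CATEGORY_COUNT_COLUMNS = {
    "nh_white": "count_nh_white",
    "hispanic": "count_hispanic",
    "black": "count_black",
    "asian_pi": "count_asian_pi",
    "frl": "count_frl",
}
RACE_CATEGORIES = ("nh_white", "hispanic", "black", "asian_pi")
CHARACTERISTICS = ("nh_white", "hispanic", "frl")

SCHOOL_COLUMNS = (
    "school_id", "longitude", "latitude", "state_code", "county_fips", "zip",
    "school_year", "total_enrollment", *CATEGORY_COUNT_COLUMNS.values(),
)

URBANICITY_LEVELS = ("Metropolitan", "Micropolitan", "Rural")

DEFAULT_THRESHOLDS = (0.4, 0.5, 0.6)


def read_schools_csv(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"school_id": str, "state_code": str,
                                  "county_fips": str, "zip": str})
    if column_map:
        df = df.rename(columns={src: canon for canon, src in column_map.items()})
    out = pd.DataFrame(index=df.index)
    for col in SCHOOL_COLUMNS:
        out[col] = df[col] if col in df.columns else np.nan
    for col in ("school_id", "state_code", "county_fips", "zip", "school_year"):
        out[col] = out[col].astype("string")
    for col in ("longitude", "latitude"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    for col in ("total_enrollment", *CATEGORY_COUNT_COLUMNS.values()):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    return out.reset_index(drop=True)


def exclude_missing_enrollment(schools: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop schools with missing (or zero — proportions undefined) enrollment."""
    enroll = schools["total_enrollment"]
    keep = enroll.notna() & (enroll > 0)
    kept = schools[keep].reset_index(drop=True)
    return kept, int((~keep).sum())


def category_proportion(count: float, total: float) -> float:
    """Share of the student body in one category."""
    if total is None or pd.isna(total) or total <= 0:
        raise ValueError("total enrollment missing or non-positive; record should have been excluded")
    if pd.isna(count) or count < 0 or count > total:
        raise ValueError(f"category count {count} outside [0, {total}]")
    return float(count) / float(total)


def classify_predominant(proportion: float, threshold: float = 0.5) -> bool:
    """Strict dichotomy: predominant iff the share exceeds the threshold."""
    if not (0.0 <= proportion <= 1.0):
        raise ValueError(f"proportion {proportion} outside [0, 1]")
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold {threshold} outside (0, 1)")
    return proportion > threshold


def load_ruca_table(path) -> pd.Series:
    """Two-column CSV (zip, ruca_code) -> Series indexed by 5-digit ZIP."""
    df = pd.read_csv(path, dtype={"zip": str})
    return make_ruca_table(df)


def make_ruca_table(df: pd.DataFrame) -> pd.Series:
    codes = pd.to_numeric(df["ruca_code"], errors="raise").astype(int)
    if ((codes < 1) | (codes > 10)).any():
        bad = codes[(codes < 1) | (codes > 10)].iloc[0]
        raise ValueError(f"RUCA code {bad} outside 1-10")
    table = pd.Series(codes.values, index=df["zip"].astype(str).values, name="ruca_code")
    if table.index.duplicated().any():
        raise ValueError("duplicate ZIP in RUCA table")
    return table


def urbanicity_from_ruca(code) -> str:
    if code is None or (isinstance(code, float) and np.isnan(code)):
        return "Rural"
    code = int(code)
    if 1 <= code <= 3:
        return "Metropolitan"
    if 4 <= code <= 6:
        return "Micropolitan"
    if 7 <= code <= 10:
        return "Rural"
    raise ValueError(f"RUCA code {code} outside 1-10")


def assign_ruca(zip_code, table: pd.Series) -> tuple[float, str]:
    """Look up a school's RUCA code; unassigned ZIPs fall back to Rural."""
    if zip_code is None or pd.isna(zip_code) or str(zip_code) not in table.index:
        return (np.nan, "Rural")
    code = int(table.loc[str(zip_code)])
    return (code, urbanicity_from_ruca(code))


def build_school_profiles(schools: pd.DataFrame, ruca_table: pd.Series,
                          thresholds: Sequence[float] = DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Per-school category proportions, predominance flags, and urbanicity.

    Expects the post-exclusion roster (enrollment present and positive).
    Missing category counts with enrollment present are treated as zero and
    flagged in ``any_count_imputed_zero``.
    """
    enroll = schools["total_enrollment"]
    if enroll.isna().any() or (enroll <= 0).any():
        raise ValueError("profiles require the enrollment-excluded roster")

    out = schools[["school_id", "state_code", "county_fips", "zip"]].copy()
    imputed = pd.Series(False, index=schools.index)
    for cat, col in CATEGORY_COUNT_COLUMNS.items():
        counts = schools[col]
        imputed |= counts.isna()
        counts = counts.fillna(0)
        if (counts > enroll).any():
            raise ValueError(f"{col} exceeds enrollment for some school")
        out[f"prop_{cat}"] = counts / enroll
    out["any_count_imputed_zero"] = imputed.values

    race_sum = sum(out[f"prop_{c}"] for c in RACE_CATEGORIES)
    if (race_sum > 1 + 1e-9).any():
        raise ValueError("race/ethnicity proportions sum above 1")

    for thr in thresholds:
        pct = int(round(thr * 100))
        for cat in CHARACTERISTICS:
            out[f"predominant_{cat}_{pct}"] = out[f"prop_{cat}"] > thr

    ruca_codes = schools["zip"].astype("string").map(ruca_table)
    out["ruca_code"] = ruca_codes
    out["urbanicity"] = ruca_codes.map(urbanicity_from_ruca, na_action=None)
    out.loc[ruca_codes.isna(), "urbanicity"] = "Rural"
    out["total_enrollment"] = enroll.values
    return out.reset_index(drop=True)
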