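"""Synthetic well registries, school rosters, and RUCA tables.

Generates registry-shaped inputs with known planted structure so the whole
pipeline — harmonization, exclusions, exposure, and the disparity models —
runs end to end without any external download. Wells follow a Thomas-like
clustered point process inside rectangular pseudo-states; schools are placed
by an urbanicity mix (Metropolitan schools clustered around per-state cores),
and each school's predominance flags are drawn from a stratum-baseline logit
model with a planted exposure log-odds shift, after which demographic counts
are drawn consistent with the flags. Defaults emulate the magnitudes of the
national study population this generator stands in for: urbanicity mix
0.746/0.112/0.142, baseline predominance rates 0.486/0.185/0.507 for the
non-Hispanic-White/Hispanic/free-reduced-lunch characteristics, planted
odds ratios 1.37/0.92/1.14 at a 10 km truth buffer, and a missing-enrollment
fraction of 1,671/101,390.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import registry, roster
from .exposure import ActiveWellIndex, EARTH_RADIUS_M
from .registry import DATE_FIELDS, harmonize, merge_date_supplements, school_year_interval

_METERS_PER_DEG_LAT = EARTH_RADIUS_M * math.pi / 180.0

# fixed substream ids so adding one entity type never perturbs another
_STREAMS = {"wells": 0, "supplement": 1, "school_locations": 2, "baselines": 3,
            "flags": 4, "demographics": 5, "ruca": 6, "missingness": 7}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


def _default_boxes(n_states: int) -> tuple:
    """Non-overlapping 4x4-degree boxes along a mid-latitude band."""
    boxes = []
    for i in range(n_states):
        lon0 = -125.0 + 5.0 * i
        boxes.append((lon0, 33.0, lon0 + 4.0, 37.0))
    return tuple(boxes)


def _default_state_codes(n_states: int) -> tuple:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    return tuple(f"S{letters[i % 26]}{'' if i < 26 else i // 26}" for i in range(n_states))


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic study scene.

    ``planted_log_or`` are the true exposure log-odds shifts for each school
    characteristic at ``buffer_for_truth``; ``baseline_rate`` sets the
    stratum-average predominance probability, jittered per state by
    ``baseline_logit_sd`` on the logit scale.
    """

    seed: int = 0
    n_states: int = 8
    state_boxes: tuple | None = None
    state_codes: tuple | None = None
    counties_per_state: int = 4
    n_wells: int = 4000
    well_cluster_count: int = 80
    cluster_spread_m: float = 2000.0
    well_date_range: tuple = ("1950-01-01", "2023-06-30")
    frac_missing_well_date: float = 0.05
    frac_missing_well_coords: float = 0.02
    frac_supplement_recovery: float = 0.5
    n_supplement_appended: int = 20
    n_schools: int = 20000
    n_missing_enrollment: int | None = None
    enrollment_range: tuple = (60, 1500)
    urbanicity_mix: dict = field(default_factory=lambda: {
        "Metropolitan": 0.746, "Micropolitan": 0.112, "Rural": 0.142})
    baseline_rate: dict = field(default_factory=lambda: {
        "nh_white": 0.486, "hispanic": 0.185, "frl": 0.507})
    baseline_logit_sd: float = 0.3
    planted_log_or: dict = field(default_factory=lambda: {
        "nh_white": math.log(1.37), "hispanic": math.log(0.92), "frl": math.log(1.14)})
    frac_cores_near_wells: float = 0.6
    buffer_for_truth: float = 10000.0
    school_year: str = "2022-2023"
    lifespan_years: int = 30
    frac_unmapped_rural_zip: float = 0.002

    def __post_init__(self) -> None:
        if self.state_boxes is None:
            self.state_boxes = _default_boxes(self.n_states)
        if self.state_codes is None:
            self.state_codes = _default_state_codes(self.n_states)
        if len(self.state_boxes) != self.n_states or len(self.state_codes) != self.n_states:
            raise ValueError("state_boxes and state_codes must match n_states")
        for lon0, lat0, lon1, lat1 in self.state_boxes:
            if lon1 <= lon0 or lat1 <= lat0:
                raise ValueError("state boxes must be non-degenerate rectangles")
        for frac in (self.frac_missing_well_date, self.frac_missing_well_coords,
                     self.frac_supplement_recovery, self.frac_unmapped_rural_zip):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(self.urbanicity_mix.values()) - 1.0) > 1e-9:
            raise ValueError("urbanicity_mix must sum to 1")
        if self.n_missing_enrollment is None:
            self.n_missing_enrollment = int(round(self.n_schools * 1671 / 101390))
        for char, lor in self.planted_log_or.items():
            if not np.isfinite(lor):
                raise ValueError(f"planted log-OR for {char} must be finite")
            base = self.baseline_rate[char]
            if not (0.0 < base < 1.0):
                raise ValueError(f"baseline rate for {char} must lie in (0, 1)")
            # shifted probability must stay strictly inside (0, 1)
            p = expit(logit(base) + lor)
            if not (0.0 < p < 1.0):
                raise ValueError(f"planted probability for {char} leaves (0, 1)")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["state_boxes"] = [list(b) for b in self.state_boxes]
        d["state_codes"] = list(self.state_codes)
        return d


@dataclass
class SimBundle:
    """In-memory scene: every file the ingestion modules would read."""

    wells: pd.DataFrame
    supplement: pd.DataFrame
    schools: pd.DataFrame
    ruca: pd.DataFrame
    truth: pd.DataFrame
    config_echo: dict


def _meters_to_lon_deg(m, lat) -> np.ndarray:
    return np.asarray(m) / (_METERS_PER_DEG_LAT * np.cos(np.radians(np.asarray(lat))))


def generate_wells(config: ScenarioConfig) -> pd.DataFrame:
    """Clustered raw well records with exact-count missingness."""
    rng = _rng(config.seed, "wells")
    n = config.n_wells
    k = config.well_cluster_count
    boxes = np.array(config.state_boxes)

    cluster_state = rng.integers(0, config.n_states, size=k)
    u = rng.random((k, 2))
    c_lon = boxes[cluster_state, 0] + u[:, 0] * (boxes[cluster_state, 2] - boxes[cluster_state, 0])
    c_lat = boxes[cluster_state, 1] + u[:, 1] * (boxes[cluster_state, 3] - boxes[cluster_state, 1])
    sizes = rng.multinomial(n, np.full(k, 1.0 / k))
    cl = np.repeat(np.arange(k), sizes)

    dx = rng.normal(0.0, config.cluster_spread_m, size=n) if config.cluster_spread_m > 0 else np.zeros(n)
    dy = rng.normal(0.0, config.cluster_spread_m, size=n) if config.cluster_spread_m > 0 else np.zeros(n)
    lat = c_lat[cl] + dy / _METERS_PER_DEG_LAT
    lon = c_lon[cl] + _meters_to_lon_deg(dx, c_lat[cl])
    st = cluster_state[cl]
    lon = np.clip(lon, boxes[st, 0], boxes[st, 2])
    lat = np.clip(lat, boxes[st, 1], boxes[st, 3])

    d0 = pd.Timestamp(config.well_date_range[0])
    d1 = pd.Timestamp(config.well_date_range[1])
    span_days = (d1 - d0).days
    spud = d0 + pd.to_timedelta(rng.integers(0, span_days + 1, size=n), unit="D")
    completion = spud + pd.to_timedelta(rng.integers(10, 121, size=n), unit="D")
    first_prod = completion + pd.to_timedelta(rng.integers(0, 181, size=n), unit="D")
    spud = pd.Series(spud).where(rng.random(n) >= 0.15, pd.NaT)
    completion = pd.Series(completion).where(rng.random(n) >= 0.30, pd.NaT)
    first_prod = pd.Series(first_prod).where(rng.random(n) >= 0.50, pd.NaT)
    # guarantee every non-blanked record keeps at least one date
    none_left = spud.isna() & completion.isna() & first_prod.isna()
    completion = completion.where(~none_left, d0 + pd.to_timedelta(rng.integers(0, span_days + 1, size=n), unit="D"))

    df = pd.DataFrame({
        "source_id": [f"W{i:06d}" for i in range(n)],
        "source_name": "synthetic_registry",
        "longitude": lon,
        "latitude": lat,
        "spud_date": spud,
        "completion_date": completion,
        "first_production_date": first_prod,
        "production_type": rng.choice(registry.PRODUCTION_TYPES, size=n,
                                      p=[0.35, 0.30, 0.20, 0.05, 0.10]),
        "drill_type": rng.choice(registry.DRILL_TYPES, size=n, p=[0.35, 0.15, 0.40, 0.10]),
        "state_code": np.asarray(config.state_codes, dtype=object)[st],
    })

    # exact-count missingness on disjoint record sets
    n_date_blank = int(round(config.frac_missing_well_date * n))
    n_coord_blank = int(round(config.frac_missing_well_coords * n))
    order = _rng(config.seed, "missingness").permutation(n)
    date_blank = order[:n_date_blank]
    coord_blank = order[n_date_blank:n_date_blank + n_coord_blank]
    for col in DATE_FIELDS:
        df.loc[date_blank, col] = pd.NaT
    df.loc[coord_blank, ["longitude", "latitude"]] = np.nan
    return df


def generate_date_supplement(config: ScenarioConfig, wells: pd.DataFrame) -> pd.DataFrame:
    """State-source records: dates for a share of the date-blanked wells plus
    a few appended wells absent from the primary registry."""
    rng = _rng(config.seed, "supplement")
    blank = wells[wells[list(DATE_FIELDS)].isna().all(axis=1)]
    n_fill = int(round(config.frac_supplement_recovery * len(blank)))
    fill_ids = blank["source_id"].iloc[:n_fill]

    d0 = pd.Timestamp(config.well_date_range[0])
    d1 = pd.Timestamp(config.well_date_range[1])
    span = (d1 - d0).days
    rows = []
    for sid in fill_ids:
        rows.append({"source_id": sid, "source_name": "synthetic_state_source",
                     "spud_date": d0 + pd.Timedelta(days=int(rng.integers(0, span + 1)))})
    boxes = np.array(config.state_boxes)
    for j in range(config.n_supplement_appended):
        s = int(rng.integers(0, config.n_states))
        rows.append({
            "source_id": f"X{j:05d}",
            "source_name": "synthetic_state_source",
            "longitude": float(rng.uniform(boxes[s, 0], boxes[s, 2])),
            "latitude": float(rng.uniform(boxes[s, 1], boxes[s, 3])),
            "spud_date": d0 + pd.Timedelta(days=int(rng.integers(0, span + 1))),
            "production_type": "unknown",
            "drill_type": "unknown",
            "state_code": config.state_codes[s],
        })
    supp = pd.DataFrame(rows)
    return registry.normalize_raw_wells(supp)


def _place_schools(config: ScenarioConfig, rng: np.random.Generator,
                   active_wells: pd.DataFrame):
    """School locations by urbanicity, with settlement cores partly anchored
    on drilling regions (towns and well fields co-occur, which is what gives
    the study population its high 10 km exposure prevalence)."""
    n = config.n_schools
    boxes = np.array(config.state_boxes)
    state = rng.integers(0, config.n_states, size=n)

    urb_levels = list(config.urbanicity_mix)
    probs = np.array([config.urbanicity_mix[u] for u in urb_levels])
    urb = np.asarray(urb_levels, dtype=object)[rng.choice(len(urb_levels), size=n, p=probs)]

    wells_by_state = {code: g for code, g in active_wells.groupby("state_code")}

    def core_points(s: int, k: int, p_anchor: float):
        lon0, lat0, lon1, lat1 = boxes[s]
        g = wells_by_state.get(config.state_codes[s])
        cx, cy = np.empty(k), np.empty(k)
        for j in range(k):
            if g is not None and len(g) and rng.random() < p_anchor:
                w = g.iloc[int(rng.integers(0, len(g)))]
                cx[j] = w["longitude"] + rng.normal(0, 0.03)
                cy[j] = w["latitude"] + rng.normal(0, 0.03)
            else:
                cx[j] = rng.uniform(lon0, lon1)
                cy[j] = rng.uniform(lat0, lat1)
        return np.clip(cx, lon0, lon1), np.clip(cy, lat0, lat1)

    cores = {}
    for s in range(config.n_states):
        cores[s] = {
            "Metropolitan": core_points(s, 3, config.frac_cores_near_wells),
            "Micropolitan": core_points(s, 3, config.frac_cores_near_wells),
        }
    lon = np.empty(n)
    lat = np.empty(n)
    for i in range(n):
        s = state[i]
        lon0, lat0, lon1, lat1 = boxes[s]
        g = wells_by_state.get(config.state_codes[s])
        if urb[i] == "Rural":
            if g is not None and len(g) and rng.random() < 0.3:
                w = g.iloc[int(rng.integers(0, len(g)))]
                lon[i] = np.clip(w["longitude"] + rng.normal(0, 0.15), lon0, lon1)
                lat[i] = np.clip(w["latitude"] + rng.normal(0, 0.15), lat0, lat1)
            else:
                lon[i] = rng.uniform(lon0, lon1)
                lat[i] = rng.uniform(lat0, lat1)
        else:
            cx, cy = cores[s][urb[i]]
            j = int(rng.integers(0, len(cx)))
            sd = 0.06 if urb[i] == "Metropolitan" else 0.04
            lon[i] = np.clip(cx[j] + rng.normal(0, sd), lon0, lon1)
            lat[i] = np.clip(cy[j] + rng.normal(0, sd), lat0, lat1)
    return state, urb, lon, lat


def _draw_shares(rng, white_flag, hisp_flag, frl_flag):
    n = len(white_flag)
    u = np.where(white_flag, rng.uniform(0.52, 0.92, n), rng.uniform(0.03, 0.46, n))
    # uniform draws on the flag-consistent share intervals
    hi_up = np.minimum(0.92, 1.0 - u - 0.01)
    lo_up = np.minimum(0.46, 1.0 - u - 0.01)
    v_flag = 0.52 + rng.random(n) * (hi_up - 0.52)
    v_unflag = 0.01 + rng.random(n) * (lo_up - 0.01)
    v = np.where(hisp_flag, v_flag, v_unflag)
    rem = 1.0 - u - v
    black = rem * rng.beta(2.0, 6.0, n)
    asian = (rem - black) * rng.beta(1.0, 12.0, n)
    frl = np.where(frl_flag, rng.uniform(0.52, 0.95, n), rng.uniform(0.05, 0.48, n))
    return u, v, black, asian, frl


def generate_schools(config: ScenarioConfig, wells: pd.DataFrame,
                     supplement: pd.DataFrame | None = None):
    """School roster, RUCA table, and ground-truth records.

    True exposure is computed by the exposure engine on the harmonized wells
    (post merge/filter), then each predominance flag is drawn from
    ``logit p = baseline_logit(state) + planted_log_or * exposed`` and
    demographic counts are drawn inside the flag-consistent share region (the
    White and Hispanic flags are mutually exclusive because their shares
    cannot both exceed one half; the Hispanic model is applied among schools
    not flagged White, while free/reduced lunch is independent).
    """
    if supplement is None:
        supplement = pd.DataFrame(columns=list(registry.RAW_COLUMNS))
    merged, _ = merge_date_supplements(wells, supplement)
    harmonized = harmonize(merged, config.lifespan_years)

    period = school_year_interval(config.school_year)
    active = harmonized[registry.is_active(harmonized, period)]

    loc_rng = _rng(config.seed, "school_locations")
    state, urb, lon, lat = _place_schools(config, loc_rng, active)
    n = config.n_schools

    index = ActiveWellIndex(harmonized, period)
    _, ndist = index.nearest(lon, lat)
    true_exposed = np.where(np.isnan(ndist), False, ndist <= config.buffer_for_truth)

    base_rng = _rng(config.seed, "baselines")
    baselines = {char: logit(rate) + base_rng.normal(0.0, config.baseline_logit_sd, config.n_states)
                 for char, rate in config.baseline_rate.items()}

    flag_rng = _rng(config.seed, "flags")
    p_white = expit(baselines["nh_white"][state] + config.planted_log_or["nh_white"] * true_exposed)
    white_flag = flag_rng.random(n) < p_white
    p_hisp = expit(baselines["hispanic"][state] + config.planted_log_or["hispanic"] * true_exposed)
    hisp_flag = (~white_flag) & (flag_rng.random(n) < p_hisp)
    p_frl = expit(baselines["frl"][state] + config.planted_log_or["frl"] * true_exposed)
    frl_flag = flag_rng.random(n) < p_frl

    demo_rng = _rng(config.seed, "demographics")
    enroll = demo_rng.integers(config.enrollment_range[0], config.enrollment_range[1] + 1, size=n)
    u, v, black, asian, frl = _draw_shares(demo_rng, white_flag, hisp_flag, frl_flag)
    c_white = np.round(u * enroll).astype(int)
    c_hisp = np.round(v * enroll).astype(int)
    c_black = np.round(black * enroll).astype(int)
    c_asian = np.round(asian * enroll).astype(int)
    c_frl = np.round(frl * enroll).astype(int)
    over = c_white + c_hisp + c_black + c_asian - enroll
    c_asian = np.maximum(0, c_asian - np.maximum(over, 0))
    over = c_white + c_hisp + c_black + c_asian - enroll
    c_black = np.maximum(0, c_black - np.maximum(over, 0))

    # ZIPs shared within (state, urbanicity) groups; codes consistent with class
    ruca_rng = _rng(config.seed, "ruca")
    zips = np.empty(n, dtype=object)
    ruca_rows = []
    zip_counter = 10000
    code_range = {"Metropolitan": (1, 4), "Micropolitan": (4, 7), "Rural": (7, 11)}
    for s in range(config.n_states):
        for level in ("Metropolitan", "Micropolitan", "Rural"):
            m = (state == s) & (urb == level)
            cnt = int(m.sum())
            if cnt == 0:
                continue
            n_zip = max(1, cnt // 40)
            pool = [f"{zip_counter + j:05d}" for j in range(n_zip)]
            zip_counter += n_zip
            zips[m] = np.asarray(pool, dtype=object)[ruca_rng.integers(0, n_zip, size=cnt)]
            lo, hi = code_range[level]
            ruca_rows += [{"zip": z, "ruca_code": int(ruca_rng.integers(lo, hi))} for z in pool]
    ruca_df = pd.DataFrame(ruca_rows)

    # a few Rural schools get ZIPs absent from the table (fallback stays Rural)
    n_unmapped = int(round(config.frac_unmapped_rural_zip * n))
    rural_idx = np.flatnonzero(urb == "Rural")[:n_unmapped]
    for j, i in enumerate(rural_idx):
        zips[i] = f"{99000 + j:05d}"

    county = demo_rng.integers(0, config.counties_per_state, size=n)
    schools = pd.DataFrame({
        "school_id": [f"SCH{i:06d}" for i in range(n)],
        "longitude": lon,
        "latitude": lat,
        "state_code": np.asarray(config.state_codes, dtype=object)[state],
        "county_fips": [f"{s:02d}{c:03d}" for s, c in zip(state, county)],
        "zip": zips,
        "school_year": config.school_year,
        "total_enrollment": enroll.astype(float),
        "count_nh_white": c_white,
        "count_hispanic": c_hisp,
        "count_black": c_black,
        "count_asian_pi": c_asian,
        "count_frl": c_frl,
    })
    miss_rng = _rng(config.seed, "missingness")
    blank = miss_rng.choice(n, size=config.n_missing_enrollment, replace=False)
    schools.loc[blank, "total_enrollment"] = np.nan

    truth = pd.DataFrame({
        "school_id": schools["school_id"],
        "nearest_active_distance_m": ndist,
        "true_exposed": true_exposed,
        "urbanicity": urb,
        "p_nh_white": p_white,
        "flag_nh_white": white_flag,
        "p_hispanic": p_hisp,
        "flag_hispanic": hisp_flag,
        "p_frl": p_frl,
        "flag_frl": frl_flag,
        "planted_log_or_nh_white": config.planted_log_or["nh_white"],
        "planted_log_or_hispanic": config.planted_log_or["hispanic"],
        "planted_log_or_frl": config.planted_log_or["frl"],
        "buffer_for_truth": config.buffer_for_truth,
        "seed": config.seed,
    })
    return schools, ruca_df, truth


def generate_scenario(config: ScenarioConfig) -> SimBundle:
    wells = generate_wells(config)
    supplement = generate_date_supplement(config, wells)
    schools, ruca, truth = generate_schools(config, wells, supplement)
    return SimBundle(wells=wells, supplement=supplement, schools=schools,
                     ruca=ruca, truth=truth, config_echo=config.as_dict())


def write_scenario(bundle: SimBundle, outdir) -> dict:
    """Write the scene as the CSV dialects the ingestion modules read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("wells", bundle.wells), ("supplement", bundle.supplement),
                     ("schools", bundle.schools), ("ruca", bundle.ruca),
                     ("truth", bundle.truth)):
        p = outdir / f"{name}.csv"
        out = df.copy()
        for col in out.columns:
            if pd.api.types.is_datetime64_any_dtype(out[col]):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
        out.to_csv(p, index=False)
        paths[name] = p
    cfg = outdir / "config.json"
    with open(cfg, "w") as fh:
        json.dump(bundle.config_echo, fh, indent=2, sort_keys=True)
    paths["config"] = cfg
    return paths


# ---------------------------------------------------------------------------
# Worked fixture: exact exposed counts by construction

_GRID_LAT_STEP = 0.25    # ~27.8 km
_GRID_LON_STEP = 0.35    # >=25 km up to |lat| 50
_GRID_LAT_MAX = 50.0


def generate_worked_fixture(n_schools: int,
                            n_missing_enrollment: int = 0,
                            exposed_counts: dict | None = None,
                            exposed_student_totals: dict | None = None,
                            unexposed_student_total: int | None = None,
                            n_states: int = 10,
                            school_year: str = "2022-2023") -> SimBundle:
    """A deterministic scene whose exposure counts are exact by construction.

    Schools sit on a wide grid (>= ~25 km apart). Each school designated
    exposed at its tightest radius gets exactly one active well — at the
    school itself for the smallest radius, otherwise offset east to the
    midpoint of its radius band — and no well lies within 10 km of any other
    school, so the exposure engine reproduces the requested per-radius
    exposed counts exactly. Optional per-radius student totals are spread
    over the exposed classes so enrollment sums are exact too.
    """
    exposed_counts = dict(sorted((float(k), int(v)) for k, v in (exposed_counts or {}).items()))
    radii = list(exposed_counts)
    counts = list(exposed_counts.values())
    if any(b < a for a, b in zip(counts, counts[1:])):
        raise ValueError("exposed counts must be non-decreasing with radius")
    if counts and counts[-1] > n_schools:
        raise ValueError("more exposed schools requested than schools")
    if radii and max(radii) > 10000.0:
        raise ValueError("worked fixture supports radii up to 10 km")

    n_rows = int(2 * _GRID_LAT_MAX / _GRID_LAT_STEP)
    n_cols = int(360.0 / _GRID_LON_STEP) - 1
    if n_schools > n_rows * n_cols:
        raise ValueError(f"grid holds at most {n_rows * n_cols} schools at 25 km separation")
    idx = np.arange(n_schools)
    lat = -_GRID_LAT_MAX + _GRID_LAT_STEP / 2 + (idx // n_cols) * _GRID_LAT_STEP
    lon = -180.0 + _GRID_LON_STEP / 2 + (idx % n_cols) * _GRID_LON_STEP

    # tightest-radius class per school: 0..len(radii)-1 exposed, -1 unexposed
    klass = np.full(n_schools, -1)
    prev = 0
    for ki, c in enumerate(counts):
        klass[prev:c] = ki
        prev = c

    well_rows = []
    spud = pd.Timestamp("2000-06-15")
    for i in np.flatnonzero(klass >= 0):
        ki = klass[i]
        lower = 0.0 if ki == 0 else radii[ki - 1]
        offset = 0.0 if ki == 0 else (lower + radii[ki]) / 2.0
        wlat = lat[i]
        wlon = lon[i] + (offset / (_METERS_PER_DEG_LAT * math.cos(math.radians(wlat))))
        well_rows.append({
            "source_id": f"W{i:06d}", "source_name": "worked_fixture",
            "longitude": wlon, "latitude": wlat, "spud_date": spud,
            "production_type": "oil", "drill_type": "vertical",
            "state_code": None,
        })
    wells = registry.normalize_raw_wells(pd.DataFrame(
        well_rows, columns=list(registry.RAW_COLUMNS)))

    state_ix = (idx * n_states) // max(n_schools, 1)
    codes = _default_state_codes(n_states)
    wells_state = wells.copy()
    if len(wells_state):
        wells_state["state_code"] = pd.array(
            [codes[int(state_ix[int(sid[1:])])] for sid in wells_state["source_id"]], dtype="string")

    enrollment = np.zeros(n_schools, dtype=float)

    def spread(total: int, members: np.ndarray) -> None:
        if len(members) == 0:
            return
        base, rem = divmod(int(total), len(members))
        enrollment[members] += base
        enrollment[members[:rem]] += 1

    if exposed_student_totals:
        totals = dict(sorted((float(k), int(v)) for k, v in exposed_student_totals.items()))
        prev_members = np.array([], dtype=int)
        prev_total = 0
        for r, tot in totals.items():
            members = np.flatnonzero((klass >= 0) & (np.array([radii[k] if k >= 0 else np.inf for k in klass]) <= r))
            new = np.setdiff1d(members, prev_members)
            spread(tot - prev_total, new)
            prev_members, prev_total = members, tot
    else:
        enrollment[klass >= 0] = 500

    unexposed = np.flatnonzero(klass < 0)
    if n_missing_enrollment > len(unexposed):
        raise ValueError("cannot blank more enrollments than unexposed schools")
    missing = unexposed[len(unexposed) - n_missing_enrollment:]
    with_enroll = unexposed[:len(unexposed) - n_missing_enrollment]
    if unexposed_student_total is not None:
        spread(unexposed_student_total, with_enroll)
    else:
        enrollment[with_enroll] = 500
    enrollment[missing] = np.nan

    e = np.nan_to_num(enrollment)
    schools = pd.DataFrame({
        "school_id": [f"SCH{i:06d}" for i in idx],
        "longitude": lon,
        "latitude": lat,
        "state_code": np.asarray(codes, dtype=object)[state_ix],
        "county_fips": [f"{s:02d}000" for s in state_ix],
        "zip": "10001",
        "school_year": school_year,
        "total_enrollment": enrollment,
        "count_nh_white": np.round(0.48 * e).astype(int),
        "count_hispanic": np.round(0.26 * e).astype(int),
        "count_black": np.round(0.12 * e).astype(int),
        "count_asian_pi": np.round(0.02 * e).astype(int),
        "count_frl": np.round(0.55 * e).astype(int),
    })
    ruca = pd.DataFrame({"zip": ["10001"], "ruca_code": [1]})
    truth = pd.DataFrame({
        "school_id": schools["school_id"],
        "tightest_radius_m": [radii[k] if k >= 0 else np.nan for k in klass],
        "true_exposed": klass >= 0,
    })
    echo = {"kind": "worked_fixture", "n_schools": n_schools,
            "n_missing_enrollment": n_missing_enrollment,
            "exposed_counts": {str(k): v for k, v in exposed_counts.items()},
            "school_year": school_year}
    return SimBundle(wells=wells_state, supplement=pd.DataFrame(columns=list(registry.RAW_COLUMNS)),
                     schools=schools, ruca=ruca, truth=truth, config_echo=echo)
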