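"""End-to-end orchestration: harmonize -> roster -> exposure -> associations -> report."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .associations import AssociationSpec, descriptive_table, run_association_suite
from .exposure import BufferSet, build_exposure_profiles, prevalence_summary
from .registry import (harmonize, merge_date_supplements, filter_usable,
                       read_wells_csv, read_wells_geojson, wells_to_geojson)
from .roster import build_school_profiles, exclude_missing_enrollment, load_ruca_table, read_schools_csv


class StageError(RuntimeError):
    """Pipeline failure carrying the name of the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    wells_path: str
    schools_path: str
    ruca_path: str
    out_dir: str
    supplements_path: str | None = None
    join_key: str = "source_id"
    school_year: str = "2022-2023"
    lifespan_years: int = 30
    buffer_radii: tuple = (800.0, 1000.0, 1600.0, 5000.0, 10000.0)
    main_radii: tuple = (800.0, 1600.0, 10000.0)
    predominance_thresholds: tuple = (0.4, 0.5, 0.6)
    analysis_threshold: float = 0.5
    fixed_effect_level: str = "state"
    subsets: tuple = ("all", "per-urbanicity")
    denominator_mode: str = "full_roster"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("buffer_radii", "main_radii", "predominance_thresholds", "subsets"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def as_dict(self) -> dict:
        d = asdict(self)
        for key in ("buffer_radii", "main_radii", "predominance_thresholds", "subsets"):
            d[key] = list(d[key])
        return d


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_wells(path):
    p = Path(path)
    if p.suffix.lower() in (".geojson", ".json"):
        return read_wells_geojson(p)
    return read_wells_csv(p)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to the out dir).

    Any stage exception aborts the run wrapped in a StageError naming the
    stage. The run is deterministic for fixed inputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": config.as_dict(),
                      "inputs": {}, "stages": {}}
    for label, path in (("wells", config.wells_path), ("schools", config.schools_path),
                        ("ruca", config.ruca_path), ("supplements", config.supplements_path)):
        if path:
            entry = {"path": str(path)}
            if Path(path).exists():  # missing files fail inside their stage
                entry["sha256"] = _sha256(path)
            manifest["inputs"][label] = entry

    stage = "harmonize_wells"
    try:
        raw = _read_wells(config.wells_path)
        n_raw = len(raw)
        merge_log = {"filled": 0, "appended": 0, "conflicts": 0}
        if config.supplements_path:
            supp = _read_wells(config.supplements_path)
            raw, log = merge_date_supplements(raw, supp, config.join_key)
            merge_log = log.as_dict()
        kept, rejection_log = filter_usable(raw)
        wells = harmonize(raw, config.lifespan_years)
        wells_out = wells.copy()
        for col in ("earliest_activity_date", "activity_start", "activity_end",
                    "spud_date", "completion_date", "first_production_date"):
            if col in wells_out.columns:
                wells_out[col] = wells_out[col].dt.strftime("%Y-%m-%d")
        wells_out.to_csv(out / "harmonized_wells.csv", index=False)
        wells_to_geojson(wells, out / "harmonized_wells.geojson")
        pd.DataFrame([rejection_log]).to_csv(out / "rejection_log.csv", index=False)
        pd.DataFrame([merge_log]).to_csv(out / "merge_log.csv", index=False)
        manifest["stages"][stage] = {"records_in": n_raw, "kept": len(wells),
                                     "rejected": rejection_log, "merge": merge_log}
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    stage = "build_roster"
    try:
        schools = read_schools_csv(config.schools_path)
        ruca = load_ruca_table(config.ruca_path)
        analysis, n_excluded = exclude_missing_enrollment(schools)
        profiles = build_school_profiles(analysis, ruca, config.predominance_thresholds)
        profiles.to_csv(out / "school_profiles.csv", index=False)
        manifest["stages"][stage] = {"records_in": len(schools), "kept": len(analysis),
                                     "excluded_missing_enrollment": n_excluded}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "assign_exposure"
    try:
        buffers = BufferSet(config.buffer_radii)
        exposure = build_exposure_profiles(schools, wells, buffers, config.school_year)
        exposure.to_csv(out / "exposure_profiles.csv", index=False)
        prevalence = prevalence_summary(exposure, schools, config.main_radii,
                                        config.denominator_mode)
        prevalence.to_csv(out / "prevalence.csv", index=False)
        by_state = prevalence_summary(exposure, schools, config.main_radii,
                                      config.denominator_mode, group_by="state_code")
        by_state.to_csv(out / "prevalence_by_state.csv", index=False)
        manifest["stages"][stage] = {"schools": len(exposure),
                                     "n_exposed": {str(int(r)): int(prevalence.loc[prevalence.buffer_m == r, "n_exposed"].iloc[0])
                                                   for r in config.main_radii}}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "fit_associations"
    try:
        spec = AssociationSpec(buffers=config.main_radii,
                               fixed_effect_level=config.fixed_effect_level,
                               predominance_threshold=config.analysis_threshold,
                               subsets=config.subsets)
        results = run_association_suite(exposure, profiles, spec)
        results.to_csv(out / "associations.csv", index=False)
        manifest["stages"][stage] = {"n_results": len(results),
                                     "n_inestimable": int((~results["estimable"]).sum())}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "report"
    try:
        desc = descriptive_table(exposure, profiles, config.main_radii)
        desc.to_csv(out / "descriptive_table.csv", index=False)
        manifest["stages"][stage] = {"descriptive_rows": len(desc)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    return manifest
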