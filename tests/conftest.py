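import numpy as np
import pandas as pd
import pytest

import schoolwells as sw
from schoolwells.registry import RAW_COLUMNS, normalize_raw_wells
from schoolwells.roster import make_ruca_table


def raw_wells(rows):
    """Build a normalized raw-well table from compact dicts."""
    return normalize_raw_wells(pd.DataFrame(rows, columns=list(RAW_COLUMNS)))


@pytest.fixture(scope="session")
def small_scene():
    """A modest synthetic scene shared by read-only tests."""
    cfg = sw.ScenarioConfig(seed=11, n_schools=3000, n_wells=1200, well_cluster_count=40)
    return cfg, sw.generate_scenario(cfg)


@pytest.fixture(scope="session")
def small_scene_tables(small_scene):
    """Harmonized wells, exposure profiles, and school profiles for the scene."""
    cfg, bundle = small_scene
    merged, _ = sw.merge_date_supplements(bundle.wells, bundle.supplement)
    wells = sw.harmonize(merged, cfg.lifespan_years)
    exposure = sw.build_exposure_profiles(bundle.schools, wells, school_year=cfg.school_year)
    kept, _ = sw.exclude_missing_enrollment(bundle.schools)
    profiles = sw.build_school_profiles(kept, make_ruca_table(bundle.ruca))
    return {"wells": wells, "exposure": exposure, "profiles": profiles,
            "schools": bundle.schools, "truth": bundle.truth}
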