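import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mortframe as mf

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> mf.GeneratorConfig:
    """2 provinces x 2 districts x 3 municipalities, modest samples."""
    return mf.GeneratorConfig(
        n_provinces=2,
        districts_per_province=2,
        municipalities_per_district=3,
        persons_per_municipality=800,
        hotspot_fraction=0.25,
        hotspot_rate_multiplier=3.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    hierarchy = mf.generate_hierarchy(small_config)
    return mf.generate_persons(small_config, hierarchy)


@pytest.fixture(scope="session")
def small_summary(small_dataset):
    units = mf.hotspots.aggregate_persons(small_dataset.person_table)
    nat = mf.hotspots.national_proportion(units)
    return mf.hotspots.classify_hotspots(units, nat)


@pytest.fixture()
def collapsed_2x2() -> mf.ModelFrame:
    """2x2 table with outcome prevalence 0.6 among exposed, 0.3 among unexposed."""
    cells = pd.DataFrame({
        "municipality_id": ["u1", "u2", "u3", "u4"],
        "hotspot": [1, 0, 1, 0],
        "x": [1, 1, 0, 0],
        "weight": [60, 40, 30, 70],
    })
    return mf.ModelFrame(cells, covariates=["x"], weight="weight")
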