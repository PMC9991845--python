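import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import safbdg as sb

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mapping():
    return sb.toy_foods()


@pytest.fixture(scope="session")
def small_synthetic():
    """A small but complete synthetic study reused across read-only tests."""
    return sb.simulate_study(
        sb.SimulationConfig(n_pairs=40, n_reference=200), seed=11
    )


def make_exposures(**overrides) -> pd.DataFrame:
    """Single-subject exposure row with benign defaults."""
    base = {
        "fruitveg_g": 0.0, "legume_g": 0.0, "dairy_liquid_g": 0.0,
        "cheese_g": 0.0, "fcl_meat_g": 0.0, "egg_g": 0.0,
        "starchy_units": 0.0, "dds": 0.0, "fat_pct_te": 0.0,
        "sfa_pct_te": 12.0, "sugar_pct_te": 50.0,
    }
    base.update(overrides)
    return pd.DataFrame([base], index=pd.Index(["s1"], name="subject_id"))


def make_participant(pa_active=False, pa_metric=0.0, **overrides) -> pd.DataFrame:
    base = {
        "pair_id": "p1", "status": "case", "age": 45.0,
        "menopausal": "pre", "er": "unknown", "pr": "unknown",
        "her2": "unknown", "ethnicity": "zulu", "income_band": "R1-R3000",
        "education": "high_school", "smoker": False, "waist_cm": 90.0,
        "height_cm": 160.0, "weight_kg": 70.0, "hiv": "negative",
        "pa_metric": pa_metric, "pa_active": pa_active, "alcohol_g": 0.0,
    }
    base.update(overrides)
    return pd.DataFrame([base], index=pd.Index(["s1"], name="subject_id"))


@pytest.fixture
def fully_adherent():
    """Exposure/participant pair satisfying every guideline."""
    exposures = make_exposures(
        fruitveg_g=450.0, legume_g=30.0, dairy_liquid_g=450.0,
        fcl_meat_g=60.0, egg_g=30.0, starchy_units=11.0, dds=9.0,
        fat_pct_te=25.0, sfa_pct_te=8.0, sugar_pct_te=4.0,
    )
    return exposures, make_participant(pa_active=True, pa_metric=50.0)


@pytest.fixture
def empty_profile():
    """Zero intakes with maximally non-adherent %TE nutrients: fails every
    rule (note a literally zero SFA %TE would satisfy the '<10 %TE' rule)."""
    return make_exposures(), make_participant()


def rng(seed=0):
    return np.random.default_rng(seed)
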