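import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from neurocongruence.homology_atlas import builtin_table1_fixture, default_region_map


@pytest.fixture(scope="session")
def pair_table():
    return builtin_table1_fixture()


@pytest.fixture(scope="session")
def region_map():
    return default_region_map()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_cohort(n_per_sex=50, beta=0.0, seed=0, **overrides):
    """Small human-style synthetic cohort with one region, for unit tests."""
    from neurocongruence.synthetic_data import human_style_spec, simulate_cohort

    spec = human_style_spec(
        n_female=n_per_sex, n_male=n_per_sex,
        region_effects={"roi": beta}, seed=seed, **overrides,
    )
    return simulate_cohort(spec)


@pytest.fixture()
def toy_subjects():
    """Six subjects with a hand-solvable design (sex + centered age only)."""
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(6)],
            "sex": ["F", "F", "F", "M", "M", "M"],
            "age": [20.0, 25.0, 30.0, 20.0, 25.0, 30.0],
            "ttv": [100.0] * 6,
            "vol_roi": [3.0, 4.0, 5.0, 6.0, 8.0, 10.0],
        }
    )
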