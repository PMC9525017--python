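import numpy as np
import pandas as pd
import pytest

import csvd_brainage as cb


@pytest.fixture(scope="session")
def tiny_atlas():
    """6 cortical + 2 subcortical + 2 cerebellar regions, 4 voxels each."""
    return cb.make_atlas(6, 2, 2, voxels_per_region=4)


@pytest.fixture()
def app_config(tiny_atlas):
    """Small application study with one planted mediating region."""
    cfg = cb.SimulationConfig(
        n_train=100,
        n_app=160,
        noise_sd=10.0,
        affected_regions=("sub001",),
        delta_years=6.0,
        seed=11,
    )
    cfg.outcomes["mmse"].b_per_region = {"sub001": -0.3}
    cfg.outcomes["mmse"].direct_effect = -1.5
    return cfg


def random_subjects(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """A covariate-complete subject table with no planted structure."""
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "age": rng.uniform(50, 90, n),
            "sex": rng.integers(0, 2, n),
            "education_years": rng.uniform(0, 16, n),
            "efc": rng.normal(0.545, 0.02, n),
            "tiv_l": rng.normal(1.31, 0.12, n),
            "hypertension": rng.integers(0, 2, n),
            "diabetes": rng.integers(0, 2, n),
            "dyslipidemia": rng.integers(0, 2, n),
            "smoking": rng.integers(0, 2, n),
        }
    )


@pytest.fixture()
def subjects_60():
    return random_subjects(np.random.default_rng(7), 60)
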