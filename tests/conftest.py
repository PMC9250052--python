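import numpy as np
import pandas as pd
import pytest

from pmtl.simulate import SyntheticConfig, generate_cohort, feature_columns


@pytest.fixture(scope="session")
def small_cohort():
    """A modest heterogeneous cohort shared by read-only tests."""
    cfg = SyntheticConfig(
        n=3000, d=12, n_subgroups=3, n_informative=4, tau=1.0,
        beta_density=0.5, beta_scale=0.5, seed=7,
    )
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def small_xy(small_cohort):
    _, cohort, _ = small_cohort
    X = cohort[feature_columns(cohort)]
    y = cohort["y"].to_numpy()
    return X, y


@pytest.fixture
def rng():
    return np.random.default_rng(0)
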