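import numpy as np
import pytest

from fewlevels import ScenarioConfig, child_rng, gen_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20220120)


@pytest.fixture
def default_config():
    return ScenarioConfig(n_obs=120, n_levels=10)


@pytest.fixture
def dataset(default_config):
    """One seeded dataset from the largest scenario cell."""
    return gen_dataset(default_config, child_rng(7, 120, 10, 0))


@pytest.fixture
def small_dataset():
    """One seeded dataset from the smallest scenario cell."""
    cfg = ScenarioConfig(n_obs=30, n_levels=3)
    return gen_dataset(cfg, child_rng(7, 30, 3, 0))
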