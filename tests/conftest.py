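import numpy as np
import pandas as pd
import pytest

from mchequity import PopulationConfig, generate_population

#: covariate effects switched off: wealth is then the only channel into the
#: outcomes, which makes gradient/CI relations exact
NO_EFFECTS = {"anc": {}, "pnc": {}, "delivery": {}}


@pytest.fixture(scope="session")
def base_config() -> PopulationConfig:
    return PopulationConfig(seed=42, wealth_gradient_anc=0.4,
                            wealth_gradient_pnc=0.3,
                            wealth_gradient_delivery=0.8)


@pytest.fixture(scope="session")
def population(base_config) -> pd.DataFrame:
    return generate_population(base_config)


@pytest.fixture(scope="session")
def null_population() -> pd.DataFrame:
    """A large population with no wealth channel into any outcome."""
    cfg = PopulationConfig(seed=5, n_clusters=909, covariate_effects=NO_EFFECTS)
    return generate_population(cfg)


def random_weighted_dataset(rng: np.random.Generator, max_n: int = 500):
    """A random non-degenerate (h, wealth, weights) triple for property tests."""
    n = int(rng.integers(5, max_n + 1))
    h = rng.gamma(2.0, 1.0, size=n) + 0.01
    wealth = rng.normal(size=n)
    weights = rng.uniform(0.2, 3.0, size=n)
    return h, wealth, weights
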