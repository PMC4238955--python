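import numpy as np
import pandas as pd
import pytest

from bindqtl.synthio import SimConfig, simulate_binding_counts, simulate_genotypes


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_samples=51, n_regions=200, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_config):
    genotypes = simulate_genotypes(small_config)
    counts, truth = simulate_binding_counts(genotypes, small_config)
    return genotypes, counts, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
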