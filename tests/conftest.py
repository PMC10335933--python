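import numpy as np
import pandas as pd
import pytest

from panpav.synthdata import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_snp=500, n_pav=400, n_family=800,
                     n_selected_pav=40, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_presence() -> pd.DataFrame:
    """5 accessions x 6 families with known occupancy counts."""
    mat = np.array([
        [1, 1, 1, 1, 1],   # core
        [1, 1, 1, 1, 0],   # N-1
        [1, 1, 1, 0, 0],
        [1, 1, 0, 0, 0],
        [1, 0, 0, 0, 0],   # private
        [0, 1, 1, 0, 1],
    ], dtype=bool)
    return pd.DataFrame(mat, index=[f"f{i}" for i in range(6)],
                        columns=[f"a{i}" for i in range(5)])
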