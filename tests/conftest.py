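import numpy as np
import pandas as pd
import pytest

from sensopt import SensorGrid, SimulationConfig, generate


@pytest.fixture(scope="session")
def small_grid() -> SensorGrid:
    """2 x 3 grid: six nodes A1..B3."""
    return SensorGrid(columns=("A", "B"), rows=(1, 2, 3))


@pytest.fixture(scope="session")
def small_matrix(small_grid) -> pd.DataFrame:
    """Three synthetic days at 10-minute sampling, no missing entries."""
    cfg = SimulationConfig(
        n_days=3, sampling_interval=10, missing_fraction=0.0, rng_seed=11
    )
    return generate(small_grid, cfg)


@pytest.fixture(scope="session")
def small_matrix_missing(small_grid) -> pd.DataFrame:
    """Three synthetic days with ~1% missing entries."""
    cfg = SimulationConfig(
        n_days=3, sampling_interval=10, missing_fraction=0.01, rng_seed=12
    )
    return generate(small_grid, cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
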