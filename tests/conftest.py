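import numpy as np
import pytest

from agemetrics import SimConfig


@pytest.fixture
def small_config():
    return SimConfig(n_locations=3, years=[1990, 2019], seed=7)


@pytest.fixture
def default_config():
    return SimConfig(seed=11)


@pytest.fixture
def age_grid():
    """5-year abridged grid 0, 5, ..., 95 (last interval open)."""
    return np.arange(0.0, 100.0, 5.0)


@pytest.fixture
def gompertz_mx(age_grid):
    return 1e-4 * np.exp(0.08 * age_grid)
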