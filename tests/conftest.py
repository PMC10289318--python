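import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from arealepi.synthetic import SyntheticConfig, generate_dataset, regular_grid
from arealepi.weights import queen_weights


@pytest.fixture(scope="session")
def grid33():
    """3x3 square grid with binary queen weights."""
    areas = regular_grid(3, 3)
    return areas, queen_weights(areas, mode="binary")


@pytest.fixture(scope="session")
def small_dataset():
    """Compact synthetic study region shared across read-only tests."""
    return generate_dataset(SyntheticConfig(n_units=60, seed=42, spatial_rho=0.6))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
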