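import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from migsirs import ModelParams, baseline


@pytest.fixture
def default_params() -> ModelParams:
    return baseline().params


@pytest.fixture
def uniform_state() -> np.ndarray:
    return np.full(10, 100.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250214)


@pytest.fixture
def random_states(rng) -> np.ndarray:
    """100 random non-negative states spanning several orders of magnitude."""
    return rng.uniform(0.0, 1.0, size=(100, 10)) * rng.choice(
        [1.0, 10.0, 1000.0], size=(100, 1)
    )
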