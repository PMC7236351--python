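import numpy as np
import pytest

from transposim.model_core import ParameterSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A tiny, fast all-Low-style condition for unit tests."""
    return ParameterSet(
        carrying_capacity=10,
        nc_bp=100_000,
        initial_genes=20,
        max_cycles=50,
        seed=7,
    )
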