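import numpy as np
import pytest

from tadnmf.simulator import SimulationParams, simulate


@pytest.fixture
def small_sim():
    """A compact planted-block matrix plus truth labels (3 blocks of 20)."""
    return simulate(
        SimulationParams(n_bins=60, block_lengths=[20, 20, 20], seed=11)
    )


@pytest.fixture
def default_sim():
    """A matrix at the generator's default study conditions (6 blocks of 40)."""
    return simulate(SimulationParams(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
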