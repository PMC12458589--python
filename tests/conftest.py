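import numpy as np
import pytest

from bgthsim import SimConfig, run_cosim, synth_connectome


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def connectome4():
    """The shipped default connectome: complete 4-node graph, seed 7."""
    return synth_connectome(4, 1.0, seed=7)


@pytest.fixture(scope="session")
def short_result(connectome4):
    """A short deterministic co-simulation shared across read-only tests."""
    return run_cosim(SimConfig(duration=100.0), connectome4)
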