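import numpy as np
import pytest

from yeastdol import SimulationConfig, run


@pytest.fixture
def cfg():
    return SimulationConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_trajectory():
    """One full default run (750 steps, seed 1), shared across tests."""
    return run(SimulationConfig(seed=1))


class QueuedRNG:
    """Stands in for a Generator when a test needs to dictate the draws."""

    def __init__(self, uniforms=(), integers=()):
        self._uniforms = list(uniforms)
        self._integers = list(integers)

    def random(self):
        return self._uniforms.pop(0)

    def integers(self, n):
        return self._integers.pop(0) % n


@pytest.fixture
def queued_rng():
    return QueuedRNG
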