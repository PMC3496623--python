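import numpy as np
import pytest

import gifnet as gn


@pytest.fixture(scope="session")
def example():
    """Documented two-neuron reference network (exponential kernels)."""
    return gn.example_parameters()


@pytest.fixture(scope="session")
def example_d1():
    """Same network with degree-1 (delayed-peak) kernels."""
    return gn.example_parameters(profile_degree=1)


@pytest.fixture(scope="session")
def example_bounds(example):
    return gn.derive_bounds(example)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_history():
    """Seeded 40-step random history for the reference network."""
    return gn.fixture("random", 2, 40, t0=0, seed=3)


def decoupled(params):
    """Copy of ``params`` with all synapses removed (pure leaky dynamics)."""
    import copy

    p = copy.deepcopy(params)
    p.G = np.zeros((p.N, p.N))
    return p
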