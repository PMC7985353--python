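import numpy as np
import pytest

from tseqnet import fixtures as fx


@pytest.fixture
def chain_fixture():
    return fx.make_chain(3, delays=[2, 3])


@pytest.fixture
def diamond_fixture():
    return fx.make_diamond()


@pytest.fixture
def cycle_fixture():
    # window long enough for three laps to reach the tap
    return fx.make_cycle_with_tap(delay=3, refractory=2, n_steps=20)


@pytest.fixture
def random_fixture():
    return fx.make_random_geometric(n=20, p=0.12, seed=11, n_steps=50)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
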