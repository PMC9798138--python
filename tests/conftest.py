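import numpy as np
import pytest

from phosphonet import simnet as sn
from phosphonet import synthetic_phospho as sp


@pytest.fixture(scope="session")
def raf():
    return sn.load_raf_network()


@pytest.fixture(scope="session")
def small_world():
    """A small synthetic phospho world shared across read-only tests."""
    return sp.generate_world(n_kinases=4, n_substrates_per_kinase=6, n_background=8, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
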