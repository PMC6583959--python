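import numpy as np
import pytest

from porecosm import network as netmod


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def chain100():
    # 2 mm chain of 100 nodes, as in the dispersal comparison setup
    return netmod.build_chain(100, 2000e-6 / 99)


@pytest.fixture(scope="session")
def square3():
    return netmod.build_lattice("square", 3, 3, 1e-4)


@pytest.fixture(scope="session")
def hex_lattice():
    return netmod.build_lattice("hexagonal", 12, 12, 1e-4)


@pytest.fixture(scope="session")
def disc2mm():
    return netmod.build_aggregate_domain(2e-3, "hexagonal", 1e-4)
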