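import numpy as np
import pytest

from walklink import Network, generate_er


@pytest.fixture
def p3():
    """Path graph 0-1-2."""
    return Network(3, [(0, 1), (1, 2)])


@pytest.fixture
def k3():
    """Triangle (complete graph on 3 nodes)."""
    return Network(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def star4():
    """Star with center 0 and three leaves."""
    return Network(4, [(0, 1), (0, 2), (0, 3)])


@pytest.fixture
def c4():
    """4-cycle (bipartite)."""
    return Network(4, [(0, 1), (1, 2), (2, 3), (3, 0)])


@pytest.fixture
def single_edge():
    return Network(2, [(0, 1)])


@pytest.fixture
def er30():
    """Small random graph used for sampler-vs-oracle checks.

    Sparse (k_av = 2) so that at 10^5 draws the expected total-variation
    distance of a correct sampler (~0.013-0.016 over this support) sits
    well below the 0.02 equivalence bound.
    """
    return generate_er(30, 2.0, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
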