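import numpy as np
import pytest

from pollinet.netgen import BipartiteNetwork, GenTarget, generate_network


@pytest.fixture
def tiny_net():
    """3 plants x 3 animals: one generalist, one intermediate, one specialist."""
    M = np.array(
        [
            [1, 1, 1],
            [1, 1, 0],
            [1, 0, 0],
        ]
    )
    return BipartiteNetwork.from_matrix(M)


@pytest.fixture
def pair_net():
    """Minimal 2x2 fully connected network."""
    return BipartiteNetwork.from_matrix(np.ones((2, 2), dtype=int))


@pytest.fixture(scope="session")
def ec_ensemble():
    """20 nested S=90 / C=0.15 networks (reduced empirically connected arm)."""
    rng = np.random.default_rng(20240901)
    return [generate_network(GenTarget(90, 0.15, True), rng=rng) for _ in range(20)]


@pytest.fixture(scope="session")
def nonnested_ensemble():
    """20 non-nested S=90 / C=0.15 networks."""
    rng = np.random.default_rng(20240902)
    return [generate_network(GenTarget(90, 0.15, False), rng=rng) for _ in range(20)]
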