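import numpy as np
import pytest

from fcdec import RunConfig, default_atlas
from fcdec.fc_network import BinaryNetwork


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture(scope="session")
def config():
    return RunConfig()


def random_network(n: int, p_edge: float, rng: np.random.Generator, subject_id: str = "s") -> BinaryNetwork:
    """Erdos-Renyi-style random binary network (at least one edge guaranteed)."""
    while True:
        a = (rng.random((n, n)) < p_edge).astype(np.uint8)
        a = np.triu(a, k=1)
        a = a + a.T
        if a.sum() >= 4:  # at least two edges
            return BinaryNetwork(adjacency=a, sparsity=p_edge, subject_id=subject_id)


@pytest.fixture(scope="session")
def small_random_networks():
    """50 random graphs with N <= 12 for oracle comparisons."""
    rng = np.random.default_rng(20240507)
    nets = []
    for i in range(50):
        n = int(rng.integers(4, 13))
        p = float(rng.uniform(0.2, 0.7))
        nets.append(random_network(n, p, rng, subject_id=f"g{i}"))
    return nets
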