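import numpy as np
import pytest

from braingraph import BinaryNetwork, CohortSpec


def net_from_adj(adj) -> BinaryNetwork:
    return BinaryNetwork.from_adjacency(np.asarray(adj, dtype=bool))


def complete_graph(n: int) -> BinaryNetwork:
    return BinaryNetwork(n, frozenset((i, j) for i in range(n) for j in range(i + 1, n)))


def path_graph(n: int) -> BinaryNetwork:
    return BinaryNetwork(n, frozenset((k, k + 1) for k in range(n - 1)))


def star_graph(n_leaves: int) -> BinaryNetwork:
    return BinaryNetwork(n_leaves + 1, frozenset((0, k) for k in range(1, n_leaves + 1)))


def ring_lattice(n: int, k: int) -> BinaryNetwork:
    """Ring of n nodes, each joined to its k nearest neighbours (k even)."""
    edges = set()
    for v in range(n):
        for step in range(1, k // 2 + 1):
            u = (v + step) % n
            edges.add((min(v, u), max(v, u)))
    return BinaryNetwork(n, frozenset(edges))


@pytest.fixture(scope="session")
def tiny_spec():
    """Small, fast cohort spec used across I/O and pipeline tests."""
    return CohortSpec(n_per_group=3, n_rois=20, t_len=60,
                      module_sizes=(10, 10), r_within=0.6, r_between=0.1, seed=11)


@pytest.fixture(scope="session")
def toy_net():
    """Edges {AB, AC, BC, CD}: triangle with a pendant node."""
    return BinaryNetwork(4, frozenset({(0, 1), (0, 2), (1, 2), (2, 3)}))
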