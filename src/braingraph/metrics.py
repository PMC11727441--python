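"""Global and nodal topological metrics on binary undirected networks.

All metrics follow the standard unweighted-graph definitions:

* clustering coefficient ``NCp(v) = 2 * t(v) / (deg(v) * (deg(v) - 1))``
  where ``t(v)`` counts edges among the neighbours of v, with ``NCp = 0``
  for degree < 2; the network value Cp is the mean over all nodes,
* characteristic path length Lp = mean shortest-path distance over reachable
  ordered pairs (unreachable pairs are excluded and counted, not penalized),
* global efficiency Eglob = mean of 1/d over pairs with 1/inf = 0,
* local efficiency Nle(v) = global efficiency of the subgraph induced by the
  neighbours of v (v itself removed), Eloc = mean Nle,
* betweenness centrality = unnormalized Brandes counts over unordered pairs,
* degree centrality = plain degree.

Distances are computed by level-synchronous BFS expressed as boolean matrix
products, which is exact for unweighted graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .connectome import BinaryNetwork

logger = logging.getLogger(__name__)

try:  # compiled BFS kernels; the numpy path below is the reference fallback
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(f):
            return f
        return wrap


@_njit(cache=False)
def _bfs_all_pairs(adj):
    """All-pairs BFS distances on a dense uint8 adjacency matrix."""
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    queue = np.empty(n, np.int64)
    for s in range(n):
        d[s, s] = 0.0
        head, tail = 0, 1
        queue[0] = s
        while head < tail:
            u = queue[head]
            head += 1
            du = d[s, u]
            for v in range(n):
                if adj[u, v] != 0 and d[s, v] == np.inf:
                    d[s, v] = du + 1.0
                    queue[tail] = v
                    tail += 1
    return d


@_njit(cache=False)
def _nle_kernel(adj):
    """Local efficiency per node: Eglob of each neighbour-induced subgraph."""
    n = adj.shape[0]
    nle = np.zeros(n)
    for u in range(n):
        k = 0
        for v in range(n):
            if adj[u, v] != 0:
                k += 1
        if k < 2:
            continue
        nb = np.empty(k, np.int64)
        t = 0
        for v in range(n):
            if adj[u, v] != 0:
                nb[t] = v
                t += 1
        sub = np.zeros((k, k), np.uint8)
        for i in range(k):
            for j in range(k):
                sub[i, j] = adj[nb[i], nb[j]]
        dsub = _bfs_all_pairs(sub)
        acc = 0.0
        for i in range(k):
            for j in range(k):
                if i != j and dsub[i, j] != np.inf:
                    acc += 1.0 / dsub[i, j]
        nle[u] = acc / (k * (k - 1))
    return nle


@dataclass(frozen=True)
class GlobalMetrics:
    cp: float
    lp: float
    eglob: float
    eloc: float
    unreachable_pairs: int = 0

    def as_dict(self) -> dict[str, float]:
        return {"Cp": self.cp, "Lp": self.lp, "Eglob": self.eglob, "Eloc": self.eloc}


@dataclass(frozen=True)
class NodalMetrics:
    """Per-node metric arrays (length N; NaN marks undefined values)."""

    bc: np.ndarray
    dc: np.ndarray
    ncp: np.ndarray
    nlp: np.ndarray
    ne: np.ndarray
    nle: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"BC": self.bc, "DC": self.dc, "NCp": self.ncp,
                "NLp": self.nlp, "Ne": self.ne, "Nle": self.nle}


def _adjacency(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net, BinaryNetwork):
        return net.adjacency()
    a = np.asarray(net, dtype=bool)
    return a


def distance_matrix(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path distances (np.inf if unreachable)."""
    a = _adjacency(net)
    if _HAVE_NUMBA:
        return _bfs_all_pairs(a.astype(np.uint8))
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    if not a.any():
        return d
    d[a] = 1.0
    reached = a | np.eye(n, dtype=bool)
    frontier = a
    dist = 1
    au8 = a.astype(np.uint8)
    while True:
        nxt = (frontier.astype(np.uint8) @ au8) > 0
        new = nxt & ~reached
        if not new.any():
            break
        dist += 1
        d[new] = dist
        reached |= new
        frontier = new
    return d


def degree_centrality(net: BinaryNetwork) -> np.ndarray:
    """Degree of every node."""
    return _adjacency(net).sum(axis=0).astype(float)


def nodal_clustering(net: BinaryNetwork, v: int | None = None):
    """Clustering coefficient per node (or for a single node ``v``)."""
    a = _adjacency(net)
    au8 = a.astype(np.uint8)
    deg = au8.sum(axis=0).astype(float)
    # diag(A^3) counts closed 2-walks back to each node = 2 * triangles
    tri2 = np.einsum("ij,jk,ki->i", au8, au8, au8).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ncp = np.where(deg >= 2, tri2 / (deg * (deg - 1.0)), 0.0)
    return float(ncp[v]) if v is not None else ncp


def clustering_coefficient(net: BinaryNetwork) -> float:
    """Network clustering coefficient Cp = mean nodal clustering."""
    return float(np.mean(nodal_clustering(net)))


def path_length_stats(net: BinaryNetwork | np.ndarray) -> tuple[float, np.ndarray, int]:
    """(Lp, per-node NLp, number of unreachable ordered pairs).

    Lp averages finite off-diagonal distances over ordered pairs; NLp(v)
    averages finite distances from v (NaN for isolated nodes).
    """
    d = distance_matrix(net)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_unreach = int((off & ~np.isfinite(d)).sum())
    if not finite.any():
        raise ValueError("no reachable pair: characteristic path length undefined")
    lp = float(d[finite].sum() / finite.sum())
    row_counts = finite.sum(axis=1)
    with np.errstate(invalid="ignore"):
        nlp = np.where(row_counts > 0,
                       np.where(finite, d, 0.0).sum(axis=1) / np.maximum(row_counts, 1),
                       np.nan)
    if n_unreach:
        logger.debug("Lp excluded %d unreachable ordered pairs", n_unreach)
    return lp, nlp, n_unreach


def characteristic_path_length(net: BinaryNetwork) -> float:
    return path_length_stats(net)[0]


def nodal_path_length(net: BinaryNetwork, v: int | None = None):
    nlp = path_length_stats(net)[1]
    return float(nlp[v]) if v is not None else nlp


def _efficiency_from_distances(d: np.ndarray) -> tuple[float, np.ndarray]:
    n = d.shape[0]
    if n < 2:
        return 0.0, np.zeros(n)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    ne = inv.sum(axis=1) / (n - 1)
    eglob = float(inv.sum() / (n * (n - 1)))
    return eglob, ne


def global_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """Mean inverse shortest-path distance over node pairs (1/inf = 0)."""
    return _efficiency_from_distances(distance_matrix(net))[0]


def nodal_efficiency(net: BinaryNetwork, v: int | None = None):
    ne = _efficiency_from_distances(distance_matrix(net))[1]
    return float(ne[v]) if v is not None else ne


def nodal_local_efficiency(net: BinaryNetwork, v: int | None = None):
    """Per-node local efficiency: Eglob of the neighbour-induced subgraph."""
    a = _adjacency(net)
    if _HAVE_NUMBA:
        nle = _nle_kernel(a.astype(np.uint8))
        return float(nle[v]) if v is not None else nle
    n = a.shape[0]
    nle = np.zeros(n)
    deg = a.sum(axis=0)
    for u in range(n):
        if deg[u] < 2:
            continue
        nb = np.nonzero(a[u])[0]
        sub = a[np.ix_(nb, nb)]
        nle[u] = _efficiency_from_distances(distance_matrix(sub))[0]
    return float(nle[v]) if v is not None else nle


def local_efficiency(net: BinaryNetwork) -> float:
    """Network local efficiency Eloc = mean nodal local efficiency."""
    return float(np.mean(nodal_local_efficiency(net)))


def betweenness(net: BinaryNetwork) -> np.ndarray:
    """Unnormalized betweenness centrality (Brandes), unordered pairs."""
    import networkx as nx

    g = net.to_networkx()
    bc = nx.betweenness_centrality(g, normalized=False)
    return np.array([bc[v] for v in range(net.n_nodes)])


def global_metrics(net: BinaryNetwork) -> GlobalMetrics:
    """Cp, Lp, Eglob and Eloc of one binarized network."""
    a = net.adjacency()
    d = distance_matrix(a)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise ValueError("no reachable pair: characteristic path length undefined")
    lp = float(d[finite].sum() / finite.sum())
    eglob, _ = _efficiency_from_distances(d)
    cp = float(np.mean(nodal_clustering(net)))
    eloc = float(np.mean(nodal_local_efficiency(net)))
    return GlobalMetrics(cp=cp, lp=lp, eglob=eglob, eloc=eloc,
                         unreachable_pairs=int((off & ~finite).sum()))


def nodal_metrics(net: BinaryNetwork) -> NodalMetrics:
    """All six per-node metrics of one binarized network."""
    _, nlp, _ = path_length_stats(net)
    _, ne = _efficiency_from_distances(distance_matrix(net))
    return NodalMetrics(
        bc=betweenness(net),
        dc=degree_centrality(net),
        ncp=nodal_clustering(net),
        nlp=nlp,
        ne=ne,
        nle=nodal_local_efficiency(net),
    )
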