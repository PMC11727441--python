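"""Connectivity matrices, sparsity thresholding and the small-world regime.

ROI time series are turned into Pearson correlation matrices; each matrix is
binarized at a *sparsity* level S (the fraction of realized edges out of all
N(N-1)/2 possible node pairs) so that every subject's network has exactly the
same number of nodes and edges before topology is compared.  The analysis
regime is the contiguous run of sparsity levels on which every subject's
network keeps a mean degree above ``2*log(N)`` and a small-world coefficient
sigma above 1.1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

#: Default sparsity grid: 0.05 to 0.18 in steps of 0.01 (14 levels).
DEFAULT_GRID = tuple(round(0.05 + 0.01 * k, 2) for k in range(14))

#: Conventional small-world cutoff on sigma.
SIGMA_MIN = 1.1


class ConstantSeriesError(ValueError):
    """An ROI time series has zero variance, so its correlations are undefined."""


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric N x N matrix of pairwise Pearson correlations.

    The diagonal is stored as 1 but is never a candidate edge.
    """

    values: np.ndarray
    roi_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if len(self.roi_names) != v.shape[0]:
            raise ValueError("roi_names length must match matrix size")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        object.__setattr__(self, "values", v)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class BinaryNetwork:
    """Undirected, unweighted graph produced by sparsity thresholding."""

    n_nodes: int
    edges: frozenset[tuple[int, int]]
    sparsity: float = float("nan")

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on node {i}")
            if not (0 <= i < j < self.n_nodes):
                raise ValueError(f"edge ({i}, {j}) not in canonical order/range")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes

    def adjacency(self) -> np.ndarray:
        """Dense boolean adjacency matrix."""
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        if self.edges:
            idx = np.array(sorted(self.edges))
            a[idx[:, 0], idx[:, 1]] = True
            a[idx[:, 1], idx[:, 0]] = True
        return a

    @classmethod
    def from_adjacency(cls, a: np.ndarray, sparsity: float = float("nan")) -> "BinaryNetwork":
        a = np.asarray(a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        iu, ju = np.nonzero(np.triu(a, k=1))
        return cls(a.shape[0], frozenset(zip(iu.tolist(), ju.tolist())), sparsity)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class SparsityRegime:
    """Contiguous run of sparsity levels passing the two small-world conditions."""

    s_min: float
    s_max: float
    grid: tuple[float, ...]
    degree_floor: float
    diagnostics: dict = field(default_factory=dict, compare=False)


def pearson_matrix(timeseries: np.ndarray, roi_names: Sequence[str] | None = None) -> ConnectivityMatrix:
    """Pearson correlation matrix of a T x N ROI time-series array.

    Parameters
    ----------
    timeseries
        T x N array; rows are time points, columns are ROIs.
    roi_names
        Optional column labels; defaults to ``ROI001 ...``.

    Raises
    ------
    ConstantSeriesError
        If any column is constant (names the offending ROI).
    ValueError
        If fewer than 3 time points are supplied.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be a 2-D T x N array")
    t_len, n = ts.shape
    if t_len < 3:
        raise ValueError(f"need at least 3 time points, got {t_len}")
    if roi_names is None:
        roi_names = tuple(f"ROI{k + 1:03d}" for k in range(n))
    roi_names = tuple(roi_names)
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        bad = [roi_names[k] for k in np.nonzero(sd == 0)[0]]
        raise ConstantSeriesError(f"constant time series for ROI(s): {', '.join(bad)}")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, roi_names)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def rank_edges(m: ConnectivityMatrix, mode: str = "absolute") -> list[tuple[int, int]]:
    """All node pairs ordered by edge strength, strongest first.

    ``mode="absolute"`` ranks by \\|r\\| (the default: both strongly positive and
    strongly negative correlations count as connections), ``mode="positive"``
    ranks by signed r.  Ties are broken by lexicographic node-pair order so
    thresholding is bit-reproducible; the resulting edge sets are nested
    across sparsity levels by construction.
    """
    if mode not in ("absolute", "positive"):
        raise ValueError(f"unknown edge-ranking mode: {mode!r}")
    n = m.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    r = m.values[iu, ju]
    strength = np.abs(r) if mode == "absolute" else r
    # lexsort: last key is primary -> sort by -strength, then i, then j
    order = np.lexsort((ju, iu, -strength))
    return list(zip(iu[order].tolist(), ju[order].tolist()))


def binarize_at_sparsity(
    m: ConnectivityMatrix,
    s: float,
    mode: str = "absolute",
    ranked: Sequence[tuple[int, int]] | None = None,
) -> BinaryNetwork:
    """Keep the top ``round(s * N(N-1)/2)`` strongest pairs as edges.

    ``ranked`` may carry a precomputed :func:`rank_edges` result so that a
    whole sparsity grid can reuse one ranking.
    """
    if not 0.0 < s < 1.0:
        raise ValueError(f"sparsity must be in (0, 1), got {s}")
    n = m.n_nodes
    m_pairs = n * (n - 1) // 2
    k = _round_half_away(s * m_pairs)
    if k == 0:
        raise ValueError(f"sparsity {s} keeps zero edges on {n} nodes (degenerate network)")
    if ranked is None:
        ranked = rank_edges(m, mode=mode)
    return BinaryNetwork(n, frozenset(ranked[:k]), sparsity=s)


def largest_component_size(net: BinaryNetwork) -> int:
    """Number of nodes in the largest connected component."""
    if not net.edges:
        return 1 if net.n_nodes else 0
    a = csr_matrix(net.adjacency().astype(np.int8))
    n_comp, labels = connected_components(a, directed=False)
    return int(np.bincount(labels).max())


def degree_floor(n_nodes: int, log_base: float = math.e) -> float:
    """The mean-degree threshold ``2 * log(N)`` (natural log by default)."""
    return 2.0 * math.log(n_nodes) / math.log(log_base)


def determine_regime(
    cohort: Iterable[ConnectivityMatrix],
    candidate_grid: Sequence[float] = DEFAULT_GRID,
    null_cfg=None,
    *,
    mode: str = "absolute",
    log_base: float = math.e,
    sigma_min: float = SIGMA_MIN,
) -> SparsityRegime:
    """Find the maximal contiguous sparsity run satisfying both conditions.

    Condition (1): mean degree of every subject's network exceeds
    ``2*log(N)``.  Condition (2): every subject's small-world coefficient
    sigma exceeds ``sigma_min``.  If several runs tie in length the
    lowest-sparsity run is returned.  Per-subject failures outside the regime
    are collected in ``SparsityRegime.diagnostics``.
    """
    from .null_models import NullConfig, small_world

    grid = [round(float(s), 10) for s in candidate_grid]
    if len(grid) < 1 or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("candidate grid must be strictly ascending")
    steps = np.diff(grid)
    if len(steps) and not np.allclose(steps, steps[0], atol=1e-9):
        raise ValueError("candidate grid must have constant step")
    if null_cfg is None:
        null_cfg = NullConfig()

    matrices = list(cohort)
    if not matrices:
        raise ValueError("empty cohort")
    n = matrices[0].n_nodes
    floor = degree_floor(n, log_base=log_base)

    ok = np.ones(len(grid), dtype=bool)
    failures: dict[float, list[str]] = {s: [] for s in grid}
    rankings = [rank_edges(m, mode=mode) for m in matrices]
    for si, s in enumerate(grid):
        for subj, (m, ranked) in enumerate(zip(matrices, rankings)):
            net = binarize_at_sparsity(m, s, mode=mode, ranked=ranked)
            if net.mean_degree <= floor:
                ok[si] = False
                failures[s].append(f"subject {subj}: mean degree {net.mean_degree:.3f} <= {floor:.3f}")
                continue
            sw = small_world(net, null_cfg)
            if not sw.sigma > sigma_min:
                ok[si] = False
                failures[s].append(f"subject {subj}: sigma {sw.sigma:.3f} <= {sigma_min}")

    best_start, best_len = None, 0
    run_start = None
    for si in range(len(grid) + 1):
        if si < len(grid) and ok[si]:
            if run_start is None:
                run_start = si
        else:
            if run_start is not None:
                run_len = si - run_start
                if run_len > best_len:
                    best_start, best_len = run_start, run_len
                run_start = None
    if best_start is None:
        lines = [msg for s in grid for msg in failures[s]]
        raise ValueError("no sparsity level satisfies both conditions:\n" + "\n".join(lines[:40]))

    sub = grid[best_start : best_start + best_len]
    diag = {s: msgs for s, msgs in failures.items() if msgs}
    if diag:
        logger.info("regime excludes %d grid points; see diagnostics", len(diag))
    return SparsityRegime(sub[0], sub[-1], tuple(sub), floor, diagnostics=diag)
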