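"""Degree-preserving null networks and small-world normalization.

Small-worldness is judged against an ensemble of random reference graphs
that keep every node's degree but are otherwise scrambled (repeated
double-edge swaps, the Maslov–Sneppen procedure).  The normalized
quantities are

* gamma  = Cp(net)  / mean Cp over the null ensemble,
* lambda = Lp(net)  / mean Lp over the null ensemble,
* sigma  = gamma / lambda,

with sigma > 1.1 the conventional small-world criterion: a small-world
network is much more clustered than random (gamma > 1) while keeping
near-random path lengths (lambda close to 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .connectome import BinaryNetwork
from .metrics import clustering_coefficient, path_length_stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NullConfig:
    """Ensemble parameters for the rewired reference networks.

    ``n_rand`` random networks are generated, each by attempting
    ``swaps_per_edge * n_edges`` double-edge swaps.  Both values are
    recorded in pipeline output metadata.
    """

    n_rand: int = 100
    swaps_per_edge: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rand < 1:
            raise ValueError("n_rand must be >= 1")
        if self.swaps_per_edge < 1:
            raise ValueError("swaps_per_edge must be >= 1")


@dataclass(frozen=True)
class SmallWorldMetrics:
    gamma: float
    lam: float
    sigma: float
    null_cp_mean: float = float("nan")
    null_cp_sd: float = float("nan")
    null_lp_mean: float = float("nan")
    null_lp_sd: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {"Gamma": self.gamma, "Lambda": self.lam, "Sigma": self.sigma}


def _rewire_once(edges: np.ndarray, edge_set: set, n_attempts: int, rng: np.random.Generator) -> np.ndarray:
    """Attempt ``n_attempts`` double-edge swaps on an edge array in place."""
    m = len(edges)
    picks = rng.integers(0, m, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    for (ei, ej), flip in zip(picks, flips):
        if ei == ej:
            continue
        a, b = edges[ei]
        c, d = edges[ej]
        if flip:
            c, d = d, c
        # proposed: (a, c) and (b, d)
        if a == c or b == d:
            continue
        e1 = (a, c) if a < c else (c, a)
        e2 = (b, d) if b < d else (d, b)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard((min(a, b), max(a, b)))
        edge_set.discard((min(c, d), max(c, d)))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[ei] = e1
        edges[ej] = e2
    return edges


def rewire_preserving_degrees(net: BinaryNetwork, cfg: NullConfig) -> list[BinaryNetwork]:
    """Generate ``cfg.n_rand`` degree-matched random networks.

    Each null attempts ``cfg.swaps_per_edge * n_edges`` double-edge swaps;
    swaps that would create a self-loop or duplicate edge are rejected.
    Rigid graphs (no valid swap exists, e.g. complete graphs or stars) come
    back unchanged with a warning.
    """
    if net.n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    base = np.array(sorted(net.edges), dtype=np.int64)
    n_attempts = cfg.swaps_per_edge * net.n_edges
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    nulls = []
    any_moved = False
    for _ in range(cfg.n_rand):
        edges = base.copy()
        edge_set = set(map(tuple, edges))
        _rewire_once(edges, edge_set, n_attempts, rng)
        if edge_set != set(map(tuple, base)):
            any_moved = True
        nulls.append(BinaryNetwork(net.n_nodes, frozenset(edge_set), net.sparsity))
    if not any_moved:
        warnings.warn("no valid double-edge swap found; null networks equal the input",
                      stacklevel=2)
    return nulls


def small_world(net: BinaryNetwork, cfg: NullConfig | None = None) -> SmallWorldMetrics:
    """Gamma, lambda and sigma of a network against its rewired ensemble."""
    if cfg is None:
        cfg = NullConfig()
    cp = clustering_coefficient(net)
    lp = path_length_stats(net)[0]
    nulls = rewire_preserving_degrees(net, cfg)
    null_cp = np.array([clustering_coefficient(g) for g in nulls])
    null_lp = np.array([path_length_stats(g)[0] for g in nulls])
    mean_cp = float(null_cp.mean())
    mean_lp = float(null_lp.mean())
    if mean_cp == 0.0:
        raise ValueError("mean null clustering is zero: network too sparse to normalize")
    gamma = cp / mean_cp
    lam = lp / mean_lp
    return SmallWorldMetrics(
        gamma=gamma, lam=lam, sigma=gamma / lam,
        null_cp_mean=mean_cp, null_cp_sd=float(null_cp.std(ddof=1)) if len(null_cp) > 1 else 0.0,
        null_lp_mean=mean_lp, null_lp_sd=float(null_lp.std(ddof=1)) if len(null_lp) > 1 else 0.0,
    )
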