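"""Independent brute-force oracles used to check the graph-metric layer.

Everything here is written from first principles (pair enumeration,
Floyd-Warshall, exhaustive path counting) and deliberately avoids the
package's own code paths and networkx.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.full((n, n), math.inf)
    for i in range(n):
        d[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def clustering_by_triangles(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nb = [u for u in range(n) if adj[v, u]]
        k = len(nb)
        if k < 2:
            continue
        links = sum(1 for a, b in combinations(nb, 2) if adj[a, b])
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def char_path_length(adj: np.ndarray) -> float:
    d = floyd_warshall(adj)
    vals = [d[i, j] for i in range(len(d)) for j in range(len(d))
            if i != j and math.isfinite(d[i, j])]
    return sum(vals) / len(vals)


def nodal_path_length(adj: np.ndarray) -> np.ndarray:
    d = floyd_warshall(adj)
    n = len(d)
    out = np.full(n, np.nan)
    for v in range(n):
        vals = [d[v, u] for u in range(n) if u != v and math.isfinite(d[v, u])]
        if vals:
            out[v] = sum(vals) / len(vals)
    return out


def global_efficiency(adj: np.ndarray) -> float:
    d = floyd_warshall(adj)
    n = len(d)
    if n < 2:
        return 0.0
    total = sum(1.0 / d[i, j] for i in range(n) for j in range(n)
                if i != j and math.isfinite(d[i, j]))
    return total / (n * (n - 1))


def nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    d = floyd_warshall(adj)
    n = len(d)
    out = np.zeros(n)
    for v in range(n):
        out[v] = sum(1.0 / d[v, u] for u in range(n)
                     if u != v and math.isfinite(d[v, u])) / (n - 1)
    return out


def local_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nb = [u for u in range(n) if adj[v, u]]
        if len(nb) < 2:
            continue
        sub = adj[np.ix_(nb, nb)]
        out[v] = global_efficiency(sub)
    return out


def betweenness_by_path_enumeration(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness over unordered pairs via exhaustive DFS.

    All simple paths between s and t no longer than the shortest distance
    are enumerated (the depth bound makes this tractable on small graphs).
    """
    n = adj.shape[0]
    d = floyd_warshall(adj)
    bc = np.zeros(n)
    for s, t in combinations(range(n), 2):
        if not math.isfinite(d[s, t]) or d[s, t] == 0:
            continue
        target_len = int(d[s, t])
        paths: list[tuple[int, ...]] = []

        def dfs(node: int, visited: tuple[int, ...]) -> None:
            if len(visited) - 1 > target_len:
                return
            if node == t:
                if len(visited) - 1 == target_len:
                    paths.append(visited)
                return
            for u in range(n):
                if adj[node, u] and u not in visited:
                    dfs(u, visited + (u,))

        dfs(s, (s,))
        sigma = len(paths)
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / sigma
    return bc


def pearson_two_pass(x: np.ndarray, y: np.ndarray) -> float:
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).sum()
    return cov / math.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())


def union_find_largest_component(n: int, edges) -> int:
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    from collections import Counter

    return max(Counter(find(v) for v in range(n)).values()) if n else 0


def trapezoid_quadrature(x, y) -> float:
    total = 0.0
    for k in range(len(x) - 1):
        total += 0.5 * (y[k] + y[k + 1]) * (x[k + 1] - x[k])
    return total


def chi2_2x2(a, b, c, d) -> float:
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    adj = np.zeros((n, n), dtype=bool)
    for i, j in combinations(range(n), 2):
        if rng.random() < p:
            adj[i, j] = adj[j, i] = True
    return adj
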