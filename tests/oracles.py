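"""Independent brute-force oracles for graph metrics and BH-FDR.

Pure-Python enumeration, deliberately naive: these never share code with the
implementations they check.
"""

from itertools import combinations

import numpy as np


def bf_distances(adj: np.ndarray) -> np.ndarray:
    """Floyd-Warshall all-pairs shortest paths."""
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[adj > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def bf_clustering(adj: np.ndarray) -> tuple[np.ndarray, float]:
    n = adj.shape[0]
    c = np.zeros(n)
    for v in range(n):
        nbrs = [u for u in range(n) if adj[v, u]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if adj[a, b])
        c[v] = 2.0 * links / (k * (k - 1))
    return c, float(c.mean())


def bf_char_path_length(adj: np.ndarray) -> float:
    d = bf_distances(adj)
    n = d.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals))


def bf_global_efficiency(adj: np.ndarray) -> float:
    d = bf_distances(adj)
    n = d.shape[0]
    vals = [1.0 / d[i, j] if np.isfinite(d[i, j]) else 0.0 for i in range(n) for j in range(n) if i != j]
    return float(np.mean(vals))


def bf_local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    vals = []
    for v in range(n):
        nbrs = [u for u in range(n) if adj[v, u]]
        if len(nbrs) < 2:
            vals.append(0.0)
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        vals.append(bf_global_efficiency(sub))
    return float(np.mean(vals))


def bf_nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    d = bf_distances(adj)
    n = d.shape[0]
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(1.0 / d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])) / (n - 1)
    return out


def _count_shortest_paths(adj: np.ndarray, s: int, t: int, via=None) -> int:
    """Number of shortest s-t paths (optionally only those passing through `via`)."""
    n = adj.shape[0]
    d = bf_distances(adj)
    if not np.isfinite(d[s, t]):
        return 0
    # enumerate by DFS along distance-decreasing edges
    def walk(u, visited):
        if u == t:
            return 1
        total = 0
        for v in range(n):
            if adj[u, v] and d[u, t] == d[v, t] + 1:
                total += walk(v, visited + [v])
        return total

    if via is None:
        return walk(s, [s])

    def walk_via(u, seen_via):
        if u == t:
            return 1 if seen_via else 0
        total = 0
        for v in range(n):
            if adj[u, v] and d[u, t] == d[v, t] + 1:
                total += walk_via(v, seen_via or v == via)
        return total

    return walk_via(s, s == via)


def bf_betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness, undirected pairs counted once."""
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        for s, t in combinations([u for u in range(n) if u != v], 2):
            total = _count_shortest_paths(adj, s, t)
            if total == 0:
                continue
            through = _count_shortest_paths(adj, s, t, via=v)
            out[v] += through / total
    return out


def bf_fdr_bh(pvalues) -> np.ndarray:
    """Step-up BH by scanning all rank cutoffs."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = min(1.0, p[idx] * m / rank_from_top)
        running_min = min(running_min, val)
        adjusted[idx] = running_min
    return adjusted
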