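"""Brute-force reference implementations used only by the test suite.

Deliberately naive and independent of the package's code paths: BFS by
hand, shortest-path counting by adjacency-matrix powers, betweenness by
explicit enumeration of every shortest path, and greedy mRMR by exhaustive
re-evaluation of the set objective with an independent MI routine.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bfs_distances(adj: np.ndarray, source: int) -> np.ndarray:
    v = adj.shape[0]
    dist = np.full(v, np.inf)
    dist[source] = 0
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in range(v):
            if adj[u, w] and np.isinf(dist[w]):
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def oracle_path_length(adj: np.ndarray, unreachable_value: float | None = None) -> np.ndarray:
    """Mean BFS distance; unreachable pairs contribute V (or a given value)."""
    v = adj.shape[0]
    fill = float(v) if unreachable_value is None else unreachable_value
    out = np.empty(v)
    for i in range(v):
        d = bfs_distances(adj, i)
        d = np.where(np.isinf(d), fill, d)
        out[i] = (d.sum() - d[i]) / (v - 1)
    return out


def enumerate_shortest_paths(adj: np.ndarray, s: int, t: int) -> list[tuple[int, ...]]:
    """All shortest s-t paths by DFS along distance-decreasing edges."""
    dist_to_t = bfs_distances(adj, t)
    if np.isinf(dist_to_t[s]):
        return []
    paths = []

    def extend(node, path):
        if node == t:
            paths.append(tuple(path))
            return
        for nxt in range(adj.shape[0]):
            if adj[node, nxt] and dist_to_t[nxt] == dist_to_t[node] - 1:
                extend(nxt, path + [nxt])

    extend(s, [s])
    return paths


def oracle_betweenness(adj: np.ndarray) -> np.ndarray:
    """Betweenness by explicit enumeration: per unordered pair, the through-node fraction."""
    v = adj.shape[0]
    bc = np.zeros(v)
    for j in range(v):
        for m in range(j + 1, v):
            paths = enumerate_shortest_paths(adj, j, m)
            if not paths:
                continue
            for path in paths:
                for node in path[1:-1]:
                    bc[node] += 1.0 / len(paths)
    return bc


def oracle_shortest_path_counts(adj: np.ndarray) -> np.ndarray:
    """sigma_ij via matrix powers: walks of minimal length are exactly paths."""
    v = adj.shape[0]
    dist = np.full((v, v), np.inf)
    np.fill_diagonal(dist, 0)
    counts = np.zeros((v, v))
    power = np.eye(v)
    for length in range(1, v):
        power = power @ adj
        newly = (power > 0) & np.isinf(dist)
        dist[newly] = length
        counts[newly] = power[newly]
    return counts


def random_adjacency(rng: np.random.Generator, v: int, p_edge: float) -> np.ndarray:
    upper = rng.random((v, v)) < p_edge
    adj = np.triu(upper, k=1).astype(int)
    return adj + adj.T


# ---------------------------------------------------------------------------
# mRMR oracle


def oracle_mi_bits(a, b) -> float:
    """Plug-in MI from an explicitly built contingency table."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = a.size
    mi = 0.0
    for av in np.unique(a):
        pa = np.mean(a == av)
        for bv in np.unique(b):
            pj = np.sum((a == av) & (b == bv)) / n
            if pj > 0:
                mi += pj * np.log2(pj / (pa * np.mean(b == bv)))
    return mi


def oracle_mrmr_ranking(Xd: np.ndarray, y: np.ndarray, k: int) -> list[int]:
    """Greedy set-objective mRMR by exhaustive re-evaluation per candidate.

    Objective on S: mean I(x; y) over S minus (1/|S|^2) * sum of I(x_i; x_j)
    over ordered distinct pairs of S.
    """
    p = Xd.shape[1]
    chosen: list[int] = []
    while len(chosen) < k:
        best, best_j = -np.inf, None
        for j in range(p):
            if j in chosen:
                continue
            trial = chosen + [j]
            d_term = np.mean([oracle_mi_bits(Xd[:, f], y) for f in trial])
            r_term = 0.0
            for a in trial:
                for b in trial:
                    if a != b:
                        r_term += oracle_mi_bits(Xd[:, a], Xd[:, b])
            r_term /= len(trial) ** 2
            score = d_term - r_term
            if score > best:
                best, best_j = score, j
        chosen.append(best_j)
    return chosen
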