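"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (exhaustive enumeration, direct
formula evaluation) and shares no code with the package internals.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

_REL_TOL = 1e-12


def all_simple_paths(adj: np.ndarray, s: int, t: int):
    """Every simple path s -> t as a node list (adjacency > 0 = edge)."""
    n = adj.shape[0]
    out = []

    def extend(path, visited):
        u = path[-1]
        if u == t:
            out.append(list(path))
            return
        for v in range(n):
            if adj[u, v] > 0 and v not in visited:
                path.append(v)
                visited.add(v)
                extend(path, visited)
                visited.remove(v)
                path.pop()

    extend([s], {s})
    return out


def _path_length(adj: np.ndarray, path) -> float:
    return sum(1.0 / adj[a, b] for a, b in zip(path, path[1:]))


def oracle_pair_shortest(adj: np.ndarray, s: int, t: int):
    """(min length, list of minimal paths) on lengths 1/w; (inf, []) if none."""
    paths = all_simple_paths(adj, s, t)
    if not paths:
        return np.inf, []
    lengths = [_path_length(adj, p) for p in paths]
    d = min(lengths)
    tol = _REL_TOL * max(1.0, abs(d))
    minimal = [p for p, l in zip(paths, lengths) if l <= d + tol]
    return d, minimal


def oracle_betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness by exhaustive shortest-path enumeration."""
    n = adj.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            _, minimal = oracle_pair_shortest(adj, s, t)
            if not minimal:
                continue
            sigma = len(minimal)
            for path in minimal:
                for v in path[1:-1]:
                    bc[v] += 1.0 / sigma
    return bc


def oracle_global_efficiency(adj: np.ndarray) -> float:
    """Mean inverse exhaustively-enumerated shortest distance."""
    n = adj.shape[0]
    total = 0.0
    for s in range(n):
        for t in range(s + 1, n):
            d, _ = oracle_pair_shortest(adj, s, t)
            if np.isfinite(d):
                total += 2.0 / d  # both ordered directions
    return total / (n * (n - 1))


def oracle_modularity(adj: np.ndarray, labels: np.ndarray) -> float:
    """Q by direct double-sum over all ordered node pairs (incl. i == j)."""
    k = adj.sum(axis=1)
    two_m = adj.sum()
    q = 0.0
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += adj[i, j] - k[i] * k[j] / two_m
    return q / two_m


def set_partitions(n: int):
    """All set partitions of range(n) as label arrays (restricted growth)."""
    labels = np.zeros(n, dtype=int)

    def rec(i, max_label):
        if i == n:
            yield labels.copy()
            return
        for lab in range(max_label + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_label, lab))

    yield from rec(1, 0)


def oracle_best_partition(adj: np.ndarray) -> tuple[float, np.ndarray]:
    """Exhaustive modularity maximum over every set partition."""
    best_q = -np.inf
    best = None
    for labels in set_partitions(adj.shape[0]):
        q = oracle_modularity(adj, labels)
        if q > best_q:
            best_q = q
            best = labels
    return best_q, best


def oracle_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg by its definition: min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * m / (rank + 1))
        adj[idx] = min(running, 1.0)
    return adj


def random_graph(rng: np.random.Generator, n: int, density: float = 0.6
                 ) -> np.ndarray:
    """Random symmetric weighted adjacency with zero diagonal."""
    a = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.uniform() < density:
                w = rng.uniform(0.1, 1.0)
                a[i, j] = a[j, i] = w
    return a
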