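"""Weighted-graph metrics on thresholded connectivity matrices.

Implements the four measures used to contrast conditions — participation
coefficient, betweenness centrality, global efficiency and modularity —
plus adjacency preparation (absolute value then proportional thresholding,
weights preserved) and Newman's spectral community detection.

Conventions
-----------
* Path-based measures travel on edge lengths ``L_ij = 1 / A_ij`` (strong
  connections are short), the weighted-network convention of the standard
  brain-connectivity tooling.
* Betweenness sums ``sigma_st(v) / sigma_st`` over unordered pairs
  ``s < t`` and is left unnormalized, so values run from 0 upward.
* Isolated nodes: PC = 0, BC = 0; disconnected pairs contribute 0 to
  global efficiency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import igraph as ig
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "WeightedGraph",
    "CommunityPartition",
    "prepare_adjacency",
    "participation_coefficient",
    "betweenness_centrality",
    "global_efficiency",
    "modularity",
    "newman_communities",
]

#: minimum modularity gain for accepting a split or a refinement move
_Q_TOL = 1e-12


@dataclass(frozen=True)
class WeightedGraph:
    """Nonnegative symmetric weighted adjacency with zero diagonal."""

    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency must be square, got {a.shape}")
        if (a < 0).any():
            raise ValueError("adjacency must be nonnegative")
        if not np.allclose(a, a.T, atol=0, rtol=0):
            raise ValueError("adjacency must be exactly symmetric")
        if np.diagonal(a).any():
            raise ValueError("adjacency diagonal must be zero")
        object.__setattr__(self, "adjacency", a)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def strength(self) -> np.ndarray:
        """Node strength ``k_i = sum_j A_ij``."""
        return self.adjacency.sum(axis=1)

    @property
    def total_weight(self) -> float:
        """Half the adjacency sum, ``m``."""
        return float(self.adjacency.sum()) / 2.0

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))


@dataclass(frozen=True)
class CommunityPartition:
    """Node-to-community assignment as integer labels."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int64)
        if lab.ndim != 1:
            raise ValueError("labels must be a 1-d integer array")
        object.__setattr__(self, "labels", lab)

    @property
    def n_communities(self) -> int:
        return int(len(np.unique(self.labels)))


def prepare_adjacency(matrix: np.ndarray, cost: float) -> WeightedGraph:
    """Absolute value, then keep the strongest ``cost`` fraction of edges.

    Retains the ``ceil(cost * N*(N-1)/2)`` largest upper-triangle entries
    of ``|matrix|`` (weights preserved, not binarized) and zeroes the rest.
    Ties at the cutoff are broken by ``(i, j)`` lexicographic order so the
    result is deterministic.
    """
    if not 0.0 < cost <= 1.0:
        raise ValueError(f"cost must lie in (0, 1], got {cost}")
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix must be square, got {m.shape}")
    n = m.shape[0]
    w = np.abs(m)
    np.fill_diagonal(w, 0.0)
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    n_keep = ceil(cost * n * (n - 1) / 2)
    # primary key: descending weight; then ascending (i, j)
    order = np.lexsort((ju, iu, -vals))
    keep = order[:n_keep]
    out = np.zeros_like(w)
    out[iu[keep], ju[keep]] = vals[keep]
    out = out + out.T
    return WeightedGraph(out)


def participation_coefficient(
    graph: WeightedGraph, partition: CommunityPartition
) -> np.ndarray:
    """``PC_i = 1 - sum_s (k_is / k_i)^2`` against a community partition.

    ``k_is`` is node *i*'s strength into community *s*.  Nodes with zero
    strength get PC = 0 by convention.
    """
    labels = partition.labels
    if len(labels) != graph.n_nodes:
        raise ValueError("partition does not cover the graph's nodes")
    a = graph.adjacency
    communities = np.unique(labels)
    # k_is: (N, M) strength of each node into each community
    k_is = np.stack([a[:, labels == s].sum(axis=1) for s in communities], axis=1)
    k = k_is.sum(axis=1)
    pc = np.zeros(graph.n_nodes)
    nz = k > 0
    pc[nz] = 1.0 - np.sum((k_is[nz] / k[nz, None]) ** 2, axis=1)
    return pc


def _as_igraph(graph: WeightedGraph) -> tuple[ig.Graph, list[float]]:
    src, dst = np.nonzero(np.triu(graph.adjacency, 1))
    g = ig.Graph(n=graph.n_nodes, edges=list(zip(src.tolist(), dst.tolist())))
    lengths = (1.0 / graph.adjacency[src, dst]).tolist()
    return g, lengths

def betweenness_centrality(graph: WeightedGraph) -> np.ndarray:
    """Unnormalized weighted betweenness on lengths ``1 / A_ij``.

    Each unordered pair ``s < t`` contributes ``sigma_st(v)/sigma_st`` to
    the intermediate node ``v``; pairs with no connecting path contribute
    nothing.
    """
    if graph.n_edges == 0:
        return np.zeros(graph.n_nodes)
    g, lengths = _as_igraph(graph)
    return np.asarray(g.betweenness(weights=lengths, directed=False), dtype=float)


def shortest_path_lengths(graph: WeightedGraph) -> np.ndarray:
    """All-pairs shortest-path distances on lengths ``1 / A_ij``."""
    a = graph.adjacency
    with np.errstate(divide="ignore"):
        lengths = np.where(a > 0, 1.0 / np.where(a > 0, a, 1.0), 0.0)
    return dijkstra(csr_matrix(lengths), directed=False)


def global_efficiency(graph: WeightedGraph) -> float:
    """Mean inverse shortest-path distance over ordered node pairs.

    ``E = 1/(N(N-1)) * sum_{i != j} 1/d_ij`` with disconnected pairs
    contributing zero.  Equals 1 on a complete unit-weight graph and 0 on
    an edgeless one.
    """
    n = graph.n_nodes
    if n < 2:
        raise ValueError("global efficiency requires at least 2 nodes")
    d = shortest_path_lengths(graph)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def modularity(graph: WeightedGraph, partition: CommunityPartition) -> float:
    """Newman modularity ``Q = 1/(2m) sum_ij (A_ij - k_i k_j/2m) d(c_i,c_j)``."""
    m = graph.total_weight
    if m <= 0:
        raise ValueError("modularity undefined for a graph with no edges")
    labels = partition.labels
    if len(labels) != graph.n_nodes:
        raise ValueError("partition does not cover the graph's nodes")
    a = graph.adjacency
    k = graph.strength
    q = 0.0
    for s in np.unique(labels):
        mask = labels == s
        w_ss = a[np.ix_(mask, mask)].sum()
        k_s = k[mask].sum()
        q += w_ss / (2 * m) - (k_s / (2 * m)) ** 2
    return float(q)


# ---------------------------------------------------------------------------
# Newman spectral community detection
# ---------------------------------------------------------------------------

def _leading_eigvec(b_sub: np.ndarray) -> np.ndarray:
    """Eigenvector of the largest eigenvalue, deterministically signed."""
    vals, vecs = np.linalg.eigh(b_sub)
    v = vecs[:, -1]
    # fix the sign ambiguity: largest-magnitude entry made positive
    pivot = int(np.argmax(np.abs(v)))
    if v[pivot] < 0:
        v = -v
    return v


def _kl_refine(b_sub: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan–Lin-style fine-tuning of a bisection vector ``s`` (+/-1).

    Repeatedly moves every vertex exactly once (best gain first, gains may
    be negative), keeps the best intermediate state, and restarts until a
    full pass yields no improvement.
    """
    n = len(s)
    s = s.copy()
    diag = np.diagonal(b_sub)
    scale = max(1.0, float(np.abs(b_sub).sum()))
    tol = 1e-10 * scale
    for _ in range(n + 10):  # pass cap; convergence is usually immediate
        g = b_sub @ s
        start_obj = float(s @ g)
        best_obj = start_obj
        obj = start_obj
        best_state = s.copy()
        moved = np.zeros(n, dtype=bool)
        trial = s.copy()
        for _ in range(n):
            gains = 4.0 * (diag - trial * g)
            gains[moved] = -np.inf
            i = int(np.argmax(gains))
            obj += gains[i]
            g = g - 2.0 * trial[i] * b_sub[:, i]
            trial[i] = -trial[i]
            moved[i] = True
            if obj > best_obj + tol:
                best_obj = obj
                best_state = trial.copy()
        # exact re-evaluation guards against incremental round-off drift
        exact_best = float(best_state @ b_sub @ best_state)
        if exact_best <= start_obj + tol:
            return s
        s = best_state
    return s


def _local_move_refine(
    a: np.ndarray, k: np.ndarray, m: float, labels: np.ndarray
) -> np.ndarray:
    """Greedy node moves and community merges until Q stops improving."""
    labels = labels.copy()
    n = len(labels)
    tol = max(_Q_TOL, 1e-10)
    improved = True
    sweeps = 0
    while improved and sweeps < 100:  # cap guards against round-off cycling
        sweeps += 1
        improved = False
        comms = np.unique(labels)
        # strength of each node into each community
        k_ic = np.stack([a[:, labels == c].sum(axis=1) for c in comms], axis=1)
        k_c = np.array([k[labels == c].sum() for c in comms])
        idx = {c: j for j, c in enumerate(comms)}
        for i in range(n):
            ci = idx[labels[i]]
            # dQ of moving i from its community to community d
            loss = k_ic[i, ci] / m - (k[i] * (k_c[ci] - k[i])) / (2 * m * m)
            gains = k_ic[i] / m - (k[i] * k_c) / (2 * m * m) - loss
            gains[ci] = 0.0
            d = int(np.argmax(gains))
            # splitting i off into its own new community gains exactly -loss
            if -loss > tol and -loss > gains[d] and (labels == labels[i]).sum() > 1:
                labels[i] = int(labels.max()) + 1
                improved = True
                break  # community set changed; restart the sweep
            if gains[d] > tol:
                labels[i] = comms[d]
                k_ic[:, ci] -= a[:, i]
                k_ic[:, d] += a[:, i]
                k_c[ci] -= k[i]
                k_c[d] += k[i]
                ci = d
                improved = True
        # try merging community pairs
        comms = np.unique(labels)
        if len(comms) > 1:
            for x in range(len(comms)):
                for y in range(x + 1, len(comms)):
                    mx = labels == comms[x]
                    my = labels == comms[y]
                    w_xy = a[np.ix_(mx, my)].sum()
                    dq = w_xy / m - (k[mx].sum() * k[my].sum()) / (2 * m * m)
                    if dq > tol:
                        labels[my] = comms[x]
                        improved = True
                        break
                else:
                    continue
                break
    return labels


#: graphs at or below this size get the exhaustive kick polish
_KICK_POLISH_MAX_NODES = 20


def _partition_q(a: np.ndarray, k: np.ndarray, m: float,
                 labels: np.ndarray) -> float:
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        q += a[np.ix_(mask, mask)].sum() / (2 * m) - (k[mask].sum() / (2 * m)) ** 2
    return q


def _kick_polish(a: np.ndarray, k: np.ndarray, m: float,
                 labels: np.ndarray) -> np.ndarray:
    """Escape shallow local optima on small graphs.

    Deterministically forces each node into every other community (or a
    new one), re-runs the greedy refinement from that start, and keeps the
    best resulting partition.  Quadratic blowup limits this to small
    graphs; larger graphs rely on the greedy refinement alone.
    """
    n = len(labels)
    if n > _KICK_POLISH_MAX_NODES:
        return labels
    tol = max(_Q_TOL, 1e-10)
    best = labels.copy()
    best_q = _partition_q(a, k, m, best)
    improved = True
    while improved:
        improved = False
        for i in range(n):
            targets = list(np.unique(best))
            targets.append(int(max(targets)) + 1)
            for target in targets:
                if target == best[i]:
                    continue
                trial = best.copy()
                trial[i] = target
                trial = _local_move_refine(a, k, m, trial)
                q = _partition_q(a, k, m, trial)
                if q > best_q + tol:
                    best_q = q
                    best = trial
                    improved = True
        if not improved and n <= 10:
            # depth-2 kicks: force two nodes at once before re-refining
            base = best.copy()
            comms = list(np.unique(base))
            new_label = int(max(comms)) + 1
            options = comms + [new_label]
            for i in range(n):
                for j in range(i + 1, n):
                    for ti in options:
                        for tj in options:
                            if ti == base[i] and tj == base[j]:
                                continue
                            trial = base.copy()
                            trial[i] = ti
                            trial[j] = tj
                            trial = _local_move_refine(a, k, m, trial)
                            q = _partition_q(a, k, m, trial)
                            if q > best_q + tol:
                                best_q = q
                                best = trial
                                improved = True
                    if improved:
                        break
                if improved:
                    break
    return best


def newman_communities(graph: WeightedGraph) -> CommunityPartition:
    """Modularity-maximizing partition by recursive spectral bisection.

    Each group is split by the sign of the leading eigenvector of its
    generalized modularity matrix, fine-tuned with Kernighan–Lin-style
    node swaps; splitting stops when no bisection increases Q.  A final
    node-move/merge refinement pass polishes the partition.  The whole
    procedure is deterministic for a given adjacency.
    """
    n = graph.n_nodes
    m = graph.total_weight
    if m <= 0:
        warnings.warn("graph has no edges; returning a single community",
                      stacklevel=2)
        return CommunityPartition(np.zeros(n, dtype=np.int64))
    a = graph.adjacency
    k = graph.strength
    b = a - np.outer(k, k) / (2 * m)

    labels = np.zeros(n, dtype=np.int64)
    next_label = 1
    stack = [np.arange(n)]
    while stack:
        group = stack.pop()
        if len(group) < 2:
            continue
        b_g = b[np.ix_(group, group)]
        # generalized modularity matrix for the subgraph
        b_sub = b_g - np.diag(b_g.sum(axis=1))
        v = _leading_eigvec(b_sub)
        s = np.where(v >= 0, 1.0, -1.0)
        s = _kl_refine(b_sub, s)
        delta_q = float(s @ b_sub @ s) / (4 * m)
        if delta_q <= _Q_TOL or np.all(s > 0) or np.all(s < 0):
            continue
        neg = group[s < 0]
        pos = group[s > 0]
        labels[neg] = next_label
        next_label += 1
        stack.append(pos)
        stack.append(neg)

    labels = _local_move_refine(a, k, m, labels)
    labels = _kick_polish(a, k, m, labels)
    # relabel to consecutive ids in order of first appearance
    _, labels = np.unique(labels, return_inverse=True)
    return CommunityPartition(labels.astype(np.int64))
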