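"""Independent oracles used by the test suite.

Everything here is computed from first principles (enumeration, closed
forms, brute force) and deliberately does not reuse the package's own
implementations.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def set_partition_labels(n: int) -> np.ndarray:
    """All set partitions of range(n) as restricted-growth label arrays."""
    out = []

    def rec(i: int, labels: list[int], m: int) -> None:
        if i == n:
            out.append(labels.copy())
            return
        for lab in range(m + 1):
            labels[i] = lab
            rec(i + 1, labels, m + 1 if lab == m else m)

    rec(0, [0] * n, 0)
    return np.array(out)


def brute_modularity(A: np.ndarray, labels: np.ndarray) -> float:
    """Weighted Newman modularity of one labelled partition, by definition:
    Q = (1/2m) * sum_ij (A_ij - d_i d_j / 2m) * [c_i == c_j]."""
    d = A.sum(axis=1)
    m2 = d.sum()
    q = 0.0
    n = len(labels)
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += A[i, j] - d[i] * d[j] / m2
    return q / m2


def max_modularity_partitions(A: np.ndarray, tol: float = 1e-12):
    """Brute-force maximum modularity over every set partition.

    Returns (qmax, list of argmax label arrays), vectorized over the
    same-community masks of all partitions.
    """
    n = A.shape[0]
    P = set_partition_labels(n)
    S = (P[:, :, None] == P[:, None, :]).reshape(len(P), -1).astype(float)
    d = A.sum(axis=1)
    m2 = d.sum()
    q = S @ A.ravel() / m2 - (S @ np.outer(d, d).ravel()) / (m2 * m2)
    qmax = float(q.max())
    return qmax, [P[i] for i in np.flatnonzero(q >= qmax - tol)]


def is_single_bridge_clique_partition(A: np.ndarray, labels: np.ndarray) -> bool:
    """True when every part induces a *maximal* clique and any two parts are
    joined by at most one edge — the clique-union-with-single-weak-bridges
    structure."""
    n = A.shape[0]
    parts = [np.flatnonzero(labels == lab) for lab in sorted(set(labels))]
    for mem in parts:
        k = len(mem)
        if A[np.ix_(mem, mem)].astype(bool).sum() != k * (k - 1):
            return False
        for v in range(n):
            if v not in mem and A[v, mem].astype(bool).sum() == k:
                return False  # clique extendable -> not maximal
    for p, q_ in itertools.combinations(parts, 2):
        if A[np.ix_(p, q_)].astype(bool).sum() > 1:
            return False
    return True


# --- trees ------------------------------------------------------------------

def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """A random unrooted binary tree with positive branch lengths and its
    exact additive leaf-to-leaf distance matrix.

    Built by inserting leaves one at a time on a uniformly chosen edge.
    Returns (labels, D) with labels "T0".."T{n-1}".
    """
    # adjacency with lengths; leaves 0..n-1, internal nodes from 1000
    adj: dict[int, dict[int, float]] = {}

    def connect(a: int, b: int, w: float) -> None:
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    nxt = 1000
    connect(0, nxt, float(rng.uniform(0.1, 2.0)))
    connect(1, nxt, float(rng.uniform(0.1, 2.0)))
    connect(2, nxt, float(rng.uniform(0.1, 2.0)))
    nxt += 1
    for leaf in range(3, n_taxa):
        edges = sorted({tuple(sorted(e)) for a in adj for e in ((a, b) for b in adj[a])})
        a, b = edges[rng.integers(len(edges))]
        w = adj[a][b]
        frac = float(rng.uniform(0.2, 0.8))
        mid = nxt
        nxt += 1
        del adj[a][b], adj[b][a]
        connect(a, mid, w * frac)
        connect(b, mid, w * (1 - frac))
        connect(leaf, mid, float(rng.uniform(0.1, 2.0)))
    D = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        queue = deque([src])
        while queue:
            u = queue.popleft()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    queue.append(v)
        for dst in range(n_taxa):
            D[src, dst] = dist[dst]
    np.fill_diagonal(D, 0.0)
    return [f"T{i}" for i in range(n_taxa)], (D + D.T) / 2.0


def enumerate_unrooted_topologies(n_taxa: int):
    """Every unrooted binary topology on n_taxa leaves (1*3*5*...*(2n-5)
    of them), as adjacency-set dicts with leaves 0..n-1."""
    base = {0: {1000}, 1: {1000}, 2: {1000}, 1000: {0, 1, 2}}
    topologies = [base]
    nxt_id = 1001
    for leaf in range(3, n_taxa):
        grown = []
        for topo in topologies:
            edges = sorted({tuple(sorted((a, b))) for a in topo for b in topo[a]})
            for a, b in edges:
                new = {k: set(v) for k, v in topo.items()}
                mid = nxt_id
                new[a].discard(b)
                new[b].discard(a)
                new[mid] = {a, b, leaf}
                new[a].add(mid)
                new[b].add(mid)
                new[leaf] = {mid}
                grown.append(new)
        topologies = grown
        nxt_id += 1
    return topologies


def pauplin_length(topo: dict[int, set[int]], D: np.ndarray) -> float:
    """Balanced (Pauplin) tree length of a topology: sum over leaf pairs of
    d_ij * 2^(1 - topological distance)."""
    n = D.shape[0]
    total = 0.0
    for src in range(n):
        depth = {src: 0}
        queue = deque([src])
        while queue:
            u = queue.popleft()
            for v in topo[u]:
                if v not in depth:
                    depth[v] = depth[u] + 1
                    queue.append(v)
        for dst in range(src + 1, n):
            total += D[src, dst] * 2.0 ** (1 - depth[dst])
    return total
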