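"""Within-cluster dendrograms from inverse shared IBD length.

Each pair's local familial distance is 1 / (shared cM spanning the locus):
the longer the shared haplotype, the more recent the common ancestor and
the smaller the distance.  Trees are built from the resulting distance
matrix either by classic neighbor joining (default; exact on additive
matrices) or by balanced minimum evolution with nearest-neighbor-
interchange improvement (the criterion FastME optimizes by default).
Pairs with no retained spanning segment are imputed at twice the largest
observed distance so the matrix is complete, and flagged.

Trees are scikit-bio ``TreeNode`` objects; Newick output carries branch
lengths at six significant digits.
"""

from __future__ import annotations

import logging
import re
from collections import deque
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
from skbio import DistanceMatrix, TreeNode

from .clustering import Cluster

logger = logging.getLogger(__name__)

__all__ = ["distance_matrix", "build_tree", "nj_tree", "bme_tree", "to_newick", "bme_length"]


def distance_matrix(
    cluster: Cluster,
    graph: nx.Graph,
    by_haplotype: bool = False,
) -> tuple[DistanceMatrix, list[tuple[str, str]]]:
    """Pairwise 1/cM distances among cluster members.

    Taxa default to individuals, with the distance taken from the best
    (longest) shared segment across their haplotype pairs; ``by_haplotype``
    keeps one taxon per haplotype.  Returns the completed matrix and the
    list of taxon pairs whose distance was imputed (2 × max observed)
    because no retained segment joins them.
    """
    members = sorted(cluster.members)
    if by_haplotype:
        labels = [str(m) for m in members]
        index = {m: i for i, m in enumerate(members)}
        best: dict[tuple[int, int], float] = {}
        mset = set(members)
        for u, v, d in graph.edges(members, data=True):
            if u in mset and v in mset:
                i, j = sorted((index[u], index[v]))
                best[(i, j)] = max(best.get((i, j), 0.0), float(d["weight"]))
    else:
        samples = sorted({m.sample for m in members})
        labels = list(samples)
        index = {s: i for i, s in enumerate(samples)}
        best = {}
        mset = set(members)
        for u, v, d in graph.edges(members, data=True):
            if u in mset and v in mset and u.sample != v.sample:
                i, j = sorted((index[u.sample], index[v.sample]))
                best[(i, j)] = max(best.get((i, j), 0.0), float(d["weight"]))
    n = len(labels)
    if n < 3:
        raise ValueError(f"need at least 3 taxa for a dendrogram, got {n}")
    if not best:
        raise ValueError("no retained segment joins any pair of taxa")
    dist = np.zeros((n, n))
    missing: list[tuple[int, int]] = []
    for i, j in combinations(range(n), 2):
        w = best.get((i, j))
        if w is None:
            missing.append((i, j))
        else:
            dist[i, j] = dist[j, i] = 1.0 / w
    fill = 2.0 * dist.max()
    imputed = []
    for i, j in missing:
        dist[i, j] = dist[j, i] = fill
        imputed.append((labels[i], labels[j]))
    if imputed:
        logger.warning(
            "%d taxon pair(s) share no retained segment; distance imputed at %.6g",
            len(imputed), fill,
        )
    return DistanceMatrix(dist, ids=labels), imputed


# --- neighbor joining -------------------------------------------------------

def _nj_adjacency(D: np.ndarray) -> dict[int, dict[int, float]]:
    """Classic NJ on a complete distance matrix; leaves are 0..n-1.

    Returns an unrooted tree as an adjacency map with branch lengths
    (internal nodes numbered from n).  Ties in the Q matrix resolve to the
    first (row-major) minimum, so the result is deterministic.
    """
    n = D.shape[0]
    active = list(range(n))
    M = D.astype(float).copy()
    adj: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    nxt = n

    def connect(a: int, b: int, length: float) -> None:
        adj.setdefault(a, {})[b] = length
        adj.setdefault(b, {})[a] = length

    while len(active) > 3:
        k = len(M)
        r = M.sum(axis=1)
        Q = (k - 2) * M - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), k)
        if i > j:
            i, j = j, i
        li = 0.5 * M[i, j] + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = M[i, j] - li
        parent = nxt
        nxt += 1
        connect(parent, active[i], li)
        connect(parent, active[j], lj)
        d_new = 0.5 * (M[i] + M[j] - M[i, j])
        keep = [x for x in range(k) if x not in (i, j)]
        M2 = np.empty((k - 1, k - 1))
        M2[:-1, :-1] = M[np.ix_(keep, keep)]
        M2[-1, :-1] = M2[:-1, -1] = d_new[keep]
        M2[-1, -1] = 0.0
        M = M2
        active = [active[x] for x in keep] + [parent]

    if len(active) == 3:
        a, b, c = active
        dab, dac, dbc = M[0, 1], M[0, 2], M[1, 2]
        center = nxt
        connect(center, a, 0.5 * (dab + dac - dbc))
        connect(center, b, 0.5 * (dab + dbc - dac))
        connect(center, c, 0.5 * (dac + dbc - dab))
    else:  # 2 taxa: a single edge
        a, b = active
        connect(a, b, M[0, 1])
    return adj


def _adjacency_to_tree(
    adj: dict[int, dict[int, float]], labels: list[str]
) -> TreeNode:
    """Root the unrooted adjacency at its smallest internal node and build a
    TreeNode; negative branch lengths are clamped to zero with a warning."""
    n = len(labels)
    internal = sorted(node for node in adj if node >= n)
    root_id = internal[0] if internal else min(adj)
    clamped = 0

    def build(node: int, parent: int | None, length: float | None) -> TreeNode:
        nonlocal clamped
        if length is not None and length < 0:
            clamped += 1
            length = 0.0
        name = labels[node] if node < n else None
        children = [
            build(child, node, edge_len)
            for child, edge_len in sorted(adj[node].items())
            if child != parent
        ]
        return TreeNode(name=name, length=length, children=children or None)

    tree = build(root_id, None, None)
    if clamped:
        logger.warning("clamped %d negative branch length(s) to 0", clamped)
    return tree


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; reconstructs additive matrices exactly."""
    _validate(dm)
    return _adjacency_to_tree(_nj_adjacency(np.asarray(dm.data)), list(dm.ids))


# --- balanced minimum evolution --------------------------------------------

def _leaf_path_lengths(topo: dict[int, set[int]], n_leaves: int) -> np.ndarray:
    """Topological (edge-count) distances between all leaf pairs."""
    p = np.zeros((n_leaves, n_leaves), dtype=int)
    for src in range(n_leaves):
        depth = {src: 0}
        queue = deque([src])
        while queue:
            node = queue.popleft()
            for nb in topo[node]:
                if nb not in depth:
                    depth[nb] = depth[node] + 1
                    queue.append(nb)
        for dst in range(src + 1, n_leaves):
            p[src, dst] = p[dst, src] = depth[dst]
    return p


def bme_length(topo: dict[int, set[int]], D: np.ndarray) -> float:
    """Pauplin's balanced tree-length estimate: sum over leaf pairs of
    d_ij * 2^(1 - p_ij), with p_ij the number of edges between the leaves."""
    n = D.shape[0]
    p = _leaf_path_lengths(topo, n)
    total = 0.0
    for i, j in combinations(range(n), 2):
        total += D[i, j] * 2.0 ** (1 - p[i, j])
    return total


def _nni_neighbors(topo: dict[int, set[int]], n_leaves: int):
    """Yield (edge, swap) descriptions of the two NNI rearrangements around
    each internal edge, in deterministic order."""
    for u in sorted(topo):
        if u < n_leaves:
            continue
        for v in sorted(topo[u]):
            if v < n_leaves or v < u:
                continue
            a = sorted(x for x in topo[u] if x != v)
            b = sorted(x for x in topo[v] if x != u)
            # swapping a[1] with either neighbor of v gives the two alternatives
            yield (u, v, a[1], b[0])
            yield (u, v, a[1], b[1])


def _apply_swap(topo: dict[int, set[int]], u: int, v: int, x: int, y: int) -> None:
    topo[u].remove(x); topo[x].remove(u)
    topo[v].remove(y); topo[y].remove(v)
    topo[u].add(y); topo[y].add(u)
    topo[v].add(x); topo[x].add(v)


def _ols_lengths(
    topo: dict[int, set[int]], D: np.ndarray
) -> dict[int, dict[int, float]]:
    """Ordinary least-squares branch lengths for a fixed topology."""
    n = D.shape[0]
    edges = sorted({tuple(sorted((a, b))) for a in topo for b in topo[a]})
    eindex = {e: i for i, e in enumerate(edges)}
    rows, rhs = [], []
    for src in range(n):
        parent = {src: None}
        queue = deque([src])
        while queue:
            node = queue.popleft()
            for nb in topo[node]:
                if nb not in parent:
                    parent[nb] = node
                    queue.append(nb)
        for dst in range(src + 1, n):
            row = np.zeros(len(edges))
            node = dst
            while parent[node] is not None:
                row[eindex[tuple(sorted((node, parent[node])))] ] = 1.0
                node = parent[node]
            rows.append(row)
            rhs.append(D[src, dst])
    sol, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    adj: dict[int, dict[int, float]] = {}
    for (a, b), val in zip(edges, sol):
        adj.setdefault(a, {})[b] = float(val)
        adj.setdefault(b, {})[a] = float(val)
    return adj


def bme_tree(dm: DistanceMatrix) -> TreeNode:
    """Balanced-minimum-evolution tree: NJ starting topology, greedy NNI
    moves minimizing the Pauplin length, OLS branch lengths."""
    _validate(dm)
    D = np.asarray(dm.data)
    n = D.shape[0]
    topo = {a: set(nbrs) for a, nbrs in _nj_adjacency(D).items()}
    if n > 3:  # a 3-taxon tree has a unique topology
        best = bme_length(topo, D)
        improved = True
        while improved:
            improved = False
            best_move = None
            for u, v, x, y in _nni_neighbors(topo, n):
                _apply_swap(topo, u, v, x, y)
                cand = bme_length(topo, D)
                _apply_swap(topo, u, v, y, x)  # undo
                if cand < best - 1e-12 and (best_move is None or cand < best_move[0]):
                    best_move = (cand, u, v, x, y)
            if best_move is not None:
                _, u, v, x, y = best_move
                _apply_swap(topo, u, v, x, y)
                best = best_move[0]
                improved = True
    return _adjacency_to_tree(_ols_lengths(topo, D), list(dm.ids))


def _validate(dm: DistanceMatrix) -> None:
    data = np.asarray(dm.data)
    if (data < 0).any():
        raise ValueError("distance matrix has negative entries")
    if not np.allclose(data, data.T):
        raise ValueError("distance matrix is not symmetric")
    if dm.shape[0] < 3:
        raise ValueError("need at least 3 taxa")


def build_tree(dm: DistanceMatrix, method: str = "nj") -> TreeNode:
    """Build a dendrogram from a complete distance matrix.

    ``method`` is ``"nj"`` (classic neighbor joining, default) or ``"bme"``
    (balanced minimum evolution with NNI improvement, FastME's default
    criterion).
    """
    if method == "nj":
        return nj_tree(dm)
    if method == "bme":
        return bme_tree(dm)
    raise ValueError(f"unknown tree method {method!r}")


# --- Newick output ----------------------------------------------------------

_PLAIN_LABEL = re.compile(r"^[^\s():;,\[\]']+$")


def _newick_label(name: str) -> str:
    if _PLAIN_LABEL.match(name):
        return name
    return "'" + name.replace("'", "''") + "'"


def _newick_node(node: TreeNode) -> str:
    if node.is_tip():
        text = _newick_label(node.name or "")
    else:
        text = "(" + ",".join(_newick_node(c) for c in node.children) + ")"
        if node.name:
            text += _newick_label(node.name)
    if node.length is not None:
        text += f":{node.length:.6g}"
    return text


def to_newick(tree: TreeNode, path: str | Path | None = None) -> str:
    """Serialize a tree to Newick (branch lengths at 6 significant digits);
    optionally write it to ``path``.  Labels with spaces or Newick
    metacharacters are single-quoted."""
    text = _newick_node(tree) + ";\n"
    if path is not None:
        Path(path).write_text(text)
    return text
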