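"""Random-walk community detection on the locus sharing graph.

The partitioning step is a deterministic Pons–Latapy walktrap with walk
length ``t`` (default 3) on the centimorgan-weighted graph.  The walk is
lazy — each node carries a self-loop of weight equal to its weighted
degree, so the walker stays put with probability 1/2 — which removes the
odd/even parity artifacts of short walks (this matches the canonical
walktrap implementation).  Transition probabilities are then
P[i, j] = w_ij / (2 sum_k w_ik) off the diagonal; the distance between
communities C1, C2 is

    r(C1, C2)^2 = sum_k (Pt[C1, k] - Pt[C2, k])^2 / d(k)

with Pt[C, .] the mean t-step transition profile of C's members and d(k)
the weighted degree.  Communities are merged agglomeratively, always the
adjacent pair minimizing the walktrap merge cost

    delta_sigma = (1/n) * |C1||C2| / (|C1| + |C2|) * r(C1, C2)^2,

and the dendrogram is cut at the level of maximum *unweighted*
(topological) modularity, computed within each connected component;
clusters never span components.  Segment lengths shape the walk and hence
the merge order, while connectivity alone decides where a cluster ends:
cutting on length-weighted modularity instead would shear well-connected
extended families along their strong close-relative edges (sibling pairs
share an order of magnitude more cM than distant cousins), splitting
groups that are topologically cliques.  Everything is deterministic: ties
in the merge order are broken by the lexicographically smallest member of
each community, and "random" refers to the walk model, not to sampling.

Large (size > max_size) *and* sparse (pairwise edge density < min_density)
clusters are then re-clustered on their induced subgraphs, for at most
``max_refine_iter`` rounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringConfig",
    "Cluster",
    "walk_cluster",
    "refine",
    "reportable",
    "clusters_containing",
    "pair_density",
    "modularity",
]


@dataclass(frozen=True)
class ClusteringConfig:
    """Thresholds governing segment filtering, clustering and refinement.

    Defaults follow the published analysis settings: segments longer than
    3 cM, three-step walks, refinement of clusters with more than 30 members
    and under half of their pairs connected, at most five refinement rounds,
    reported clusters of at least three members, and 1 cM for cross-cluster
    short-segment sharing.
    """

    min_cm: float = 3.0
    walk_steps: int = 3
    max_size: int = 30
    min_density: float = 0.5
    max_refine_iter: int = 5
    min_cluster_size: int = 3
    cross_cluster_min_cm: float = 1.0

    def __post_init__(self) -> None:
        if not self.min_cm > 0:
            raise ValueError("min_cm must be positive")
        if self.walk_steps < 1:
            raise ValueError("walk_steps must be >= 1")
        if self.max_size < 1:
            raise ValueError("max_size must be >= 1")
        if not 0 < self.min_density <= 1:
            raise ValueError("min_density must be in (0, 1]")
        if self.max_refine_iter < 1:
            raise ValueError("max_refine_iter must be >= 1")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if not self.cross_cluster_min_cm > 0:
            raise ValueError("cross_cluster_min_cm must be positive")


@dataclass(frozen=True)
class Cluster:
    """A candidate carrier group: one set of haplotype nodes.

    ``converged`` is False only for clusters that still violated the
    size/density gates when the refinement iteration cap was reached.
    """

    cluster_id: str
    members: frozenset
    converged: bool = True
    refine_iterations_used: int = 0

    def __len__(self) -> int:
        return len(self.members)

    @property
    def samples(self) -> frozenset:
        return frozenset(m.sample if hasattr(m, "sample") else m for m in self.members)


def pair_density(members: Iterable[Hashable], graph: nx.Graph) -> float:
    """Fraction of unordered member pairs joined by a retained edge.

    Defined as 1.0 for clusters with fewer than two members (no pair can be
    missing).
    """
    members = list(members)
    n = len(members)
    if n < 2:
        return 1.0
    mset = set(members)
    edges = sum(1 for u, v in graph.edges(members) if u in mset and v in mset)
    return edges / (n * (n - 1) / 2)


def modularity(partition: Sequence[Iterable[Hashable]], graph: nx.Graph) -> float:
    """Weighted Newman modularity of a node partition."""
    m2 = sum(d.get("weight", 1.0) for _, _, d in graph.edges(data=True)) * 2.0
    if m2 == 0:
        return 0.0
    q = 0.0
    for part in partition:
        nodes = set(part)
        w_in = sum(
            d.get("weight", 1.0)
            for u, v, d in graph.edges(nodes, data=True)
            if u in nodes and v in nodes
        )
        deg = sum(graph.degree(n, weight="weight") for n in nodes)
        q += 2.0 * w_in / m2 - (deg / m2) ** 2
    return q


def _walktrap_component(A: np.ndarray, steps: int) -> list[list[int]]:
    """Walktrap partition of one connected component given its dense weighted
    adjacency matrix (index order defines the deterministic tie-break order).

    Returns communities as lists of row indices.
    """
    n = A.shape[0]
    if n == 1:
        return [[0]]
    deg = A.sum(axis=1)
    # the modularity used for the dendrogram cut is topological: every edge
    # counts 1 regardless of its cM weight (see module docstring)
    B = (A > 0).astype(float)
    bdeg = B.sum(axis=1)
    m2 = bdeg.sum()  # twice the edge count
    # lazy walk: a self-loop of weight deg(i) gives staying probability 1/2,
    # removing odd/even parity artifacts of short walks (canonical walktrap)
    lazy_deg = 2.0 * deg
    P = (A + np.diag(deg)) / lazy_deg[:, None]
    Pt = np.linalg.matrix_power(P, steps)
    inv_deg = 1.0 / lazy_deg

    # community state, keyed by integer community id
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    prob: dict[int, np.ndarray] = {i: Pt[i].copy() for i in range(n)}
    w_in: dict[int, float] = {i: 0.0 for i in range(n)}
    degsum: dict[int, float] = {i: float(bdeg[i]) for i in range(n)}
    # between-community edge counts (adjacency of the community graph)
    between: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if A[i, j] > 0:
                between[i][j] = 1.0
                between[j][i] = 1.0
    rep: dict[int, int] = {i: i for i in range(n)}  # smallest member index

    def q_current() -> float:
        return sum(2.0 * w_in[c] / m2 - (degsum[c] / m2) ** 2 for c in members)

    labels = np.arange(n)
    snapshots: list[tuple[float, np.ndarray]] = [(q_current(), labels.copy())]
    next_id = n

    while len(members) > 1:
        best_key: tuple[float, int, int] | None = None
        best_pair: tuple[int, int] | None = None
        for c1 in members:
            s1 = len(members[c1])
            p1 = prob[c1]
            for c2, _w in between[c1].items():
                if c2 <= c1:
                    continue
                diff = p1 - prob[c2]
                s2 = len(members[c2])
                dsig = (s1 * s2 / (s1 + s2)) * float(np.dot(diff * diff, inv_deg)) / n
                r1, r2 = rep[c1], rep[c2]
                key = (dsig, min(r1, r2), max(r1, r2))
                if best_key is None or key < best_key:
                    best_key = key
                    best_pair = (c1, c2)
        assert best_pair is not None  # a connected component always has an adjacent pair
        c1, c2 = best_pair
        cid = next_id
        next_id += 1
        s1, s2 = len(members[c1]), len(members[c2])
        members[cid] = members.pop(c1) + members.pop(c2)
        prob[cid] = (s1 * prob.pop(c1) + s2 * prob.pop(c2)) / (s1 + s2)
        w_in[cid] = w_in.pop(c1) + w_in.pop(c2) + between[c1].get(c2, 0.0)
        degsum[cid] = degsum.pop(c1) + degsum.pop(c2)
        rep[cid] = min(rep.pop(c1), rep.pop(c2))
        nbrs: dict[int, float] = {}
        for old in (c1, c2):
            for other, w in between.pop(old).items():
                if other in (c1, c2):
                    continue
                nbrs[other] = nbrs.get(other, 0.0) + w
        between[cid] = nbrs
        for other, w in nbrs.items():
            d = between[other]
            d.pop(c1, None)
            d.pop(c2, None)
            d[cid] = w
        for idx in members[cid]:
            labels[idx] = cid
        snapshots.append((q_current(), labels.copy()))

    # cut at maximum modularity; ties resolved toward the most merged level
    best_q = max(q for q, _ in snapshots)
    chosen = None
    for q, lab in snapshots:
        if q >= best_q - 1e-12:
            chosen = lab
    assert chosen is not None
    out: dict[int, list[int]] = {}
    for idx, lab in enumerate(chosen):
        out.setdefault(int(lab), []).append(idx)
    return [sorted(v) for v in out.values()]


def walk_cluster(graph: nx.Graph, steps: int = 3) -> list[set]:
    """Partition graph nodes into communities by the deterministic walktrap.

    The graph is processed one connected component at a time; communities
    never span components and every node is assigned to exactly one
    community.  Returns member sets ordered by their smallest node.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    partition: list[set] = []
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    for comp in components:
        nodes = sorted(comp)
        if len(nodes) == 1:
            partition.append({nodes[0]})
            continue
        index = {node: i for i, node in enumerate(nodes)}
        A = np.zeros((len(nodes), len(nodes)))
        for u, v, d in graph.subgraph(nodes).edges(data=True):
            w = float(d.get("weight", 1.0))
            A[index[u], index[v]] = w
            A[index[v], index[u]] = w
        for part in _walktrap_component(A, steps):
            partition.append({nodes[i] for i in part})
    partition.sort(key=lambda s: min(s))
    return partition


@dataclass
class _WorkCluster:
    members: set
    iterations: int = 0


def _qualifies(members: set, graph: nx.Graph, config: ClusteringConfig) -> bool:
    return len(members) > config.max_size and pair_density(members, graph) < config.min_density


def refine(
    partition: Sequence[Iterable[Hashable]],
    graph: nx.Graph,
    config: ClusteringConfig | None = None,
) -> list[Cluster]:
    """Iteratively split large, sparse clusters by re-running the walktrap on
    their induced subgraphs.

    A cluster qualifies for splitting when its size exceeds ``max_size`` AND
    its pairwise edge density is below ``min_density``.  Splitting stops when
    no cluster qualifies or after ``max_refine_iter`` rounds; a qualifying
    cluster the walktrap cannot split is left intact, with the round counted.
    Returns every cluster (including those below ``min_cluster_size``; use
    :func:`reportable` to apply the reporting filter), with deterministic ids
    assigned by decreasing size then smallest member.
    """
    if config is None:
        config = ClusteringConfig()
    work = [_WorkCluster(set(p)) for p in partition]
    for rnd in range(1, config.max_refine_iter + 1):
        todo = {id(c) for c in work if _qualifies(c.members, graph, config)}
        if not todo:
            break
        nxt: list[_WorkCluster] = []
        for c in work:
            if id(c) not in todo:
                nxt.append(c)
                continue
            sub_parts = walk_cluster(graph.subgraph(c.members), steps=config.walk_steps)
            if len(sub_parts) == 1:
                c.iterations = rnd
                nxt.append(c)
            else:
                nxt.extend(_WorkCluster(set(p), iterations=rnd) for p in sub_parts)
        work = nxt

    work.sort(key=lambda c: (-len(c.members), min(c.members)))
    clusters = []
    for i, c in enumerate(work, start=1):
        converged = not _qualifies(c.members, graph, config)
        clusters.append(
            Cluster(
                cluster_id=f"c{i}",
                members=frozenset(c.members),
                converged=converged,
                refine_iterations_used=c.iterations,
            )
        )
    return clusters


def reportable(clusters: Iterable[Cluster], config: ClusteringConfig | None = None) -> list[Cluster]:
    """Apply the reporting filter: clusters below ``min_cluster_size`` are
    dropped (and logged), mirroring the published at-least-three-members rule."""
    if config is None:
        config = ClusteringConfig()
    kept = []
    for c in clusters:
        if len(c.members) >= config.min_cluster_size:
            kept.append(c)
        else:
            logger.info(
                "dropping cluster %s with %d member(s) (< min_cluster_size %d)",
                c.cluster_id, len(c.members), config.min_cluster_size,
            )
    return kept


def clusters_containing(
    clusters: Iterable[Cluster],
    seed_samples: Iterable[str],
    min_seeds: int = 1,
) -> list[Cluster]:
    """Clusters containing at least ``min_seeds`` distinct seed individuals.

    Used to carry forward only the clusters anchored by known carriers.
    """
    seeds = set(seed_samples)
    return [c for c in clusters if len(c.samples & seeds) >= min_seeds]
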