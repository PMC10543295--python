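"""Per-cluster and cross-cluster diagnostics.

``summarize`` reports, per cluster, the haplotype and individual counts, the
percentage of member pairs connected by a retained spanning edge, and the
mean retained edge length in centimorgans — the connectedness statistics
used to judge whether a cluster behaves like a genuine extended family
sharing one founder haplotype.  ``cross_cluster_segments`` quantifies
distant relatedness *between* clusters from short segments anywhere in the
genome (they need not span the target locus, and typically cannot exceed
the spanning filter's threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import networkx as nx

from .clustering import Cluster, ClusteringConfig
from .ibd_io import IBDSegment, TargetLocus

__all__ = ["ClusterSummary", "summarize", "cross_cluster_segments", "round_half_up"]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (so 82.857… → 82.9 and 0.25 → 0.3)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClusterSummary:
    """Printable one-row diagnostics for a cluster."""

    cluster_id: str
    n_haplotypes: int
    n_individuals: int
    density_pct: float  # % of member pairs connected, one decimal
    mean_cm: float  # mean retained edge length, one decimal; NaN if no edge
    members: tuple[str, ...]  # "sample:hap" labels, sorted
    converged: bool = True


def summarize(
    cluster: Cluster,
    graph: nx.Graph,
    config: ClusteringConfig | None = None,
) -> ClusterSummary:
    """Compute the connectedness summary of one cluster against the retained
    spanning-segment graph.

    density = 100 × (connected member pairs) / C(n, 2), rounded half-up to one
    decimal; mean_cm is the mean of the retained edge weights among member
    pairs, also one decimal.  Haplotype-level members are collapsed to
    distinct sample ids for the individual count only.
    """
    members = sorted(cluster.members)
    n = len(members)
    if n < 2:
        raise ValueError(f"cluster {cluster.cluster_id} has {n} member(s); cannot form pairs")
    mset = set(members)
    weights = [
        float(d["weight"])
        for u, v, d in graph.edges(members, data=True)
        if u in mset and v in mset
    ]
    n_pairs = n * (n - 1) // 2
    density_pct = round_half_up(100.0 * len(weights) / n_pairs, 1)
    mean_cm = round_half_up(sum(weights) / len(weights), 1) if weights else math.nan
    samples = {m.sample if hasattr(m, "sample") else str(m) for m in members}
    return ClusterSummary(
        cluster_id=cluster.cluster_id,
        n_haplotypes=n,
        n_individuals=len(samples),
        density_pct=density_pct,
        mean_cm=mean_cm,
        members=tuple(str(m) for m in members),
        converged=cluster.converged,
    )


def cross_cluster_segments(
    cluster_x: Cluster,
    cluster_y: Cluster,
    all_segments: Iterable[IBDSegment],
    locus: TargetLocus | None = None,
    min_cm: float = 1.0,
    span_only: bool = False,
) -> tuple[int, float]:
    """Count IBD segments longer than ``min_cm`` (strict) joining an individual
    of one cluster to an individual of the other, anywhere in the genome.

    Returns ``(count, mean_cm)``; the mean is NaN when the count is zero.
    With ``span_only=True`` only segments spanning ``locus`` are counted.
    Membership is at the individual (sample) level; the count is symmetric in
    the two clusters, and segments internal to either cluster are ignored.
    """
    if cluster_x.members & cluster_y.members:
        raise ValueError("clusters must be disjoint")
    if span_only and locus is None:
        raise ValueError("span_only requires a locus")
    sx, sy = cluster_x.samples, cluster_y.samples
    lengths: list[float] = []
    for seg in all_segments:
        if not seg.length_cm > min_cm:
            continue
        cross = (seg.sample1 in sx and seg.sample2 in sy) or (
            seg.sample1 in sy and seg.sample2 in sx
        )
        if not cross:
            continue
        if span_only:
            assert locus is not None
            if seg.chrom != locus.chrom:
                continue
            if not (seg.start_bp <= locus.start_bp and seg.end_bp >= locus.end_bp):
                continue
        lengths.append(seg.length_cm)
    if not lengths:
        return 0, math.nan
    return len(lengths), sum(lengths) / len(lengths)
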