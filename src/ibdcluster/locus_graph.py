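"""Locus-spanning segment selection and haplotype-sharing graph assembly.

A segment "spans" the target locus when its interval fully contains the
target interval on the same chromosome — a merely overlapping segment does
not carry the locus's complete local haplotype.  An any-overlap mode is
available but non-default.  Retained segments become edges of an undirected
graph whose nodes are haplotypes (sample id + haplotype index) and whose
edge weights are segment lengths in centimorgans.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

import networkx as nx

from .ibd_io import IBDSegment, TargetLocus

__all__ = ["HaplotypeNode", "filter_spanning", "build_graph"]


class HaplotypeNode(NamedTuple):
    """One phased haplotype: the unit of IBD sharing."""

    sample: str
    hap: int

    def __str__(self) -> str:  # used in reports and member lists
        return f"{self.sample}:{self.hap}"


def filter_spanning(
    segments: Iterable[IBDSegment],
    locus: TargetLocus,
    min_cm: float = 3.0,
    overlap: bool = False,
) -> list[IBDSegment]:
    """Keep segments on the locus chromosome, longer than ``min_cm`` (strict),
    that contain the locus interval (or merely overlap it if ``overlap=True``).

    Input order is preserved; the operation is idempotent.
    """
    if not min_cm > 0:
        raise ValueError(f"min_cm must be positive, got {min_cm}")
    kept = []
    for seg in segments:
        if seg.chrom != locus.chrom or not seg.length_cm > min_cm:
            continue
        if overlap:
            hit = seg.start_bp <= locus.end_bp and seg.end_bp >= locus.start_bp
        else:
            hit = seg.start_bp <= locus.start_bp and seg.end_bp >= locus.end_bp
        if hit:
            kept.append(seg)
    return kept


def _endpoints(seg: IBDSegment) -> tuple[HaplotypeNode, HaplotypeNode]:
    return HaplotypeNode(seg.sample1, seg.hap1), HaplotypeNode(seg.sample2, seg.hap2)


def build_graph(segments: Sequence[IBDSegment]) -> nx.Graph:
    """Assemble the weighted haplotype-sharing graph from locus-filtered segments.

    One node per haplotype seen, one edge per unordered haplotype pair.  When a
    pair has several spanning segments, the longest is retained (ties keep the
    first in input order).  Edge attributes: ``weight`` (cM) and ``segment``
    (the retained :class:`~ibdcluster.ibd_io.IBDSegment`).
    """
    graph = nx.Graph()
    for seg in segments:
        u, v = _endpoints(seg)
        graph.add_node(u)
        graph.add_node(v)
        if graph.has_edge(u, v):
            if seg.length_cm > graph.edges[u, v]["weight"]:
                graph.edges[u, v].update(weight=seg.length_cm, segment=seg)
        else:
            graph.add_edge(u, v, weight=seg.length_cm, segment=seg)
    return graph
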