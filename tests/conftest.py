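import itertools

import networkx as nx
import numpy as np
import pytest

from ibdcluster import HaplotypeNode, build_graph, filter_spanning
from ibdcluster.simulate import make_cluster_fixture


def weighted_graph(edges):
    """Build a graph from (u, v, weight) triples with integer or string nodes."""
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=float(w))
    return g


def clique_union(sizes, rng, intra=(6.0, 15.0), bridge=3.1):
    """Vertex-disjoint cliques with random intra-clique weights, chained by
    single weak bridge edges.  Returns (graph, list of clique node sets)."""
    g = nx.Graph()
    cliques = []
    base = 0
    for s in sizes:
        nodes = list(range(base, base + int(s)))
        base += int(s)
        for u, v in itertools.combinations(nodes, 2):
            g.add_edge(u, v, weight=float(rng.uniform(*intra)))
        cliques.append(set(nodes))
    for a, b in zip(cliques, cliques[1:]):
        g.add_edge(min(a), min(b), weight=bridge)
    return g, cliques


@pytest.fixture(scope="session")
def cluster_a():
    """The deterministic 21-member worked-example fixture, pre-filtered and
    assembled into its sharing graph."""
    segments, locus, expected = make_cluster_fixture()
    spanning = filter_spanning(segments, locus, min_cm=3.0)
    graph = build_graph(spanning)
    return {
        "segments": segments,
        "locus": locus,
        "expected": expected,
        "spanning": spanning,
        "graph": graph,
    }


def hap(sample, h=1):
    return HaplotypeNode(sample, h)
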