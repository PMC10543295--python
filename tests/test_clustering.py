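import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import clique_union, weighted_graph
from oracles import brute_modularity, max_modularity_partitions

from ibdcluster.clustering import (
    Cluster,
    ClusteringConfig,
    clusters_containing,
    modularity,
    pair_density,
    refine,
    reportable,
    walk_cluster,
)
from ibdcluster.locus_graph import HaplotypeNode


class TestWalkCluster:
    def test_two_disjoint_cliques_give_two_clusters(self):
        g = nx.Graph()
        for base in (0, 10):
            for u, v in itertools.combinations(range(base, base + 5), 2):
                g.add_edge(u, v, weight=10.0)
        part = walk_cluster(g)
        assert sorted(sorted(p) for p in part) == [list(range(5)), list(range(10, 15))]

    def test_single_edge_is_one_cluster_of_two(self):
        g = weighted_graph([("A1", "B1", 5.0)])
        assert walk_cluster(g) == [{"A1", "B1"}]

    def test_bridged_six_cliques_split_at_modularity_optimum(self):
        g = nx.Graph()
        for base in (0, 10):
            for u, v in itertools.combinations(range(base, base + 6), 2):
                g.add_edge(u, v, weight=10.0)
        g.add_edge(0, 10, weight=3.1)
        part = walk_cluster(g)
        assert sorted(sorted(p) for p in part) == [list(range(6)), list(range(10, 16))]
        # brute force over all 2-way partitions confirms the clique split is optimal
        nodes = sorted(g.nodes)
        A = nx.to_numpy_array(g, nodelist=nodes)
        best_q, best_side = -np.inf, None
        for mask in range(1, 2 ** (len(nodes) - 1)):
            side = [i for i in range(len(nodes)) if mask >> i & 1]
            labels = np.array([1 if i in side else 0 for i in range(len(nodes))])
            q = brute_modularity(A, labels)
            if q > best_q:
                best_q, best_side = q, set(side)
        assert best_side in ({0, 1, 2, 3, 4, 5}, {6, 7, 8, 9, 10, 11})
        assert modularity(part, g) == pytest.approx(best_q, abs=1e-12)

    def test_partition_covers_all_nodes_disjointly(self):
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(40, 0.15, seed=7)
        for u, v in g.edges:
            g.edges[u, v]["weight"] = float(rng.uniform(3.1, 12.0))
        part = walk_cluster(g)
        seen = [n for p in part for n in p]
        assert len(seen) == len(set(seen)) == g.number_of_nodes()

    def test_clusters_never_span_components(self):
        g, cliques = clique_union([5, 6], np.random.default_rng(0))
        g.remove_edge(min(cliques[0]), min(cliques[1]))  # disconnect
        g.add_node(99)  # isolated haplotype
        for p in walk_cluster(g):
            comps = [c for c in nx.connected_components(g) if p <= c]
            assert len(comps) == 1

    def test_deterministic_across_runs_and_node_insertion_order(self):
        rng = np.random.default_rng(11)
        seen = {}
        for u, v, w in zip(rng.integers(0, 30, 120), rng.integers(0, 30, 120), rng.uniform(3.1, 9, 120)):
            if u != v:
                seen.setdefault(frozenset((int(u), int(v))), float(w))
        edges = [(min(k), max(k), w) for k, w in seen.items()]
        g1 = weighted_graph(edges)
        g2 = weighted_graph(list(reversed(edges)))
        assert walk_cluster(g1) == walk_cluster(g2)

    def test_rejects_nonpositive_steps(self):
        with pytest.raises(ValueError):
            walk_cluster(nx.Graph(), steps=0)

    def test_agrees_with_igraph_walktrap_on_clique_unions(self):
        # independent reference implementation of the same community method
        import igraph as ig

        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            g, cliques = clique_union(rng.integers(5, 15, size=3), rng)
            nodes = sorted(g.nodes)
            A = nx.to_numpy_array(g, nodelist=nodes)
            igg = ig.Graph.Weighted_Adjacency(A.tolist(), mode="undirected", attr="weight")
            theirs = igg.community_walktrap(weights="weight", steps=3).as_clustering()
            theirs_parts = sorted(sorted(nodes[i] for i in c) for c in theirs)
            ours_parts = sorted(sorted(p) for p in walk_cluster(g))
            want = sorted(sorted(c) for c in cliques)
            assert ours_parts == want == theirs_parts


class TestRefine:
    def test_large_sparse_cluster_split_into_dense_halves(self):
        # two 20-cliques with 4 bridges: density 384/780 < 0.5, size 40 > 30
        g = nx.Graph()
        for base in (0, 100):
            for u, v in itertools.combinations(range(base, base + 20), 2):
                g.add_edge(u, v, weight=8.0)
        for k in range(4):
            g.add_edge(k, 100 + k, weight=3.5)
        merged = set(g.nodes)
        assert pair_density(merged, g) < 0.5
        clusters = refine([merged], g, ClusteringConfig())
        assert sorted(len(c.members) for c in clusters) == [20, 20]
        for c in clusters:
            assert c.converged
            assert pair_density(c.members, g) == 1.0

    def test_small_sparse_cluster_untouched(self):
        # 10 nodes, density 0.3 but size <= 30: size gate keeps it whole
        rng = np.random.default_rng(3)
        g = nx.Graph()
        pairs = list(itertools.combinations(range(10), 2))
        rng.shuffle(pairs)
        for u, v in pairs[: int(0.3 * len(pairs))]:
            g.add_edge(u, v, weight=5.0)
        g.add_nodes_from(range(10))
        members = set(range(10))
        clusters = refine([members], g, ClusteringConfig())
        assert [c.members for c in clusters] == [frozenset(members)]
        assert clusters[0].converged

    def test_unsplittable_sparse_cluster_hits_iteration_cap(self):
        # a 31-node star is sparse (density 30/465) but has no
        # positive-modularity split, so the walktrap keeps it whole each round
        g = nx.star_graph(30)
        nx.set_edge_attributes(g, 10.0, "weight")
        members = set(g.nodes)
        assert len(walk_cluster(g)) == 1
        clusters = refine([members], g, ClusteringConfig())
        (c,) = clusters
        assert not c.converged
        assert c.refine_iterations_used == 5

    def test_reported_clusters_satisfy_contract_on_random_graphs(self):
        config = ClusteringConfig()
        for seed in range(25):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(20, 60))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.05, 0.5)), seed=seed)
            for u, v in g.edges:
                g.edges[u, v]["weight"] = float(rng.uniform(3.1, 15.0))
            clusters = refine(walk_cluster(g), g, config)
            seen = [m for c in clusters for m in c.members]
            assert len(seen) == len(set(seen)) == g.number_of_nodes()
            for c in clusters:
                ok = (
                    len(c.members) <= config.max_size
                    or pair_density(c.members, g) >= config.min_density
                    or (not c.converged and c.refine_iterations_used == config.max_refine_iter)
                )
                assert ok


class TestReportingAndSeeds:
    def _clusters(self):
        mk = lambda cid, names: Cluster(cid, frozenset(HaplotypeNode(n, 1) for n in names))
        return [mk("c1", ["C1", "B1", "B2", "B3"]), mk("c2", ["X1", "X2", "X3"]), mk("c3", ["Y1", "Y2"])]

    def test_small_clusters_dropped_from_report(self):
        kept = reportable(self._clusters(), ClusteringConfig())
        assert [c.cluster_id for c in kept] == ["c1", "c2"]

    def test_seed_selection(self):
        clusters = self._clusters()
        assert [c.cluster_id for c in clusters_containing(clusters, {"C1"})] == ["c1"]
        assert clusters_containing(clusters, set()) == []
        assert clusters_containing(clusters, {"C1"}, min_seeds=2) == []
        assert [c.cluster_id for c in clusters_containing(clusters, {"C1", "B1"}, min_seeds=2)] == ["c1"]


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"min_cm": 0.0},
            {"walk_steps": 0},
            {"min_density": 0.0},
            {"min_density": 1.5},
            {"max_refine_iter": 0},
            {"min_cluster_size": 0},
            {"cross_cluster_min_cm": -1.0},
        ],
    )
    def test_invalid_thresholds_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ClusteringConfig(**kwargs)
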