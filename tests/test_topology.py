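"""Components, clique enumeration, centralities, MCL."""

import itertools

import networkx as nx
import pytest

from crossnet import (
    centralities,
    clique_k_subnetwork,
    connected_subgraphs,
    maximal_cliques,
    mcl,
    score_and_rank,
)
from crossnet.errors import ParameterError

from _oracles import (
    exhaustive_maximal_cliques,
    flood_fill_components,
    path_enumeration_betweenness,
)
from conftest import random_graph


class TestConnectedSubgraphs:
    def test_edgeless_graph_has_zero_subgraphs(self):
        g = nx.empty_graph(5)
        n, comps = connected_subgraphs(g)
        assert n == 0 and len(comps) == 5

    def test_two_triangles(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        assert connected_subgraphs(g)[0] == 2

    def test_min_size_one_counts_isolates(self):
        g = nx.empty_graph(3)
        assert connected_subgraphs(g, min_size=1)[0] == 3

    def test_matches_flood_fill(self, rng):
        for _ in range(20):
            g = random_graph(rng, 40, 0.05)
            _, comps = connected_subgraphs(g)
            oracle = flood_fill_components(list(g.nodes), list(g.edges))
            assert sorted(map(sorted, comps)) == sorted(map(sorted, oracle))


class TestMaximalCliques:
    def test_triangle(self):
        assert maximal_cliques(nx.complete_graph(3)) == [(0, 1, 2)]

    def test_path(self):
        g = nx.path_graph(3)
        assert maximal_cliques(g) == [(0, 1), (1, 2)]

    def test_matches_exhaustive_enumeration_small(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 11))
            g = random_graph(rng, n, float(rng.uniform(0.1, 0.7)))
            assert maximal_cliques(g) == exhaustive_maximal_cliques(n, set(g.edges))


class TestCliqueK:
    def test_k5_complete_graph_has_five_4_cliques(self):
        cs = clique_k_subnetwork(nx.complete_graph(5), 4)
        assert len(cs.cliques) == 5
        assert len(cs.subnetwork_nodes) == 5 and len(cs.subnetwork_edges) == 10

    def test_triangle_has_no_4_cliques(self):
        cs = clique_k_subnetwork(nx.complete_graph(3), 4)
        assert len(cs.cliques) == 0 and not cs.subnetwork_nodes

    def test_two_overlapping_5_cliques_union(self):
        # two 5-cliques sharing nodes {3, 4}: 8 nodes, 2*10 edges minus the shared one
        g = nx.Graph()
        a, b = [0, 1, 2, 3, 4], [3, 4, 5, 6, 7]
        g.add_edges_from(itertools.combinations(a, 2))
        g.add_edges_from(itertools.combinations(b, 2))
        expected_edges = set(map(frozenset, itertools.combinations(a, 2))) | set(
            map(frozenset, itertools.combinations(b, 2))
        )
        assert len(expected_edges) == 19
        cs = clique_k_subnetwork(g, 5)
        assert sorted(cs.cliques) == [tuple(a), tuple(b)]
        assert len(cs.subnetwork_nodes) == 8 and cs.subnetwork_edges == expected_edges

    def test_removing_a_clique_edge_removes_the_clique(self):
        g = nx.complete_graph(5)
        assert len(clique_k_subnetwork(g, 5).cliques) == 1
        g.remove_edge(0, 1)
        assert len(clique_k_subnetwork(g, 5).cliques) == 0

    def test_every_reported_clique_is_complete(self, rng):
        g = random_graph(rng, 25, 0.35)
        cs = clique_k_subnetwork(g, 4)
        for c in cs.cliques:
            assert all(g.has_edge(u, v) for u, v in itertools.combinations(c, 2))

    def test_k_below_three_rejected(self):
        with pytest.raises(ParameterError):
            clique_k_subnetwork(nx.complete_graph(4), 2)


class TestCentralities:
    def test_star_closed_form(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        tbl = centralities(g).set_index("node")
        assert tbl.loc[0, "betweenness"] == pytest.approx(6.0)  # C(4,2)
        assert all(tbl.loc[leaf, "betweenness"] == 0 for leaf in range(1, 5))
        assert tbl.loc[0, "closeness"] == pytest.approx(1.0)
        assert tbl.loc[1, "closeness"] == pytest.approx((1 + 3 * 0.5) / 4)

    def test_path_middle_node(self):
        tbl = centralities(nx.path_graph(3)).set_index("node")
        assert tbl.loc[1, "betweenness"] == pytest.approx(1.0)

    def test_isolated_node_closeness_zero(self):
        tbl = centralities(nx.empty_graph(3)).set_index("node")
        assert (tbl["closeness"] == 0).all() and (tbl["betweenness"] == 0).all()

    def test_degree_one_nodes_have_zero_betweenness(self, rng):
        g = random_graph(rng, 20, 0.1)
        tbl = centralities(g)
        low = tbl[tbl["degree"] <= 1]
        assert (low["betweenness"] == 0).all()

    def test_matches_path_enumeration(self, rng):
        for _ in range(15):
            n = int(rng.integers(4, 9))
            g = random_graph(rng, n, 0.4)
            tbl = centralities(g).set_index("node")
            oracle = path_enumeration_betweenness(n, set(g.edges))
            for v in range(n):
                assert tbl.loc[v, "betweenness"] == pytest.approx(oracle[v], abs=1e-9)


class TestMCL:
    def test_disjoint_triangles_are_two_clusters(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        res = mcl(g)
        assert sorted(map(sorted, res.clusters)) == [[0, 1, 2], [3, 4, 5]]

    def test_isolated_node_is_singleton_cluster(self):
        res = mcl(nx.empty_graph(1))
        assert res.clusters == [{0}]

    def test_bridged_six_cliques_split_at_the_bridge(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        g.add_edge(0, 6)
        res = mcl(g, inflation=2.0)
        assert sorted(map(sorted, res.clusters)) == [list(range(6)), list(range(6, 12))]
        assert res.converged

    def test_clusters_partition_nodes(self, rng):
        g = random_graph(rng, 30, 0.1)
        res = mcl(g)
        seen = [v for c in res.clusters for v in c]
        assert sorted(seen) == sorted(g.nodes)
        assert len(seen) == len(set(seen))

    def test_disjoint_union_clusters_like_the_parts(self, rng):
        g1 = random_graph(rng, 10, 0.4)
        g2 = random_graph(rng, 10, 0.4)
        both = mcl(nx.disjoint_union(g1, g2))
        parts = mcl(g1).clusters + [
            {v + 10 for v in c} for c in mcl(g2).clusters
        ]
        assert sorted(map(sorted, both.clusters)) == sorted(map(sorted, parts))

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ParameterError):
            mcl(nx.complete_graph(3), inflation=1.0)


class TestRanking:
    def test_star_center_ranked_first(self):
        g = nx.star_graph(4)
        tbl = score_and_rank(g, {v: 1.0 for v in g.nodes})
        assert tbl.iloc[0]["node"] == 0

    def test_score_breaks_topological_ties(self):
        g = nx.Graph()
        g.add_edges_from([("A", "B"), ("C", "D")])
        tbl = score_and_rank(g, {"A": 1.0, "B": 1.0, "C": 5.0, "D": 1.0})
        assert tbl.iloc[0]["node"] == "C"

    def test_ranking_is_a_permutation(self, rng):
        g = random_graph(rng, 25, 0.1)
        tbl = score_and_rank(g)
        assert sorted(tbl["node"]) == sorted(g.nodes)
        assert list(tbl["rank"]) == list(range(1, 26))
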