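"""Interactome loading and QQPPI/L1PPI query-network construction."""

import itertools

import networkx as nx
import pytest

from crossnet import (
    CandidateGeneSet,
    Interactome,
    MediatorOverlap,
    assemble_networks,
    build_l1ppi,
    build_qqppi,
    load_interactome,
    mediator_overlap,
)
from crossnet.errors import ParameterError, ParseError

from conftest import random_graph, relabel_str


class TestLoader:
    def test_reversed_duplicates_collapse(self, tmp_path):
        f = tmp_path / "e.tsv"
        f.write_text("A\tB\nB\tA\n")
        net = load_interactome(f)
        assert net.edges == {frozenset({"A", "B"})}

    def test_self_loop_dropped(self, tmp_path):
        f = tmp_path / "e.tsv"
        f.write_text("A\tA\nA\tB\n")
        net = load_interactome(f)
        assert net.edges == {frozenset({"A", "B"})}

    def test_sif_multi_target_line(self, tmp_path):
        f = tmp_path / "e.sif"
        f.write_text("A\tinteracts\tB\tC\nD\n")
        net = load_interactome(f)
        assert net.edges == {frozenset({"A", "B"}), frozenset({"A", "C"})}
        assert "D" in net.nodes  # isolated node survives

    def test_malformed_line_reports_line_number(self, tmp_path):
        f = tmp_path / "e.tsv"
        f.write_text("A\tB\nonlyone\n")
        with pytest.raises(ParseError, match=":2"):
            load_interactome(f)

    def test_symbols_uppercased_by_default(self, tmp_path):
        f = tmp_path / "e.tsv"
        f.write_text("abc\tdef\n")
        assert load_interactome(f).nodes == {"ABC", "DEF"}


class TestQQPPI:
    def test_direct_edge_kept(self):
        net = Interactome.from_edges([("A", "B")])
        qq = build_qqppi(net, {"A", "B"})
        assert qq.nodes == {"A", "B"} and qq.edges == {frozenset({"A", "B"})}

    def test_unconnected_queries_are_isolated(self):
        net = Interactome.from_edges([("A", "C"), ("B", "D")])
        qq = build_qqppi(net, {"A", "B"})
        assert qq.nodes == {"A", "B"} and not qq.edges

    def test_matches_all_pairs_membership_oracle(self, rng):
        for _ in range(20):
            g = relabel_str(random_graph(rng, 30, 0.2))
            net = Interactome(g)
            queries = set(rng.choice(sorted(g.nodes), size=10, replace=False))
            qq = build_qqppi(net, queries)
            expected = {
                frozenset({a, b})
                for a, b in itertools.combinations(sorted(queries), 2)
                if g.has_edge(a, b)
            }
            assert qq.edges == expected and qq.nodes == queries


class TestL1PPI:
    def test_only_query_neighbors_join(self):
        net = Interactome.from_edges([("A", "B"), ("B", "C")])
        l1 = build_l1ppi(net, {"A"})
        assert l1.nodes == {"A", "B"} and l1.edges == {frozenset({"A", "B"})}

    def test_mediator_mediator_edge_retained(self):
        net = Interactome.from_edges([("A", "B"), ("A", "C"), ("B", "C")])
        l1 = build_l1ppi(net, {"A"})
        assert l1.nodes == {"A", "B", "C"} and len(l1.edges) == 3

    def test_star_variant_drops_mediator_edges(self):
        net = Interactome.from_edges([("A", "B"), ("A", "C"), ("B", "C")])
        l1 = build_l1ppi(net, {"A"}, mediator_edges=False)
        assert l1.edges == {frozenset({"A", "B"}), frozenset({"A", "C"})}

    def test_qqppi_is_restriction_of_l1ppi(self, rng):
        for _ in range(100):
            g = relabel_str(random_graph(rng, 25, 0.15))
            net = Interactome(g)
            k = int(rng.integers(1, 10))
            queries = set(rng.choice(sorted(g.nodes), size=k, replace=False))
            qq, l1 = build_qqppi(net, queries), build_l1ppi(net, queries)
            assert qq.nodes <= l1.nodes
            assert qq.edges == {e for e in l1.edges if e <= queries}

    def test_idempotent_on_own_node_set(self, rng):
        g = relabel_str(random_graph(rng, 30, 0.15))
        net = Interactome(g)
        queries = set(rng.choice(sorted(g.nodes), size=8, replace=False))
        l1 = build_l1ppi(net, queries)
        again = Interactome(l1.graph.copy())
        assert build_l1ppi(again, l1.nodes).edges == l1.edges

    def test_every_mediator_touches_a_query(self, rng):
        g = relabel_str(random_graph(rng, 40, 0.08))
        net = Interactome(g)
        queries = set(rng.choice(sorted(g.nodes), size=6, replace=False))
        l1 = build_l1ppi(net, queries)
        for m in l1.mediators:
            assert any(n in queries for n in l1.graph.neighbors(m))


class TestAssemble:
    def test_absent_gene_isolated_in_both(self):
        net = Interactome.from_edges([("A", "B")])
        cs = CandidateGeneSet("s", "schizophrenia", {"A": "over", "ZZZ": "under"})
        qq, l1 = assemble_networks(net, cs)
        assert "ZZZ" in qq.nodes and qq.graph.degree("ZZZ") == 0
        assert "ZZZ" in l1.nodes and l1.graph.degree("ZZZ") == 0

    def test_annotations_carried_onto_nodes(self):
        net = Interactome.from_edges([("A", "B")])
        cs = CandidateGeneSet("s", "schizophrenia", {"A": "over", "B": "under"})
        qq, _ = assemble_networks(net, cs)
        assert qq.annotations["A"]["direction"] == "over"
        assert qq.annotations["B"]["disease"] == "schizophrenia"

    def test_planted_clique_survives_in_both_networks(self, planted_interactome):
        net, truth = planted_interactome
        clique = truth.planted_cliques[0]
        members = {g: "over" for g in clique}
        qq, l1 = assemble_networks(net, CandidateGeneSet("s", "schizophrenia", members))
        want = {frozenset(p) for p in itertools.combinations(sorted(clique), 2)}
        assert want <= qq.edges and want <= l1.edges

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ParameterError):
            assemble_networks(Interactome(nx.Graph()), CandidateGeneSet("s", "other", {}))


class TestMediatorOverlap:
    def test_identical_lists_share_everything(self):
        net = Interactome.from_edges([("A", "M1"), ("B", "M2")])
        ov = mediator_overlap(net, [{"A", "B"}, {"A", "B"}, {"A", "B"}])
        assert ov.shared_percentages == [100.0, 100.0, 100.0]
        assert ov.common_all == ov.common_any_two == 2

    def test_disjoint_neighborhoods_share_nothing(self):
        net = Interactome.from_edges([("A", "M1"), ("B", "M2")])
        ov = mediator_overlap(net, [{"A"}, {"B"}])
        assert ov.common_all == 0

    def test_fewer_than_two_lists_rejected(self):
        with pytest.raises(ParameterError):
            mediator_overlap(Interactome(nx.Graph()), [{"A"}])

    def test_order_permutation_only_permutes_labels(self, rng):
        g = relabel_str(random_graph(rng, 40, 0.1))
        net = Interactome(g)
        lists = [set(rng.choice(sorted(g.nodes), size=6, replace=False)) for _ in range(3)]
        a = mediator_overlap(net, lists, labels=["x", "y", "z"])
        b = mediator_overlap(net, lists[::-1], labels=["z", "y", "x"])
        assert a.common_all == b.common_all and a.common_any_two == b.common_any_two
        assert a.interactor_counts == b.interactor_counts[::-1]

    def test_published_interactor_counts_give_15_to_46_percent(self):
        ov = MediatorOverlap.from_counts([4386, 2611, 1438], common_all=663, common_any_two=1520)
        assert ov.shared_percentages == pytest.approx([15.12, 25.39, 46.11], abs=0.01)
        assert round(min(ov.shared_percentages)) == 15
        assert round(max(ov.shared_percentages)) == 46
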