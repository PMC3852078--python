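"""Connectivity null, hypergeometric enrichment, Benjamini-Hochberg."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from crossnet import (
    AnnotationCatalog,
    Interactome,
    benjamini_hochberg,
    connectivity_null,
    empirical_percentile_top,
    gene_universe,
    hypergeom_enrich,
)
from crossnet.errors import ParameterError
from crossnet.significance import hypergeom_pvalue

from _oracles import hypergeom_tail_by_enumeration
from conftest import random_graph, relabel_str


class TestConnectivityNull:
    def test_percentile_is_rank_arithmetic(self):
        # 226 of 5000 null draws at or above the observed edge count -> top 4.52%
        null = np.concatenate([np.full(226, 40.0), np.full(4774, 10.0)])
        assert empirical_percentile_top(null, 36.0) == pytest.approx(4.52)

    def test_empty_interactome_gives_zero_stats_at_percentile_100(self):
        net = Interactome(nx.Graph())
        res = connectivity_null(net, gene_universe(50), 10, gene_universe(50)[:10],
                                n_draws=50, seed=0)
        assert res.observed == (0, 0)
        assert res.subgraphs.percentile_top == 100.0
        assert res.qqppi_edges.percentile_top == 100.0

    def test_deterministic_for_fixed_seed(self, rng):
        net = Interactome(relabel_str(random_graph(rng, 60, 0.05)))
        universe = sorted(net.nodes) + ["X1", "X2"]
        kw = dict(n_query=15, observed_queries=universe[:15], n_draws=100)
        a = connectivity_null(net, universe, seed=7, **kw)
        b = connectivity_null(net, universe, seed=7, **kw)
        assert a.qqppi_edges.__dict__ == b.qqppi_edges.__dict__
        assert a.subgraphs.__dict__ == b.subgraphs.__dict__

    def test_null_mean_stable_across_seeds(self, rng):
        net = Interactome(relabel_str(random_graph(rng, 80, 0.05)))
        universe = sorted(net.nodes)
        kw = dict(n_query=20, observed_queries=universe[:20], n_draws=400)
        a = connectivity_null(net, universe, seed=1, **kw)
        b = connectivity_null(net, universe, seed=2, **kw)
        for sa, sb in [(a.qqppi_edges, b.qqppi_edges), (a.subgraphs, b.subgraphs)]:
            se = np.hypot(sa.null_sd, sb.null_sd) / np.sqrt(400)
            assert abs(sa.null_mean - sb.null_mean) < 3 * se + 1e-9

    def test_oversized_query_rejected(self):
        with pytest.raises(ParameterError):
            connectivity_null(Interactome(nx.Graph()), ["A"], 2, ["A"], n_draws=5)

    def test_self_drawn_observed_percentile_centered(self, rng):
        # short-run calibration: observed queries drawn by the null mechanism
        net = Interactome(relabel_str(random_graph(rng, 100, 0.05)))
        universe = sorted(net.nodes)
        percs = []
        for rep in range(60):
            obs = rng.choice(universe, size=20, replace=False)
            res = connectivity_null(net, universe, 20, obs, n_draws=100, seed=1000 + rep)
            percs.append(res.qqppi_edges.percentile_top / 100)
        assert 0.4 < np.mean(percs) < 0.65  # >= comparison puts mass slightly above 1/2


class TestHypergeomEnrich:
    def test_exhaustive_draw_enumeration_universe_10(self):
        universe = gene_universe(10)
        annotated = set(universe[:5])
        # P(overlap >= 4 | query of 4): C(5,4)C(5,0)/C(10,4) = 5/210
        p = hypergeom_pvalue(4, 10, 5, 4)
        assert p == pytest.approx(5 / 210)
        oracle = hypergeom_tail_by_enumeration(universe, annotated, 4, 4)
        assert p == pytest.approx(oracle, rel=1e-12)

    def test_set_equal_to_universe_is_certain(self):
        universe = gene_universe(8)
        catalog = AnnotationCatalog.from_sets({"ALL": universe})
        tbl = hypergeom_enrich(universe[:3], catalog, universe)
        assert tbl.loc[0, "p_value"] == pytest.approx(1.0)
        assert tbl.loc[0, "overlap"] == 3

    def test_disjoint_set_and_query_p_is_one(self):
        universe = gene_universe(10)
        catalog = AnnotationCatalog.from_sets({"S": universe[:4]})
        tbl = hypergeom_enrich(universe[6:], catalog, universe)
        assert tbl.loc[0, "p_value"] == pytest.approx(1.0)

    def test_matches_fisher_one_sided(self, rng):
        for _ in range(200):
            m = int(rng.integers(10, 60))
            n_set = int(rng.integers(1, m))
            n_query = int(rng.integers(1, m))
            k_max = min(n_set, n_query)
            k = int(rng.integers(0, k_max + 1))
            if k < max(0, n_set + n_query - m):
                k = max(0, n_set + n_query - m)
            p = hypergeom_pvalue(k, m, n_set, n_query)
            table = [[k, n_set - k], [n_query - k, m - n_set - n_query + k]]
            _, p_fisher = fisher_exact(table, alternative="greater")
            assert p == pytest.approx(p_fisher, rel=1e-9)

    def test_query_outside_universe_dropped(self):
        universe = gene_universe(10)
        catalog = AnnotationCatalog.from_sets({"S": universe[:5]})
        a = hypergeom_enrich(universe[:3] + ["ALIEN"], catalog, universe)
        b = hypergeom_enrich(universe[:3], catalog, universe)
        assert a.loc[0, "p_value"] == b.loc[0, "p_value"]

    def test_empty_universe_rejected(self):
        with pytest.raises(ParameterError):
            hypergeom_enrich(["A"], AnnotationCatalog.from_sets({"S": ["A"]}), [])


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.2]) == [pytest.approx(0.2)]

    def test_hand_computed_step_up(self):
        assert benjamini_hochberg([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones_stay_ones(self):
        assert benjamini_hochberg([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_rejects_out_of_range(self):
        with pytest.raises(ParameterError):
            benjamini_hochberg([0.0, 0.5])
        with pytest.raises(ParameterError):
            benjamini_hochberg([0.5, 1.5])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0, exclude_min=False),
                    min_size=1, max_size=30))
    def test_step_up_invariants_hold_for_any_p_vector(self, p):
        q = np.array(benjamini_hochberg(p))
        p = np.array(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()  # monotone in sorted-p order

    def test_matches_statsmodels_and_dominates_raw_p(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 40)))
            q = np.array(benjamini_hochberg(p.tolist()))
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(q, q_sm)
            assert (q >= p - 1e-12).all()
            order = np.argsort(p)
            assert (np.diff(q[order]) >= -1e-12).all()
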