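"""Centralities against brute-force BFS oracles; the two-stage median screen."""

import networkx as nx
import numpy as np
import pytest

from netpharm import (
    betweenness_centrality,
    build_ppi_graph,
    closeness_centrality,
    degree_centrality,
    median_screen,
)
from netpharm.models import InteractionEdge

from oracles import oracle_betweenness, oracle_closeness, oracle_degree


def path_graph(*nodes):
    return nx.Graph(list(zip(nodes, nodes[1:])))


class TestCentralities:
    def test_degree_triangle_and_star(self):
        tri = nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])
        assert degree_centrality(tri) == {"A": 2, "B": 2, "C": 2}
        star = nx.star_graph(4)
        assert degree_centrality(star)[0] == 4
        assert all(degree_centrality(star)[i] == 1 for i in range(1, 5))

    def test_betweenness_path_and_clique(self):
        bc = betweenness_centrality(path_graph("A", "B", "C"))
        assert bc == {"A": 0.0, "B": 1.0, "C": 0.0}
        k4 = nx.complete_graph(4)
        assert all(v == 0.0 for v in betweenness_centrality(k4).values())

    def test_closeness_path_and_disjoint_edges(self):
        cc = closeness_centrality(path_graph("A", "B", "C"))
        assert cc["B"] == pytest.approx(1.0)
        assert cc["A"] == pytest.approx(2 / 3)
        # two disjoint edges, n=4: each node cc = (1/3) * (1/1) = 1/3
        g = nx.Graph([("A", "B"), ("C", "D")])
        assert all(v == pytest.approx(1 / 3) for v in closeness_centrality(g).values())

    def test_isolated_node_closeness_zero(self):
        g = nx.Graph([("A", "B")])
        g.add_node("Z")
        assert closeness_centrality(g)["Z"] == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_random_graphs_match_bfs_oracles(self, seed, random_graph_factory):
        g = random_graph_factory(seed, n_max=25)
        assert degree_centrality(g) == oracle_degree(g)
        bc, obc = betweenness_centrality(g), oracle_betweenness(g)
        cc, occ = closeness_centrality(g), oracle_closeness(g)
        for v in g.nodes:
            assert bc[v] == pytest.approx(obc[v], abs=1e-9)
            assert cc[v] == pytest.approx(occ[v], abs=1e-9)

    def test_degree_sum_is_twice_edges(self, random_graph_factory):
        g = random_graph_factory(123)
        assert sum(degree_centrality(g).values()) == 2 * g.number_of_edges()


class TestMedianScreen:
    def test_star_hand_evaluation(self):
        # degrees (4,1,1,1,1): median 1, threshold 2 -> hub = {center};
        # the singleton subgraph trivially meets all its own medians
        g = nx.star_graph(4)
        res = median_screen(g)
        assert res.hub_nodes == {0}
        assert res.core_targets == {0}
        assert res.thresholds["stage1_dc_threshold"] == 2.0

    def test_complete_graph_degenerates_to_empty(self, caplog):
        g = nx.complete_graph(5)
        with caplog.at_level("WARNING"):
            res = median_screen(g)
        assert res.hub_nodes == frozenset() and res.core_targets == frozenset()

    def test_strict_hub_excludes_exact_double(self):
        # path of 5: degrees (1,2,2,2,1), median 2 -> threshold 4; nobody
        # reaches it either way, so build a graph where dc == 2*median
        g = nx.star_graph(2)  # degrees (2,1,1), median 1, threshold 2
        assert median_screen(g, strict_hub=False).hub_nodes == {0}
        assert median_screen(g, strict_hub=True).hub_nodes == frozenset()

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            median_screen(nx.Graph())

    def test_core_subset_of_hubs_random(self, random_graph_factory):
        for seed in range(30):
            g = random_graph_factory(seed)
            res = median_screen(g)
            assert res.core_targets <= res.hub_nodes <= set(g.nodes)

    def test_planted_clique_recovered(self, study):
        g = build_ppi_graph(study.ppi_edges)
        res = median_screen(g)
        assert set(study.truth["planted_core"]) <= res.core_targets


class TestScreenInvariances:
    @pytest.mark.parametrize("seed", range(15))
    def test_label_invariance(self, seed, random_graph_factory):
        g = random_graph_factory(seed)
        relabel = {n: f"X_{n}" for n in g.nodes}
        res, res2 = median_screen(g), median_screen(nx.relabel_nodes(g, relabel))
        assert {relabel[n] for n in res.hub_nodes} == set(res2.hub_nodes)
        assert {relabel[n] for n in res.core_targets} == set(res2.core_targets)

    def test_bc_scale_invariance(self, random_graph_factory):
        # the screen compares bc to its own median, so toggling
        # normalization (a positive rescale) cannot change the outcome
        for seed in range(10):
            g = random_graph_factory(seed)
            hubs = median_screen(g).hub_nodes
            if len(hubs) < 2:
                continue
            sub = g.subgraph(hubs)
            bc_raw = betweenness_centrality(sub, normalized=False)
            bc_norm = betweenness_centrality(sub, normalized=True)
            med_raw = float(np.median(list(bc_raw.values())))
            med_norm = float(np.median(list(bc_norm.values())))
            keep_raw = {v for v in sub if bc_raw[v] >= med_raw}
            keep_norm = {v for v in sub if bc_norm[v] >= med_norm}
            assert keep_raw == keep_norm


def test_build_ppi_graph_carries_scores():
    g = build_ppi_graph([InteractionEdge("A", "B", 0.9)])
    assert g.edges["A", "B"]["combined_score"] == pytest.approx(0.9)
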