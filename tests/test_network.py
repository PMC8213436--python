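import networkx as nx
import numpy as np
import pandas as pd
import pytest

import herbnet as h
from conftest import brute_force_centralities, random_graph, small_network_config


def star(leaves=4):
    g = nx.Graph()
    g.add_edges_from(("c", f"l{i}") for i in range(leaves))
    return g


class TestBuildNetwork:
    def test_union_and_edge_restriction(self):
        tm = pd.DataFrame({"constituent": ["x"], "gene": ["b"]})
        g = h.build_network({"a"}, tm, {"c"}, [("a", "b"), ("b", "c"), ("c", "d")])
        assert set(g.nodes) == {"a", "b", "c"}
        assert set(map(frozenset, g.edges)) == {frozenset("ab"), frozenset("bc")}
        assert g.nodes["a"]["roles"] == ["anti_inflammatory"]
        assert g.nodes["b"]["roles"] == ["putative_target"]

    def test_overlapping_roles(self):
        g = h.build_network({"a"}, None, {"a"}, [])
        assert g.nodes["a"]["roles"] == ["anti_inflammatory", "disease"]

    def test_empty_union_errors(self):
        with pytest.raises(ValueError):
            h.build_network(set(), None, set(), [("a", "b")])

    def test_edgeless_network_warns(self, caplog):
        with caplog.at_level("WARNING"):
            g = h.build_network({"a"}, None, {"b"}, [("x", "y")])
        assert g.number_of_edges() == 0
        assert any("no edges" in r.message for r in caplog.records)

    def test_self_loops_and_duplicates_dropped(self):
        g = h.build_network({"a", "b"}, None, set(), [("a", "a"), ("a", "b"), ("b", "a")])
        assert g.number_of_edges() == 1

    def test_generator_bookkeeping(self):
        cfg = small_network_config(1)
        ppi, preds, lib, disease, gt = h.gen_network_inputs(cfg)
        g = h.build_network(set(gt.hub_tier[:2]), h.filter_predictions(preds), disease, ppi)
        assert g.number_of_nodes() == cfg.n_nodes
        assert g.number_of_edges() == len(ppi)  # generator emits clean in-set edges


class TestCentralities:
    def test_star(self):
        t = h.centralities(star())
        assert t.loc["c", "degree"] == 4
        assert t.loc["c", "betweenness"] == pytest.approx(6.0)
        assert t.loc["c", "closeness"] == pytest.approx(1.0)
        for leaf in ("l0", "l1", "l2", "l3"):
            assert t.loc[leaf, "degree"] == 1
            assert t.loc[leaf, "betweenness"] == pytest.approx(0.0)
            assert t.loc[leaf, "closeness"] == pytest.approx(4 / 7)

    def test_path(self):
        g = nx.path_graph(["a", "b", "c", "d"])
        t = h.centralities(g)
        assert list(t["degree"]) == [1, 2, 2, 1]
        assert t.loc["a", "closeness"] == pytest.approx(0.5)
        assert t.loc["b", "closeness"] == pytest.approx(0.75)

    def test_isolated_node(self):
        g = nx.Graph()
        g.add_node("solo")
        g.add_edge("a", "b")
        t = h.centralities(g)
        assert t.loc["solo", "degree"] == 0
        assert t.loc["solo", "betweenness"] == 0
        assert t.loc["solo", "closeness"] == 0

    @pytest.mark.parametrize("block", range(4))
    def test_matches_brute_force_oracle(self, block):
        """Exact equivalence with all-pairs path enumeration, graphs <= 12 nodes."""
        rng = np.random.default_rng(1000 + block)
        for _ in range(50):
            nodes, edges = random_graph(rng)
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            table = h.centralities(g)
            oracle = brute_force_centralities(nodes, edges)
            for n, (deg, bet, clo) in oracle.items():
                assert table.loc[n, "degree"] == deg
                assert table.loc[n, "betweenness"] == pytest.approx(bet, abs=1e-9)
                assert table.loc[n, "closeness"] == pytest.approx(clo, abs=1e-9)


class TestSelectCore:
    def test_star_selects_center(self):
        assert h.select_core(star()) == {"c"}

    def test_regular_graph_selects_nothing(self):
        assert h.select_core(nx.cycle_graph(5)) == set()

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        nodes, edges = random_graph(rng)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        mapping = {n: f"x_{n}" for n in nodes}
        g2 = nx.relabel_nodes(g, mapping)
        assert {mapping[n] for n in h.select_core(g)} == h.select_core(g2)

    def test_betweenness_rescaling_is_inert(self):
        """Any positive rescaling of betweenness leaves the selection unchanged."""
        rng = np.random.default_rng(11)
        nodes, edges = random_graph(rng)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        t = h.centralities(g)
        t2 = t.copy()
        t2["betweenness"] *= 17.3
        assert h.select_core(g, t) == h.select_core(g, t2)


class TestDensity:
    @pytest.mark.parametrize(
        "nodes,edges,rounded",
        [(2251, 53254, 0.011), (566, 23558, 0.074), (2, 1, 0.5)],
    )
    def test_printed_densities(self, nodes, edges, rounded):
        assert round(h.density(nodes, edges), 3) == rounded

    def test_ordered_pair_convention_not_unordered(self):
        """The printed study densities single out E/(N(N-1))."""
        assert round(53254 / (2251 * 2250 / 2), 3) != 0.011
        assert round(h.density(2251, 53254), 3) == 0.011

    def test_monotone_in_edges(self):
        assert h.density(100, 50) < h.density(100, 51)

    def test_too_few_nodes(self):
        with pytest.raises(ValueError):
            h.density(1, 0)


class TestExtractHubs:
    def test_containment_invariant(self, small_cfg):
        ppi, preds, lib, disease, gt = h.gen_network_inputs(small_cfg)
        g = h.build_network(set(gt.hub_tier[:2]), h.filter_predictions(preds), disease, ppi)
        res = h.extract_hubs(g, ppi)
        assert res.hubs <= res.core <= set(g.nodes)

    def test_planted_tier_recovered(self, small_cfg):
        ppi, preds, lib, disease, gt = h.gen_network_inputs(small_cfg)
        g = h.build_network(set(gt.hub_tier[:2]), h.filter_predictions(preds), disease, ppi)
        res = h.extract_hubs(g, ppi)
        assert res.core == set(gt.hub_tier) | set(gt.mid_tier)
        assert res.hubs == set(gt.hub_tier)
        assert res.stage2.density > res.stage1.density

    def test_regular_graph_skips_stage2(self):
        g = nx.cycle_graph(6)
        res = h.extract_hubs(g, list(g.edges))
        assert res.core == set() and res.hubs == set()
        assert res.stage2 is None
        assert any("skipped" in w for w in res.warnings)

    def test_density_warning_when_not_increasing(self):
        # a star's core is the center alone -> stage 2 skipped; use two hubs
        g = nx.Graph()
        g.add_edges_from([("h1", "h2")])
        g.add_edges_from(("h1", f"a{i}") for i in range(6))
        g.add_edges_from(("h2", f"b{i}") for i in range(6))
        res = h.extract_hubs(g, list(g.edges))
        if res.stage2 is not None and res.stage2.density < res.stage1.density:
            assert any("density" in w for w in res.warnings)
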