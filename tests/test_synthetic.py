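import numpy as np
import pandas as pd
import pytest

import herbnet as h
from conftest import small_network_config


class TestDeterminism:
    def test_library_features(self):
        cfg = h.GeneratorConfig(seed=17)
        a = h.gen_library_and_features(cfg)
        b = h.gen_library_and_features(cfg)
        assert a[0] == b[0]
        assert a[1] == b[1]

    def test_counts(self):
        cfg = h.GeneratorConfig(seed=17, n_genes=400, n_up1=10, n_down1=10,
                                n_up2=5, n_down2=5, n_counter=4)
        a, _ = h.gen_counts(cfg)
        b, _ = h.gen_counts(cfg)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_network_and_genesets(self):
        cfg = small_network_config(17)
        a = h.gen_network_inputs(cfg)
        b = h.gen_network_inputs(cfg)
        assert a[0] == b[0]
        pd.testing.assert_frame_equal(a[1], b[1])
        sa, ua, _ = h.gen_genesets(cfg)
        sb, ub, _ = h.gen_genesets(cfg)
        assert sa == sb and ua == ub

    def test_streams_independent(self):
        """Changing count sizes never perturbs the network stream."""
        c1 = small_network_config(5)
        import dataclasses

        c2 = dataclasses.replace(c1, n_genes=777)
        assert h.gen_network_inputs(c1)[0] == h.gen_network_inputs(c2)[0]

    def test_different_seeds_differ(self):
        a, _, _ = h.gen_library_and_features(h.GeneratorConfig(seed=1))
        b, _, _ = h.gen_library_and_features(h.GeneratorConfig(seed=2))
        assert [r.formula for r in a] != [r.formula for r in b]


class TestLibraryFeatures:
    def test_reference_compounds_always_present(self):
        lib, _, _ = h.gen_library_and_features(h.GeneratorConfig(seed=3))
        by_name = {r.name: r.formula for r in lib}
        assert by_name["baohuoside VI"] == "C39H50O19"
        assert by_name["akebiasaponin D"] == "C47H76O18"

    def test_noiseless_features_annotate_exactly(self):
        cfg = h.GeneratorConfig(seed=4, mz_noise_mda=0.0)
        lib, feats, gt = h.gen_library_and_features(cfg)
        for f, src in zip(feats, gt.feature_sources):
            assert f.mz == pytest.approx(src["theoretical_mz"], abs=1e-9)

    def test_mz_grid_separation(self):
        cfg = h.GeneratorConfig(seed=5)
        lib, _, _ = h.gen_library_and_features(cfg)
        grid = sorted(
            rule.mz(h.formula_mass(r.formula))
            for r in lib
            for rule in h.ADDUCTS.values()
        )
        gaps = np.diff(grid) * 1e3
        assert gaps.min() >= cfg.min_mz_separation_mda - 1e-6


class TestCounts:
    def test_group_layout(self):
        cm, _ = h.gen_counts(h.GeneratorConfig(seed=6, n_genes=1000))
        assert sorted(set(cm.groups)) == ["Con", "TNF", "TNF+WBT"]
        assert all(len(cm.samples_in(g)) == 3 for g in set(cm.groups))

    def test_ground_truth_bookkeeping(self):
        cfg = h.GeneratorConfig(seed=7)
        cm, gt = h.gen_counts(cfg)
        assert len(gt.deg_up1) == cfg.n_up1
        assert len(gt.deg_down1) == cfg.n_down1
        assert len(gt.deg_up2) == cfg.n_up2
        assert len(gt.deg_down2) == cfg.n_down2
        assert len(gt.counter_regulated) == cfg.n_counter
        assert set(gt.counter_regulated) <= set(gt.deg_up1) | set(gt.deg_down1)
        # counter genes flip direction in contrast 2
        assert set(gt.counter_regulated) <= set(gt.deg_up2) | set(gt.deg_down2)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            h.GeneratorConfig(n_genes=100)  # planted DEGs exceed gene count
        with pytest.raises(ValueError):
            h.GeneratorConfig(n_counter=10**6)


class TestNetworkInputs:
    def test_edge_and_node_bookkeeping(self, small_cfg):
        ppi, preds, lib, disease, gt = h.gen_network_inputs(small_cfg)
        nodes = {u for e in ppi for u in e}
        assert len(gt.hub_tier) == small_cfg.n_hub_tier
        assert len(gt.mid_tier) == small_cfg.n_mid_tier
        assert len(nodes) <= small_cfg.n_nodes
        assert not set(gt.hub_tier) & set(gt.mid_tier)
        # no self-loops, no duplicates
        assert all(u != v for u, v in ppi)
        assert len({frozenset(e) for e in ppi}) == len(ppi)

    def test_planted_frequencies_match_rows(self, small_cfg):
        ppi, preds, lib, disease, gt = h.gen_network_inputs(small_cfg)
        kept = h.filter_predictions(preds)
        hubs = set(gt.hub_tier)
        for c, expected in gt.hub_frequencies.items():
            got = kept[(kept.constituent == c) & kept.gene.isin(hubs)]["gene"].nunique()
            assert got == expected

    def test_key_block_has_top_contents(self, small_cfg):
        _, _, lib, _, gt = h.gen_network_inputs(small_cfg)
        contents = lib.set_index("constituent")["content"]
        key = set(gt.key_constituents)
        assert contents[list(key)].min() > contents.drop(list(key)).max()


class TestGenesets:
    def test_gmt_round_trip_bytes(self, tmp_path):
        cfg = h.GeneratorConfig(seed=8)
        sets, uni, gt = h.gen_genesets(cfg)
        p1, p2 = tmp_path / "a.gmt", tmp_path / "b.gmt"
        from herbnet import io as hio

        hio.write_gmt(sets, p1)
        again, _ = hio.read_gmt(p1)
        hio.write_gmt(again, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert again == sets

    def test_planted_set_contains_hub_genes(self):
        cfg = h.GeneratorConfig(seed=9)
        hubs = [f"hub{i:03d}" for i in range(cfg.n_hub_tier)]
        sets, uni, gt = h.gen_genesets(cfg, hub_genes=hubs)
        planted = sets[gt.enriched_set]
        coverage = len(planted & set(hubs)) / len(hubs)
        assert coverage >= cfg.planted_set_coverage - 0.05


def test_generate_all_is_coherent():
    bundle = h.generate_all(h.GeneratorConfig(seed=10))
    gt = bundle["ground_truth"]
    gene_pool = set(bundle["counts"].counts.index)
    assert set(gt.hub_tier) <= gene_pool
    assert set(gt.counter_regulated) <= gene_pool
    # constituents reuse compound names, and contents equal MS responses
    names = {r.name for r in bundle["library"]}
    assert set(gt.key_constituents) <= names
    resp = {r.name: r.response for r in bundle["library"]}
    for c, content in gt.contents.items():
        assert resp[c] == pytest.approx(content)
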