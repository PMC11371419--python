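"""Generator properties: determinism, planted structure, calibration hooks."""

import numpy as np
import pytest

from ecoconverge.phylo import branch_key
from ecoconverge.synth import (
    SimConfig,
    gene_truth_table,
    simulate_annotations,
    simulate_dataset,
    simulate_rate_matrix,
    simulate_selection_matrix,
    simulate_time_tree,
)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimConfig(pi0=1.5)
        with pytest.raises(ValueError):
            SimConfig(mu_fg=0.5)
        with pytest.raises(ValueError):
            SimConfig(n_taxa=29)  # ecomorph sizes + outgroups mismatch

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(seed=3, n_genes=123, lambda_age=0.1)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SimConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg


class TestTree:
    def test_ultrametric_small(self):
        cfg = SimConfig(
            seed=1, n_taxa=6, n_outgroup=2,
            ecomorph_sizes={"gleaner": 2, "trawler": 1, "aerial_hawker": 1},
        )
        tree, eco, reg = simulate_time_tree(cfg)
        depths = [tree.depth_of_tip(t) for t in tree.tips]
        assert max(depths) - min(depths) < 1e-6

    def test_deterministic_newick(self):
        t1, _, _ = simulate_time_tree(SimConfig(seed=8))
        t2, _, _ = simulate_time_tree(SimConfig(seed=8))
        assert t1.to_newick() == t2.to_newick()

    def test_ecomorphs_repeatedly_evolved(self):
        tree, eco, _ = simulate_time_tree(SimConfig(seed=8))
        clades = set(tree.branch_ids(include_root=True))
        for group in ("gleaner", "trawler", "aerial_hawker"):
            members = frozenset(s for s, e in eco.items() if e == group)
            assert len(members) >= 2
            assert members not in clades  # not monophyletic

    def test_root_age_and_outgroups(self):
        cfg = SimConfig(seed=2)
        tree, eco, reg = simulate_time_tree(cfg)
        assert tree.depth_of_tip("Outgroup_sp08") == pytest.approx(cfg.root_age, rel=1e-6)
        assert sum(1 for e in eco.values() if e == "outgroup") == cfg.n_outgroup

    def test_yule_growth_rate(self):
        # lineage count through time grows exponentially for a pure-birth
        # process: log(n(t)) vs t roughly linear across the tree depth
        tree, _, _ = simulate_time_tree(SimConfig(seed=4))
        cfg = SimConfig(seed=4)
        depth = cfg.crown_age
        # count lineages at a grid of times within the ingroup radiation
        ingroup = {t for t in tree.tips if t.startswith("Myotis_")}
        events = []
        for bid in tree.branch_ids(include_root=True):
            if len(bid) > 1 and bid < ingroup:
                sub = sorted(bid)
                age = tree.node_age(sub[0], sub[-1]).age
                events.append(age)
        # number of splits increases toward the present (more recent nodes)
        recent = sum(1 for a in events if a < depth / 2)
        old = sum(1 for a in events if a >= depth / 2)
        assert recent > old


class TestRateMatrix:
    def test_null_chain_proportional(self):
        cfg = SimConfig(seed=3, n_genes=20, sigma=0.0, mu_fg=1.0, absent_rate=0.0,
                        gene_rate_sigma=0.0)
        tree, eco, _ = simulate_time_tree(cfg)
        rates = simulate_rate_matrix(tree, cfg, eco)
        times = np.array([tree.branch_length_of(b) for b in tree.branch_ids()])
        row = rates.data.iloc[0].to_numpy()
        ratio = row / times
        assert np.allclose(ratio, ratio[0])

    def test_foreground_acceleration_visible(self):
        cfg = SimConfig(seed=5, n_genes=300, mu_fg=3.0, absent_rate=0.0)
        tree, eco, _ = simulate_time_tree(cfg)
        truth = gene_truth_table(cfg)
        rates = simulate_rate_matrix(tree, cfg, eco, truth)
        conv = truth.index[truth.ecomorph == "trawler"]
        fg_cols = [branch_key(frozenset([s])) for s, e in eco.items() if e == "trawler"]
        bg_cols = [c for c in rates.data.columns if c not in fg_cols and "|" not in c]
        times = {branch_key(b): tree.branch_length_of(b) for b in tree.branch_ids()}
        fg_rate = np.nanmean(
            [rates.data.loc[g, c] / times[c] for g in conv for c in fg_cols]
        )
        bg_rate = np.nanmean(
            [rates.data.loc[g, c] / times[c] for g in conv for c in bg_cols]
        )
        assert fg_rate > 2.0 * bg_rate

    def test_deterministic(self):
        cfg = SimConfig(seed=6, n_genes=30)
        tree, eco, _ = simulate_time_tree(cfg)
        r1 = simulate_rate_matrix(tree, cfg, eco)
        r2 = simulate_rate_matrix(tree, cfg, eco)
        assert r1.data.equals(r2.data)


class TestSelectionMatrix:
    def test_empty_when_nothing_planted(self):
        cfg = SimConfig(seed=7, n_genes=60, pi0=0.0, rho_conv=0.0, absent_rate=0.0)
        tree, eco, reg = simulate_time_tree(cfg)
        matrix, _ = simulate_selection_matrix(tree, cfg, eco, reg)
        assert int((matrix.data == 1.0).sum().sum()) == 0

    def test_full_sharing_without_age_decay(self):
        cfg = SimConfig(seed=7, n_genes=60, pi0=0.0, lambda_age=0.0, p_fg=1.0,
                        absent_rate=0.0)
        tree, eco, reg = simulate_time_tree(cfg)
        truth = gene_truth_table(cfg)
        matrix, _ = simulate_selection_matrix(tree, cfg, eco, reg, truth)
        for gene, row in truth[truth.convergent].iterrows():
            for sp, e in eco.items():
                if e == row["ecomorph"]:
                    assert matrix.data.loc[gene, branch_key(frozenset([sp]))] == 1.0

    def test_reader_consistency_selected_iff_planted(self, small_sim):
        # calls reconstructed from emitted p-values equal the matrix
        from ecoconverge.screen import apply_fdr, build_selection_matrix

        calls = apply_fdr(small_sim.screen_records, alpha=small_sim.config.alpha)
        rebuilt = build_selection_matrix(
            calls, small_sim.matrix.meta, genes=small_sim.matrix.genes
        )
        assert rebuilt.data.equals(small_sim.matrix.data)

    def test_baseline_frequency_near_pi0(self):
        cfg = SimConfig(seed=9, n_genes=2000, rho_conv=0.0, pi0=0.02, absent_rate=0.0)
        tree, eco, reg = simulate_time_tree(cfg)
        matrix, _ = simulate_selection_matrix(tree, cfg, eco, reg)
        freq = float((matrix.data == 1.0).to_numpy().mean())
        n_cells = matrix.data.size
        half = 2.576 * np.sqrt(0.02 * 0.98 / n_cells)
        assert abs(freq - 0.02) < half

    def test_deterministic(self):
        cfg = SimConfig(seed=10, n_genes=40)
        tree, eco, reg = simulate_time_tree(cfg)
        m1, r1 = simulate_selection_matrix(tree, cfg, eco, reg)
        m2, r2 = simulate_selection_matrix(tree, cfg, eco, reg)
        assert m1.data.equals(m2.data)
        assert r1 == r2


class TestAnnotations:
    def test_deterministic_gmt(self, tmp_path):
        from ecoconverge.enrichment import write_gmt

        cfg = SimConfig(seed=11, n_genes=300)
        a1, p1 = simulate_annotations(cfg)
        a2, p2 = simulate_annotations(cfg)
        assert a1 == a2 and p1 == p2
        write_gmt(a1, tmp_path / "a.gmt")
        write_gmt(a2, tmp_path / "b.gmt")
        assert (tmp_path / "a.gmt").read_text() == (tmp_path / "b.gmt").read_text()

    def test_no_planting_at_effect_one(self):
        cfg = SimConfig(seed=12, n_genes=300, planted_effect=1.0)
        ann, planted = simulate_annotations(cfg)
        assert planted == []

    def test_planted_term_enriched_in_convergent_pool(self):
        cfg = SimConfig(seed=13, n_genes=500, planted_effect=8.0)
        truth = gene_truth_table(cfg)
        ann, planted = simulate_annotations(cfg, truth)
        conv = set(truth.index[truth.convergent])
        term = planted[0]
        frac_planted = len(ann[term] & conv) / len(ann[term])
        others = [t for t in ann if t not in planted]
        frac_other = np.mean([len(ann[t] & conv) / len(ann[t]) for t in others])
        assert frac_planted > 2 * frac_other


def test_demo_fixture_loads_and_is_consistent():
    from ecoconverge.synth import load_demo_tree

    tree, eco, reg = load_demo_tree()
    assert len(tree.tips) == 30
    assert tree.is_ultrametric(1e-6)
    assert set(eco) == tree.tips and set(reg) == tree.tips
    clades = set(tree.branch_ids(include_root=True))
    for group in ("gleaner", "trawler", "aerial_hawker"):
        members = frozenset(s for s, e in eco.items() if e == group)
        assert members not in clades


def test_dataset_parses_through_all_readers(tmp_path, small_sim):
    """Generative consistency: everything written is readable back."""
    from ecoconverge import phylo, rer, screen
    from ecoconverge.convergence import read_omega_c_tsv
    from ecoconverge.enrichment import read_gmt
    from ecoconverge.synth import write_dataset

    paths = write_dataset(small_sim, tmp_path)
    tree = phylo.read_tree(paths["tree"])
    assert tree.tips == small_sim.tree.tips
    eco = phylo.read_group_map(paths["ecomorphs"])
    assert eco == small_sim.ecomorph_map
    rates = rer.RateMatrix.from_tsv(paths["rates"])
    assert rates.data.shape == small_sim.rates.data.shape
    records, unresolved = screen.read_screen_results([paths["screen"]], tree)
    assert not unresolved
    assert read_gmt(paths["annotations"]) == {
        t: set(g) for t, g in small_sim.annotations.items()
    }
    assert len(read_omega_c_tsv(paths["omega_c"])) == len(small_sim.omega_records)
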