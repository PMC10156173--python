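import hashlib
from pathlib import Path

import numpy as np
import pytest

from concord import backbone as bb
from concord import consensus as cons
from concord import phylo_core as pc
from concord import simulate as sim
from concord.motif import lxnxlr_spec, score_motif


def vertical_config(seed, **kw):
    defaults = dict(p_hgt=0.0, p_duplication=0.0, p_nni_noise=0.0,
                    missingness=0.0)
    defaults.update(kw)
    return sim.SimConfig(seed=seed, **defaults)


class TestSpeciesTree:
    def test_backbone_concordant_by_construction(self):
        for seed in (1, 2, 3):
            cfg = sim.SimConfig(seed=seed, n_gloeo=2, n_thermo=2, n_higher=2,
                                n_outgroup=1)
            tree, clade_map = sim.simulate_species_tree(cfg)
            assert bb.check_backbone(tree, clade_map).concordant

    def test_same_seed_same_newick(self):
        cfg = sim.SimConfig(seed=77)
        t1, _ = sim.simulate_species_tree(cfg)
        t2, _ = sim.simulate_species_tree(cfg)
        assert pc.write_newick(t1) == pc.write_newick(t2)

    def test_within_clade_topologies_vary_across_seeds(self):
        shapes = set()
        for seed in range(40):
            cfg = sim.SimConfig(seed=seed, n_gloeo=4, n_thermo=2, n_higher=2,
                                n_outgroup=1)
            tree, clade_map = sim.simulate_species_tree(cfg)
            gloeo = [t for t, c in clade_map.items() if c == "GLOEO"]
            sub = pc.restrict(tree, gloeo)
            shapes.add(frozenset(pc.clades(sub)))
        assert len(shapes) > 1

    def test_branch_lengths_positive(self):
        tree, _ = sim.simulate_species_tree(sim.SimConfig(seed=5))
        assert all(e.length > 0 for e in pc.iter_edges(tree))


class TestGeneTree:
    def test_zero_noise_equals_species_topology(self):
        cfg = vertical_config(9)
        species, clade_map = sim.simulate_species_tree(cfg)
        for i in (1, 2, 3):
            gene, truth = sim.simulate_gene_tree(species, cfg, i)
            assert truth.mode == "vertical"
            assert pc.clades(gene) == pc.clades(species)

    def test_forced_hgt_breaks_recipient_lineage_coherence(self):
        """With p_hgt = 1, whenever the transfer exits the recipient's
        lineage that lineage must stop being monophyletic."""
        cfg = sim.SimConfig(seed=21, p_hgt=1.0, p_duplication=0.0,
                            p_nni_noise=0.0, missingness=0.0)
        species, clade_map = sim.simulate_species_tree(cfg)
        n_exit = 0
        for i in range(1, 21):
            gene, truth = sim.simulate_gene_tree(species, cfg, i)
            assert truth.mode == "hgt"
            lineage = clade_map[truth.hgt_recipient]
            members = frozenset(t for t in pc.leaf_labels(gene)
                                if clade_map.get(t) == lineage)
            mono = pc.is_monophyletic(gene, members)
            if truth.hgt_exits_lineage:
                n_exit += 1
                assert not mono
            else:
                assert mono
        assert n_exit > 0

    def test_fixed_seed_reproducible(self):
        cfg = sim.SimConfig(seed=33)
        species, _ = sim.simulate_species_tree(cfg)
        t1, _ = sim.simulate_gene_tree(species, cfg, 4)
        t2, _ = sim.simulate_gene_tree(species, cfg, 4)
        assert pc.write_newick(t1) == pc.write_newick(t2)


class TestDuplication:
    def test_leaf_count_and_labels(self):
        cfg = vertical_config(15)
        species, clade_map = sim.simulate_species_tree(cfg)
        gene, truth = sim.simulate_gene_tree(species, cfg, 1)
        n_before = len(pc.leaf_labels(gene))
        dup, truth = sim.simulate_duplication(gene, cfg, truth=truth)
        paralogs = truth.paralog_leaves
        assert paralogs
        assert len(pc.leaf_labels(dup)) == n_before + len(paralogs)
        assert all(p.endswith("_par") for p in paralogs)
        assert "duplication" in truth.mode

    def test_paralog_clade_monophyletic_by_construction(self):
        cfg = vertical_config(16)
        species, _ = sim.simulate_species_tree(cfg)
        gene, truth = sim.simulate_gene_tree(species, cfg, 1)
        dup, truth = sim.simulate_duplication(gene, cfg, truth=truth)
        if len(truth.paralog_leaves) >= 2:
            assert pc.is_monophyletic(dup, truth.paralog_leaves)

    def test_copy_branch_lengths_scaled_by_multiplier(self):
        cfg = vertical_config(17, paralog_rate_multiplier=3.0)
        species, _ = sim.simulate_species_tree(cfg)
        gene, truth = sim.simulate_gene_tree(species, cfg, 1)
        original = {
            frozenset(pc.node_leafset(e.head_node)): e.length
            for e in pc.iter_edges(gene)}
        dup, truth = sim.simulate_duplication(gene, cfg, truth=truth)
        for edge in pc.iter_edges(dup):
            leafset = pc.node_leafset(edge.head_node)
            if not all(l.endswith("_par") for l in leafset):
                continue
            source = frozenset(l[:-4] for l in leafset)
            if source in original and len(leafset) < len(truth.paralog_leaves):
                assert edge.length == pytest.approx(3.0 * original[source])

    def test_degraded_positions_recorded(self):
        cfg = vertical_config(18, degrade_count=2)
        species, _ = sim.simulate_species_tree(cfg)
        gene, truth = sim.simulate_gene_tree(species, cfg, 1)
        _, truth = sim.simulate_duplication(gene, cfg, truth=truth)
        motif_positions = {p.ref_position for p in cfg.motif_positions}
        assert len(truth.degraded_positions) == 2
        assert set(truth.degraded_positions) <= motif_positions


class TestEvolveSequences:
    def test_zero_length_tree_gives_identical_rows(self):
        cfg = vertical_config(25, seq_length=80, motif_start=10)
        tree = pc.read_newick("((A:0,B:0):0,(C:0,D:0):0);", rooted=True)
        aln = sim.evolve_sequences(tree, cfg)
        assert len(set(aln.rows)) == 1

    def test_saturation_matches_poisson_closed_form(self):
        """Two-taxon tree, total path 2t: the observed proportion of
        differing (non-motif) sites must sit within 3 standard errors of
        (19/20)(1 - exp(-(20/19) 2t)) at length 10,000."""
        cfg = sim.SimConfig(seed=41, seq_length=10_000, motif_start=1)
        motif_cols = {p.ref_position - 1 for p in cfg.motif_positions}
        for t in (0.05, 0.3, 1.0):
            tree = pc.read_newick(f"(A:{t},B:{t});", rooted=True)
            aln = sim.evolve_sequences(tree, cfg)
            pairs = [(x, y) for k, (x, y) in
                     enumerate(zip(aln.row("A"), aln.row("B")))
                     if k not in motif_cols]
            p_obs = sum(x != y for x, y in pairs) / len(pairs)
            p_exp = sim.expected_difference(2 * t)
            se = (p_exp * (1 - p_exp) / len(pairs)) ** 0.5
            assert abs(p_obs - p_exp) <= 3 * se

    def test_ortholog_motif_frozen(self):
        cfg = vertical_config(26)
        species, _ = sim.simulate_species_tree(cfg)
        gene, truth = sim.simulate_gene_tree(species, cfg, 1)
        aln = sim.evolve_sequences(gene, cfg, truth=truth)
        spec = lxnxlr_spec(aln.ids[0], cfg.motif_start)
        reports = score_motif(aln, spec)
        assert all(r.n_retained == 4 for r in reports.values())

    def test_paralogs_always_lack_two_of_four(self):
        """Every paralog row must satisfy the degradation contrast in
        every replicate — the generator enforces it by construction."""
        for seed in range(5):
            cfg = sim.SimConfig(seed=seed, p_hgt=0.0, p_duplication=1.0,
                                p_nni_noise=0.0, missingness=0.0)
            species, clade_map = sim.simulate_species_tree(cfg)
            gene, truth, aln = sim.simulate_gene(cfg, species, clade_map, 1)
            spec = lxnxlr_spec(
                next(i for i in aln.ids if not i.endswith("_par")),
                cfg.motif_start)
            reports = score_motif(aln, spec)
            for leaf in truth.paralog_leaves:
                if leaf in aln.ids:
                    assert reports[leaf].lacks_ge2

    def test_missing_branch_length_rejected(self):
        cfg = vertical_config(27, seq_length=20, motif_start=5)
        tree = pc.read_newick("((A:1,B:1),(C:1,D));", rooted=True)
        with pytest.raises(ValueError, match="branch lengths"):
            sim.evolve_sequences(tree, cfg)


class TestGenerateDataset:
    def test_file_counts_match_n_genes(self, tmp_path):
        cfg = sim.SimConfig(seed=51, n_genes=4)
        sim.generate_dataset(cfg, tmp_path)
        assert len(list(tmp_path.glob("gene_*.nwk"))) == 4
        assert len(list(tmp_path.glob("gene_*.fasta"))) == 4
        for name in ("species.nwk", "clades.tsv", "truth.tsv", "config.json"):
            assert (tmp_path / name).exists()

    def test_missingness_thins_taxa_binomially(self, tmp_path):
        cfg = sim.SimConfig(seed=52, n_genes=30, missingness=0.3,
                            p_hgt=0.0, p_duplication=0.0, p_nni_noise=0.0)
        sim.generate_dataset(cfg, tmp_path / "d")
        total = cfg.n_gloeo + cfg.n_thermo + cfg.n_higher + cfg.n_outgroup
        counts = [
            len(pc.leaf_labels(pc.read_newick(p.read_text())))
            for p in sorted((tmp_path / "d").glob("gene_*.nwk"))]
        mean_kept = np.mean(counts) / total
        # binomial SE over 30 genes x 26 taxa draws
        se = (0.3 * 0.7 / (30 * total)) ** 0.5
        assert abs(mean_kept - 0.7) <= 4 * se

    def test_rerun_with_same_seed_is_byte_identical(self, tmp_path):
        cfg = sim.SimConfig(seed=53, n_genes=3)
        sim.generate_dataset(cfg, tmp_path / "run1")
        sim.generate_dataset(cfg, tmp_path / "run2")

        def digests(d: Path):
            return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                    for p in sorted(d.iterdir())}

        assert digests(tmp_path / "run1") == digests(tmp_path / "run2")

    def test_different_seeds_differ(self, tmp_path):
        sim.generate_dataset(sim.SimConfig(seed=1, n_genes=2), tmp_path / "a")
        sim.generate_dataset(sim.SimConfig(seed=2, n_genes=2), tmp_path / "b")
        a = (tmp_path / "a" / "species.nwk").read_text()
        b = (tmp_path / "b" / "species.nwk").read_text()
        assert a != b


class TestEndToEndRecovery:
    def test_vertical_zero_noise_consensus_recovers_species_tree(self):
        """Ten vertical, noise-free genes: the 0.70 meta-consensus must
        equal the species topology with every edge solid."""
        cfg = vertical_config(61, n_genes=10)
        species, clade_map = sim.simulate_species_tree(cfg)
        trees = []
        for i in range(1, 11):
            tree, truth, _ = sim.simulate_gene(cfg, species, clade_map, i)
            trees.append((truth.gene, tree))
        gts = cons.GeneTreeSet(trees, clade_map)
        result = cons.greedy_threshold_consensus(gts, threshold=0.70)
        assert pc.clades(result.tree) == pc.clades(species)
        assert all(a.status == cons.SOLID for a in result.agreements.values())

    def test_hgt_detection_matches_truth_records(self):
        """p_hgt = 0.3 over 100 genes: genes whose lineage-coherence test
        fails must be exactly the genes whose transfer exited a lineage,
        and the detected fraction must fall in the exact binomial 95%
        interval around the realized exit fraction."""
        from scipy.stats import binomtest

        cfg = sim.SimConfig(seed=62, n_genes=100, p_hgt=0.3,
                            p_duplication=0.0, p_nni_noise=0.0,
                            missingness=0.0)
        species, clade_map = sim.simulate_species_tree(cfg)
        n_exit = n_detected = 0
        for i in range(1, 101):
            tree, truth = sim.simulate_gene_tree(species, cfg, i)
            detected = False
            for lineage in ("GLOEO", "THERMO", "HIGHER"):
                members = sorted(t for t in pc.leaf_labels(tree)
                                 if clade_map.get(t) == lineage)
                res = bb.lineage_coherence(tree, clade_map, lineage, members[0])
                detected = detected or not res.monophyletic
            n_exit += truth.hgt_exits_lineage
            n_detected += detected
        assert n_exit > 0
        ci = binomtest(n_exit, 100).proportion_ci(confidence_level=0.95)
        assert ci.low <= n_detected / 100 <= ci.high
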