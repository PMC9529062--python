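"""Simulator: panels, clone trees, variant assignment, duplex families."""
import numpy as np
import pytest

import dupliseq as dq
from dupliseq.simulate import FamilySizeModel

from conftest import TIMEPOINTS


class TestPanel:
    def test_study_scale_panel(self, study_scale_panel):
        assert len(study_scale_panel) == 71
        assert study_scale_panel.total_span == 71 * 89 == 6319
        genes = {r.gene for r in study_scale_panel.regions}
        assert len(genes) == 28

    def test_minimal_panel(self):
        panel = dq.generate_panel(1, 20, seed=0)
        (region,) = panel.regions
        assert (region.start, region.end) == (0, 20)
        assert set(region.sequence) <= set("ACGT")

    def test_deterministic_for_seed(self):
        a = dq.generate_panel(5, 30, seed=7)
        b = dq.generate_panel(5, 30, seed=7)
        assert [r.sequence for r in a.regions] == [r.sequence for r in b.regions]
        c = dq.generate_panel(5, 30, seed=8)
        assert [r.sequence for r in a.regions] != [r.sequence for r in c.regions]

    @pytest.mark.parametrize("n,length", [(0, 30), (-1, 30), (3, 19), (3, 0)])
    def test_rejects_degenerate_sizes(self, n, length):
        with pytest.raises(ValueError):
            dq.generate_panel(n, length, seed=0)

    def test_ref_base_lookup(self, small_panel):
        r = small_panel.regions[0]
        assert small_panel.ref_base(r.contig, 5) == r.sequence[5]
        with pytest.raises(KeyError):
            small_panel.ref_base("nowhere", 0)


class TestCloneTree:
    def test_p28_like_accepted(self, p28_tree):
        assert p28_tree.root == "A"
        assert p28_tree.clones["D"].prevalence[0] == 0.002
        assert p28_tree.clones["D"].prevalence[208] == 0.85

    def test_child_exceeding_parent_rejected(self):
        spec = [("P", None, {0: 0.5}), ("K", "P", {0: 0.6})]
        with pytest.raises(dq.CloneTreeError):
            dq.generate_clone_tree(spec, [0])

    def test_children_sum_exceeding_parent_rejected(self):
        spec = [("P", None, {0: 0.5}),
                ("K1", "P", {0: 0.3}), ("K2", "P", {0: 0.3})]
        with pytest.raises(dq.CloneTreeError):
            dq.generate_clone_tree(spec, [0])

    def test_trivial_single_clone(self):
        tree = dq.generate_clone_tree([("A", None, {0: 1.0, 1: 1.0})], [0, 1])
        assert tree.normal_fraction(0) == 0.0
        assert tree.exclusive_prevalence("A", 1) == 1.0

    def test_multiple_roots_rejected(self):
        spec = [("A", None, {0: 0.4}), ("B", None, {0: 0.4})]
        with pytest.raises(dq.CloneTreeError):
            dq.generate_clone_tree(spec, [0])

    def test_cycle_rejected(self):
        clones = [dq.Clone("A", None, {0: 1.0}),
                  dq.Clone("B", "C", {0: 0.2}), dq.Clone("C", "B", {0: 0.2})]
        with pytest.raises(dq.CloneTreeError):
            dq.CloneTree(clones, [0])

    def test_exclusive_prevalence_subtracts_children(self, p28_tree):
        # B's own cells at day 0: 0.80 minus C (0.45) and D (0.002)
        assert p28_tree.exclusive_prevalence("B", 0) == pytest.approx(0.348)
        assert p28_tree.normal_fraction(0) == pytest.approx(0.05)

    def test_newick_and_fishplot_export(self, p28_tree):
        nwk = p28_tree.to_newick()
        assert nwk == "((C,D)B)A;"
        frame = p28_tree.to_fishplot_frame()
        assert set(frame.columns) == {"clone", "timepoint", "prevalence", "parent"}
        assert len(frame) == 4 * len(TIMEPOINTS)


class TestAssignVariants:
    def test_true_vaf_is_half_prevalence(self, small_panel):
        tree = dq.generate_clone_tree([("A", None, {0: 0.80})], [0])
        (v,) = dq.assign_variants(tree, small_panel, {"A": 1}, seed=0)
        assert v.vaf[0] == pytest.approx(0.40)

    def test_low_prevalence_scale(self, small_panel):
        tree = dq.generate_clone_tree([("A", None, {0: 0.0044})], [0])
        (v,) = dq.assign_variants(tree, small_panel, {"A": 1}, seed=0)
        assert v.vaf[0] == pytest.approx(0.0022)

    def test_zero_variants(self, small_panel, p28_tree):
        assert dq.assign_variants(p28_tree, small_panel, {}, seed=0) == []

    def test_each_variant_has_one_clone_and_unique_site(self, small_panel, p28_tree):
        variants = dq.assign_variants(
            p28_tree, small_panel, {"A": 5, "B": 5, "C": 3, "D": 3}, seed=4)
        assert len(variants) == 16
        sites = {(v.contig, v.position, v.alt) for v in variants}
        assert len(sites) == 16
        for v in variants:
            assert p28_tree.clone_of_mutation(v.id) == v.clone
            assert small_panel.ref_base(v.contig, v.position) == v.ref

    def test_hotspot_pinned(self, small_panel, p28_tree):
        region = small_panel.regions[0]
        ref = region.sequence[10]
        alt = "ACGT".replace(ref, "")[0]
        (v,) = dq.assign_variants(
            p28_tree, small_panel, {"D": 1},
            hotspots=[(region.gene, region.start + 10, ref, alt)], seed=0)
        assert (v.contig, v.position, v.ref, v.alt) == (region.contig, 10, ref, alt)
        assert v.clone == "D"

    def test_hotspot_ref_mismatch_rejected(self, small_panel, p28_tree):
        region = small_panel.regions[0]
        wrong = "ACGT".replace(region.sequence[10], "")[0]
        with pytest.raises(ValueError, match="ref mismatch"):
            dq.assign_variants(p28_tree, small_panel, {"D": 1},
                               hotspots=[(region.gene, 10, wrong, "A")], seed=0)


def _one_clone_setup(prevalence, n_regions=1, length=40, seed=5):
    panel = dq.generate_panel(n_regions, length, seed=seed)
    tree = dq.generate_clone_tree([("A", None, {0: prevalence})], [0])
    variants = dq.assign_variants(tree, panel, {"A": 1}, seed=seed)
    return panel, tree, variants


def _config(n_genomes, **kw):
    """Config whose input mass corresponds to ``n_genomes`` genome equivalents."""
    return dq.SimulationConfig(input_mass_ng=n_genomes * 6.6 / 1000.0, **kw)


class TestSimulateFamilies:
    def test_noiseless_reads_match_truth(self):
        panel, tree, variants = _one_clone_setup(1.0)
        cfg = _config(200, pre_barcode_error=0.0, post_barcode_error=0.0)
        frags, truth = dq.simulate_families(panel, variants, tree, 0, cfg, seed=1)
        v = variants[0]
        for f in frags:
            expected = dq.encode_seq(panel.regions[0].sequence)
            if v.id in f.variant_ids:
                expected = expected.copy()
                expected[v.position] = dq.encode_seq(v.alt)[0]
            assert np.array_equal(f.true_seq, expected)
            for mat in (f.top_reads, f.bottom_reads):
                assert (mat == f.true_seq).all()

    def test_determinism(self):
        panel, tree, variants = _one_clone_setup(0.3)
        cfg = _config(100)
        f1, t1 = dq.simulate_families(panel, variants, tree, 0, cfg, seed=9)
        f2, t2 = dq.simulate_families(panel, variants, tree, 0, cfg, seed=9)
        assert t1.equals(t2)
        assert len(f1) == len(f2)
        for a, b in zip(f1, f2):
            assert a.tag_a == b.tag_a and a.tag_b == b.tag_b
            assert np.array_equal(a.top_reads, b.top_reads)
            assert np.array_equal(a.bottom_reads, b.bottom_reads)

    def test_truth_table_vaf_bookkeeping_exact(self):
        panel, tree, variants = _one_clone_setup(0.5)
        frags, truth = dq.simulate_families(panel, variants, tree, 0, _config(500), seed=2)
        row = truth.iloc[0]
        carried = sum(row.variant_id in f.variant_ids for f in frags)
        assert row.mutant_molecules == carried
        assert row.total_molecules == len(frags)
        assert row.realized_vaf == carried / len(frags)

    def test_mutant_molecules_binomial(self):
        # het variant at true VAF 0.01 on 10,000 molecules: count ~ Binomial
        panel, tree, variants = _one_clone_setup(0.02)
        cfg = _config(10_000, family_size=FamilySizeModel(kind="constant", size=1))
        _, truth = dq.simulate_families(panel, variants, tree, 0, cfg, seed=3)
        k = truth.iloc[0].mutant_molecules
        n, p = 10_000, 0.01
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(k - n * p) <= 4 * sigma

    def test_degenerate_family_size_yields_no_sscs(self):
        panel, tree, variants = _one_clone_setup(1.0)
        cfg = _config(50, family_size=FamilySizeModel(kind="constant", size=1))
        frags, _ = dq.simulate_families(panel, variants, tree, 0, cfg, seed=4)
        assert all(f.top_reads.shape[0] == 1 for f in frags)
        result = dq.collapse_families(dq.fragments_to_reads(frags))
        assert result.sscs == [] and result.dcs == []
        assert result.stats.rejected_minmem == 2 * len(frags)

    def test_pre_errors_shared_post_errors_private(self):
        panel, tree, variants = _one_clone_setup(0.0)  # no leukemia: pure reference
        cfg = _config(300, pre_barcode_error=5e-3, post_barcode_error=5e-3,
                      family_size=FamilySizeModel(kind="constant", size=3))
        frags, _ = dq.simulate_families(panel, [], tree, 0, cfg, seed=6)
        checked_pre = checked_post = 0
        for f in frags:
            for reads, pre, post in ((f.top_reads, f.top_pre_errors, f.top_post_errors),
                                     (f.bottom_reads, f.bottom_pre_errors, f.bottom_post_errors)):
                for pos in pre:
                    clean = np.delete(np.arange(reads.shape[0]),
                                      [k for k in range(reads.shape[0]) if pos in post[k]])
                    # pre-barcode errors propagate to every read of the strand
                    assert (reads[clean, pos] != f.true_seq[pos]).all()
                    checked_pre += len(clean)
                for k, positions in enumerate(post):
                    others = [j for j in range(reads.shape[0]) if j != k]
                    for pos in positions:
                        if pos in pre:
                            continue
                        # post-barcode errors are private to their read
                        other_clean = [j for j in others if pos not in post[j]]
                        assert (reads[other_clean, pos] == f.true_seq[pos]).all()
                        checked_post += 1
        assert checked_pre > 10 and checked_post > 10

    def test_clone_fractions_match_prevalence(self, p28_tree, small_panel):
        cfg = _config(4000, family_size=FamilySizeModel(kind="constant", size=1))
        frags, _ = dq.simulate_families(small_panel, [], p28_tree, 208, cfg, seed=7)
        n = len(frags)
        for cid in p28_tree.clones:
            p = p28_tree.exclusive_prevalence(cid, 208)
            k = sum(f.clone == cid for f in frags)
            sigma = np.sqrt(n * p * (1 - p)) if 0 < p < 1 else 0.0
            assert abs(k - n * p) <= 4 * sigma + 1

    def test_missing_timepoint_and_empty_panel_rejected(self, small_panel, p28_tree):
        with pytest.raises(KeyError):
            dq.simulate_families(small_panel, [], p28_tree, 999, _config(10), seed=0)
        with pytest.raises(ValueError):
            dq.simulate_families(dq.TargetPanel([]), [], p28_tree, 0, _config(10), seed=0)

    def test_softclip_fraction_flags_reads(self):
        panel, tree, variants = _one_clone_setup(1.0)
        cfg = _config(200, softclip_fraction=0.3)
        frags, _ = dq.simulate_families(panel, [], tree, 0, cfg, seed=8)
        flags = np.concatenate([np.concatenate([f.top_softclip, f.bottom_softclip])
                                for f in frags])
        assert 0.2 < flags.mean() < 0.4


class TestFamilySizeModel:
    def test_ztnb_strictly_positive(self):
        rng = np.random.default_rng(0)
        sizes = FamilySizeModel(kind="ztnb", mean=5, shape=2).sample(rng, 5000)
        assert sizes.min() >= 1
        assert 4.5 < sizes.mean() < 6.5  # zero-truncation lifts the mean slightly

    def test_config_validation(self):
        with pytest.raises(ValueError):
            dq.SimulationConfig(pre_barcode_error=0.6)
        with pytest.raises(ValueError):
            dq.SimulationConfig(input_mass_ng=0)

    def test_genome_equivalents_arithmetic(self):
        cfg = dq.SimulationConfig(input_mass_ng=250.0, genome_mass_pg=6.6)
        assert cfg.genome_equivalents == pytest.approx(37878.7878, rel=1e-6)
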