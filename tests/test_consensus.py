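"""Consensus building: family grouping, SSCS/DCS collapsing, trimming."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import dupliseq as dq
from dupliseq.consensus import family_key
from dupliseq.simulate import FamilySizeModel

from conftest import brute_force_sscs, make_reads

PARAMS = dq.ConsensusParams()


class TestGrouping:
    def test_single_family(self):
        reads = make_reads(["ACGTACGTACGTACGTACGT"] * 6)
        res = dq.group_families(reads)
        assert res.n_missing_tags == 0
        assert len(res.families) == 1
        (fam,) = res.families.values()
        assert len(fam) == 6

    def test_opposite_orientations_share_canonical_pair(self):
        top = make_reads(["ACGT" * 5] * 3, tag_a="AAAACCCC", tag_b="GGGGTTTT",
                         orientation="ab", prefix="t")
        bottom = make_reads(["ACGT" * 5] * 3, tag_a="GGGGTTTT", tag_b="AAAACCCC",
                            orientation="ba", prefix="b")
        res = dq.group_families(top + bottom)
        assert len(res.families) == 2
        keys = list(res.families)
        assert keys[0].molecule_key == keys[1].molecule_key
        assert {k.orientation for k in keys} == {0, 1}

    def test_empty_input(self):
        res = dq.group_families([])
        assert res.families == {} and res.n_missing_tags == 0

    def test_missing_tags_counted(self):
        tagged = make_reads(["ACGT" * 5] * 2)
        bare = make_reads(["ACGT" * 5] * 3, tag_a=None, tag_b=None, prefix="u")
        res = dq.group_families(tagged + bare)
        assert res.n_missing_tags == 3
        assert sum(len(v) for v in res.families.values()) == 2


class TestRepBarcodeFilter:
    def _key(self, tag_a, tag_b="ACGTACGTA"):
        (read,) = make_reads(["A" * 20], tag_a=tag_a, tag_b=tag_b)
        return family_key(read)

    def test_nine_base_homopolymer_fails(self):
        assert dq.rep_barcode_filter(self._key("AAAAAAAAA"), PARAMS) is False

    def test_broken_run_passes(self):
        assert dq.rep_barcode_filter(self._key("AAAAAAAAT"), PARAMS) is True

    def test_rep_filt_longer_than_tag_always_passes(self):
        params = dq.ConsensusParams(rep_filt=30)
        assert dq.rep_barcode_filter(self._key("AAAAAAAAA"), params) is True


class TestBuildSscs:
    def test_family_below_minmem_rejected(self):
        assert dq.build_sscs(make_reads(["ACGT" * 5] * 2), PARAMS) is None

    def test_agreement_at_cutoff_passes(self):
        # 7 A vs 3 C at position 0 with cutoff 0.7: 0.7 >= 0.7 keeps the A
        seqs = ["A" + "ACGT" * 5] * 7 + ["C" + "ACGT" * 5] * 3
        cons = dq.build_sscs(make_reads(seqs), PARAMS)
        assert cons.sequence[0] == "A"
        assert cons.agreement[0] == pytest.approx(0.7)

    def test_agreement_below_cutoff_masks(self):
        seqs = ["A" + "ACGT" * 5] * 6 + ["C" + "ACGT" * 5] * 4
        cons = dq.build_sscs(make_reads(seqs), PARAMS)
        assert cons.sequence[0] == "N"

    def test_identical_family_is_identity(self):
        cons = dq.build_sscs(make_reads(["ACGTTGCAACGTTGCAACGT"] * 5), PARAMS)
        assert cons.sequence == "ACGTTGCAACGTTGCAACGT"
        assert (cons.agreement == 1.0).all()
        assert cons.family_size == 5 and cons.tier == "SSCS"

    def test_unequal_lengths_rejected(self):
        reads = make_reads(["ACGT" * 5]) + make_reads(["ACGT" * 6], prefix="x")
        with pytest.raises(ValueError):
            dq.build_sscs(reads, PARAMS)

    def test_maxmem_downsampling_deterministic(self):
        params = dq.ConsensusParams(maxmem=5)
        # names r000..r009; the first five after the stable sort are r000-r004,
        # which all carry A at position 0 while later reads carry C
        seqs = ["A" + "ACGT" * 5] * 5 + ["C" + "ACGT" * 5] * 5
        cons1 = dq.build_sscs(make_reads(seqs), params)
        cons2 = dq.build_sscs(list(reversed(make_reads(seqs))), params)
        assert cons1.sequence[0] == "C" or cons1.sequence[0] == "A"
        assert cons1.sequence == cons2.sequence  # order of input irrelevant
        assert cons1.family_size == 5

    def test_n_fraction_rejection(self):
        params = dq.ConsensusParams(max_n_fraction=0.2)
        # half the positions disagree 2:1, well over the N budget
        seqs = ["AAAAAAAAAA" + "ACGT" * 5,
                "CCCCCCCCCC" + "ACGT" * 5,
                "GGGGGGGGGG" + "ACGT" * 5]
        assert dq.build_sscs(make_reads(seqs), params) is None

    def test_matches_brute_force_oracle_random_families(self):
        rng = np.random.default_rng(42)
        params = dq.ConsensusParams(max_n_fraction=1.0)
        for _ in range(300):
            n = int(rng.integers(3, 9))
            length = int(rng.integers(1, 13))
            seqs = ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)]
            cons = dq.build_sscs(make_reads(seqs), params)
            assert cons.sequence == brute_force_sscs(seqs, params.cutoff)

    @given(st.lists(st.integers(0, 3), min_size=3, max_size=8).flatmap(
        lambda proto: st.lists(
            st.lists(st.integers(0, 3), min_size=len(proto), max_size=len(proto)),
            min_size=3, max_size=8)))
    def test_property_matches_oracle(self, rows):
        seqs = ["".join("ACGT"[b] for b in row) for row in rows]
        params = dq.ConsensusParams(max_n_fraction=1.0)
        cons = dq.build_sscs(make_reads(seqs), params)
        assert cons.sequence == brute_force_sscs(seqs, params.cutoff)


class TestBuildDcs:
    def _pair(self, seq_top, seq_bottom):
        top = dq.build_sscs(make_reads([seq_top] * 3, orientation="ab",
                                       tag_a="AAAACCCC", tag_b="GGGGTTTT"), PARAMS)
        bottom = dq.build_sscs(make_reads([seq_bottom] * 3, orientation="ba",
                                          tag_a="GGGGTTTT", tag_b="AAAACCCC",
                                          prefix="b"), PARAMS)
        return top, bottom

    def test_agreement_everywhere_is_identity(self):
        top, bottom = self._pair("ACGTACGTACGTACGTACGT", "ACGTACGTACGTACGTACGT")
        dcs = dq.build_dcs(top, bottom)
        assert dcs.sequence == "ACGTACGTACGTACGTACGT"
        assert dcs.tier == "DCS"
        assert (dcs.family_size, dcs.family_size_b) == (3, 3)

    def test_disagreement_masked(self):
        top, bottom = self._pair("ACGTACGTACGTACGTACGT", "GCGTACGTACGTACGTACGT")
        dcs = dq.build_dcs(top, bottom)
        assert dcs.sequence[0] == "N"
        assert dcs.sequence[1:] == "CGTACGTACGTACGTACGT"

    def test_same_orientation_rejected(self):
        top, _ = self._pair("ACGT" * 5, "ACGT" * 5)
        with pytest.raises(ValueError):
            dq.build_dcs(top, top)

    def test_lone_sscs_yields_no_dcs(self):
        reads = make_reads(["ACGT" * 5] * 4)  # one strand only
        result = dq.collapse_families(reads, dq.ConsensusParams(end_trim=0))
        assert len(result.sscs) == 1 and result.dcs == []


class TestTrimEnds:
    def test_trim_five(self):
        cons = dq.build_sscs(make_reads(["ACGTACGTACGTACGTACGTACGTACGTAC"] * 3), PARAMS)
        trimmed = dq.trim_ends(cons, 5)
        assert trimmed.length == 20
        assert (trimmed.start, trimmed.end) == (5, 25)
        assert trimmed.sequence == cons.sequence[5:-5]

    def test_trim_zero_is_noop(self):
        cons = dq.build_sscs(make_reads(["ACGT" * 5] * 3), PARAMS)
        assert dq.trim_ends(cons, 0).sequence == cons.sequence

    def test_too_short_to_trim(self):
        cons = dq.build_sscs(make_reads(["ACGTACGTAC"] * 3), PARAMS)
        with pytest.raises(ValueError):
            dq.trim_ends(cons, 5)


class TestParamsValidation:
    @pytest.mark.parametrize("kw", [
        {"cutoff": 0.5}, {"cutoff": 1.1}, {"minmem": 0}, {"maxmem": 2, "minmem": 3},
    ])
    def test_invalid_params(self, kw):
        with pytest.raises(ValueError):
            dq.ConsensusParams(**kw)


def _simulate(post_error, pre_error=0.0, n_genomes=400, seed=0, length=40):
    panel = dq.generate_panel(1, length, seed=17)
    tree = dq.generate_clone_tree([("A", None, {0: 1.0})], [0])
    cfg = dq.SimulationConfig(
        input_mass_ng=n_genomes * 6.6 / 1000.0,
        pre_barcode_error=pre_error, post_barcode_error=post_error)
    frags, _ = dq.simulate_families(panel, [], tree, 0, cfg, seed=seed)
    return panel, frags


def _error_rates(frags, result):
    """Per-base mismatch rates vs the molecules' true sequences."""
    truth = {f.id: f.true_seq for f in frags}
    raw_mm = raw_n = 0
    for f in frags:
        for mat in (f.top_reads, f.bottom_reads):
            raw_mm += int((mat != f.true_seq).sum())
            raw_n += mat.size
    by_tier = {}
    for tier, reads in (("SSCS", result.sscs), ("DCS", result.dcs)):
        mm = n = 0
        frag_by_key = {}
        for f in frags:
            tags = tuple(sorted((f.tag_a, f.tag_b)))
            frag_by_key[(tags, f.contig)] = f
        for r in reads:
            f = frag_by_key[(r.key.tags, r.key.contig)]
            true = truth[f.id][r.start - f.start: r.end - f.start]
            called = r.seq != 4  # N positions are masked, not errors
            mm += int((r.seq[called] != true[called]).sum())
            n += int(called.sum())
        by_tier[tier] = (mm, n)
    return (raw_mm, raw_n), by_tier["SSCS"], by_tier["DCS"]


class TestErrorSuppression:
    def test_truth_recovery_noiseless(self):
        panel, frags = _simulate(post_error=0.0, pre_error=0.0, n_genomes=100)
        result = dq.collapse_families(dq.fragments_to_reads(frags))
        (_, _), (s_mm, s_n), (d_mm, d_n) = _error_rates(frags, result)
        assert d_n > 0 and d_mm == 0 and s_mm == 0
        for r in result.dcs:
            assert "N" not in r.sequence

    def test_sscs_error_matches_binomial_tail_model(self):
        # exaggerated per-read error so consensus failures are observable:
        # model P(wrong base fixed by >= ceil(cutoff*n) of n reads), e/3 per base
        e = 0.2
        cfg_sizes = FamilySizeModel(kind="constant", size=4)
        panel = dq.generate_panel(1, 40, seed=17)
        tree = dq.generate_clone_tree([("A", None, {0: 1.0})], [0])
        cfg = dq.SimulationConfig(input_mass_ng=1500 * 6.6 / 1000.0,
                                  pre_barcode_error=0.0, post_barcode_error=e,
                                  family_size=cfg_sizes)
        frags, _ = dq.simulate_families(panel, [], tree, 0, cfg, seed=5)
        result = dq.collapse_families(dq.fragments_to_reads(frags),
                                      dq.ConsensusParams(max_n_fraction=1.0))
        _, (s_mm, s_n), _ = _error_rates(frags, result)
        n_fam, k = 4, 3  # ceil(0.7 * 4)
        p_one_base = sps.binom.sf(k - 1, n_fam, e / 3)
        p_model = 3 * p_one_base  # three possible wrong bases
        lam = p_model * s_n
        assert abs(s_mm - lam) <= 4 * np.sqrt(lam)

    def test_monotone_suppression_chain(self):
        panel, frags = _simulate(post_error=1e-2, pre_error=1e-3, n_genomes=600)
        result = dq.collapse_families(dq.fragments_to_reads(frags))
        (r_mm, r_n), (s_mm, s_n), (d_mm, d_n) = _error_rates(frags, result)
        raw, sscs, dcs = r_mm / r_n, s_mm / s_n, d_mm / d_n
        assert raw >= sscs >= dcs
        assert raw == pytest.approx(1e-2 + 1e-3, rel=0.25)
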