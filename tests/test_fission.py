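"""Broken-gene analysis on planted fixtures.

The fixtures encode the canonical broken-ccmFc layouts; every number the
analyzer reports is checked against the generator truth table, and the
conservation identity (fragments + losses = whole gene) is asserted on
substitution-free fixtures.
"""

import numpy as np
import pytest

from orgamosaic import (
    CoverageProfile,
    GeneModel,
    Genome,
    Interval,
    analyze_fission,
    analyze_gap,
    binding_region_check,
    classify_gene_status,
    exonic_target_intervals,
    infer_breakpoints,
    locate_fragments,
    scan_expansion,
    simulate_coverage,
    simulate_fission_fixture,
    splicing_call,
)
from orgamosaic.simulate import GENE_LEN

from conftest import rand_seq


@pytest.fixture(scope="module")
def leafy():
    return simulate_fission_fixture("leafy", seed=5)


@pytest.fixture(scope="module")
def leafy_frags(leafy):
    target, ref, model, pt, truth = leafy
    return locate_fragments(target, ref, model)


class TestLocateFragments:
    def test_intact_gene_single_full_span_fragment(self):
        target, ref, model, _, _ = simulate_fission_fixture("intact", seed=5)
        frags = locate_fragments(target, ref, model)
        assert len(frags) == 1
        assert frags[0].ref_span == (0, GENE_LEN)

    def test_leafy_three_fragments_in_reference_order(self, leafy, leafy_frags):
        _, _, _, _, truth = leafy
        assert [f.label for f in leafy_frags] == ["FR1", "FR2", "FR3"]
        for f in leafy_frags:
            t = truth.fixture["fragments"][f.label]
            assert f.genomic.start == t["target_start"]
            assert f.genomic.end == t["target_end"]

    def test_grammica_three_distinct_loci(self):
        target, ref, model, _, truth = simulate_fission_fixture("grammica", seed=5)
        frags = locate_fragments(target, ref, model)
        assert len(frags) == 3
        by = {f.label: f for f in frags}
        assert by["FR3"].genomic.start - by["FR2"].genomic.end >= 14_000

    def test_absent_gene_reported_as_empty_not_error(self):
        _, ref, model, _, _ = simulate_fission_fixture("intact", seed=5)
        target = Genome(id="t", seq=rand_seq(np.random.default_rng(70), 5000))
        assert locate_fragments(target, ref, model) == []


class TestInferBreakpoints:
    def test_lost_coding_segment_is_43_aa(self, leafy_frags):
        _, _, model, _, _ = simulate_fission_fixture("leafy", seed=5)
        aa, nt = infer_breakpoints(leafy_frags, model)
        assert aa == 43

    def test_intron_break_without_base_loss(self, leafy_frags):
        _, _, model, _, _ = simulate_fission_fixture("leafy", seed=5)
        _, nt = infer_breakpoints(leafy_frags, model)
        assert nt == 0

    def test_conservation_fragments_plus_losses_equal_gene(self, leafy_frags):
        frag_nt = sum(f.ref_span[1] - f.ref_span[0] for f in leafy_frags)
        aa, nt = infer_breakpoints(
            leafy_frags, simulate_fission_fixture("leafy", seed=5)[2]
        )
        assert frag_nt + 3 * aa + nt == GENE_LEN

    def test_single_fragment_rejected(self, leafy_frags):
        model = simulate_fission_fixture("leafy", seed=5)[2]
        with pytest.raises(ValueError):
            infer_breakpoints(leafy_frags[:1], model)

    @pytest.mark.parametrize("seed", range(10))
    def test_breakpoints_exact_over_random_placements(self, seed):
        target, ref, model, _, truth = simulate_fission_fixture("leafy", seed=seed)
        frags = locate_fragments(target, ref, model)
        aa, nt = infer_breakpoints(frags, model)
        assert (aa, nt) == (43, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_breakpoints_within_3nt_at_2pct_substitutions(self, seed):
        target, ref, model, _, _ = simulate_fission_fixture(
            "leafy", seed=seed, substitution_rate=0.02
        )
        frags = locate_fragments(target, ref, model)
        aa, nt = infer_breakpoints(frags, model)
        assert abs(3 * aa - 129) <= 3
        assert nt <= 3


class TestAnalyzeGap:
    def test_leafy_insertion_and_plastid_content(self, leafy, leafy_frags):
        target, _, _, pt, truth = leafy
        gap = analyze_gap(target, leafy_frags, [pt])
        assert gap.status == "adjacent"
        assert gap.insertion_len == truth.fixture["insertion"]["len"] == 3500
        assert gap.plastid_bp == truth.fixture["insertion"]["plastid_bp"] == 2800

    def test_epilinum_reduced_insertion(self):
        target, ref, model, pt, truth = simulate_fission_fixture("epilinum", seed=5)
        frags = locate_fragments(target, ref, model)
        gap = analyze_gap(target, frags, [pt])
        assert gap.status == "adjacent"
        assert gap.insertion_len == 1300

    def test_grammica_separated(self):
        target, ref, model, pt, _ = simulate_fission_fixture("grammica", seed=5)
        frags = locate_fragments(target, ref, model)
        gap = analyze_gap(target, frags, [pt])
        assert gap.status == "separated"
        assert gap.insertion_len is None


class TestScanExpansion:
    def test_sweet_potato_planted_expansions_recovered(self):
        target, ref, model, _, truth = simulate_fission_fixture("sweet_potato", seed=5)
        frags = locate_fragments(target, ref, model)
        rep = scan_expansion(target, frags, model)
        assert rep.ccmFc1_aa == truth.fixture["ccmFc1_expansion_aa"] == 185
        assert rep.ccmFc2_aa == truth.fixture["ccmFc2_expansion_aa"] == 118
        assert rep.ccmFc1_truncated_at is None

    def test_nonsense_at_ten_codons_reported_as_truncation(self):
        target, ref, model, _, _ = simulate_fission_fixture("dodder_truncated", seed=5)
        frags = locate_fragments(target, ref, model)
        rep = scan_expansion(target, frags, model)
        assert rep.ccmFc1_aa == 10
        assert rep.ccmFc1_truncated_at == 10

    def test_stop_right_after_break_gives_minimal_expansion(self):
        target, ref, model, _, _ = simulate_fission_fixture("leafy", seed=5)
        frags = locate_fragments(target, ref, model)
        fr1 = [f for f in frags if f.label == "FR1"][0]
        # rewrite the second downstream codon to TAA (the first codon is the
        # junction-sanitized one and must stay, or the fragment end shifts)
        e = fr1.genomic.end + 3
        hacked = Genome(id="t2", seq=target.seq[:e] + "TAA" + target.seq[e + 3 :])
        rep = scan_expansion(hacked, locate_fragments(hacked, ref, model), model)
        assert rep.ccmFc1_aa == 1

    def test_no_stop_in_window_flags_unresolved(self):
        target, ref, model, _, _ = simulate_fission_fixture("leafy", seed=5)
        frags = locate_fragments(target, ref, model)
        rep = scan_expansion(target, frags, model, scan_window=0)
        assert rep.ccmFc1_unresolved

    def test_expansion_translates_without_internal_stop(self):
        """Frame consistency: the reported ccmFc1 expansion contains no
        in-frame stop before its boundary."""
        target, ref, model, _, _ = simulate_fission_fixture("sweet_potato", seed=6)
        frags = locate_fragments(target, ref, model)
        rep = scan_expansion(target, frags, model)
        fr1 = [f for f in frags if f.label == "FR1"][0]
        e = fr1.genomic.end
        region = target.seq[e : e + 3 * rep.ccmFc1_aa]
        codons = [region[i : i + 3] for i in range(0, len(region), 3)]
        assert not any(c in {"TAA", "TAG", "TGA"} for c in codons)


class TestClassifyGeneStatus:
    REF_PROT = "M" + "A" * 99  # 100 aa

    def _cds(self):
        rng = np.random.default_rng(71)
        from orgamosaic.simulate import _clean_codons

        return "ATG" + _clean_codons(rng, 99) + "TAA"

    def test_exact_copy_is_intact(self):
        cds = self._cds()
        assert classify_gene_status(cds, "M" * 100) == "intact"

    def test_internal_stop_is_pseudo(self):
        cds = self._cds()
        broken = cds[:150] + "TAA" + cds[153:]
        assert classify_gene_status(broken, "M" * 100) == "pseudo"

    def test_frameshift_deletion_is_pseudo(self):
        cds = self._cds()
        assert classify_gene_status(cds[:90] + cds[91:], "M" * 100) == "pseudo"

    def test_in_frame_deletion_stays_intact_until_truncation_rule(self):
        cds = self._cds()
        # removing one codon keeps the frame and is only 1% shorter
        assert classify_gene_status(cds[:90] + cds[93:], "M" * 100) == "intact"

    def test_heavy_truncation_is_pseudo(self):
        cds = self._cds()
        # keep frame but drop 30% of codons
        assert classify_gene_status(cds[: 3 * 70] + "TAA", "M" * 100) == "pseudo"

    def test_empty_or_foreign_sequence_is_missing(self):
        assert classify_gene_status("", "M" * 100) == "missing"
        rng = np.random.default_rng(72)
        foreign = rand_seq(rng, 303)
        assert classify_gene_status(foreign, "M" * 100, ref_cds=self._cds()) == "missing"


class TestSplicingCall:
    def _cov(self, regime, base_depth, seed=1):
        target, ref, model, _, _ = simulate_fission_fixture("leafy", seed=7)
        frags = locate_fragments(target, ref, model)
        by = {f.label: f for f in frags}
        ivs = exonic_target_intervals((by["FR2"], by["FR3"]), model)
        cov = simulate_coverage(target, ivs, regime, base_depth=base_depth, seed=seed)
        return cov, frags, model

    def test_trans_like_regime_called_trans(self):
        cov, frags, model = self._cov("trans_like", 500)
        assert splicing_call(cov, frags, model) == "trans"

    def test_cis_like_regime_called_cis(self):
        cov, frags, model = self._cov("cis_like", 500)
        assert splicing_call(cov, frags, model) == "cis"

    def test_low_depth_is_ambiguous(self):
        cov, frags, model = self._cov("trans_like", 5)
        assert splicing_call(cov, frags, model) == "ambiguous"

    def test_zero_coverage_is_ambiguous(self):
        target, ref, model, _, _ = simulate_fission_fixture("leafy", seed=7)
        frags = locate_fragments(target, ref, model)
        cov = CoverageProfile(target.id, np.zeros(len(target.seq), dtype=int))
        assert splicing_call(cov, frags, model) == "ambiguous"


class TestBindingRegion:
    def test_leafy_window_preserved_full_length(self, leafy, leafy_frags):
        target, ref, model, _, _ = simulate_fission_fixture("leafy", seed=5)
        status = binding_region_check(leafy_frags, target, ref, model)
        assert status.status == "preserved"
        assert status.matched_len == 48

    def test_americana_28bp_insertion_detected(self):
        target, ref, model, _, truth = simulate_fission_fixture("americana", seed=5)
        frags = locate_fragments(target, ref, model)
        status = binding_region_check(frags, target, ref, model)
        assert status.status == "disrupted"
        assert status.insertion_len == truth.fixture["binding_insert_len"] == 28

    def test_window_absent_reported_disrupted_without_length(self):
        _, ref, model, _, _ = simulate_fission_fixture("leafy", seed=5)
        target = Genome(id="t", seq=rand_seq(np.random.default_rng(73), 4000))
        status = binding_region_check([], target, ref, model)
        assert status.status == "disrupted"
        assert status.insertion_len is None


class TestAnalyzeFissionDriver:
    def test_full_report_on_leafy_fixture(self, leafy):
        target, ref, model, pt, truth = leafy
        report = analyze_fission(target, ref, model, plastomes=[pt])
        d = report.to_dict()
        assert d["break1_lost_aa"] == 43
        assert d["break2_lost_nt"] == 0
        assert d["fr2_fr3_gap"]["insertion_len"] == 3500
        assert d["fr2_fr3_gap"]["plastid_bp"] == 2800
        assert d["binding_region"]["status"] == "preserved"
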