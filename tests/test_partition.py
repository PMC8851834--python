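"""Five-class dissection: threshold semantics, precedence, tiling."""

import numpy as np
import pytest

from orgamosaic import ClassLabel, Genome, SimConfig, Thresholds, revcomp, simulate_family
from orgamosaic.partition import (
    classify_genome,
    conserved_intervals,
    plastid_like_intervals,
    repetitive_intervals,
    specific_intervals,
)

from conftest import mutate, rand_seq


@pytest.fixture(scope="module")
def classified(family):
    gs, truth, _ = family
    focal = gs.mitogenomes[0]
    others = gs.mitogenomes[1:]
    return focal, truth, classify_genome(focal, others, gs.plastomes)


class TestPlastidLike:
    def test_exact_plastome_copy_recovered_full_length(self):
        rng = np.random.default_rng(20)
        pt = Genome(id="pt", seq=rand_seq(rng, 6000))
        copy = pt.seq[1000:3800]
        focal = Genome(id="f", seq=rand_seq(rng, 5000) + copy + rand_seq(rng, 5000))
        ivs = plastid_like_intervals(focal, [pt])
        assert len(ivs) == 1
        # boundaries may extend by stray matching bases but the copy is covered
        assert ivs[0].start <= 5000 and ivs[0].end >= 7800
        assert ivs[0].length <= 2810

    def test_no_plastome_homology_empty(self):
        rng = np.random.default_rng(21)
        focal = Genome(id="f", seq=rand_seq(rng, 4000))
        pt = Genome(id="pt", seq=rand_seq(np.random.default_rng(22), 4000))
        assert plastid_like_intervals(focal, [pt]) == []

    def test_copy_below_identity_threshold_excluded(self):
        rng = np.random.default_rng(23)
        pt = Genome(id="pt", seq=rand_seq(rng, 6000))
        copy = mutate(rng, pt.seq[1000:3800], 0.15)  # ~85% identity
        focal = Genome(id="f", seq=rand_seq(rng, 3000) + copy + rand_seq(rng, 3000))
        assert plastid_like_intervals(focal, [pt]) == []

    def test_requires_a_plastome(self):
        with pytest.raises(ValueError):
            plastid_like_intervals(Genome(id="f", seq="ACGT" * 100), [])


class TestRepetitive:
    def test_exact_repeat_pair_both_copies(self):
        rng = np.random.default_rng(24)
        x = rand_seq(rng, 1000)
        g = Genome(id="g", seq=x + rand_seq(rng, 3000) + x)
        ivs = repetitive_intervals(g)
        assert len(ivs) == 2
        assert all(abs(iv.length - 1000) <= 10 for iv in ivs)

    def test_diverged_repeat_below_threshold_excluded(self):
        rng = np.random.default_rng(25)
        x = rand_seq(rng, 1000)
        g = Genome(id="g", seq=x + rand_seq(rng, 3000) + mutate(rng, x, 0.07))  # ~93%
        assert repetitive_intervals(g) == []

    def test_three_copy_family_gives_three_intervals(self):
        rng = np.random.default_rng(26)
        x = rand_seq(rng, 800)
        filler = lambda: rand_seq(rng, 2000)
        g = Genome(id="g", seq=filler() + x + filler() + x + filler() + x + filler())
        ivs = repetitive_intervals(g)
        assert len(ivs) == 3


class TestConservedAndSpecific:
    def test_block_in_all_members_is_conserved(self):
        rng = np.random.default_rng(27)
        block = rand_seq(rng, 2000)
        focal = Genome(id="f", seq=rand_seq(rng, 3000) + block + rand_seq(rng, 3000))
        others = [
            Genome(id=f"o{i}", seq=rand_seq(rng, 2000) + mutate(rng, block, 0.02) + rand_seq(rng, 2000))
            for i in range(3)
        ]
        ivs = conserved_intervals(focal, others)
        assert len(ivs) == 1
        assert ivs[0].start <= 3005 and ivs[0].end >= 4995

    def test_block_missing_from_one_member_excluded(self):
        rng = np.random.default_rng(28)
        block = rand_seq(rng, 2000)
        focal = Genome(id="f", seq=rand_seq(rng, 2000) + block + rand_seq(rng, 2000))
        carriers = [
            Genome(id=f"o{i}", seq=rand_seq(rng, 1000) + block + rand_seq(rng, 1000))
            for i in range(2)
        ]
        non_carrier = Genome(id="o9", seq=rand_seq(rng, 4000))
        assert conserved_intervals(focal, carriers + [non_carrier]) == []

    def test_family_containing_focal_rejected(self):
        g = Genome(id="f", seq="ACGT" * 300)
        o = Genome(id="o", seq="ACGT" * 300)
        with pytest.raises(ValueError):
            conserved_intervals(g, [o, g])

    def test_donor_segment_is_specific_and_congener_share_is_genus_level(self):
        rng = np.random.default_rng(29)
        core = rand_seq(rng, 4000)
        donor_seg = rand_seq(rng, 1500)
        focal = Genome(id="f", genus="A", seq=core + donor_seg)
        congener = Genome(id="c", genus="A", seq=core + donor_seg)  # shares the segment
        other_genus = Genome(id="o", genus="B", seq=mutate(rng, core, 0.03))
        other_genus2 = Genome(id="o2", genus="B", seq=mutate(rng, core, 0.03))
        genus_sp, species_sp = specific_intervals(
            focal, [congener, other_genus, other_genus2], split_species_specific=True
        )
        covered = sum(iv.length for iv in genus_sp if iv.start >= 3990)
        assert covered >= 1490  # genus-specific: yes
        sp_covered = sum(iv.length for iv in species_sp if iv.start >= 3990)
        assert sp_covered == 0  # species-specific: no (congener has it)

    def test_whole_genome_shared_with_other_genus_not_specific(self):
        rng = np.random.default_rng(30)
        core = rand_seq(rng, 5000)
        focal = Genome(id="f", genus="A", seq=core)
        other = Genome(id="o", genus="B", seq=core)
        assert specific_intervals(focal, [other]) == []


class TestClassifyGenome:
    def test_segments_tile_genome_exactly(self, classified):
        focal, _, result = classified
        pos = 0
        for iv, _label in result.segments:
            assert iv.start == pos
            pos = iv.end
        assert pos == len(focal)
        assert sum(result.totals.values()) == len(focal)
        assert abs(sum(result.proportions.values()) - 1.0) < 1e-9

    def test_recovered_proportions_match_planted_truth(self, classified):
        focal, truth, result = classified
        planted = truth.proportions(focal.id)
        for label in ClassLabel:
            assert abs(result.proportions[label] - planted[label]) < 0.02, label

    def test_all_unique_genome_is_fully_specific(self):
        rng = np.random.default_rng(31)
        focal = Genome(id="f", genus="A", seq=rand_seq(rng, 5000))
        others = [
            Genome(id=f"o{i}", genus="B", seq=rand_seq(rng, 5000)) for i in range(2)
        ]
        pt = Genome(id="pt", seq=rand_seq(rng, 4000))
        res = classify_genome(focal, others, [pt])
        assert res.proportions[ClassLabel.SPECIFIC] == 1.0

    def test_plastid_precedence_over_repeat(self):
        """A base inside both a repeat pair and a plastid insertion is
        labelled plastid_like."""
        rng = np.random.default_rng(32)
        pt = Genome(id="pt", seq=rand_seq(rng, 6000))
        copy = pt.seq[1000:3000]  # planted twice: repeat pair AND plastid-like
        focal = Genome(
            id="f", genus="A", seq=rand_seq(rng, 2000) + copy + rand_seq(rng, 2000) + copy
        )
        others = [Genome(id=f"o{i}", genus="B", seq=rand_seq(rng, 4000)) for i in range(2)]
        res = classify_genome(focal, others, [pt])
        assert res.totals[ClassLabel.PLASTID_LIKE] >= 3990
        assert res.totals[ClassLabel.REPETITIVE] == 0

    def test_monotone_in_plastid_identity_threshold(self):
        rng = np.random.default_rng(33)
        pt = Genome(id="pt", seq=rand_seq(rng, 6000))
        copy = mutate(rng, pt.seq[500:2500], 0.04)
        focal = Genome(id="f", seq=rand_seq(rng, 2000) + copy + rand_seq(rng, 2000))
        loose = sum(
            iv.length
            for iv in plastid_like_intervals(focal, [pt], Thresholds(plastid_identity_min=90))
        )
        tight = sum(
            iv.length
            for iv in plastid_like_intervals(focal, [pt], Thresholds(plastid_identity_min=97))
        )
        assert tight <= loose

    def test_adding_family_member_never_grows_conserved_or_specific(self):
        rng = np.random.default_rng(34)
        core = rand_seq(rng, 4000)
        focal = Genome(id="f", genus="A", seq=core + rand_seq(rng, 2000))
        base = [
            Genome(id=f"o{i}", genus="B", seq=mutate(rng, core, 0.03)) for i in range(2)
        ]
        extra = Genome(id="oz", genus="C", seq=rand_seq(rng, 4000))
        cons_before = sum(iv.length for iv in conserved_intervals(focal, base))
        cons_after = sum(iv.length for iv in conserved_intervals(focal, base + [extra]))
        assert cons_after <= cons_before
        spec_before = sum(iv.length for iv in specific_intervals(focal, base))
        spec_after = sum(iv.length for iv in specific_intervals(focal, base + [extra]))
        assert spec_after <= spec_before
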