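"""Seed-and-extend engine vs closed forms and the Smith-Waterman oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orgamosaic import Genome, Interval, Topology, revcomp
from orgamosaic.homology import (
    AlignmentParams,
    find_hits,
    find_hits_blastn,
    merge_hit_intervals,
    self_hits,
    sw_oracle,
)
from orgamosaic.model import HomologyHit

from conftest import mutate, rand_seq


def _hit(qs, qe, ss, se, sid="s", strand="+"):
    return HomologyHit(
        q=Interval("q", qs, qe),
        s=Interval(sid, ss, se, strand),
        identity=100.0,
        aln_len=qe - qs,
        mismatches=0,
        gap_opens=0,
        bitscore=50.0,
        evalue=1e-10,
    )


class TestSwOracle:
    def test_identical_sequences_score_closed_form(self):
        seq = rand_seq(np.random.default_rng(0), 50)
        score, qi, si, ident = sw_oracle(seq, seq)
        assert score == 50 * AlignmentParams().match
        assert ident == 100.0
        assert (qi.start, qi.end) == (0, 50)

    def test_disjoint_alphabets_empty_alignment(self):
        score, qi, si, ident = sw_oracle("A" * 30, "C" * 30)
        assert (score, qi, si) == (0.0, None, None)

    def test_single_internal_mismatch_closed_form(self):
        rng = np.random.default_rng(1)
        a = rand_seq(rng, 21)
        b = a[:10] + ("A" if a[10] != "A" else "C") + a[11:]
        score, *_ = sw_oracle(a, b)
        p = AlignmentParams()
        assert score == 20 * p.match + p.mismatch

    def test_size_guard(self):
        with pytest.raises(ValueError, match="guard"):
            sw_oracle("A" * 3000, "C" * 3000)


class TestFindHits:
    def test_exact_substring_single_full_identity_hit(self):
        rng = np.random.default_rng(2)
        s = rand_seq(rng, 3000)
        q = Genome(id="q", seq=s[500:600])
        hits = find_hits(q, Genome(id="s", seq=s))
        best = hits[0]
        assert best.identity == 100.0
        assert best.aln_len == 100
        assert (best.s.start, best.s.end, best.s.strand) == (500, 600, "+")

    def test_reverse_complement_hit_on_minus_strand(self):
        rng = np.random.default_rng(3)
        s = rand_seq(rng, 3000)
        q = Genome(id="q", seq=revcomp(s[1000:1100]))
        best = find_hits(q, Genome(id="s", seq=s))[0]
        assert best.s.strand == "-"
        assert (best.s.start, best.s.end) == (1000, 1100)

    def test_diverged_copy_matches_oracle_interval_and_identity(self):
        """5% substitutions: best hit within +-5 bp and +-1 identity point
        of the optimal local alignment."""
        rng = np.random.default_rng(4)
        s = rand_seq(rng, 3000)
        q = mutate(rng, s[800:1300], 0.05)
        score, qi, si, ident = sw_oracle(q, s)
        best = find_hits(Genome(id="q", seq=q), Genome(id="s", seq=s))[0]
        assert abs(best.s.start - si.start) <= 5
        assert abs(best.s.end - si.end) <= 5
        assert abs(best.identity - ident) <= 1.0

    def test_insertion_bridged_by_gapped_join(self):
        rng = np.random.default_rng(5)
        s = rand_seq(rng, 2000)
        q = s[500:750] + rand_seq(rng, 12) + s[750:1000]
        best = find_hits(Genome(id="q", seq=q), Genome(id="s", seq=s))[0]
        assert best.s.start == 500 and best.s.end == 1000
        assert best.gap_opens >= 1

    def test_circular_subject_origin_spanning_hit(self):
        rng = np.random.default_rng(6)
        s = rand_seq(rng, 2000)
        # query matches the junction of the circle: last 100 + first 100
        q = Genome(id="q", seq=s[1900:] + s[:100])
        subj = Genome(id="s", seq=s, topology=Topology.CIRCULAR)
        best = find_hits(q, subj)[0]
        assert best.aln_len == 200
        assert best.s.start == 1900 and best.s.end == 2100  # unwrapped frame

    def test_no_homology_gives_empty_result(self):
        rng = np.random.default_rng(7)
        q = Genome(id="q", seq=rand_seq(rng, 200))
        s = Genome(id="s", seq=rand_seq(np.random.default_rng(8), 200))
        assert find_hits(q, s) == []

    def test_determinism_byte_identical_tables(self, tmp_path):
        from orgamosaic import io as oio

        rng = np.random.default_rng(9)
        s = rand_seq(rng, 4000)
        q = Genome(id="q", seq=mutate(rng, s[100:1500], 0.03))
        subj = Genome(id="s", seq=s)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        oio.write_tsv_hits(find_hits(q, subj), p1)
        oio.write_tsv_hits(find_hits(q, subj), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_strand_involution(self):
        """hits(q, revcomp(s)) equal hits(q, s) with strand flipped and
        subject coordinates mirrored."""
        rng = np.random.default_rng(10)
        s = rand_seq(rng, 3000)
        q = Genome(id="q", seq=mutate(rng, s[500:1200], 0.04))
        subj = Genome(id="s", seq=s)
        subj_rc = Genome(id="s", seq=revcomp(s))
        fwd = find_hits(q, subj)
        rev = find_hits(q, subj_rc)
        n = len(s)
        mapped = sorted(
            (h.q.start, h.q.end, n - h.s.end, n - h.s.start, "-" if h.s.strand == "+" else "+")
            for h in rev
        )
        direct = sorted((h.q.start, h.q.end, h.s.start, h.s.end, h.s.strand) for h in fwd)
        assert mapped == direct


class TestSelfHits:
    def test_repeat_free_genome_empty(self):
        g = Genome(id="g", seq=rand_seq(np.random.default_rng(11), 3000))
        assert self_hits(g) == []

    def test_direct_repeat_pair_reported_once_canonical(self):
        rng = np.random.default_rng(12)
        x = rand_seq(rng, 1000)
        g = Genome(id="g", seq=x + rand_seq(rng, 2000) + x)
        hits = self_hits(g)
        assert len(hits) == 1
        h = hits[0]
        assert h.q.start < h.s.start
        assert h.identity == 100.0
        assert (h.q.start, h.q.end) == (0, 1000)
        assert (h.s.start, h.s.end) == (3000, 4000)

    def test_inverted_repeat_pair_opposite_strand(self):
        rng = np.random.default_rng(13)
        x = rand_seq(rng, 1000)
        g = Genome(id="g", seq=x + rand_seq(rng, 2000) + revcomp(x))
        hits = self_hits(g)
        assert len(hits) == 1
        assert hits[0].s.strand == "-"


class TestMergeHitIntervals:
    def test_overlap_union(self):
        ivs = merge_hit_intervals([_hit(0, 100, 0, 100), _hit(50, 150, 50, 150)], "query")
        assert [(i.start, i.end) for i in ivs] == [(0, 150)]

    def test_gap_bridging(self):
        ivs = merge_hit_intervals(
            [_hit(0, 100, 0, 100), _hit(105, 200, 105, 200)], "query", max_gap=10
        )
        assert [(i.start, i.end) for i in ivs] == [(0, 200)]

    def test_empty_input(self):
        assert merge_hit_intervals([], "query") == []

    def test_mixed_seq_ids_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            merge_hit_intervals([_hit(0, 10, 0, 10, "a"), _hit(0, 10, 0, 10, "b")], "subject")

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 80)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            min_size=1,
            max_size=20,
        ),
        st.integers(0, 30),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_merge_output_sorted_disjoint_covers_inputs(self, pairs, max_gap):
        hits = [_hit(s, e, s, e) for s, e in pairs]
        out = merge_hit_intervals(hits, "query", max_gap=max_gap)
        for a, b in zip(out, out[1:]):
            assert a.end <= b.start
        total_in = set()
        for s, e in pairs:
            total_in.update(range(s, e))
        covered = set()
        for iv in out:
            covered.update(range(iv.start, iv.end))
        assert total_in <= covered


class TestOracleDominanceAndSensitivity:
    def test_engine_never_beats_oracle_and_stays_close(self):
        """Best engine score <= SW optimum, and >= 90% of it on seeded
        instances with a >= 90%-identity planted homologous region."""
        rng = np.random.default_rng(14)
        p = AlignmentParams()
        low = 0
        for _ in range(25):
            s = rand_seq(rng, 1500)
            q = mutate(rng, s[200:800], 0.08)
            opt, *_ = sw_oracle(q, s, p)
            hits = find_hits(Genome(id="q", seq=q), Genome(id="s", seq=s), p)
            eng = max(
                (h.identity / 100 * h.aln_len) * p.match
                + h.mismatches * p.mismatch
                + h.gap_opens * p.gap_open
                for h in hits
            )
            assert eng <= opt + 1e-6
            if eng < 0.9 * opt:
                low += 1
        assert low == 0


class TestBlastnCrossCheck:
    def test_engine_agrees_with_blastn_on_planted_homology(self):
        """The external BLASTN backend finds the same homologous region the
        native engine does (coordinates within a few bp)."""
        import shutil

        if shutil.which("blastn") is None:
            pytest.skip("blastn not on PATH")
        rng = np.random.default_rng(15)
        s = rand_seq(rng, 5000)
        q = mutate(rng, s[1000:2500], 0.03)
        qg, sg = Genome(id="q", seq=q), Genome(id="s", seq=s)
        native = find_hits(qg, sg)[0]
        external = find_hits_blastn(qg, sg)[0]
        assert abs(native.s.start - external.s.start) <= 10
        assert abs(native.s.end - external.s.end) <= 10
        assert abs(native.identity - external.identity) <= 1.5
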