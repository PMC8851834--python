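"""Pairwise whole-genome synteny via fixed-length fragment anchors.

Both genomes are cut into consecutive 50 bp windows which are treated as
"genes": each fragment of A is matched to its best counterpart among the
fragments of B (>= 90% identity over >= 80% of the fragment), giving an
anchor list, and anchors are chained into collinear blocks by splitting
the A-ordered anchor sequence wherever the B index stops moving
monotonically within a bounded gap.  Inversions appear as blocks whose B
indices run backwards.  The anchor list can be exported in the MCscan
``.anchors`` tab format for cross-checking with JCVI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .homology import AlignmentParams, _kmer_codes, encode
from .model import Genome, Interval, Thresholds, revcomp


@dataclass(frozen=True)
class Fragment:
    index: int
    interval: Interval
    seq: str


@dataclass(frozen=True)
class Anchor:
    """Best-hit pairing of fragment ``a_index`` of genome A with fragment
    ``b_index`` of genome B."""

    a_index: int
    b_index: int
    a_interval: Interval
    b_interval: Interval
    strand: str  # relative orientation of the match
    identity: float


@dataclass
class SyntenyBlock:
    anchors: list[Anchor]
    a_span: Interval
    b_span: Interval
    orientation: str  # "same" | "inverted"

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def fragment_genome(genome: Genome, thresholds: Optional[Thresholds] = None) -> list[Fragment]:
    """Consecutive non-overlapping windows of ``synteny_fragment_len``
    (default 50 bp); a trailing remainder shorter than the window is
    dropped."""
    thresholds = thresholds or Thresholds()
    L = thresholds.synteny_fragment_len
    n = len(genome.seq) // L
    return [
        Fragment(i, Interval(genome.id, i * L, (i + 1) * L), genome.seq[i * L : (i + 1) * L])
        for i in range(n)
    ]


def _frag_align(a: str, b: str) -> tuple[int, float]:
    """(aligned length, % identity) of two equal-length fragments compared
    at the best ungapped offset (|offset| small)."""
    best_len, best_id = 0, 0.0
    ca, cb = encode(a), encode(b)
    L = len(a)
    for off in range(-10, 11):
        if off >= 0:
            xa, xb = ca[off:], cb[: L - off]
        else:
            xa, xb = ca[: L + off], cb[-off:]
        if len(xa) == 0:
            continue
        eq = (xa == xb) & (xa < 4)
        matches = int(eq.sum())
        ident = 100.0 * matches / len(xa)
        if matches > best_len * best_id / 100.0:
            best_len, best_id = len(xa), ident
    return best_len, best_id


def anchor_map(
    frags_a: Sequence[Fragment],
    frags_b: Sequence[Fragment],
    thresholds: Optional[Thresholds] = None,
    min_identity: float = 90.0,
    min_cover: float = 0.8,
    reciprocal_best: bool = False,
    seed_k: int = 12,
) -> list[Anchor]:
    """At most one anchor per A fragment: its best qualifying B fragment.

    Qualifying means identity >= ``min_identity`` over at least
    ``min_cover`` of the fragment length, on either strand.  Candidate
    pairs are found by shared ``seed_k``-mers, then scored by the best
    ungapped offset alignment.
    """
    thresholds = thresholds or Thresholds()
    L = thresholds.synteny_fragment_len
    # index all B k-mers -> fragment ids (both strands)
    index: dict[int, set[tuple[int, str]]] = {}
    for fb in frags_b:
        for strand, seq in (("+", fb.seq), ("-", revcomp(fb.seq))):
            h, v = _kmer_codes(encode(seq), seed_k)
            for code in np.unique(h[v]):
                index.setdefault(int(code), set()).add((fb.index, strand))
    by_index = {fb.index: fb for fb in frags_b}
    anchors: list[Anchor] = []
    best_for_b: dict[int, tuple[float, int]] = {}
    for fa in frags_a:
        h, v = _kmer_codes(encode(fa.seq), seed_k)
        cands: set[tuple[int, str]] = set()
        for code in np.unique(h[v]):
            cands |= index.get(int(code), set())
        best: Optional[Anchor] = None
        for b_idx, strand in sorted(cands):
            fb = by_index[b_idx]
            bseq = fb.seq if strand == "+" else revcomp(fb.seq)
            aln_len, ident = _frag_align(fa.seq, bseq)
            if ident < min_identity or aln_len < min_cover * L:
                continue
            cand = Anchor(fa.index, b_idx, fa.interval, fb.interval, strand, ident)
            if best is None or (cand.identity, -abs(cand.b_index - cand.a_index)) > (
                best.identity,
                -abs(best.b_index - best.a_index),
            ):
                best = cand
        if best is not None:
            anchors.append(best)
    if reciprocal_best:
        best_b: dict[int, Anchor] = {}
        for a in anchors:
            cur = best_b.get(a.b_index)
            if cur is None or a.identity > cur.identity:
                best_b[a.b_index] = a
        anchors = [a for a in anchors if best_b[a.b_index] is a]
    return anchors


def chain_blocks(
    anchors: Sequence[Anchor],
    max_gap_frags: int = 10,
    min_block_anchors: int = 5,
) -> list[SyntenyBlock]:
    """Chain A-ordered anchors into maximal collinear runs.

    A run continues while the strand is unchanged, the A index advances by
    at most ``max_gap_frags``, and the B index moves in the run's direction
    (forward for same-orientation, backward for inverted) by at most
    ``max_gap_frags``.  Runs shorter than ``min_block_anchors`` are
    dropped.  Every anchor belongs to at most one block.
    """
    ordered = sorted(anchors, key=lambda a: a.a_index)
    runs: list[list[Anchor]] = []
    for a in ordered:
        placed = False
        if runs:
            run = runs[-1]
            prev = run[-1]
            da = a.a_index - prev.a_index
            db = a.b_index - prev.b_index
            if a.strand == prev.strand and 0 < da <= max_gap_frags:
                if a.strand == "+" and 0 < db <= max_gap_frags:
                    placed = True
                elif a.strand == "-" and -max_gap_frags <= db < 0:
                    placed = True
            if placed:
                run.append(a)
        if not placed:
            runs.append([a])
    blocks = []
    for run in runs:
        if len(run) < min_block_anchors:
            continue
        a_lo = min(x.a_interval.start for x in run)
        a_hi = max(x.a_interval.end for x in run)
        b_lo = min(x.b_interval.start for x in run)
        b_hi = max(x.b_interval.end for x in run)
        sid_a = run[0].a_interval.seq_id
        sid_b = run[0].b_interval.seq_id
        blocks.append(
            SyntenyBlock(
                anchors=run,
                a_span=Interval(sid_a, a_lo, a_hi),
                b_span=Interval(sid_b, b_lo, b_hi),
                orientation="same" if run[0].strand == "+" else "inverted",
            )
        )
    blocks.sort(key=lambda b: (b.a_span.start, b.a_span.end))
    return blocks


def compare(
    genome_a: Genome,
    genome_b: Genome,
    thresholds: Optional[Thresholds] = None,
    max_gap_frags: int = 10,
    min_block_anchors: int = 5,
) -> tuple[list[Anchor], list[SyntenyBlock]]:
    """Fragment, anchor, and chain two genomes in one call."""
    thresholds = thresholds or Thresholds()
    fa = fragment_genome(genome_a, thresholds)
    fb = fragment_genome(genome_b, thresholds)
    anchors = anchor_map(fa, fb, thresholds)
    blocks = chain_blocks(anchors, max_gap_frags, min_block_anchors)
    return anchors, blocks


def write_anchors(anchors: Sequence[Anchor], path: str | Path, prefix_a="A", prefix_b="B") -> None:
    """MCscan-compatible ``.anchors`` output: geneA, geneB, score."""
    with open(path, "w") as fh:
        fh.write("###\n")
        for a in anchors:
            fh.write(f"{prefix_a}_{a.a_index}\t{prefix_b}_{a.b_index}\t{a.identity:.0f}\n")


def write_blocks(blocks: Sequence[SyntenyBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("a_start\ta_end\tb_start\tb_end\torientation\tn_anchors\n")
        for b in blocks:
            fh.write(
                f"{b.a_span.start}\t{b.a_span.end}\t{b.b_span.start}\t{b.b_span.end}\t"
                f"{b.orientation}\t{b.n_anchors}\n"
            )
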