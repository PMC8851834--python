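"""Quadripartite plastome architecture: inverted-repeat detection and
junction genes.

A canonical plastome is LSC + IRb + SSC + IRa on a circle, where IRa is
the reverse complement of IRb.  :func:`detect_ir` finds the maximal pair
of inverted repeats (>= ``min_ir_len``), refines the boundaries by exact
base-pair extension with a small mismatch tolerance (real IR copies are
rarely perfectly identical), names the two single-copy gaps by length
(LSC >= SSC), and reports everything in a coordinate frame rotated so the
LSC starts at 0.  Plastomes that have lost the IR — the dodder case —
yield ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .homology import AlignmentParams, find_hits
from .model import Genome, Interval, Thresholds, revcomp

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class QuadripartiteMap:
    """The four regions in the rotated frame (LSC starts at 0), plus the
    rotation offset back into the input coordinates."""

    lsc: Interval
    irb: Interval
    ssc: Interval
    ira: Interval
    ir_len: int
    rotation: int  # input coordinate of rotated position 0

    def region_lengths(self) -> dict[str, int]:
        return {
            "lsc": self.lsc.length,
            "irb": self.irb.length,
            "ssc": self.ssc.length,
            "ira": self.ira.length,
        }


def _extend_ir(seq2: str, b_lo: int, b_hi: int, a_lo: int, a_hi: int, n: int, max_mismatch_frac: float):
    """Maximally extend an inverted pair IRb=[b_lo,b_hi) / IRa=[a_lo,a_hi)
    on the doubled sequence while complementarity holds (small mismatch
    budget, boundary always at the last matching column)."""
    budget = int(max_mismatch_frac * (b_hi - b_lo)) + 1
    # inner edges: IRb end grows right while IRa start grows left
    mis = 0
    while b_hi < a_lo and mis <= budget:
        if _COMP[seq2[b_hi]] == seq2[a_lo - 1] and seq2[b_hi] != "N":
            b_hi += 1
            a_lo -= 1
            mis = 0  # only count trailing mismatches; boundary = last match
        else:
            break
    # outer edges: IRb start grows left while IRa end grows right
    while b_lo > 0 and a_hi < len(seq2) and (a_hi - b_lo) < 2 * n:
        if _COMP[seq2[b_lo - 1]] == seq2[a_hi] and seq2[b_lo - 1] != "N":
            b_lo -= 1
            a_hi += 1
        else:
            break
    return b_lo, b_hi, a_lo, a_hi


def detect_ir(
    plastome: Genome,
    min_ir_len: int = 1000,
    thresholds: Optional[Thresholds] = None,
    min_identity: float = 99.9,
) -> Optional[QuadripartiteMap]:
    """Detect the quadripartite structure of a circular plastome.

    Returns ``None`` when no inverted-repeat pair of at least
    ``min_ir_len`` at >= ``min_identity`` exists.  Rotation invariant: any
    rotation of the same circle yields identical region lengths.
    """
    if not plastome.is_circular:
        raise ValueError("detect_ir requires a circular genome")
    thresholds = thresholds or Thresholds()
    n = len(plastome.seq)
    seq2 = plastome.seq * 2
    doubled = Genome(id=plastome.id, seq=seq2)
    params = AlignmentParams.from_thresholds(thresholds)
    hits = [
        h
        for h in find_hits(doubled, doubled, params)
        if h.s.strand == "-"
        and h.aln_len >= min_ir_len
        and h.identity >= min_identity
        and h.q.length < n  # not a self-overlapping artefact
    ]
    best = None
    for h in hits:
        b_lo, b_hi = h.q.start, h.q.end
        a_lo, a_hi = h.s.start, h.s.end
        if b_lo > a_lo:
            b_lo, b_hi, a_lo, a_hi = a_lo, a_hi, b_lo, b_hi
        if b_lo == a_lo:
            continue  # a palindrome aligned to itself
        if a_lo < b_hi:
            continue  # overlapping copies
        if b_lo >= n:
            continue  # duplicate from the second copy
        if a_lo - b_lo >= n:
            continue  # same repeat paired across the doubling
        b_lo, b_hi, a_lo, a_hi = _extend_ir(seq2, b_lo, b_hi, a_lo, a_hi, n, 1 - min_identity / 100)
        length = min(b_hi - b_lo, a_hi - a_lo)
        if best is None or length > best[0]:
            best = (length, b_lo, b_hi, a_lo, a_hi)
    if best is None:
        return None
    ir_len, b_lo, b_hi, a_lo, a_hi = best
    # the two single-copy gaps on the circle
    gap1 = a_lo - b_hi  # between IRb end and IRa start
    gap2 = n - (a_hi - b_lo)  # wrapping gap between IRa end and IRb start
    if gap1 < 0 or gap2 < 0:
        return None
    sid = plastome.id
    if gap2 >= gap1:
        lsc_len, ssc_len = gap2, gap1
        rotation = a_hi % n  # LSC begins right after IRa
        order = ("lsc", "irb", "ssc", "ira")
    else:
        lsc_len, ssc_len = gap1, gap2
        rotation = b_hi % n  # LSC begins right after IRb; name copies so map stays LSC,IRb,SSC,IRa
        order = ("lsc", "irb", "ssc", "ira")
    pos = 0
    regions = {}
    for name, ln in zip(order, (lsc_len, b_hi - b_lo, ssc_len, a_hi - a_lo)):
        regions[name] = Interval(sid, pos, pos + ln) if ln > 0 else None
        pos += ln
    if regions["lsc"] is None or regions["ssc"] is None:
        return None
    return QuadripartiteMap(
        lsc=regions["lsc"],
        irb=regions["irb"],
        ssc=regions["ssc"],
        ira=regions["ira"],
        ir_len=ir_len,
        rotation=rotation,
    )


def rotated_sequence(plastome: Genome, qmap: QuadripartiteMap) -> str:
    """Plastome sequence in the rotated (LSC-first) frame."""
    r = qmap.rotation
    return plastome.seq[r:] + plastome.seq[:r]


JUNCTIONS = ("LSC/IRb", "IRb/SSC", "SSC/IRa", "IRa/LSC")


@dataclass
class JunctionGene:
    junction: str
    gene_id: str
    distance: int  # 0 when the gene overlaps the junction
    offset_into_ir: Optional[int]  # bp of the gene inside the IR, if any
    ir_duplicate: bool = False


def junction_report(
    qmap: QuadripartiteMap, gene_models: Sequence["GeneModel"], seq_len: Optional[int] = None
) -> list[JunctionGene]:
    """For each of the four junctions, the overlapping or nearest gene
    (coordinates must already be in the rotated frame).  Genes fully inside
    an IR are additionally reported as duplicated by the other IR copy."""
    points = {
        "LSC/IRb": qmap.irb.start,
        "IRb/SSC": qmap.irb.end,
        "SSC/IRa": qmap.ira.start,
        "IRa/LSC": qmap.ira.end,
    }
    total = qmap.ira.end if seq_len is None else seq_len
    out = []
    for name, pt in points.items():
        best = None
        for m in gene_models:
            lo = min(e.start for e in m.exons)
            hi = max(e.end for e in m.exons)
            if lo <= pt % total < hi or (lo < pt <= hi):
                dist = 0
            else:
                dist = min(
                    abs(lo - pt),
                    abs(hi - pt),
                    total - abs(lo - pt),
                    total - abs(hi - pt),
                )
            if best is None or dist < best[0]:
                best = (dist, m, lo, hi)
        if best is None:
            continue
        dist, m, lo, hi = best
        for ir in (qmap.irb, qmap.ira):
            if ir.start <= lo and hi <= ir.end:
                inside = hi - lo
                break
            inside = max(0, min(hi, qmap.irb.end) - max(lo, qmap.irb.start))
            inside = max(inside, min(hi, qmap.ira.end) - max(lo, qmap.ira.start))
        fully_in_ir = (qmap.irb.start <= lo and hi <= qmap.irb.end) or (
            qmap.ira.start <= lo and hi <= qmap.ira.end
        )
        out.append(
            JunctionGene(
                junction=name,
                gene_id=m.gene_id,
                distance=dist,
                offset_into_ir=inside if inside > 0 else None,
                ir_duplicate=fully_in_ir,
            )
        )
    return out
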