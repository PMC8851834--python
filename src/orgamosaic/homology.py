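"""Self-contained local nucleotide homology search.

The engine is a classic seed-and-extend aligner: exact ``word_size``-mer
seeding on both strands (numpy sort/merge intersection of 2-bit k-mer
codes), greedy ungapped x-drop extension along each seeded diagonal, and a
collinear join step that fuses nearby hits across small diagonal shifts
into gapped hits.  E-values come from Karlin–Altschul statistics with the
ungapped nucleotide defaults (K = 0.71, lambda = 1.37) applied to the
gapped scores — an approximation that is entirely adequate for the
thresholding this pipeline does, which is the point of the e-value here.

Words containing N never seed, and N columns never count as matches.

:func:`sw_oracle` is a full Smith–Waterman local alignment (via
Biopython's ``PairwiseAligner``) used as an independent reference in the
test-suite; production code paths never call it.

If a BLASTN executable is available, :func:`find_hits_blastn` shells out
to it and parses the 12-column table into the same ``HomologyHit`` shape,
so results can be cross-checked against real BLAST.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import (
    Genome,
    HomologyHit,
    Interval,
    Thresholds,
    hit_sort_key,
    merge_intervals,
    revcomp,
)

# Karlin-Altschul parameters for ungapped +1/-2 nucleotide scoring.
_KA_K = 0.71
_KA_LAMBDA = 1.37

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


@dataclass
class AlignmentParams:
    """Scoring scheme and search cut-offs (megablast-like defaults)."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    xdrop: int = 20
    word_size: int = 16
    evalue_max: float = 1e-5
    # joining of collinear hits into gapped hits
    max_join_gap: int = 50
    max_diag_shift: int = 30

    @classmethod
    def from_thresholds(cls, thr: Thresholds) -> "AlignmentParams":
        return cls(word_size=thr.word_size, evalue_max=thr.evalue_max)


def encode(seq: str) -> np.ndarray:
    """2-bit base codes, with N (and anything unexpected) as 4."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(hashes, valid) for every window of length k; windows with N invalid."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    weights = (np.uint64(4) ** np.arange(k, dtype=np.uint64))[::-1]
    hashes = (win.astype(np.uint64) * weights).sum(axis=1)
    valid = (win < 4).all(axis=1)
    return hashes, valid


def _seed_matches(qcodes: np.ndarray, scodes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All (qpos, spos) pairs whose k-mers are identical and N-free."""
    hq, vq = _kmer_codes(qcodes, k)
    hs, vs = _kmer_codes(scodes, k)
    qidx = np.nonzero(vq)[0]
    sidx = np.nonzero(vs)[0]
    if len(qidx) == 0 or len(sidx) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    hq, hs = hq[qidx], hs[sidx]
    order = np.argsort(hs, kind="stable")
    hs_sorted = hs[order]
    left = np.searchsorted(hs_sorted, hq, side="left")
    right = np.searchsorted(hs_sorted, hq, side="right")
    counts = right - left
    nz = np.nonzero(counts)[0]
    if len(nz) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    lens = counts[nz]
    total = int(lens.sum())
    offs = np.cumsum(lens) - lens
    flat = np.arange(total, dtype=np.int64) - np.repeat(offs, lens) + np.repeat(left[nz], lens)
    qpos = qidx[np.repeat(nz, lens)]
    spos = sidx[order[flat]]
    return qpos, spos


def _xdrop_reach(scores: np.ndarray, xdrop: int) -> int:
    """Length of the best-scoring prefix before the score falls ``xdrop``
    below its running maximum.  Returns 0 if extension never helps."""
    if len(scores) == 0:
        return 0
    cs = np.cumsum(scores)
    runmax = np.maximum.accumulate(cs)
    dropped = np.nonzero(runmax - cs > xdrop)[0]
    limit = dropped[0] if len(dropped) else len(cs)
    if limit == 0:
        return 0
    best = int(np.argmax(cs[:limit]))
    return best + 1 if cs[best] > 0 else 0


@dataclass
class _RawHit:
    qs: int
    qe: int
    ss: int
    se: int
    matches: int
    mismatches: int
    gap_opens: int
    gap_bases: int

    @property
    def score(self) -> int:
        return self.matches - 2 * self.mismatches - self.gap_opens * 5 - self.gap_bases * 2


def _extend_cluster(
    qcodes: np.ndarray,
    scodes: np.ndarray,
    diag: int,
    q_lo: int,
    q_hi: int,
    params: AlignmentParams,
) -> Optional[_RawHit]:
    """Ungapped x-drop extension of a seed cluster lying on one diagonal.

    ``diag = qpos - spos``; the cluster spans query [q_lo, q_hi).
    """
    nq, ns = len(qcodes), len(scodes)
    # right extension
    q_right_max = min(nq, ns + diag)
    qr = qcodes[q_hi:q_right_max]
    sr = scodes[q_hi - diag : q_right_max - diag]
    eq_r = (qr == sr) & (qr < 4)
    reach_r = _xdrop_reach(np.where(eq_r, params.match, params.mismatch), params.xdrop)
    # left extension
    q_left_min = max(0, diag)
    ql = qcodes[q_left_min:q_lo][::-1]
    sl = scodes[q_left_min - diag : q_lo - diag][::-1]
    eq_l = (ql == sl) & (ql < 4)
    reach_l = _xdrop_reach(np.where(eq_l, params.match, params.mismatch), params.xdrop)
    qs, qe = q_lo - reach_l, q_hi + reach_r
    qseg = qcodes[qs:qe]
    sseg = scodes[qs - diag : qe - diag]
    eq = (qseg == sseg) & (qseg < 4)
    matches = int(eq.sum())
    if matches == 0:
        return None
    return _RawHit(qs, qe, qs - diag, qe - diag, matches, int(len(eq) - matches), 0, 0)


def _cluster_and_extend(
    qcodes: np.ndarray, scodes: np.ndarray, params: AlignmentParams
) -> list[_RawHit]:
    k = params.word_size
    qpos, spos = _seed_matches(qcodes, scodes, k)
    if len(qpos) == 0:
        return []
    diag = qpos - spos
    order = np.lexsort((qpos, diag))
    qpos, spos, diag = qpos[order], spos[order], diag[order]
    # split into clusters: same diagonal, query gap below the join cap
    brk = np.nonzero((np.diff(diag) != 0) | (np.diff(qpos) > params.max_join_gap + k))[0] + 1
    bounds = np.concatenate(([0], brk, [len(qpos)]))
    hits: list[_RawHit] = []
    covered: dict[int, list[tuple[int, int]]] = {}
    for a, b in zip(bounds[:-1], bounds[1:]):
        d = int(diag[a])
        q_lo, q_hi = int(qpos[a]), int(qpos[b - 1]) + k
        spans = covered.get(d, [])
        if any(s <= q_lo and q_hi <= e for s, e in spans):
            continue  # cluster already inside an extended hit on this diagonal
        h = _extend_cluster(qcodes, scodes, d, q_lo, q_hi, params)
        if h is None:
            continue
        covered.setdefault(d, []).append((h.qs, h.qe))
        hits.append(h)
    return _dedupe_same_diag(hits)


def _dedupe_same_diag(hits: list[_RawHit]) -> list[_RawHit]:
    """Merge hits on one diagonal whose query spans overlap (keep the union
    stats by recomputation later; here overlapping same-diagonal extensions
    are byproducts of clustering, the larger one wins)."""
    by_diag: dict[int, list[_RawHit]] = {}
    for h in hits:
        by_diag.setdefault(h.qs - h.ss, []).append(h)
    out = []
    for d, group in by_diag.items():
        group.sort(key=lambda h: (h.qs, -(h.qe - h.qs)))
        kept: list[_RawHit] = []
        for h in group:
            if kept and h.qs < kept[-1].qe:
                if h.qe > kept[-1].qe:
                    kept[-1] = h if (h.qe - h.qs) > (kept[-1].qe - kept[-1].qs) else kept[-1]
                continue
            kept.append(h)
        out.extend(kept)
    return out


def _join_collinear(
    hits: list[_RawHit], qcodes: np.ndarray, scodes: np.ndarray, params: AlignmentParams
) -> list[_RawHit]:
    """Fuse nearby hits across small diagonal shifts into gapped hits."""
    hits = sorted(hits, key=lambda h: (h.qs, h.ss))
    joined: list[_RawHit] = []
    for h in hits:
        if joined:
            p = joined[-1]
            qgap = h.qs - p.qe
            sgap = h.ss - p.se
            shift = abs((h.qs - h.ss) - (p.qs - p.ss))
            if (
                -params.word_size < qgap <= params.max_join_gap
                and -params.word_size < sgap <= params.max_join_gap
                and 0 < shift <= params.max_diag_shift
            ):
                gap_cost = -params.gap_open - params.gap_extend * shift
                mis_extra = max(min(qgap, sgap), 0)
                if h.score - gap_cost - 2 * mis_extra > 0:
                    joined[-1] = _RawHit(
                        qs=p.qs,
                        qe=max(h.qe, p.qe),
                        ss=p.ss,
                        se=max(h.se, p.se),
                        matches=p.matches + h.matches,
                        mismatches=p.mismatches + h.mismatches + mis_extra,
                        gap_opens=p.gap_opens + h.gap_opens + 1,
                        gap_bases=p.gap_bases + h.gap_bases + shift,
                    )
                    continue
        joined.append(h)
    return joined


def _bitscore(score: float) -> float:
    return (_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2.0)


def _evalue(score: float, m: int, n: int) -> float:
    return _KA_K * m * n * math.exp(-_KA_LAMBDA * score)


def _raw_to_hit(
    h: _RawHit, qid: str, sid: str, strand: str, s_len_orig: int, m: int, n: int
) -> HomologyHit:
    aln_len = max(h.qe - h.qs, h.se - h.ss)
    if strand == "+":
        ss, se = h.ss, h.se
    else:
        ss, se = s_len_orig - h.se, s_len_orig - h.ss
    identity = 100.0 * h.matches / aln_len
    score = h.score
    return HomologyHit(
        q=Interval(qid, h.qs, h.qe),
        s=Interval(sid, ss, se, strand),
        identity=identity,
        aln_len=aln_len,
        mismatches=h.mismatches,
        gap_opens=h.gap_opens,
        bitscore=round(_bitscore(score), 2),
        evalue=_evalue(score, m, n),
    )


def find_hits(
    query: Genome, subject: Genome, params: Optional[AlignmentParams] = None
) -> list[HomologyHit]:
    """All local homology hits of ``query`` against ``subject``, both strands.

    Circular subjects are searched on their doubled sequence and hits are
    mapped back to the original frame (an origin-spanning hit keeps
    ``end > len(subject)``); duplicates from the second copy are removed.
    Hits are filtered at ``params.evalue_max`` and returned best-first.
    """
    params = params or AlignmentParams()
    if not query.seq or not subject.seq:
        raise ValueError("empty sequence")
    s_seq = subject.seq * 2 if subject.is_circular else subject.seq
    s_len = len(subject.seq)
    qcodes = encode(query.seq)
    m, n = len(query.seq), s_len
    hits: list[HomologyHit] = []
    for strand, sseq in (("+", s_seq), ("-", revcomp(s_seq))):
        scodes = encode(sseq)
        raw = _cluster_and_extend(qcodes, scodes, params)
        raw = _join_collinear(raw, qcodes, scodes, params)
        for h in raw:
            hit = _raw_to_hit(h, query.id, subject.id, strand, len(sseq), m, n)
            hits.append(hit)
    if subject.is_circular:
        hits = _dedupe_circular(hits, s_len)
    hits = [
        h
        for h in hits
        if h.evalue <= params.evalue_max and h.aln_len >= params.word_size
    ]
    hits.sort(key=hit_sort_key)
    return hits


def _dedupe_circular(hits: list[HomologyHit], s_len: int) -> list[HomologyHit]:
    seen = {}
    for h in hits:
        ss = h.s.start % s_len
        key = (h.q.start, h.q.end, ss, h.s.end - h.s.start, h.s.strand)
        if key in seen:
            continue
        if h.s.start >= s_len:
            h = HomologyHit(
                q=h.q,
                s=Interval(h.s.seq_id, h.s.start - s_len, h.s.end - s_len, h.s.strand),
                identity=h.identity,
                aln_len=h.aln_len,
                mismatches=h.mismatches,
                gap_opens=h.gap_opens,
                bitscore=h.bitscore,
                evalue=h.evalue,
            )
        seen[key] = h
    return list(seen.values())


def self_hits(genome: Genome, params: Optional[AlignmentParams] = None) -> list[HomologyHit]:
    """Internal repeats of a genome: ``find_hits(genome, genome)`` with the
    trivial full-length self-diagonal removed and each repeat pair reported
    once, in ``q.start < s.start`` canonical order."""
    params = params or AlignmentParams()
    hits = find_hits(genome, genome, params)
    n = len(genome.seq)
    out: list[HomologyHit] = []
    for h in hits:
        if h.s.strand == "+" and (h.q.start - h.s.start) % n == 0:
            continue  # self-diagonal (possibly via the doubled copy)
        if h.s.strand == "-" and h.q.start == (n - h.s.end) and h.q.end == (n - h.s.start):
            # palindrome matching itself reversed at the same locus
            if h.q.start == h.s.start and h.q.end == h.s.end:
                continue
        if (h.s.start % n, h.s.end) < (h.q.start, h.q.end):
            h = HomologyHit(
                q=Interval(h.q.seq_id, h.s.start % n, h.s.start % n + (h.s.end - h.s.start)),
                s=Interval(h.s.seq_id, h.q.start, h.q.end, h.s.strand),
                identity=h.identity,
                aln_len=h.aln_len,
                mismatches=h.mismatches,
                gap_opens=h.gap_opens,
                bitscore=h.bitscore,
                evalue=h.evalue,
            )
        out.append(h)
    return _dedupe_reciprocal(out)


def _dedupe_reciprocal(hits: list[HomologyHit]) -> list[HomologyHit]:
    kept: list[HomologyHit] = []
    for h in sorted(hits, key=hit_sort_key):
        dup = False
        for k in kept:
            if (
                h.s.strand == k.s.strand
                and _overlap_frac(h.q, k.q) > 0.9
                and _overlap_frac(h.s, k.s) > 0.9
            ):
                dup = True
                break
        if not dup:
            kept.append(h)
    return kept


def _overlap_frac(a: Interval, b: Interval) -> float:
    inter = a.intersection_len(b)
    return inter / min(a.length, b.length) if inter else 0.0


def merge_hit_intervals(
    hits: Sequence[HomologyHit], side: str = "query", max_gap: int = 0
) -> list[Interval]:
    """Strand-agnostic union of the chosen-side intervals of ``hits``.

    Adjacent intervals separated by less than ``max_gap`` are bridged; the
    result is sorted and disjoint.
    """
    if side not in ("query", "subject"):
        raise ValueError("side must be 'query' or 'subject'")
    ivs = [h.q if side == "query" else h.s for h in hits]
    if not ivs:
        return []
    seq_ids = {iv.seq_id for iv in ivs}
    if len(seq_ids) > 1:
        raise ValueError(f"mixed seq_ids on {side} side: {sorted(seq_ids)}")
    sid = seq_ids.pop()
    merged = merge_intervals([(iv.start, iv.end) for iv in ivs], max_gap=max_gap)
    return [Interval(sid, s, e) for s, e in merged]


# ---------------------------------------------------------------------------
# Smith-Waterman oracle (test reference, never on the production path)

_SW_GUARD = 4_000_000


def sw_oracle(
    query: str, subject: str, params: Optional[AlignmentParams] = None
) -> tuple[float, Optional[Interval], Optional[Interval], float]:
    """Optimal local alignment by full dynamic programming.

    Returns ``(score, q_interval, s_interval, identity)``; the zero-score
    case returns ``(0.0, None, None, 0.0)``.  Guarded to products of
    sequence lengths at or below 4e6.
    """
    from Bio import Align

    params = params or AlignmentParams()
    if len(query) * len(subject) > _SW_GUARD:
        raise ValueError("sw_oracle size guard exceeded (len(q)*len(s) > 4e6)")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    score = float(aligner.score(query, subject))
    if score <= 0:
        return 0.0, None, None, 0.0
    aln = aligner.align(query, subject)[0]
    qa, sa = aln.aligned
    q_lo, q_hi = int(qa[0][0]), int(qa[-1][1])
    s_lo, s_hi = int(sa[0][0]), int(sa[-1][1])
    matches = 0
    columns = 0
    for (qs, qe), (ss, se) in zip(qa, sa):
        qseg, sseg = query[qs:qe], subject[ss:se]
        matches += sum(1 for a, b in zip(qseg, sseg) if a == b and a != "N")
        columns += qe - qs
    # count gap columns too
    gap_cols = (q_hi - q_lo - columns) + (s_hi - s_lo - sum(se - ss for ss, se in sa))
    aln_len = columns + gap_cols
    identity = 100.0 * matches / aln_len if aln_len else 0.0
    return score, Interval("query", q_lo, q_hi), Interval("subject", s_lo, s_hi), identity


# ---------------------------------------------------------------------------
# Optional BLASTN pass-through backend


def find_hits_blastn(
    query: Genome,
    subject: Genome,
    params: Optional[AlignmentParams] = None,
    blastn_path: str = "blastn",
) -> list[HomologyHit]:
    """Run an external BLASTN and parse its 12-column output into
    :class:`HomologyHit` records (circularity is the caller's problem)."""
    from .io import read_tsv_hits

    params = params or AlignmentParams()
    if shutil.which(blastn_path) is None:
        raise RuntimeError(f"BLASTN executable {blastn_path!r} not found")
    with tempfile.TemporaryDirectory() as tmp:
        qf, sf, of = (Path(tmp) / n for n in ("q.fa", "s.fa", "out.tsv"))
        qf.write_text(f">{query.id}\n{query.seq}\n")
        sf.write_text(f">{subject.id}\n{subject.seq}\n")
        subprocess.run(
            [
                blastn_path,
                "-query",
                str(qf),
                "-subject",
                str(sf),
                "-word_size",
                str(params.word_size),
                "-evalue",
                str(params.evalue_max),
                "-outfmt",
                "6",
                "-out",
                str(of),
            ],
            check=True,
            capture_output=True,
        )
        hits = read_tsv_hits(of)
    hits.sort(key=hit_sort_key)
    return hits
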