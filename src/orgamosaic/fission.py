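"""Gene-fission forensics for a broken mitochondrial gene.

The model case is ccmFc: canonically two exons split by one group II
cis-splicing intron.  Against an intact reference gene, a target genome is
scanned for the surviving fragments (FR1, FR2, FR3, ... in reference
order), and from their layout the module infers

* the coding loss at the first break (reported in amino acids),
* base loss inside the intron at the second break (nt),
* the size and plastid content of any insertion sitting between FR2 and
  FR3 (or the fact that the two have become separated loci),
* coding expansions: how far FR1 must read on to its next in-frame stop,
  and how far upstream of FR2 the nearest usable in-frame ATG sits,
* whether the intron's 48-nt protein-binding window survived intact,
* a cis/trans splicing call from per-base transcriptome coverage, and
* an intact / pseudo / missing status for arbitrary gene copies.

All reference coordinates are "gene-local": nt offsets along the 5'->3'
oriented reference gene (exon1 + intron + exon2), so position 0 is the
first base of the start codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np

from .homology import AlignmentParams, find_hits
from .model import Genome, Interval, Thresholds, revcomp

_STOPS = {"TAA", "TAG", "TGA"}  # standard code; plant mitochondria use it


@dataclass
class GeneModel:
    """An intact reference gene: ordered exons and the derived intron(s)."""

    gene_id: str
    exons: list[Interval]
    strand: str = "+"
    code: int = 1
    protein_len: Optional[int] = None
    binding_region: Optional[Interval] = None  # genomic coords, inside the intron

    def __post_init__(self) -> None:
        ex = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ex, ex[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in gene {self.gene_id!r}")
        self.exons = ex if self.strand == "+" else ex[::-1]

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
        )

    @property
    def introns(self) -> list[Interval]:
        ex = sorted(self.exons, key=lambda e: e.start)
        sid = ex[0].seq_id
        return [Interval(sid, a.end, b.start, self.strand) for a, b in zip(ex, ex[1:])]

    def coding_len(self) -> int:
        return sum(e.length for e in self.exons)

    # --- gene-local coordinates (0 = first base of the 5' exon) ---

    def _to_local(self, genomic_pos: int) -> int:
        lo, hi = self.span
        return genomic_pos - lo if self.strand == "+" else hi - genomic_pos

    def local_exons(self) -> list[tuple[int, int]]:
        out = []
        for e in self.exons:
            a, b = self._to_local(e.start), self._to_local(e.end)
            out.append((min(a, b), max(a, b)))
        return out

    def local_introns(self) -> list[tuple[int, int]]:
        out = []
        for iv in self.introns:
            a, b = self._to_local(iv.start), self._to_local(iv.end)
            out.append((min(a, b), max(a, b)))
        return out

    def local_binding_region(self) -> Optional[tuple[int, int]]:
        if self.binding_region is None:
            return None
        a = self._to_local(self.binding_region.start)
        b = self._to_local(self.binding_region.end)
        return (min(a, b), max(a, b))

    def gene_seq(self, genome: Genome) -> str:
        lo, hi = self.span
        s = genome.seq[lo:hi]
        return s if self.strand == "+" else revcomp(s)

    def coding_seq(self, genome: Genome) -> str:
        parts = []
        for e in self.exons:
            s = genome.seq[e.start : e.end]
            parts.append(s if self.strand == "+" else revcomp(s))
        return "".join(parts)

    def local_coding_pos(self, local_pos: int) -> Optional[int]:
        """Coding-nt offset of a gene-local position, None if intronic."""
        acc = 0
        for s, e in self.local_exons():
            if s <= local_pos < e:
                return acc + (local_pos - s)
            if local_pos >= e:
                acc += e - s
        return acc if local_pos >= self.local_exons()[-1][1] else None


@dataclass
class FragmentMatch:
    """One surviving gene fragment located on the target genome."""

    label: str  # FR1, FR2, ...
    genomic: Interval  # target coordinates; strand = orientation vs the gene
    ref_span: tuple[int, int]  # gene-local nt span
    identity: float


@dataclass
class GapReport:
    status: str  # "adjacent" | "separated"
    insertion_len: Optional[int] = None
    plastid_bp: Optional[int] = None


@dataclass
class ExpansionReport:
    ccmFc1_aa: Optional[int] = None
    ccmFc1_truncated_at: Optional[int] = None
    ccmFc1_unresolved: bool = False
    ccmFc2_aa: Optional[int] = None
    ccmFc2_unresolved: bool = False


@dataclass
class BindingRegionStatus:
    status: str  # "preserved" | "disrupted"
    insertion_len: Optional[int] = None
    matched_len: Optional[int] = None


@dataclass
class CoverageProfile:
    seq_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        if (np.asarray(self.depth) < 0).any():
            raise ValueError("negative coverage depth")
        self.depth = np.asarray(self.depth, dtype=np.int64)


@dataclass
class FissionReport:
    fragments: list[FragmentMatch]
    break1_lost_aa: Optional[int] = None
    break2_lost_nt: Optional[int] = None
    fr2_fr3_gap: Optional[GapReport] = None
    expansion: Optional[ExpansionReport] = None
    splicing: str = "ambiguous"
    binding_region_status: Optional[BindingRegionStatus] = None

    def to_dict(self) -> dict:
        return {
            "fragments": [
                {
                    "label": f.label,
                    "target_start": f.genomic.start,
                    "target_end": f.genomic.end,
                    "strand": f.genomic.strand,
                    "ref_start": f.ref_span[0],
                    "ref_end": f.ref_span[1],
                    "identity": round(f.identity, 2),
                }
                for f in self.fragments
            ],
            "break1_lost_aa": self.break1_lost_aa,
            "break2_lost_nt": self.break2_lost_nt,
            "fr2_fr3_gap": vars(self.fr2_fr3_gap) if self.fr2_fr3_gap else None,
            "expansion": vars(self.expansion) if self.expansion else None,
            "splicing": self.splicing,
            "binding_region": vars(self.binding_region_status)
            if self.binding_region_status
            else None,
        }


# ---------------------------------------------------------------------------
# Fragment location


def locate_fragments(
    target: Genome,
    ref: Genome,
    model: GeneModel,
    thresholds: Optional[Thresholds] = None,
    min_fragment_len: int = 50,
) -> list[FragmentMatch]:
    """Homology hits of the oriented reference gene against the target,
    merged when collinear and adjacent, labelled FR1.. in reference order.

    An intact copy yields a single fragment; an absent gene yields an
    empty list (not an error).
    """
    thresholds = thresholds or Thresholds()
    params = AlignmentParams.from_thresholds(thresholds)
    gene = Genome(id=f"{model.gene_id}_ref", seq=model.gene_seq(ref))
    hits = [h for h in find_hits(gene, target, params) if h.aln_len >= min_fragment_len]
    if not hits:
        return []
    # merge collinear adjacent hits at one locus (same strand, consistent
    # small gaps on both reference and target)
    hits.sort(key=lambda h: h.q.start)
    merged = []
    for h in hits:
        if merged:
            p = merged[-1]
            q_gap = h.q.start - p.q.end
            if p.s.strand == h.s.strand == "+":
                s_gap = h.s.start - p.s.end
            elif p.s.strand == h.s.strand == "-":
                s_gap = p.s.start - h.s.end
            else:
                s_gap = None
            if s_gap is not None and -10 < q_gap < 100 and -10 < s_gap < 100:
                merged[-1] = _merge_pair(p, h)
                continue
        merged.append(h)
    merged.sort(key=lambda h: h.q.start)
    return [
        FragmentMatch(
            label=f"FR{i + 1}",
            genomic=h.s,
            ref_span=(h.q.start, h.q.end),
            identity=h.identity,
        )
        for i, h in enumerate(merged)
    ]


def _merge_pair(a, b):
    from .model import HomologyHit

    s_lo = min(a.s.start, b.s.start)
    s_hi = max(a.s.end, b.s.end)
    q_lo, q_hi = a.q.start, max(a.q.end, b.q.end)
    aln = max(q_hi - q_lo, s_hi - s_lo)
    matches = round(a.identity / 100 * a.aln_len + b.identity / 100 * b.aln_len)
    return HomologyHit(
        q=Interval(a.q.seq_id, q_lo, q_hi),
        s=Interval(a.s.seq_id, s_lo, s_hi, a.s.strand),
        identity=min(100.0, 100.0 * matches / aln),
        aln_len=aln,
        mismatches=a.mismatches + b.mismatches,
        gap_opens=a.gap_opens + b.gap_opens + 1,
        bitscore=a.bitscore + b.bitscore,
        evalue=min(a.evalue, b.evalue),
    )


# ---------------------------------------------------------------------------
# Breakpoints


def infer_breakpoints(
    fragments: Sequence[FragmentMatch],
    ref_model: GeneModel,
    word_size: int = 16,
) -> tuple[int, int]:
    """(break1_lost_aa, break2_lost_nt) from the reference-span gaps.

    The coding gap (midpoint inside an exon) is reported in amino acids
    (floor of nt/3); the intronic gap in nt.  Fragments overlapping on the
    reference by more than ``word_size`` indicate an inconsistent layout.
    """
    if len(fragments) < 2:
        raise ValueError("need at least two fragments to infer breakpoints")
    frs = sorted(fragments, key=lambda f: f.ref_span[0])
    for a, b in zip(frs, frs[1:]):
        if a.ref_span[1] - b.ref_span[0] > word_size:
            raise ValueError(
                f"fragments {a.label}/{b.label} overlap on the reference by "
                f"{a.ref_span[1] - b.ref_span[0]} nt"
            )
    exons = ref_model.local_exons()
    introns = ref_model.local_introns()
    coding_lost_nt = 0
    intron_lost_nt = 0
    for a, b in zip(frs, frs[1:]):
        gap_lo, gap_hi = a.ref_span[1], b.ref_span[0]
        if gap_hi <= gap_lo:
            continue
        mid = (gap_lo + gap_hi) // 2
        if any(s <= mid < e for s, e in introns):
            intron_lost_nt += gap_hi - gap_lo
        elif any(s <= mid < e for s, e in exons):
            coding_lost_nt += gap_hi - gap_lo
    return coding_lost_nt // 3, intron_lost_nt


# ---------------------------------------------------------------------------
# FR2-FR3 gap


def analyze_gap(
    target: Genome,
    fragments: Sequence[FragmentMatch],
    plastomes: Sequence[Genome] = (),
    thresholds: Optional[Thresholds] = None,
    max_adjacent_gap: int = 10_000,
) -> GapReport:
    """Status of the former intron between FR2 and FR3.

    ``adjacent``: both fragments sit at one locus in gene orientation with
    at most ``max_adjacent_gap`` bp between them; the insertion length is
    that gap, and its plastid content is measured by the same >90%-identity
    homology rule the partitioner uses for plastid-like sequence.
    ``separated``: anything else (relocated or inverted fragments).
    """
    thresholds = thresholds or Thresholds()
    by_label = {f.label: f for f in fragments}
    fr2, fr3 = by_label.get("FR2"), by_label.get("FR3")
    if fr2 is None or fr3 is None:
        raise ValueError("analyze_gap requires located FR2 and FR3 fragments")
    if fr2.genomic.strand == fr3.genomic.strand == "+":
        gap_lo, gap_hi = fr2.genomic.end, fr3.genomic.start
    elif fr2.genomic.strand == fr3.genomic.strand == "-":
        gap_lo, gap_hi = fr3.genomic.end, fr2.genomic.start
    else:
        return GapReport(status="separated")
    gap = gap_hi - gap_lo
    if gap < 0 or gap > max_adjacent_gap:
        return GapReport(status="separated")
    plastid_bp = 0
    if gap >= thresholds.word_size and plastomes:
        from .partition import plastid_like_intervals

        gap_genome = Genome(id="fr2_fr3_gap", seq=target.seq[gap_lo:gap_hi])
        plastid_bp = sum(
            iv.length for iv in plastid_like_intervals(gap_genome, plastomes, thresholds)
        )
    return GapReport(status="adjacent", insertion_len=gap, plastid_bp=plastid_bp)


# ---------------------------------------------------------------------------
# Coding expansion


def _codon_at(target: Genome, pos: int, strand: str) -> Optional[str]:
    """Codon whose first base (in gene orientation) sits at target
    position ``pos``; None when out of bounds."""
    if strand == "+":
        if pos < 0 or pos + 3 > len(target.seq):
            return None
        return target.seq[pos : pos + 3]
    if pos - 3 < -1 or pos >= len(target.seq):
        return None
    return revcomp(target.seq[pos - 2 : pos + 1])


def scan_expansion(
    target: Genome,
    fragments: Sequence[FragmentMatch],
    ref_model: GeneModel,
    scan_window: int = 3000,
    truncation_call_max: int = 30,
) -> ExpansionReport:
    """Coding expansions created by the fission.

    ccmFc1 (FR1 side): complete in-frame codons from the FR1 3' break to
    the first stop codon downstream, exclusive of the stop.  A stop within
    ``truncation_call_max`` codons is reported as a truncation back to the
    breakpoint (the nonsense-mutation signature).  No stop inside
    ``scan_window`` nt -> unresolved.

    ccmFc2 (FR2 side): codons from the first usable in-frame ATG upstream
    of the FR2 5' break down to the break.  A stop codon encountered
    before any ATG makes the expansion unresolved (no upstream ORF start
    can reach the fragment past a stop).
    """
    by_label = {f.label: f for f in fragments}
    fr1, fr2 = by_label.get("FR1"), by_label.get("FR2")
    if fr1 is None or fr2 is None:
        raise ValueError("scan_expansion requires located FR1 and FR2 fragments")
    rep = ExpansionReport()

    # --- FR1: downstream stop scan ---
    phase = fr1.ref_span[1] % 3
    skip = (3 - phase) % 3  # to the next codon boundary
    strand = fr1.genomic.strand
    pos = fr1.genomic.end + skip if strand == "+" else fr1.genomic.start - 1 - skip
    count = 0
    found_stop = False
    while count * 3 <= scan_window:
        codon = _codon_at(target, pos, strand)
        if codon is None:
            break
        if codon in _STOPS:
            found_stop = True
            break
        count += 1
        pos = pos + 3 if strand == "+" else pos - 3
    if not found_stop:
        rep.ccmFc1_unresolved = True
    else:
        rep.ccmFc1_aa = count
        if count <= truncation_call_max:
            rep.ccmFc1_truncated_at = count

    # --- FR2: upstream ATG scan ---
    phase2 = fr2.ref_span[0] % 3
    strand2 = fr2.genomic.strand
    # first complete codon strictly upstream of the break (gene orientation)
    if strand2 == "+":
        base = fr2.genomic.start + phase2
        step = -3
        first = base - 3
    else:
        base = fr2.genomic.end - 1 - phase2
        step = +3
        first = base + 3
    pos = first
    j = 1
    found_atg = None
    while (j - 1) * 3 <= scan_window:
        codon = _codon_at(target, pos, strand2)
        if codon is None:
            break
        if codon in _STOPS:
            break
        if codon == "ATG":
            found_atg = j
            break
        j += 1
        pos += step if strand2 == "-" else -3
    if found_atg is None:
        rep.ccmFc2_unresolved = True
    else:
        rep.ccmFc2_aa = found_atg
    return rep


# ---------------------------------------------------------------------------
# Gene status


def classify_gene_status(
    target_gene_seq: str,
    ref_protein: str,
    ref_cds: Optional[str] = None,
    max_truncation: float = 0.2,
) -> str:
    """intact / pseudo / missing call for a coding-gene copy.

    pseudo: premature internal stop, a length change that is not a
    multiple of 3 (frame-disrupting indel), or a truncation of more than
    ``max_truncation`` of the reference protein.  missing: no sequence, or
    (when ``ref_cds`` is given) no homology with the reference CDS.
    """
    seq = target_gene_seq.upper()
    if not seq:
        return "missing"
    if ref_cds is not None:
        params = AlignmentParams(word_size=11, evalue_max=10.0)
        try:
            hits = find_hits(Genome(id="q", seq=seq), Genome(id="s", seq=ref_cds), params)
        except ValueError:
            hits = []
        if not hits:
            return "missing"
    ref_nt = 3 * (len(ref_protein) + 1)  # CDS incl. stop codon
    if (len(seq) - ref_nt) % 3 != 0:
        return "pseudo"
    codons = [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
    aa_count = 0
    for i, codon in enumerate(codons):
        if codon in _STOPS:
            if i < len(codons) - 1:
                return "pseudo"  # premature internal stop
            break
        aa_count += 1
    if aa_count < (1 - max_truncation) * len(ref_protein):
        return "pseudo"
    return "intact"


# ---------------------------------------------------------------------------
# Splicing call from coverage


def exonic_target_intervals(
    fragments: Sequence[FragmentMatch], ref_model: GeneModel
) -> list[Interval]:
    """Target-coordinate intervals of the exonic parts of the given
    fragments (affine mapping through each fragment's ref span)."""
    out: list[Interval] = []
    exons = ref_model.local_exons()
    for fr in fragments:
        r_lo, r_hi = fr.ref_span
        for e_lo, e_hi in exons:
            lo, hi = max(r_lo, e_lo), min(r_hi, e_hi)
            if hi <= lo:
                continue
            if fr.genomic.strand == "+":
                t_lo = fr.genomic.start + (lo - r_lo)
                out.append(Interval(fr.genomic.seq_id, t_lo, t_lo + (hi - lo)))
            else:
                t_hi = fr.genomic.end - (lo - r_lo)
                out.append(Interval(fr.genomic.seq_id, t_hi - (hi - lo), t_hi))
    return out


def splicing_call(
    coverage: CoverageProfile,
    fragments: Sequence[FragmentMatch],
    ref_model: GeneModel,
    thresholds: Optional[Thresholds] = None,
    intron_window: int = 1000,
) -> str:
    """cis / trans / ambiguous from per-base transcriptome coverage.

    E = median depth over the exonic bases of FR2 and FR3; I = median
    depth over the intron-side window immediately 3' of FR2.  The call is
    ``trans`` when the intron side is essentially silent (I < cov_low)
    while the exons are strongly expressed (E > cov_high); ``cis`` when
    the intron side keeps at least half the exonic signal; otherwise
    ``ambiguous``.
    """
    thresholds = thresholds or Thresholds()
    by_label = {f.label: f for f in fragments}
    fr2, fr3 = by_label.get("FR2"), by_label.get("FR3")
    if fr2 is None or fr3 is None:
        raise ValueError("splicing_call requires located FR2 and FR3 fragments")
    depth = coverage.depth
    exon_ivs = exonic_target_intervals((fr2, fr3), ref_model)
    if not exon_ivs:
        return "ambiguous"
    epos = np.concatenate([np.arange(iv.start, iv.end) for iv in exon_ivs])
    epos = epos[(epos >= 0) & (epos < len(depth))]
    if len(epos) == 0 or depth[epos].max() == 0:
        return "ambiguous"
    e_med = float(np.median(depth[epos]))
    if e_med < thresholds.cov_low:
        return "ambiguous"  # too little exonic signal for any call
    if fr2.genomic.strand == "+":
        w_lo = fr2.genomic.end
        w_hi = min(w_lo + intron_window, fr3.genomic.start if fr3.genomic.start > w_lo else len(depth))
    else:
        w_hi = fr2.genomic.start
        w_lo = max(w_hi - intron_window, fr3.genomic.end if fr3.genomic.end < w_hi else 0)
    if w_hi <= w_lo:
        return "ambiguous"
    i_med = float(np.median(depth[w_lo:w_hi]))
    if i_med < thresholds.cov_low and e_med > thresholds.cov_high:
        return "trans"
    if i_med >= 0.5 * e_med:
        return "cis"
    return "ambiguous"


# ---------------------------------------------------------------------------
# Binding-region check


def binding_region_check(
    fragments: Sequence[FragmentMatch],
    target: Genome,
    ref: Genome,
    ref_model: GeneModel,
    max_edits_frac: float = 0.15,
) -> BindingRegionStatus:
    """Fate of the intron's protein-binding window (48 nt in ccmFc).

    preserved: the full-length window aligns without indels (substitutions
    within the edit budget allowed).  disrupted(n): the two halves of the
    window are found but ``n`` extra bases sit between them.  disrupted
    with no length: the window is not found at all.
    """
    if ref_model.binding_region is None:
        raise ValueError("reference model has no binding_region set")
    lo, hi = ref_model.local_binding_region()
    window = ref_model.gene_seq(ref)[lo:hi]
    L = len(window)
    budget = int(max_edits_frac * L)
    best = None
    for strand_seq in (target.seq, revcomp(target.seq)):
        r = edlib.align(window, strand_seq, mode="HW", task="path")
        if r["editDistance"] >= 0 and (best is None or r["editDistance"] < best[0]):
            span = r["locations"][0][1] - r["locations"][0][0] + 1
            has_indel = span != L or ("I" in r["cigar"] or "D" in r["cigar"])
            best = (r["editDistance"], has_indel, strand_seq)
    if best is not None and best[0] <= budget and not best[1]:
        return BindingRegionStatus(status="preserved", matched_len=L)
    # two-anchor search for an internal insertion
    half = L // 2
    left, right = window[:half], window[half:]
    for strand_seq in (target.seq, revcomp(target.seq)):
        rl = edlib.align(left, strand_seq, mode="HW", task="locations")
        rr = edlib.align(right, strand_seq, mode="HW", task="locations")
        if rl["editDistance"] < 0 or rr["editDistance"] < 0:
            continue
        if rl["editDistance"] > budget // 2 + 1 or rr["editDistance"] > budget // 2 + 1:
            continue
        for l_lo, l_hi in rl["locations"]:
            for r_lo, r_hi in rr["locations"]:
                ins = r_lo - (l_hi + 1)
                if ins >= 0:
                    return BindingRegionStatus(
                        status="preserved" if ins == 0 else "disrupted",
                        insertion_len=ins if ins > 0 else None,
                        matched_len=L if ins == 0 else None,
                    )
    return BindingRegionStatus(status="disrupted", insertion_len=None)


# ---------------------------------------------------------------------------
# Driver


def analyze_fission(
    target: Genome,
    ref: Genome,
    ref_model: GeneModel,
    plastomes: Sequence[Genome] = (),
    coverage: Optional[CoverageProfile] = None,
    thresholds: Optional[Thresholds] = None,
) -> FissionReport:
    """Run the full fission analysis and assemble a report."""
    thresholds = thresholds or Thresholds()
    fragments = locate_fragments(target, ref, ref_model, thresholds)
    report = FissionReport(fragments=fragments)
    if len(fragments) >= 2:
        report.break1_lost_aa, report.break2_lost_nt = infer_breakpoints(
            fragments, ref_model, thresholds.word_size
        )
    labels = {f.label for f in fragments}
    if {"FR2", "FR3"} <= labels:
        report.fr2_fr3_gap = analyze_gap(target, fragments, plastomes, thresholds)
    if {"FR1", "FR2"} <= labels:
        report.expansion = scan_expansion(target, fragments, ref_model)
    if ref_model.binding_region is not None:
        report.binding_region_status = binding_region_check(fragments, target, ref, ref_model)
    if coverage is not None and {"FR2", "FR3"} <= labels:
        report.splicing = splicing_call(coverage, fragments, ref_model, thresholds)
    return report
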