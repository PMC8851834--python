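"""Attribution of specific sequences to donor taxa and HGT-like calls.

Genus-/species-specific segments (from the partitioner) are searched
against a donor pool whose records carry a taxonomic-order label; the best
single hit per segment decides the attributed order.  Hits shorter than
100 bp are ignored; segments whose best hit exceeds 500 bp are flagged as
HGT-like, and those can be profiled across a panel of target genomes as a
per-base coverage-fraction matrix (the heatmap device for asking whether
relatives share any trace of the transfers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .homology import AlignmentParams, find_hits
from .model import Genome, HomologyHit, Interval, Thresholds, hit_sort_key


@dataclass
class DonorDB:
    """A pool of potential donor genomes, each labelled with its order."""

    records: list[tuple[Genome, str]]

    def __post_init__(self) -> None:
        for g, order in self.records:
            if not order:
                raise ValueError(f"donor record {g.id!r} lacks an order label")

    @classmethod
    def from_genome_set(cls, genome_set) -> "DonorDB":
        """Donors from a GenomeSet; the order label rides in ``species``
        (header token ``species=<Order>``) for want of a dedicated field."""
        recs = [(g, g.species or g.genus) for g in genome_set.donors]
        return cls(recs)


@dataclass
class Attribution:
    query: Interval
    best_hit: Optional[HomologyHit]
    order: str

    def __post_init__(self) -> None:
        if (self.best_hit is None) != (self.order == "unknown"):
            raise ValueError("order must be 'unknown' exactly when there is no hit")


def _segment_genome(segment: Interval, source: Genome) -> Genome:
    return Genome(
        id=f"{segment.seq_id}:{segment.start}-{segment.end}",
        seq=source.subseq(segment.start, segment.end),
    )


def attribute(
    specific_segments: Sequence[Interval],
    source: Genome,
    donor_db: DonorDB,
    thresholds: Optional[Thresholds] = None,
) -> list[Attribution]:
    """Best donor hit per specific segment; hits shorter than
    ``donor_hit_min_len`` (default 100 bp) count as no hit."""
    thresholds = thresholds or Thresholds()
    if not donor_db.records:
        raise ValueError("empty donor database")
    params = AlignmentParams.from_thresholds(thresholds)
    out = []
    for seg in specific_segments:
        qg = _segment_genome(seg, source)
        best: Optional[HomologyHit] = None
        best_order = "unknown"
        for donor, order in donor_db.records:
            for h in find_hits(qg, donor, params):
                if h.aln_len < thresholds.donor_hit_min_len:
                    continue
                if best is None or hit_sort_key(h) < hit_sort_key(best):
                    best, best_order = h, order
        out.append(Attribution(query=seg, best_hit=best, order=best_order))
    return out


def aggregate_by_order(
    attributions: Sequence[Attribution], thresholds: Optional[Thresholds] = None
) -> tuple[dict[str, int], dict[str, int]]:
    """Total attributed bp per order, and the display subset (orders whose
    total exceeds ``order_display_min``, default 5 kb; 'unknown' is always
    reported in the full map)."""
    thresholds = thresholds or Thresholds()
    totals: dict[str, int] = {}
    for a in attributions:
        totals[a.order] = totals.get(a.order, 0) + a.query.length
    display = {
        o: bp for o, bp in totals.items() if o != "unknown" and bp > thresholds.order_display_min
    }
    return totals, display


def hgt_like(
    attributions: Sequence[Attribution], thresholds: Optional[Thresholds] = None
) -> list[Interval]:
    """Segments whose best donor hit is strictly longer than
    ``hgt_like_min_len`` (default 500 bp)."""
    thresholds = thresholds or Thresholds()
    return [
        a.query
        for a in attributions
        if a.best_hit is not None and a.best_hit.aln_len > thresholds.hgt_like_min_len
    ]


def coverage_matrix(
    hgt_segments: Sequence[Interval],
    source: Genome,
    target_genomes: Sequence[Genome],
    thresholds: Optional[Thresholds] = None,
) -> pd.DataFrame:
    """Fraction of each segment covered by at least one qualifying hit
    (e-value filtered) against each target genome; rows are segments,
    columns are target genome ids, values in [0, 1]."""
    thresholds = thresholds or Thresholds()
    if not target_genomes:
        raise ValueError("at least one target genome is required")
    params = AlignmentParams.from_thresholds(thresholds)
    rows = {}
    for seg in hgt_segments:
        qg = _segment_genome(seg, source)
        row = {}
        for tg in target_genomes:
            mask = np.zeros(seg.length, dtype=bool)
            for h in find_hits(qg, tg, params):
                mask[h.q.start : h.q.end] = True
            row[tg.id] = float(mask.sum()) / seg.length
        rows[qg.id] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=[g.id for g in target_genomes])


def coverage_by_order(
    matrix: pd.DataFrame, attributions: Sequence[Attribution]
) -> pd.DataFrame:
    """Optional summarizer: mean coverage per attributed donor order."""
    order_of = {
        f"{a.query.seq_id}:{a.query.start}-{a.query.end}": a.order for a in attributions
    }
    grouped = matrix.groupby([order_of.get(i, "unknown") for i in matrix.index])
    return grouped.mean()
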