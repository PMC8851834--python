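"""Dissection of a mitogenome into five sequence classes.

Every base of a focal mitogenome is assigned to exactly one of:

* ``conserved``    — has a qualifying homolog in *every* other family
  mitogenome supplied;
* ``plastid_like`` — homologous to a family plastome at > 90% identity
  (putative plastid insertions, MTPT);
* ``repetitive``   — member of an internal repeat pair at > 95% identity;
* ``specific``     — no homology to any mitogenome of another genus
  (genus- or/and species-specific sequence, GSS);
* ``other``        — everything else (typically shared with some but not
  all relatives).

Classes can overlap as raw homology calls, so a fixed precedence makes
them disjoint: plastid_like > repetitive > conserved > specific > other.
Plastid-like wins because those bases have a known non-mitochondrial
origin regardless of any other homology they show.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .homology import AlignmentParams, find_hits, merge_hit_intervals, self_hits
from .model import ClassLabel, Genome, Interval, Thresholds

# painting codes, in increasing precedence
_CODE = {
    ClassLabel.OTHER: 0,
    ClassLabel.SPECIFIC: 1,
    ClassLabel.CONSERVED: 2,
    ClassLabel.REPETITIVE: 3,
    ClassLabel.PLASTID_LIKE: 4,
}
_LABEL = {v: k for k, v in _CODE.items()}


@dataclass
class PartitionResult:
    """Disjoint class-labelled segments tiling a genome, with totals."""

    genome_id: str
    segments: list[tuple[Interval, ClassLabel]]
    totals: dict[ClassLabel, int]
    proportions: dict[ClassLabel, float]
    metadata: dict = field(default_factory=dict)

    def total_len(self) -> int:
        return sum(self.totals.values())


def _paint(mask: np.ndarray, intervals: Sequence[Interval]) -> None:
    n = len(mask)
    for iv in intervals:
        if iv.end <= n:
            mask[iv.start : iv.end] = True
        else:  # origin-spanning (unwrapped) interval on a circular molecule
            mask[iv.start : n] = True
            mask[: iv.end - n] = True


def _mask_to_intervals(mask: np.ndarray, seq_id: str) -> list[Interval]:
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return [Interval(seq_id, int(s), int(e)) for s, e in zip(starts, ends)]


def plastid_like_intervals(
    focal: Genome, plastomes: Sequence[Genome], thresholds: Optional[Thresholds] = None
) -> list[Interval]:
    """Focal-side union of hits against any supplied plastome with identity
    above the plastid threshold (default > 90%)."""
    thresholds = thresholds or Thresholds()
    if not plastomes:
        raise ValueError("at least one plastome is required")
    params = AlignmentParams.from_thresholds(thresholds)
    mask = np.zeros(len(focal), dtype=bool)
    for pt in plastomes:
        hits = [
            h
            for h in find_hits(focal, pt, params)
            if h.identity > thresholds.plastid_identity_min
        ]
        _paint(mask, [h.q for h in hits])
    return _mask_to_intervals(mask, focal.id)


def repetitive_intervals(
    focal: Genome, thresholds: Optional[Thresholds] = None
) -> list[Interval]:
    """Both-side union of internal repeat hits above the repeat identity
    threshold (default > 95%)."""
    thresholds = thresholds or Thresholds()
    params = AlignmentParams.from_thresholds(thresholds)
    hits = [
        h for h in self_hits(focal, params) if h.identity > thresholds.repeat_identity_min
    ]
    mask = np.zeros(len(focal), dtype=bool)
    _paint(mask, [h.q for h in hits])
    _paint(mask, [h.s for h in hits])
    return _mask_to_intervals(mask, focal.id)


def conserved_intervals(
    focal: Genome,
    other_family_mitogenomes: Sequence[Genome],
    thresholds: Optional[Thresholds] = None,
) -> list[Interval]:
    """Bases of the focal genome with a qualifying hit in *all* other family
    mitogenomes."""
    thresholds = thresholds or Thresholds()
    if any(g.id == focal.id for g in other_family_mitogenomes):
        raise ValueError("the family set must not contain the focal genome itself")
    if len(other_family_mitogenomes) < 2:
        raise ValueError("need at least two other mitogenomes for a conserved call")
    params = AlignmentParams.from_thresholds(thresholds)
    mask = np.ones(len(focal), dtype=bool)
    for g in other_family_mitogenomes:
        gm = np.zeros(len(focal), dtype=bool)
        _paint(gm, [h.q for h in find_hits(focal, g, params)])
        mask &= gm
        if not mask.any():
            break
    return _mask_to_intervals(mask, focal.id)


def specific_intervals(
    focal: Genome,
    family_mitogenomes: Sequence[Genome],
    thresholds: Optional[Thresholds] = None,
    split_species_specific: bool = False,
):
    """Genus- or/and species-specific sequences (GSS) of the focal genome.

    A base is genus-specific when it has no qualifying hit against any
    mitogenome of *another* genus.  With ``split_species_specific=True`` the
    return value is ``(genus_specific, species_specific)`` where the second
    list is the subset with no hits against congeners either.
    """
    thresholds = thresholds or Thresholds()
    if not focal.genus:
        raise ValueError(f"focal genome {focal.id!r} lacks a genus label")
    params = AlignmentParams.from_thresholds(thresholds)
    others = [g for g in family_mitogenomes if g.id != focal.id]
    hit_other_genus = np.zeros(len(focal), dtype=bool)
    hit_congener = np.zeros(len(focal), dtype=bool)
    for g in others:
        target = hit_congener if g.genus == focal.genus else hit_other_genus
        _paint(target, [h.q for h in find_hits(focal, g, params)])
    genus_specific = _mask_to_intervals(~hit_other_genus, focal.id)
    if not split_species_specific:
        return genus_specific
    species_specific = _mask_to_intervals(~hit_other_genus & ~hit_congener, focal.id)
    return genus_specific, species_specific


def classify_genome(
    focal: Genome,
    family_mitogenomes: Sequence[Genome],
    plastomes: Sequence[Genome],
    thresholds: Optional[Thresholds] = None,
) -> PartitionResult:
    """Assign every base of ``focal`` to one of the five classes.

    Precedence (highest wins): plastid_like > repetitive > conserved >
    specific > other.  Segments are maximal runs of equal label and tile
    ``[0, len(focal))`` exactly.
    """
    thresholds = thresholds or Thresholds()
    others = [g for g in family_mitogenomes if g.id != focal.id]
    if len(others) != len(family_mitogenomes):
        raise ValueError("family set must exclude the focal genome")
    code = np.zeros(len(focal), dtype=np.int8)  # OTHER

    layers = [
        (ClassLabel.SPECIFIC, specific_intervals(focal, others, thresholds)),
        (ClassLabel.CONSERVED, conserved_intervals(focal, others, thresholds)),
        (ClassLabel.REPETITIVE, repetitive_intervals(focal, thresholds)),
        (ClassLabel.PLASTID_LIKE, plastid_like_intervals(focal, plastomes, thresholds)),
    ]
    for label, intervals in layers:
        mask = np.zeros(len(focal), dtype=bool)
        _paint(mask, intervals)
        code[mask] = _CODE[label]

    segments: list[tuple[Interval, ClassLabel]] = []
    boundaries = np.nonzero(np.diff(code))[0] + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(code)]))
    for s, e in zip(starts, ends):
        segments.append((Interval(focal.id, int(s), int(e)), _LABEL[int(code[s])]))

    totals = {label: 0 for label in ClassLabel}
    for iv, label in segments:
        totals[label] += iv.length
    n = len(focal)
    proportions = {label: totals[label] / n for label in ClassLabel}
    return PartitionResult(
        genome_id=focal.id,
        segments=segments,
        totals=totals,
        proportions=proportions,
        metadata={
            "precedence": [
                ClassLabel.PLASTID_LIKE.value,
                ClassLabel.REPETITIVE.value,
                ClassLabel.CONSERVED.value,
                ClassLabel.SPECIFIC.value,
                ClassLabel.OTHER.value,
            ],
            "thresholds": vars(thresholds),
        },
    )
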