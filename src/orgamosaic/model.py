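"""Core data model shared by every stage of the pipeline.

Coordinate convention: all in-memory intervals are 0-based, half-open
``[start, end)``.  On-disk formats keep their native conventions (GFF3 and
the 12-column hit table are 1-based inclusive, BED is 0-based half-open);
the translation happens exclusively in :mod:`orgamosaic.io`.

Circular sequences: features that span the origin of a circular molecule
are represented with ``end > seq_len`` ("unwrapped" coordinates) by the
homology engine and are split back into two in-frame segments wherever a
linear tiling is required.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class Topology(str, Enum):
    CIRCULAR = "circular"
    LINEAR = "linear"


class Role(str, Enum):
    MITOGENOME = "mitogenome"
    PLASTOME = "plastome"
    DONOR = "donor"


class ClassLabel(str, Enum):
    """The five mutually exclusive mitogenome sequence classes."""

    CONSERVED = "conserved"
    PLASTID_LIKE = "plastid_like"
    REPETITIVE = "repetitive"
    SPECIFIC = "specific"
    OTHER = "other"


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval.

    ``end`` may exceed the molecule length for origin-spanning features on
    circular sequences; callers that need linear coordinates split such
    intervals with :meth:`split_at`.
    """

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise ValueError(f"negative coordinate in {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.seq_id == other.seq_id and self.start < other.end and other.start < self.end

    def intersection_len(self, other: "Interval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def split_at(self, seq_len: int) -> list["Interval"]:
        """Split an unwrapped origin-spanning interval into linear pieces."""
        if self.end <= seq_len:
            return [self]
        return [
            Interval(self.seq_id, self.start, seq_len, self.strand),
            Interval(self.seq_id, 0, self.end - seq_len, self.strand),
        ]


@dataclass
class Genome:
    """A labelled organelle DNA sequence."""

    id: str
    seq: str
    genus: str = ""
    species: str = ""
    topology: Topology = Topology.LINEAR

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"genome {self.id!r} has an empty sequence")
        self.seq = self.seq.upper()
        bad = set(self.seq) - VALID_BASES
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise ValueError(
                f"genome {self.id!r}: invalid character {self.seq[pos]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology is Topology.CIRCULAR

    def subseq(self, start: int, end: int) -> str:
        """Sequence of ``[start, end)``; wraps around the origin when circular."""
        n = len(self.seq)
        if end <= n:
            return self.seq[start:end]
        if not self.is_circular:
            raise ValueError(f"interval ({start}, {end}) outside linear genome {self.id!r}")
        return self.seq[start:] + self.seq[: end - n]

    def revcomp(self) -> "Genome":
        return dataclasses.replace(self, id=self.id + "_rc", seq=revcomp(self.seq))


class GenomeSet:
    """A collection of genomes with role tags (mitogenome / plastome / donor)."""

    def __init__(self, genomes: Iterable[Genome], roles: Optional[dict[str, Role]] = None):
        self.genomes: list[Genome] = list(genomes)
        ids = [g.id for g in self.genomes]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate genome id {dup!r}")
        self.roles: dict[str, Role] = dict(roles or {})
        for g in self.genomes:
            self.roles.setdefault(g.id, Role.MITOGENOME)

    def __iter__(self) -> Iterator[Genome]:
        return iter(self.genomes)

    def __len__(self) -> int:
        return len(self.genomes)

    def __getitem__(self, genome_id: str) -> Genome:
        for g in self.genomes:
            if g.id == genome_id:
                return g
        raise KeyError(genome_id)

    def with_role(self, role: Role) -> list[Genome]:
        return [g for g in self.genomes if self.roles[g.id] is role]

    @property
    def mitogenomes(self) -> list[Genome]:
        return self.with_role(Role.MITOGENOME)

    @property
    def plastomes(self) -> list[Genome]:
        return self.with_role(Role.PLASTOME)

    @property
    def donors(self) -> list[Genome]:
        return self.with_role(Role.DONOR)


@dataclass
class Thresholds:
    """Tunable cut-offs of the analysis, with the study defaults.

    identity thresholds are percentages in (0, 100]; lengths in bp.
    """

    word_size: int = 16
    evalue_max: float = 1e-5
    plastid_identity_min: float = 90.0
    repeat_identity_min: float = 95.0
    donor_hit_min_len: int = 100
    hgt_like_min_len: int = 500
    order_display_min: int = 5000
    synteny_fragment_len: int = 50
    cov_low: int = 50
    cov_high: int = 400

    def __post_init__(self) -> None:
        for name in (
            "word_size",
            "donor_hit_min_len",
            "hgt_like_min_len",
            "order_display_min",
            "synteny_fragment_len",
            "cov_low",
            "cov_high",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        for name in ("plastid_identity_min", "repeat_identity_min"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ValueError(f"{name} must be in (0, 100]")


@dataclass(frozen=True)
class HomologyHit:
    """A local alignment between a query and a subject interval."""

    q: Interval
    s: Interval
    identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if not 0 < self.identity <= 100:
            raise ValueError(f"identity {self.identity} outside (0, 100]")
        if self.evalue < 0:
            raise ValueError("negative evalue")


def hit_sort_key(h: HomologyHit):
    """Canonical deterministic ordering: best bitscore first, then longest,
    then subject id, then leftmost subject start."""
    return (-h.bitscore, -h.aln_len, h.s.seq_id, h.s.start, h.q.start)


def merge_intervals(
    intervals: Iterable[tuple[int, int]], max_gap: int = 0
) -> list[tuple[int, int]]:
    """Union of (start, end) pairs, bridging gaps strictly smaller than max_gap."""
    ivs = sorted(intervals)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s - out[-1][1] < max_gap or (out and s <= out[-1][1]):
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]
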