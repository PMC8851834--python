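"""Synthetic organelle-genome families and gene-fission fixtures.

Everything downstream of raw assembly is exercised on generated data with
a full truth table: a family of related mitogenomes built from a shared
mutated core with planted plastome insertions, dispersed repeats,
donor-derived specific segments and partially shared blocks; fission
fixtures that reproduce the canonical broken-ccmFc layouts (lost coding
segment, intron break with or without an insertion, coding expansions,
binding-window insertion); and Poisson coverage profiles for the
cis/trans splicing regimes.

Determinism: the same config and seed give byte-identical sequences.

Planted junctions are "sanitized": the two bases flanking every planted
fragment are forced to differ from the corresponding reference
continuation, so that maximal homology extension stops exactly at the
planted boundary and breakpoint arithmetic is exact rather than blurred
by chance matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fission import CoverageProfile, GeneModel
from .model import ClassLabel, Genome, GenomeSet, Interval, Role, revcomp

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _mutate(rng: np.random.Generator, seq: str, sub_rate: float) -> str:
    if sub_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(arr)) < sub_rate)[0]
    for i in hit:
        old = arr[i].decode()
        choices = [b for b in "ACGT" if b != old]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _diff_base(rng: np.random.Generator, avoid: str) -> str:
    choices = [b for b in "ACGT" if b != avoid]
    return choices[rng.integers(0, len(choices))]


def _clean_codon(
    rng: np.random.Generator,
    forbid: frozenset = frozenset(_STOPS),
    avoid0: Optional[str] = None,
    avoid1: Optional[str] = None,
    avoid2: Optional[str] = None,
) -> str:
    while True:
        c = _rand_seq(rng, 3)
        if c in forbid:
            continue
        if avoid0 and c[0] == avoid0:
            continue
        if avoid1 and c[1] == avoid1:
            continue
        if avoid2 and c[2] == avoid2:
            continue
        return c


def _clean_codons(rng: np.random.Generator, n: int, forbid=frozenset(_STOPS)) -> str:
    return "".join(_clean_codon(rng, forbid) for _ in range(n))


# ---------------------------------------------------------------------------
# Family simulation


@dataclass
class PlantedFeature:
    interval: Interval
    label: ClassLabel
    donor_order: Optional[str] = None
    note: str = ""


@dataclass
class TruthTable:
    """Generator-side record of every planted feature, the test oracle."""

    features: dict[str, list[PlantedFeature]] = field(default_factory=dict)
    fixture: dict = field(default_factory=dict)
    events: dict[str, list] = field(default_factory=dict)

    def add(self, genome_id: str, feature: PlantedFeature) -> None:
        self.features.setdefault(genome_id, []).append(feature)

    def class_bp(self, genome_id: str) -> dict[ClassLabel, int]:
        out = {label: 0 for label in ClassLabel}
        for f in self.features.get(genome_id, []):
            out[f.label] += f.interval.length
        return out

    def proportions(self, genome_id: str) -> dict[ClassLabel, float]:
        bp = self.class_bp(genome_id)
        total = sum(bp.values())
        return {k: v / total for k, v in bp.items()}


@dataclass
class SimConfig:
    """Study conditions for a simulated mitogenome family.

    The defaults describe a desk-scale family of 3 genera x 2 species with
    a 50 kb shared core, ~10% plastid-like, ~5% repetitive, ~15% specific
    and ~5% partially shared content per genome, diverged at 2%
    substitutions per branch.
    """

    n_genera: int = 3
    species_per_genus: int = 2
    core_len: int = 50_000
    substitution_rate: float = 0.02
    indel_rate: float = 0.0
    plastome_len: int = 15_000
    donor_len: int = 30_000
    # every mitogenome receives its own copies drawn from these specs
    plastid_insert_spec: list[tuple[int, float]] = field(
        default_factory=lambda: [(2800, 100.0), (2800, 100.0), (2100, 100.0)]
    )
    repeat_spec: list[tuple[int, int, float, str]] = field(
        default_factory=lambda: [(1000, 2, 100.0, "direct"), (900, 2, 100.0, "inverted")]
    )
    # per-species donor-derived segments; None = the default recipe for all
    specific_spec: Optional[dict[str, list[tuple[str, int]]]] = None
    default_specific: list[tuple[str, int]] = field(
        default_factory=lambda: [
            ("Fabales", 2900),
            ("Solanales", 2900),
            ("Lamiales", 2900),
            ("Malpighiales", 2800),
        ]
    )
    shared_spec: list[int] = field(default_factory=lambda: [1900, 1900])
    circular: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_rate < 1 and 0 <= self.indel_rate < 1):
            raise ValueError("rates must be in [0, 1)")
        for ln, ident in self.plastid_insert_spec:
            if ln <= 0 or not 0 < ident <= 100:
                raise ValueError("invalid plastid_insert_spec entry")
        total_inserts = sum(ln for ln, _ in self.plastid_insert_spec) + sum(
            ln * c for ln, c, _, _ in self.repeat_spec
        )
        if total_inserts > 10 * self.core_len:
            raise ValueError("planted features exceed genome capacity")

    def species_ids(self) -> list[str]:
        return [
            f"G{g + 1}_sp{s + 1}"
            for g in range(self.n_genera)
            for s in range(self.species_per_genus)
        ]


class _Assembler:
    """Builds a genome by interleaving core chunks with planted features,
    recording truth intervals as it goes."""

    def __init__(self, genome_id: str):
        self.genome_id = genome_id
        self.pieces: list[str] = []
        self.length = 0
        self.planted: list[PlantedFeature] = []

    def add(self, seq: str, label: ClassLabel, order: Optional[str] = None, note: str = ""):
        if not seq:
            return
        iv = Interval(self.genome_id, self.length, self.length + len(seq))
        self.planted.append(PlantedFeature(iv, label, order, note))
        self.pieces.append(seq)
        self.length += len(seq)

    def sequence(self) -> str:
        return "".join(self.pieces)


def simulate_family(config: SimConfig) -> tuple[GenomeSet, TruthTable, "DonorDB"]:
    """Generate a mitogenome family, its plastome, and a donor pool.

    Returns ``(genome_set, truth, donor_db)``; the genome set contains the
    mitogenomes plus one family plastome, the donor pool carries the
    taxon-order labels used for the specific segments.
    """
    from .attribution import DonorDB
    from .model import Topology

    rng = np.random.default_rng(config.seed)
    core = _rand_seq(rng, config.core_len)
    plastome_seq = _rand_seq(rng, config.plastome_len)
    topo = Topology.CIRCULAR if config.circular else Topology.LINEAR

    species = config.species_ids()
    spec_by_species = {
        sid: (config.specific_spec or {}).get(sid, config.default_specific) for sid in species
    }
    orders = sorted({o for lst in spec_by_species.values() for o, _ in lst})
    donor_seqs = {o: _rand_seq(rng, config.donor_len) for o in orders}
    donor_cursor = {o: 0 for o in orders}

    # shared blocks: planted into pairs of genomes from different genera
    shared_blocks = [_rand_seq(rng, ln) for ln in config.shared_spec]

    truth = TruthTable()
    genomes = []
    for gi, sid in enumerate(species):
        grng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1000 + gi]).generate_state(1)[0]
        )
        mutated_core = _mutate(grng, core, config.substitution_rate)
        inserts: list[tuple[str, ClassLabel, Optional[str], str]] = []
        for ln, ident in config.plastid_insert_spec:
            start = int(grng.integers(0, config.plastome_len - ln))
            copy = _mutate(grng, plastome_seq[start : start + ln], 1 - ident / 100)
            inserts.append((copy, ClassLabel.PLASTID_LIKE, None, f"pt:{start}"))
        for ln, copies, ident, orientation in config.repeat_spec:
            unit = _rand_seq(grng, ln)
            for c in range(copies):
                copy = _mutate(grng, unit, 1 - ident / 100)
                if orientation == "inverted" and c % 2 == 1:
                    copy = revcomp(copy)
                inserts.append((copy, ClassLabel.REPETITIVE, None, f"repeat_unit_{ln}"))
        for order, ln in spec_by_species[sid]:
            cur = donor_cursor[order]
            if cur + ln > config.donor_len:
                raise ValueError("donor pool exhausted; increase donor_len")
            seg = donor_seqs[order][cur : cur + ln]
            donor_cursor[order] = cur + ln
            inserts.append((seg, ClassLabel.SPECIFIC, order, "donor_copy"))
        genus = sid.split("_")[0]
        for bi, block in enumerate(shared_blocks):
            carrier_a = species[(2 * bi) % len(species)]
            partner = species[(2 * bi + config.species_per_genus) % len(species)]
            if sid in (carrier_a, partner):
                inserts.append((block, ClassLabel.OTHER, None, f"shared_block_{bi}"))

        asm = _Assembler(sid)
        n_ins = len(inserts)
        cuts = sorted(grng.choice(np.arange(1, len(mutated_core)), size=n_ins, replace=False))
        order_perm = grng.permutation(n_ins)
        prev = 0
        for k, cut in enumerate(cuts):
            asm.add(mutated_core[prev:cut], ClassLabel.CONSERVED, note="core")
            seq, label, order, note = inserts[order_perm[k]]
            asm.add(seq, label, order, note)
            prev = cut
        asm.add(mutated_core[prev:], ClassLabel.CONSERVED, note="core")
        g = Genome(id=sid, seq=asm.sequence(), genus=genus, species=sid, topology=topo)
        genomes.append(g)
        for f in asm.planted:
            truth.add(sid, f)

    plastome = Genome(id="family_pt", seq=plastome_seq, topology=topo)
    roles = {g.id: Role.MITOGENOME for g in genomes}
    roles["family_pt"] = Role.PLASTOME
    gs = GenomeSet(genomes + [plastome], roles)
    donor_db = DonorDB(
        records=[
            (Genome(id=f"donor_{o}", seq=donor_seqs[o], species=o), o) for o in orders
        ]
    )
    return gs, truth, donor_db


# ---------------------------------------------------------------------------
# Rearrangements (synteny fixtures)


def apply_rearrangements(
    genome: Genome,
    n_inversions: int = 0,
    n_translocations: int = 0,
    seed: int = 0,
    min_len: int = 2000,
    max_len: int = 8000,
    snap: int = 50,
) -> tuple[Genome, list[dict]]:
    """Apply non-overlapping inversions/translocations; returns the
    rearranged genome and the event list (kind, original span).

    Event boundaries are snapped to multiples of ``snap`` (default: the
    synteny fragment length) so that fixed-window fragment anchors survive
    orientation flips — an off-grid inversion shifts the fragment frame of
    the flipped copy and its anchors would dissolve.
    """
    rng = np.random.default_rng(seed)
    n_events = n_inversions + n_translocations
    seq = genome.seq
    events: list[dict] = []
    spans: list[tuple[int, int]] = []
    attempts = 0
    while len(spans) < n_events:
        attempts += 1
        if attempts > 1000:
            raise ValueError("could not place non-overlapping rearrangements")
        ln = int(rng.integers(min_len, max_len + 1)) // snap * snap
        start = int(rng.integers(0, len(seq) - ln)) // snap * snap
        if all(start + ln + min_len // 2 <= s or e + min_len // 2 <= start for s, e in spans):
            spans.append((start, start + ln))
    spans.sort()
    kinds = ["inversion"] * n_inversions + ["translocation"] * n_translocations
    rng.shuffle(kinds)
    out = []
    prev = 0
    moved: list[str] = []
    for (s, e), kind in zip(spans, kinds):
        out.append(seq[prev:s])
        if kind == "inversion":
            out.append(revcomp(seq[s:e]))
        else:
            moved.append(seq[s:e])
        events.append({"kind": kind, "start": s, "end": e})
        prev = e
    out.append(seq[prev:])
    new_seq = "".join(out) + "".join(moved)  # translocated blocks move to the end
    g = Genome(
        id=genome.id + "_rearr",
        seq=new_seq,
        genus=genome.genus,
        species=genome.species,
        topology=genome.topology,
    )
    return g, events


# ---------------------------------------------------------------------------
# Fission fixtures

# reference gene geometry (gene-local nt coordinates)
EXON1_LEN = 720  # 240 codons
INTRON_LEN = 1200
EXON2_LEN = 606  # 201 codons + stop
GENE_LEN = EXON1_LEN + INTRON_LEN + EXON2_LEN
BREAK1_LO = 489  # first break removes codons 164..206 -> 43 aa
BREAK1_HI = 618
INTRON_BREAK = 1320  # second break, inside the intron, no base loss
BINDING_LO, BINDING_HI = 1500, 1548  # the 48-nt protein-binding window
REF_FLANK = 500
FIXTURE_PRESETS = (
    "intact",
    "leafy",
    "sweet_potato",
    "epilinum",
    "grammica",
    "americana",
    "dodder_truncated",
)


def _make_reference(rng: np.random.Generator) -> tuple[Genome, GeneModel]:
    exon1 = "ATG" + _clean_codons(rng, EXON1_LEN // 3 - 1)
    intron = _rand_seq(rng, INTRON_LEN)
    exon2 = _clean_codons(rng, EXON2_LEN // 3 - 1) + "TAA"
    gene = exon1 + intron + exon2
    ref_seq = _rand_seq(rng, REF_FLANK) + gene + _rand_seq(rng, REF_FLANK)
    ref = Genome(id="ref_genome", seq=ref_seq)
    model = GeneModel(
        gene_id="ccmFc",
        exons=[
            Interval("ref_genome", REF_FLANK, REF_FLANK + EXON1_LEN),
            Interval(
                "ref_genome",
                REF_FLANK + EXON1_LEN + INTRON_LEN,
                REF_FLANK + GENE_LEN,
            ),
        ],
        strand="+",
        protein_len=(EXON1_LEN + EXON2_LEN) // 3 - 1,
        binding_region=Interval("ref_genome", REF_FLANK + BINDING_LO, REF_FLANK + BINDING_HI),
    )
    return ref, model


def _mutate_interior(rng: np.random.Generator, seq: str, rate: float, margin: int = 3) -> str:
    if rate <= 0 or len(seq) <= 2 * margin:
        return seq
    mid = _mutate(rng, seq[margin:-margin], rate)
    return seq[:margin] + mid + seq[-margin:]


def simulate_fission_fixture(
    preset: str, seed: int = 0, substitution_rate: float = 0.0
) -> tuple[Genome, Genome, GeneModel, Genome, TruthTable]:
    """Build a target genome carrying a preset broken-gene layout.

    Returns ``(target, ref_genome, ref_model, plastome, truth)``.

    Presets:

    * ``intact``          — one unbroken gene copy.
    * ``leafy``           — FR1 relocated; FR2/FR3 adjacent with a 3,500 bp
      insertion of which 2,800 bp is an exact plastome copy.
    * ``sweet_potato``    — leafy layout plus planted coding expansions:
      first in-frame stop 185 codons past the FR1 break, first usable
      in-frame ATG 118 codons before the FR2 break.
    * ``epilinum``        — the insertion shrunk to 1,300 bp.
    * ``grammica``        — FR2 and FR3 separated to distant loci.
    * ``americana``       — separated, plus a 28 bp insertion in the middle
      of the 48-nt intron binding window.
    * ``dodder_truncated``— separated, with a nonsense codon 10 codons past
      the FR1 break (truncated ccmFc1 expansion).

    ``substitution_rate`` mutates the interiors of the planted fragments
    (3 bp junction margins kept intact) to probe robustness.
    """
    if preset not in FIXTURE_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {FIXTURE_PRESETS}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]).generate_state(1)[0])
    ref, model = _make_reference(rng)
    gene = model.gene_seq(ref)
    plastome_seq = _rand_seq(rng, 6000)
    plastome = Genome(id="fixture_pt", seq=plastome_seq)
    truth = TruthTable()
    truth.fixture["preset"] = preset

    if preset == "intact":
        target_seq = _rand_seq(rng, 1000) + gene + _rand_seq(rng, 1000)
        target = Genome(id="target", seq=target_seq)
        truth.fixture["fragments"] = {"FR1": {"ref_span": (0, GENE_LEN)}}
        return target, ref, model, plastome, truth

    separated = preset in ("grammica", "americana", "dodder_truncated")
    insertion_total, plastid_part = {
        "leafy": (3500, 2800),
        "sweet_potato": (3500, 2800),
        "epilinum": (1300, 1000),
    }.get(preset, (None, None))

    fr1 = _mutate_interior(rng, gene[:BREAK1_LO], substitution_rate)
    fr2 = _mutate_interior(rng, gene[BREAK1_HI:INTRON_BREAK], substitution_rate)
    fr3_seq = gene[INTRON_BREAK:]
    bind_insert_len = 28 if preset == "americana" else 0
    if bind_insert_len:
        # insert at the midpoint of the binding window
        mid = (BINDING_LO + BINDING_HI) // 2 - INTRON_BREAK
        ins = _rand_seq(rng, bind_insert_len)
        ins = (
            _diff_base(rng, fr3_seq[mid])
            + ins[1:-1]
            + _diff_base(rng, fr3_seq[mid - 1])
        )
        fr3_seq = fr3_seq[:mid] + ins + fr3_seq[mid:]
    fr3 = _mutate_interior(rng, fr3_seq, substitution_rate)

    # --- the region downstream of FR1 (the ccmFc1 expansion) ---
    exp1_codons = {"sweet_potato": 185, "dodder_truncated": 10}.get(preset)
    first = _clean_codon(rng, avoid0=gene[BREAK1_LO], avoid1=gene[BREAK1_LO + 1])
    if exp1_codons is not None:
        post_fr1 = first + _clean_codons(rng, exp1_codons - 1) + "TAA" + _rand_seq(rng, 300)
        truth.fixture["ccmFc1_expansion_aa"] = exp1_codons
    else:
        post_fr1 = first + _rand_seq(rng, 600)

    # --- the region upstream of FR2 (the ccmFc2 expansion) ---
    no_atg = frozenset(_STOPS | {"ATG"})
    exp2_codons = 118 if not separated or preset == "dodder_truncated" else 118
    last = _clean_codon(
        rng, forbid=no_atg, avoid1=gene[BREAK1_HI - 2], avoid2=gene[BREAK1_HI - 1]
    )
    pre_fr2 = (
        _rand_seq(rng, 300)
        + "ATG"
        + "".join(_clean_codon(rng, forbid=no_atg) for _ in range(exp2_codons - 2))
        + last
    )
    truth.fixture["ccmFc2_expansion_aa"] = exp2_codons

    pieces = [_rand_seq(rng, 800), fr1, post_fr1, _rand_seq(rng, 1500), pre_fr2, fr2]
    frag_truth = {}
    pos = 0
    for p, name in zip(pieces, (None, "FR1", None, None, None, "FR2")):
        if name:
            frag_truth[name] = {"target_start": pos, "target_end": pos + len(p)}
        pos += len(p)

    if not separated:
        fill = insertion_total - plastid_part
        fill_l, fill_r = fill // 2, fill - fill // 2
        pt_start = 1000
        pt_copy = plastome_seq[pt_start : pt_start + plastid_part]
        left = _rand_seq(rng, fill_l)
        left = (
            _diff_base(rng, gene[INTRON_BREAK])
            + _diff_base(rng, gene[INTRON_BREAK + 1])
            + left[2 : fill_l - 2]
            + _diff_base(rng, plastome_seq[pt_start - 2])
            + _diff_base(rng, plastome_seq[pt_start - 1])
        )
        right = _rand_seq(rng, fill_r)
        right = (
            _diff_base(rng, plastome_seq[pt_start + plastid_part])
            + _diff_base(rng, plastome_seq[pt_start + plastid_part + 1])
            + right[2 : fill_r - 2]
            + _diff_base(rng, gene[INTRON_BREAK - 2])
            + _diff_base(rng, gene[INTRON_BREAK - 1])
        )
        insertion = left + pt_copy + right
        truth.fixture["insertion"] = {
            "len": len(insertion),
            "plastid_bp": plastid_part,
            "filler_bp": len(insertion) - plastid_part,
        }
        pieces += [insertion, fr3, _rand_seq(rng, 800)]
        frag_truth["FR3"] = {
            "target_start": pos + len(insertion),
            "target_end": pos + len(insertion) + len(fr3),
        }
    else:
        sep = _rand_seq(rng, 15_000)
        sep = (
            _diff_base(rng, gene[INTRON_BREAK])
            + _diff_base(rng, gene[INTRON_BREAK + 1])
            + sep[2:-2]
            + _diff_base(rng, gene[INTRON_BREAK - 2])
            + _diff_base(rng, gene[INTRON_BREAK - 1])
        )
        truth.fixture["separation_bp"] = len(sep)
        pieces += [sep, fr3, _rand_seq(rng, 800)]
        frag_truth["FR3"] = {
            "target_start": pos + len(sep),
            "target_end": pos + len(sep) + len(fr3),
        }

    truth.fixture["fragments"] = frag_truth
    truth.fixture["break1_lost_aa"] = (BREAK1_HI - BREAK1_LO) // 3
    truth.fixture["break2_lost_nt"] = 0
    truth.fixture["binding_insert_len"] = bind_insert_len or None
    target = Genome(id="target", seq="".join(pieces))
    return target, ref, model, plastome, truth


# ---------------------------------------------------------------------------
# Quadripartite plastome fixture

_COMP1 = {"A": "T", "T": "A", "C": "G", "G": "C"}


def make_quadripartite(
    seed: int = 0, lsc_len: int = 8000, ir_len: int = 2500, ssc_len: int = 1500
) -> tuple[Genome, dict]:
    """A circular LSC + IRb + SSC + IRa plastome with sanitized junctions.

    The bases flanking each IR copy are forced to break reverse
    complementarity, so the maximal inverted-repeat extension equals the
    planted coordinates exactly.  Returns the genome and a truth dict with
    region intervals in the generated (LSC-first) frame.
    """
    from .model import Topology

    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]).generate_state(1)[0])
    lsc = list(_rand_seq(rng, lsc_len))
    ir = _rand_seq(rng, ir_len)
    ssc = list(_rand_seq(rng, ssc_len))
    # inner IR junctions: first SSC base must not pair with the last SSC base
    while ssc[0] == _COMP1[ssc[-1]]:
        ssc[0] = _diff_base(rng, ssc[0])
    # outer IR junctions: last LSC base must not pair with the first LSC base
    while lsc[-1] == _COMP1[lsc[0]]:
        lsc[-1] = _diff_base(rng, lsc[-1])
    seq = "".join(lsc) + ir + "".join(ssc) + revcomp(ir)
    genome = Genome(id=f"qp_{seed}", seq=seq, topology=Topology.CIRCULAR)
    truth = {
        "lsc": (0, lsc_len),
        "irb": (lsc_len, lsc_len + ir_len),
        "ssc": (lsc_len + ir_len, lsc_len + ir_len + ssc_len),
        "ira": (lsc_len + ir_len + ssc_len, len(seq)),
        "ir_len": ir_len,
    }
    return genome, truth


# ---------------------------------------------------------------------------
# Coverage simulation


def simulate_coverage(
    genome: Genome,
    expressed_intervals: Sequence[Interval],
    regime: str,
    base_depth: int = 500,
    seed: int = 0,
    intron_intervals: Optional[Sequence[Interval]] = None,
) -> CoverageProfile:
    """Poisson per-base coverage for a splicing regime.

    Expressed intervals get mean ``base_depth``; the intron-side intervals
    (by default the gaps between consecutive expressed intervals) get mean
    10 under ``trans_like`` and ``0.8 * base_depth`` under ``cis_like``;
    background mean is 2.
    """
    if regime not in ("cis_like", "trans_like"):
        raise ValueError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(seed)
    depth = rng.poisson(2, size=len(genome.seq))
    if intron_intervals is None:
        ivs = sorted(expressed_intervals, key=lambda iv: iv.start)
        intron_intervals = [
            Interval(genome.id, a.end, b.start)
            for a, b in zip(ivs, ivs[1:])
            if b.start > a.end
        ]
    intron_mean = 10 if regime == "trans_like" else 0.8 * base_depth
    for iv in intron_intervals:
        depth[iv.start : iv.end] = rng.poisson(intron_mean, size=iv.length)
    for iv in expressed_intervals:
        depth[iv.start : iv.end] = rng.poisson(base_depth, size=iv.length)
    return CoverageProfile(seq_id=genome.id, depth=depth)
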