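"""Readers and writers for the on-disk formats the pipeline touches.

FASTA headers may carry ``key=value`` tokens after the record id
(``genus=``, ``species=``, ``topology=``, ``role=``, ``order=``), which is how
genome metadata travels without a side-car file.  GFF3 and the 12-column hit
table are 1-based inclusive on disk and converted to the internal 0-based
half-open convention here; BED stays 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    ClassLabel,
    Genome,
    GenomeSet,
    HomologyHit,
    Interval,
    Role,
    Thresholds,
    Topology,
)


class FormatError(ValueError):
    pass


def _parse_header(description: str) -> dict[str, str]:
    tokens = description.split()
    meta = {}
    for tok in tokens[1:]:
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k.lower()] = v
    return meta


def read_fasta(path: str | Path) -> GenomeSet:
    """Load a FASTA file into a :class:`GenomeSet`.

    Record order is preserved; sequences are uppercased; characters outside
    ``{A,C,G,T,N}`` raise with the offending record and position named.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    genomes, roles = [], {}
    for rec in records:
        meta = _parse_header(rec.description)
        topology = Topology(meta.get("topology", "linear"))
        g = Genome(
            id=rec.id,
            seq=str(rec.seq),
            genus=meta.get("genus", ""),
            species=meta.get("species", ""),
            topology=topology,
        )
        genomes.append(g)
        roles[g.id] = Role(meta.get("role", "mitogenome"))
    return GenomeSet(genomes, roles)


def write_fasta(genome_set: GenomeSet, path: str | Path, width: int = 70) -> None:
    records = []
    for g in genome_set:
        desc = []
        if g.genus:
            desc.append(f"genus={g.genus}")
        if g.species:
            desc.append(f"species={g.species}")
        desc.append(f"topology={g.topology.value}")
        desc.append(f"role={genome_set.roles[g.id].value}")
        records.append(SeqRecord(Seq(g.seq), id=g.id, description=" ".join(desc)))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_gff3(path: str | Path, genome: Genome) -> list["GeneModel"]:
    """Parse gene/exon features for ``genome`` into :class:`GeneModel` objects.

    GFF3 coordinates (1-based inclusive) become 0-based half-open; introns
    are derived as the gaps between consecutive exons in 5'->3' order.
    """
    import gffutils

    from .fission import GeneModel

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    models = []
    for gene in db.features_of_type("gene"):
        if gene.seqid != genome.id:
            continue
        exons = []
        for ex in db.children(gene, featuretype="exon", order_by="start"):
            start, end = ex.start - 1, ex.end
            if start < 0 or end > len(genome):
                raise ValueError(
                    f"exon {ex.start}..{ex.end} outside genome {genome.id!r} (len {len(genome)})"
                )
            exons.append(Interval(genome.id, start, end, gene.strand or "+"))
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in gene {gene.id!r}")
        if gene.strand == "-":
            exons = exons[::-1]  # 5'->3' on the gene strand
        models.append(GeneModel(gene_id=gene.id, exons=exons, strand=gene.strand or "+"))
    return models


def write_gff3(models: Sequence["GeneModel"], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for m in models:
        exons = sorted(m.exons, key=lambda e: e.start)
        span = (exons[0].start + 1, exons[-1].end)
        sid = exons[0].seq_id
        lines.append(
            f"{sid}\torgamosaic\tgene\t{span[0]}\t{span[1]}\t.\t{m.strand}\t.\tID={m.gene_id}"
        )
        for i, ex in enumerate(exons, 1):
            lines.append(
                f"{sid}\torgamosaic\texon\t{ex.start + 1}\t{ex.end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}.exon{i};Parent={m.gene_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED / hit table / reports


def write_bed(intervals_with_labels: Iterable[tuple[Interval, str]], path: str | Path) -> None:
    """BED4: 0-based half-open with the class label in column 4. No header."""
    with open(path, "w") as fh:
        for iv, label in intervals_with_labels:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{label}\n")


def read_bed(path: str | Path) -> list[tuple[Interval, str]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        label = parts[3] if len(parts) > 3 else ""
        out.append((Interval(parts[0], int(parts[1]), int(parts[2])), label))
    return out


_HIT_COLS = (
    "query subject identity length mismatches gapopens "
    "qstart qend sstart send evalue bitscore"
).split()


def write_tsv_hits(hits: Sequence[HomologyHit], path: str | Path) -> None:
    """12-column tabular hit format, 1-based inclusive coordinates.

    Minus-strand subject hits are written with sstart > send, as BLAST does.
    """
    with open(path, "w") as fh:
        for h in hits:
            if h.s.strand == "+":
                ss, se = h.s.start + 1, h.s.end
            else:
                ss, se = h.s.end, h.s.start + 1
            fh.write(
                f"{h.q.seq_id}\t{h.s.seq_id}\t{h.identity:.2f}\t{h.aln_len}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.q.start + 1}\t{h.q.end}\t"
                f"{ss}\t{se}\t{h.evalue:.2g}\t{h.bitscore:.1f}\n"
            )


def read_tsv_hits(path: str | Path) -> list[HomologyHit]:
    hits = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        qs, qe = int(f[6]) - 1, int(f[7])
        ss, se = int(f[8]), int(f[9])
        strand = "+" if ss <= se else "-"
        s_lo, s_hi = (ss - 1, se) if strand == "+" else (se - 1, ss)
        hits.append(
            HomologyHit(
                q=Interval(f[0], qs, qe),
                s=Interval(f[1], s_lo, s_hi, strand),
                identity=float(f[2]),
                aln_len=int(f[3]),
                mismatches=int(f[4]),
                gap_opens=int(f[5]),
                evalue=float(f[10]),
                bitscore=float(f[11]),
            )
        )
    return hits


def write_report(report: dict, path: str | Path) -> None:
    """JSON with stable key order (insertion order preserved, no re-sorting)."""
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, ClassLabel):
        return obj.value
    if isinstance(obj, Interval):
        return {"seq_id": obj.seq_id, "start": obj.start, "end": obj.end, "strand": obj.strand}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


# ---------------------------------------------------------------------------
# Coverage profiles and threshold files


def read_coverage_tsv(path: str | Path, genome: Genome) -> np.ndarray:
    """Per-base depth table (``position<TAB>depth``, 1-based positions).

    Positions absent from the file get depth 0; the returned array has one
    entry per base of ``genome``.
    """
    depth = np.zeros(len(genome), dtype=np.int64)
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        pos_s, d_s = line.split("\t")[:2]
        pos = int(pos_s) - 1
        if not 0 <= pos < len(genome):
            raise ValueError(f"coverage position {pos + 1} outside genome {genome.id!r}")
        depth[pos] = int(d_s)
    return depth


def write_coverage_tsv(depth: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, d in enumerate(depth, 1):
            fh.write(f"{i}\t{int(d)}\n")


def read_thresholds(path: Optional[str | Path]) -> Thresholds:
    """Plain ``key=value`` config mirroring the Thresholds fields."""
    if path is None:
        return Thresholds()
    kwargs = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        k, v = line.split("=", 1)
        k = k.strip()
        field_types = Thresholds.__annotations__
        if k not in field_types:
            raise ValueError(f"unknown threshold {k!r}")
        typ = {"int": int, "float": float}[field_types[k]]
        kwargs[k] = typ(v.strip())
    return Thresholds(**kwargs)
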