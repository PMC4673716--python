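"""Readers and writers for the standard formats the pipeline touches.

One coordinate convention applies everywhere inside the package: 0-based
half-open intervals.  GFF3 (1-based inclusive) and PSL are converted at the
format boundary and nowhere else.  FASTA/FASTQ parsing is delegated to
Biopython; GFF3 feature bookkeeping to gffutils; PSL (21-column) is read and
written directly since no maintained parser exists for it.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import gffutils
import numpy as np
from Bio import SeqIO

from .mapping import SplicedAlignment


class ParseError(ValueError):
    pass


@dataclass
class SeqRecord:
    id: str
    sequence: str
    qualities: np.ndarray | None = None  # per-base phred scores

    def __post_init__(self):
        if self.qualities is not None and \
                len(self.qualities) != len(self.sequence):
            raise ParseError(
                f"record {self.id}: quality length != sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]  # merged union, 0-based half-open, sorted
    biotype: str = "protein_coding"
    transcripts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class JunctionRecord:
    contig: str
    donor_pos: int      # genomic start of the intron (0-based)
    acceptor_pos: int   # genomic end of the intron (exclusive)
    strand: str
    motif: str = "other"   # GT-AG / GC-AG / AT-AC / other
    support_count: int = 0

    def __post_init__(self):
        if self.acceptor_pos <= self.donor_pos:
            raise ValueError("acceptor_pos must exceed donor_pos")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.contig, self.donor_pos, self.acceptor_pos, self.strand)


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta(path) -> Iterator[SeqRecord]:
    """Stream records, uppercased, order preserved; duplicate ids rejected."""
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if not rec.id:
            raise ParseError(f"{path}: record {i + 1} has an empty id")
        if len(rec.seq) == 0:
            raise ParseError(f"{path}: record {rec.id} has an empty sequence")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id}")
        seen.add(rec.id)
        yield SeqRecord(id=rec.id, sequence=str(rec.seq).upper())


def write_fasta(records: Iterable[SeqRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_fastq(path) -> Iterator[SeqRecord]:
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fastq"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id}")
        seen.add(rec.id)
        quals = np.array(rec.letter_annotations["phred_quality"],
                         dtype=np.int16)
        yield SeqRecord(id=rec.id, sequence=str(rec.seq).upper(),
                        qualities=quals)


def write_fastq(records: Iterable[SeqRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.qualities is None:
                qual = "I" * len(rec.sequence)
            else:
                qual = "".join(chr(int(q) + 33) for q in rec.qualities)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


# --------------------------------------------------------------------- GFF3

def read_gff3_genes(path) -> list[GeneModel]:
    """Parse gene/mRNA/exon features into GeneModels (0-based half-open).

    Exons are grouped per mRNA (kept in ``transcripts``) and unioned into the
    gene-level ``exons`` list.  Orphan exons and unknown strands are errors.
    """
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True,
                            merge_strategy="create_unique")
    models: list[GeneModel] = []
    for exon in db.features_of_type("exon"):
        if "Parent" not in exon.attributes:
            raise ParseError(f"{path}: exon at {exon.seqid}:{exon.start} "
                             "has no Parent")
    for gene in db.features_of_type("gene"):
        if gene.strand not in ("+", "-"):
            raise ParseError(
                f"{path}: gene {gene.id} has unknown strand {gene.strand!r}")
        transcripts: dict[str, list[tuple[int, int]]] = {}
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = sorted((e.start - 1, e.end)
                           for e in db.children(mrna, featuretype="exon"))
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 < e1:
                    raise ParseError(
                        f"{path}: overlapping exons in mRNA {mrna.id}")
            transcripts[mrna.id] = exons
        if not transcripts:
            exons = sorted((e.start - 1, e.end)
                           for e in db.children(gene, featuretype="exon"))
            if exons:
                transcripts[gene.id + ".1"] = exons
        if not transcripts:
            continue
        union = _merge_intervals(
            iv for exons in transcripts.values() for iv in exons)
        biotype = gene.attributes.get("biotype", ["protein_coding"])[0]
        models.append(GeneModel(gene_id=gene.id, contig=gene.seqid,
                                strand=gene.strand, exons=union,
                                biotype=biotype, transcripts=transcripts))
    return models


def write_genes_gff3(models: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in models:
            if not gm.exons:
                raise ValueError(f"gene {gm.gene_id} has no exons")
            fh.write(f"{gm.contig}\tisoscan\tgene\t{gm.start + 1}\t{gm.end}\t"
                     f".\t{gm.strand}\t.\tID={gm.gene_id};"
                     f"biotype={gm.biotype}\n")
            transcripts = gm.transcripts or {gm.gene_id + ".1": gm.exons}
            for tid, exons in transcripts.items():
                fh.write(f"{gm.contig}\tisoscan\tmRNA\t{exons[0][0] + 1}\t"
                         f"{exons[-1][1]}\t.\t{gm.strand}\t.\t"
                         f"ID={tid};Parent={gm.gene_id}\n")
                for s, e in sorted(exons):
                    fh.write(f"{gm.contig}\tisoscan\texon\t{s + 1}\t{e}\t.\t"
                             f"{gm.strand}\t.\tParent={tid}\n")


def write_transcripts_gff3(transcripts, path) -> None:
    """Write transcript-like objects (gene_id/transcript_id/contig/strand/
    exons attributes or equivalent) as gene+mRNA+exon features.

    Round-trip safe: ``read_gff3_genes`` reproduces the coordinates exactly.
    """
    models: dict[str, GeneModel] = {}
    for tr in transcripts:
        exons = sorted(tr.exons)
        if not exons:
            raise ValueError(
                f"transcript {tr.transcript_id} has no exons")
        gid = getattr(tr, "locus_id", None) or getattr(tr, "gene_id")
        gm = models.get(gid)
        if gm is None:
            gm = GeneModel(gene_id=gid, contig=tr.contig, strand=tr.strand,
                           exons=[])
            models[gid] = gm
        gm.transcripts[tr.transcript_id] = exons
    for gm in models.values():
        gm.exons = _merge_intervals(
            iv for exons in gm.transcripts.values() for iv in exons)
    write_genes_gff3(models.values(), path)


# ----------------------------------------------------------------------- PSL

_PSL_NCOLS = 21


def read_psl_alignments(path) -> list[SplicedAlignment]:
    """Read a 21-column PSL file; identity/coverage are recomputed from the
    match/mismatch/gap columns rather than trusted from any producer."""
    out: list[SplicedAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("psLayout", "match", "-", " ")):
                continue
            f = line.split("\t")
            if len(f) != _PSL_NCOLS:
                raise ParseError(f"{path}:{lineno}: expected {_PSL_NCOLS} "
                                 f"columns, got {len(f)}")
            matches, mismatches = int(f[0]), int(f[1])
            q_gap_bases, t_gap_bases = int(f[5]), int(f[7])
            strand, qname, qsize = f[8], f[9], int(f[10])
            tname = f[13]
            block_count = int(f[17])
            sizes = [int(x) for x in f[18].rstrip(",").split(",") if x]
            qstarts = [int(x) for x in f[19].rstrip(",").split(",") if x]
            tstarts = [int(x) for x in f[20].rstrip(",").split(",") if x]
            if not (len(sizes) == len(qstarts) == len(tstarts) == block_count):
                raise ParseError(
                    f"{path}:{lineno}: inconsistent block lists")
            blocks = [(qs, qs + sz, ts, ts + sz)
                      for sz, qs, ts in zip(sizes, qstarts, tstarts)]
            out.append(SplicedAlignment(
                read_id=qname, contig=tname, strand=strand, blocks=blocks,
                matches=matches, mismatches=mismatches,
                indels=q_gap_bases + t_gap_bases, read_length=qsize))
    return out


def write_psl(alignments: Iterable[SplicedAlignment],
              contig_lengths: dict[str, int], path) -> None:
    """Write alignments as PSL.  PSL blocks are ungapped, so each exon block
    is emitted with its read-span as the block size; within-exon indels are
    carried in the gap-count columns only."""
    with open(path, "w") as fh:
        for a in alignments:
            sizes = ",".join(str(re - rs) for rs, re, _, _ in a.blocks) + ","
            qstarts = ",".join(str(rs) for rs, _, _, _ in a.blocks) + ","
            tstarts = ",".join(str(gs) for _, _, gs, _ in a.blocks) + ","
            qgap = sum(max(0, b2[0] - b1[1])
                       for b1, b2 in zip(a.blocks, a.blocks[1:]))
            # genomic gaps of intron size are introns, not indels; only
            # sub-intron gaps land in the t-gap columns the reader counts
            tgaps = [b2[2] - b1[3] for b1, b2 in zip(a.blocks, a.blocks[1:])]
            tgap_small = sum(g for g in tgaps if 0 < g < 40)
            fields = [
                a.matches, a.mismatches, 0, 0,
                0, qgap, sum(1 for g in tgaps if 0 < g < 40),
                tgap_small,
                a.strand, a.read_id, a.read_length,
                a.blocks[0][0], a.blocks[-1][1],
                a.contig, contig_lengths.get(a.contig, 0),
                a.genome_start, a.genome_end,
                len(a.blocks), sizes, qstarts, tstarts,
            ]
            fh.write("\t".join(str(x) for x in fields) + "\n")


# ---------------------------------------------------------------- junctions

def read_junction_bed(path) -> list[JunctionRecord]:
    """BED6 junctions: chrom, donor, acceptor, name, support_count, strand."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED columns")
            out.append(JunctionRecord(
                contig=f[0], donor_pos=int(f[1]), acceptor_pos=int(f[2]),
                strand=f[5], support_count=int(f[4])))
    return out


def write_junction_bed(junctions: Iterable[JunctionRecord], path) -> None:
    with open(path, "w") as fh:
        for i, j in enumerate(junctions):
            fh.write(f"{j.contig}\t{j.donor_pos}\t{j.acceptor_pos}\t"
                     f"J{i:06d}\t{j.support_count}\t{j.strand}\n")
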