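"""Stage-wise expression calling and junction-based isoform presence.

Gene expression uses RPKM = exon reads / (mapped reads in millions x exon
length in kb) with the strict "expressed iff RPKM > 1" rule; short reads
count toward a gene only when their placement is unique and overlaps the
exons of exactly one gene.  Isoform presence per stage is judged from
short-read coverage of isoform-specific splice junctions (>= 1 read);
isoforms with no specific junction are UNRESOLVABLE and excluded from
differential calling.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .isoforms import TranscriptIsoform
from .shortread import StageAlignments


@dataclass
class ExpressionRecord:
    gene_id: str
    stage: str
    exon_reads: int
    mapped_reads_millions: float
    exon_length_kb: float
    rpkm: float = field(init=False)

    def __post_init__(self):
        if self.exon_length_kb <= 0:
            raise ValueError(f"gene {self.gene_id}: zero exon length")
        if self.mapped_reads_millions <= 0:
            raise ValueError("library has no mapped reads")
        self.rpkm = self.exon_reads / (self.mapped_reads_millions *
                                       self.exon_length_kb)

    @property
    def expressed(self) -> bool:
        return self.rpkm > 1.0


def compute_rpkm(gene_id: str, stage: str, exon_reads: int,
                 mapped_reads: int, exon_length_bp: int) -> ExpressionRecord:
    return ExpressionRecord(gene_id=gene_id, stage=stage,
                            exon_reads=exon_reads,
                            mapped_reads_millions=mapped_reads / 1e6,
                            exon_length_kb=exon_length_bp / 1000.0)


@dataclass
class GeneDef:
    gene_id: str
    contig: str
    exons: list[tuple[int, int]]

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)


def count_exon_reads(stage_aln: StageAlignments, genes: list[GeneDef]
                     ) -> tuple[dict[str, int], int, int]:
    """Unique-overlap read counting (strictest HTSeq-like mode).

    Returns (per-gene counts, n_assigned, n_unassigned); a read whose blocks
    overlap the exons of several genes is assigned to none.
    """
    by_contig: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
    for g in genes:
        for s, e in g.exons:
            by_contig[g.contig].append((s, e, g.gene_id))
    for ivs in by_contig.values():
        ivs.sort()
    counts: dict[str, int] = Counter()
    assigned = 0
    unassigned = 0
    for pl in stage_aln.unique_placements:
        ivs = by_contig.get(pl.contig, [])
        hit: set[str] = set()
        for s, e in pl.blocks:
            # linear scan is fine: contigs carry only a few genes
            for gs, ge, gid in ivs:
                if gs >= e:
                    break
                if ge > s:
                    hit.add(gid)
        if len(hit) == 1:
            counts[next(iter(hit))] += 1
            assigned += 1
        else:
            unassigned += 1
    return dict(counts), assigned, unassigned


def stage_expression(stage_aln: StageAlignments, genes: list[GeneDef]
                     ) -> list[ExpressionRecord]:
    counts, _, _ = count_exon_reads(stage_aln, genes)
    mapped = stage_aln.n_unique
    out = []
    for g in genes:
        if g.exon_length <= 0:
            continue
        out.append(ExpressionRecord(
            gene_id=g.gene_id, stage=stage_aln.stage,
            exon_reads=counts.get(g.gene_id, 0),
            mapped_reads_millions=max(mapped, 1) / 1e6,
            exon_length_kb=g.exon_length / 1000.0))
    return out


def call_expressed_genes(records: list[ExpressionRecord]
                         ) -> dict[str, set[str]]:
    """Per-stage sets of genes with RPKM strictly greater than 1."""
    out: dict[str, set[str]] = defaultdict(set)
    for r in records:
        if r.expressed:
            out[r.stage].add(r.gene_id)
    return dict(out)


@dataclass
class IsoformPresence:
    transcript_id: str
    stage: str
    specific_junctions: tuple
    supporting_reads: int
    present: bool
    resolvable: bool = True


def specific_junctions(isoforms: list[TranscriptIsoform]
                       ) -> dict[str, tuple]:
    """Junctions unique to each isoform among its locus siblings."""
    by_locus: dict[str, list[TranscriptIsoform]] = defaultdict(list)
    for iso in isoforms:
        by_locus[iso.locus_id].append(iso)
    out: dict[str, tuple] = {}
    for locus, isos in by_locus.items():
        for iso in isos:
            others = set()
            for sib in isos:
                if sib.transcript_id != iso.transcript_id:
                    others.update(sib.junction_chain)
            out[iso.transcript_id] = tuple(
                j for j in iso.junction_chain if j not in others)
    return out


def isoform_presence(isoforms: list[TranscriptIsoform],
                     stage_alignments: list[StageAlignments]
                     ) -> list[IsoformPresence]:
    spec = specific_junctions(isoforms)
    out: list[IsoformPresence] = []
    for iso in isoforms:
        sj = spec[iso.transcript_id]
        for st in stage_alignments:
            if not sj:
                out.append(IsoformPresence(
                    transcript_id=iso.transcript_id, stage=st.stage,
                    specific_junctions=(), supporting_reads=0,
                    present=False, resolvable=False))
                continue
            support = sum(
                st.junction_support.get(
                    (iso.contig, d, a, iso.strand), 0)
                for d, a in sj)
            out.append(IsoformPresence(
                transcript_id=iso.transcript_id, stage=st.stage,
                specific_junctions=sj, supporting_reads=support,
                present=support >= 1))
    return out


@dataclass
class DifferentialGene:
    locus_id: str
    n_isoforms: int
    isoform_labels: dict[str, str]            # transcript_id -> 'a', 'b', ...
    presence: dict[str, tuple[bool, ...]]     # transcript_id -> per-stage


def differential_isoform_table(presences: list[IsoformPresence],
                               isoforms: list[TranscriptIsoform],
                               stages: list[str]
                               ) -> list[DifferentialGene]:
    """Loci where some resolvable isoform's presence varies across stages.

    Isoforms are labelled alphabetically per locus by descending read
    support ('a' = most supported).
    """
    by_iso: dict[str, dict[str, bool]] = defaultdict(dict)
    resolvable: dict[str, bool] = {}
    for p in presences:
        by_iso[p.transcript_id][p.stage] = p.present
        resolvable[p.transcript_id] = p.resolvable
    by_locus: dict[str, list[TranscriptIsoform]] = defaultdict(list)
    for iso in isoforms:
        by_locus[iso.locus_id].append(iso)
    out: list[DifferentialGene] = []
    for locus in sorted(by_locus):
        isos = [i for i in by_locus[locus]
                if resolvable.get(i.transcript_id, False)]
        if not isos:
            continue
        isos.sort(key=lambda i: (-i.n_supporting_reads, i.transcript_id))
        labels = {iso.transcript_id: chr(ord("a") + n)
                  for n, iso in enumerate(isos)}
        pres = {iso.transcript_id:
                tuple(by_iso[iso.transcript_id].get(s, False)
                      for s in stages)
                for iso in isos}
        if any(len(set(v)) > 1 for v in pres.values()):
            out.append(DifferentialGene(
                locus_id=locus, n_isoforms=len(isos),
                isoform_labels=labels, presence=pres))
    return out
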