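"""Flatten pipeline results into the on-disk TSV/GFF3 tables."""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .io_formats import write_transcripts_gff3
from .pipeline import PipelineResult


def groups_table(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for a in result.assignments:
        best = a.evidence[0] if a.evidence else None
        rows.append(dict(
            read_id=a.read_id, group=a.group,
            contig=best.contig if best else None,
            coverage=round(best.coverage, 2) if best else None,
            identity=round(best.identity, 2) if best else None,
            strand=result.strands.get(a.read_id)))
    return pd.DataFrame(rows)


def loci_table(result: PipelineResult) -> pd.DataFrame:
    return pd.DataFrame([dict(
        locus_id=c.locus_id, contig=c.contig, strand=c.strand,
        start=c.span[0], end=c.span[1], status=c.status,
        gene_ids=",".join(c.gene_ids), n_reads=c.n_reads,
        contig_has_other_models=c.contig_has_other_models)
        for c in result.loci])


def isoform_table(result: PipelineResult) -> pd.DataFrame:
    return pd.DataFrame([dict(
        transcript_id=t.transcript_id, locus_id=t.locus_id,
        contig=t.contig, strand=t.strand, status=t.status,
        n_junctions=len(t.junction_chain), length_bp=t.length_bp,
        n_supporting_reads=t.n_supporting_reads,
        representative_read=t.representative_read)
        for t in result.isoforms])


def expression_table(result: PipelineResult) -> pd.DataFrame:
    return pd.DataFrame([dict(
        gene_id=r.gene_id, stage=r.stage, exon_reads=r.exon_reads,
        rpkm=round(r.rpkm, 3), expressed=r.expressed)
        for r in result.expression_records])


def write_result_tables(result: PipelineResult, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    groups_table(result).to_csv(outdir / "groups.tsv", sep="\t", index=False)
    loci_table(result).to_csv(outdir / "loci.tsv", sep="\t", index=False)
    isoform_table(result).to_csv(outdir / "transcripts.tsv", sep="\t",
                                 index=False)
    expression_table(result).to_csv(outdir / "expression.tsv", sep="\t",
                                    index=False)
    multi = [t for t in result.isoforms if t.exons]
    if multi:
        write_transcripts_gff3(multi, outdir / "transcripts.gff3")
    pd.DataFrame([dict(
        read_id=b.read_id, contig_a=b.contig_a, contig_b=b.contig_b,
        end_distance_a=b.end_distance_a, end_distance_b=b.end_distance_b,
        ortholog_contig=b.ortholog_contig,
        ortholog_contiguous=b.ortholog_contiguous)
        for b in result.bridges]).to_csv(outdir / "bridges.tsv", sep="\t",
                                         index=False)
    pd.DataFrame([dict(
        transcript_id=m.transcript_id,
        spanned_genes=",".join(m.spanned_gene_ids), contig=m.contig,
        orf_length_aa=m.orf_length_aa, validation=m.ortholog_validation,
        ortholog_identity=round(m.ortholog_identity, 2))
        for m in result.merges]).to_csv(outdir / "merges.tsv", sep="\t",
                                        index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump({"counts": result.counts, "derived": result.derived},
                  fh, indent=2, default=str)
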