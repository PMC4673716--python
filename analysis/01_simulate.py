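#!/usr/bin/env python
"""Generate the default synthetic wheat-like dataset and write it to disk.

Produces the fragmented draft genome with its (deliberately imperfect)
annotation, the contiguous relative-species genomes, multi-pass long reads,
four stage-specific short-read libraries, and the planted-truth tables,
under results/dataset/.
"""
from pathlib import Path

from isoscan.sim import SimConfig, simulate
from isoscan.io_formats import (SeqRecord, write_fasta, write_fastq,
                                write_genes_gff3)

OUT = Path(__file__).resolve().parent.parent / "results" / "dataset"


def main() -> None:
    cfg = SimConfig(seed=1)
    sim = simulate(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    write_fasta([SeqRecord(n, s) for n, s in sim.draft_contigs.items()],
                OUT / "draft_genome.fasta")
    write_genes_gff3(sim.gene_models, OUT / "draft_genes.gff3")
    write_fasta([SeqRecord(n, s) for n, s in sim.ortholog_genome.items()],
                OUT / "ortholog_genome.fasta")
    write_genes_gff3(sim.ortholog_models, OUT / "ortholog_genes.gff3")
    write_fasta(sim.cdna_refs, OUT / "reference_cdnas.fasta")
    write_fastq(sim.clr_reads, OUT / "clr_reads.fastq")
    for stage, lib in sim.short_reads.items():
        write_fastq(lib, OUT / f"short_{stage}.fastq")
    sim.truth.read_table.drop(columns=["insert", "template"]).to_csv(
        OUT / "truth_reads.tsv", sep="\t", index=False)
    sim.truth.stage_presence.to_csv(OUT / "truth_stage_presence.tsv",
                                    sep="\t")
    genome_mb = sum(len(s) for s in sim.draft_contigs.values()) / 1e6
    print(f"dataset written to {OUT}")
    print(f"  draft contigs: {len(sim.draft_contigs)} ({genome_mb:.1f} Mb)")
    print(f"  gene models:   {len(sim.gene_models)}")
    print(f"  long reads:    {len(sim.clr_reads)}")
    print(f"  short reads:   "
          f"{sum(len(v) for v in sim.short_reads.values())} over "
          f"{len(sim.short_reads)} stages")


if __name__ == "__main__":
    main()
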