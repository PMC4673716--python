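"""Collapse high-quality reads into unique transcript isoforms per locus.

Two multi-exon reads represent the same isoform iff their splice-junction
chains are identical (exact coordinates; residual-error wobble is handled
upstream by canonical-motif boundary shifting).  Single-exon reads collapse
to one isoform per locus and strand.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .annotation import LocusCluster
from .io_formats import GeneModel
from .mapping import SplicedAlignment


@dataclass
class TranscriptIsoform:
    transcript_id: str
    locus_id: str
    contig: str
    strand: str
    junction_chain: tuple[tuple[int, int], ...]
    exons: list[tuple[int, int]]       # representative read's exon intervals
    span: tuple[int, int]
    length_bp: int
    status: str    # KNOWN / NOVEL_AT_KNOWN_LOCUS / NOVEL_LOCUS
    representative_read: str
    n_supporting_reads: int


def _model_chains(gm: GeneModel) -> set[tuple[tuple[int, int], ...]]:
    chains = set()
    for exons in gm.transcripts.values():
        exons = sorted(exons)
        chains.add(tuple((e1, s2) for (_, e1), (s2, _)
                         in zip(exons, exons[1:])))
    return chains


def collapse_isoforms(clusters: list[LocusCluster],
                      read_alignments: dict[str, SplicedAlignment],
                      junction_chains: dict[str, tuple],
                      gene_models: list[GeneModel]
                      ) -> list[TranscriptIsoform]:
    """Group each locus's reads by identical junction chain.

    The representative read is the longest (by aligned bases); an isoform is
    KNOWN only when its chain equals an annotated transcript's chain at an
    overlapping model (single-exon: when an overlapping annotated transcript
    is also single-exon).
    """
    models_by_id = {gm.gene_id: gm for gm in gene_models}
    out: list[TranscriptIsoform] = []
    for cluster in clusters:
        ann_chains: set = set()
        ann_single = False
        for gid in cluster.gene_ids:
            gm = models_by_id.get(gid)
            if gm is None:
                continue
            for ch in _model_chains(gm):
                if ch:
                    ann_chains.add(ch)
                else:
                    ann_single = True
        groups: dict[tuple, list[str]] = defaultdict(list)
        for rid in cluster.supporting_reads:
            groups[tuple(junction_chains.get(rid, ()))].append(rid)
        ordered = sorted(groups.items(),
                         key=lambda kv: (-len(kv[1]), kv[0]))
        for i, (chain, rids) in enumerate(ordered):
            rep = max(rids,
                      key=lambda r: (read_alignments[r].aligned_read_length,
                                     r))
            aln = read_alignments[rep]
            exons = aln.exon_intervals()
            if cluster.status == "NOVEL":
                status = "NOVEL_LOCUS"
            elif (chain and chain in ann_chains) or \
                    (not chain and ann_single):
                status = "KNOWN"
            else:
                status = "NOVEL_AT_KNOWN_LOCUS"
            out.append(TranscriptIsoform(
                transcript_id=f"{cluster.locus_id}.i{i + 1}",
                locus_id=cluster.locus_id, contig=cluster.contig,
                strand=cluster.strand, junction_chain=chain, exons=exons,
                span=(exons[0][0], exons[-1][1]),
                length_bp=sum(e - s for s, e in exons),
                status=status, representative_read=rep,
                n_supporting_reads=len(rids)))
    return out


def transcript_length_stats(novel_lengths: list[int],
                            known_lengths: list[int]) -> dict:
    """Min/max/mean (nearest bp) per set plus the difference of means."""
    def stats(v: list[int]) -> dict:
        if not v:
            raise ValueError("empty length set")
        return {"min": min(v), "max": max(v),
                "mean": int(round(sum(v) / len(v)))}

    novel = stats(novel_lengths)
    known = stats(known_lengths)
    return {"novel": novel, "known": known,
            "mean_difference": novel["mean"] - known["mean"]}


def locus_support_histogram(read_counts: list[int]) -> dict:
    """Reporting bins 2-10 / 11-100 / >100 (inclusive edges as printed),
    with percentages over all loci."""
    bins = {"2-10": 0, "11-100": 0, ">100": 0}
    for n in read_counts:
        if 2 <= n <= 10:
            bins["2-10"] += 1
        elif 11 <= n <= 100:
            bins["11-100"] += 1
        elif n > 100:
            bins[">100"] += 1
    total = len(read_counts)
    pct = {k: (100.0 * v / total if total else 0.0) for k, v in bins.items()}
    return {"bins": bins, "percent": pct, "n_loci": total}
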