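"""Annotation-improvement analyses over classified reads.

Covers the steps that turn well-mapped reads into annotation evidence:
high-quality filtering (drop 5'-truncated reads and unsupported
singletons), locus clustering (extant vs novel), cross-contig bridge
detection for partially mapped reads, spanning-transcript (gene-merge)
detection, ortholog-based rescue of poorly mapped reads, and estimation of
the fraction of reads carrying a complete ORF.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GeneModel
from .mapping import (AlignmentSet, GenomeIndex, SplicedAlignment,
                      toy_spliced_align)
from .seq import find_longest_orf


# ------------------------------------------------------------ read clustering

class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        p = self.parent.setdefault(x, x)
        if p != x:
            self.parent[x] = p = self.find(p)
        return p

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _cluster_reads(read_alignments: dict[str, SplicedAlignment]
                   ) -> list[list[str]]:
    """Single-linkage clusters of reads with >=1 bp exonic overlap on the
    same contig and strand.  Order-independent (sorted sweep)."""
    uf = _UnionFind()
    by_key: dict[tuple, list[tuple[int, int, str]]] = defaultdict(list)
    for rid, aln in read_alignments.items():
        uf.find(rid)
        for s, e in aln.exon_intervals():
            by_key[(aln.contig, aln.strand)].append((s, e, rid))
    for key, ivs in by_key.items():
        ivs.sort()
        cur_end = -1
        anchor: str | None = None
        for s, e, rid in ivs:
            if anchor is not None and s < cur_end:
                # interval overlaps the running envelope: same cluster
                uf.union(anchor, rid)
                cur_end = max(cur_end, e)
            else:
                anchor = rid
                cur_end = e
    groups: dict[str, list[str]] = defaultdict(list)
    for rid in read_alignments:
        groups[uf.find(rid)].append(rid)
    return [sorted(g) for g in sorted(groups.values())]


# ------------------------------------------------------- high-quality filter

@dataclass
class HighQualityFilterResult:
    kept: list[str]
    removed_5prime_truncated: list[str]
    removed_unsupported_singletons: list[str]


def _transcription_chain(chain, strand):
    """Junction chain in transcription order (5'->3')."""
    return tuple(chain) if strand == "+" else tuple(reversed(chain))


def filter_high_quality(read_alignments: dict[str, SplicedAlignment],
                        junction_chains: dict[str, tuple],
                        junction_support: dict | Counter,
                        coverage_masks: dict[str, np.ndarray] | None = None
                        ) -> HighQualityFilterResult:
    """Drop 5'-truncated reads and singletons without short-read support.

    A read is 5'-truncated iff its junction chain is a strict suffix (in
    transcription order) of another same-locus read's chain and its 5' end
    lies downstream of that read's 5' end.  A read is an unsupported
    singleton iff it is the only read with its junction chain at its locus
    and none of its junctions has short-read support (single-exon
    singletons: no overlapping short-read coverage at all).
    """
    truncated: set[str] = set()
    singleton: set[str] = set()
    clusters = _cluster_reads(read_alignments)
    for cluster in clusters:
        chains = {rid: _transcription_chain(junction_chains.get(rid, ()),
                                            read_alignments[rid].strand)
                  for rid in cluster}
        chain_counts = Counter(chains.values())
        for rid in cluster:
            ch = chains[rid]
            aln = read_alignments[rid]
            if ch:
                for other in cluster:
                    if other == rid:
                        continue
                    och = chains[other]
                    if len(och) <= len(ch):
                        continue
                    if och[-len(ch):] != ch:
                        continue
                    oaln = read_alignments[other]
                    if aln.strand == "+":
                        downstream = aln.genome_start > oaln.genome_start
                    else:
                        downstream = aln.genome_end < oaln.genome_end
                    if downstream:
                        truncated.add(rid)
                        break
            if rid in truncated:
                continue
            if chain_counts[ch] == 1:
                if ch:
                    if all(junction_support.get(
                            (aln.contig, d, a, aln.strand), 0) < 1
                            for d, a in junction_chains.get(rid, ())):
                        singleton.add(rid)
                else:
                    cov = None if coverage_masks is None else \
                        coverage_masks.get(aln.contig)
                    covered = False
                    if cov is not None:
                        for s, e in aln.exon_intervals():
                            if cov[s:e].any():
                                covered = True
                                break
                    if not covered:
                        singleton.add(rid)
    kept = [rid for rid in sorted(read_alignments)
            if rid not in truncated and rid not in singleton]
    return HighQualityFilterResult(
        kept=kept,
        removed_5prime_truncated=sorted(truncated),
        removed_unsupported_singletons=sorted(singleton))


# ------------------------------------------------------------ locus clusters

@dataclass
class LocusCluster:
    locus_id: str
    contig: str
    strand: str
    span: tuple[int, int]
    status: str                       # EXTANT / NOVEL
    gene_ids: list[str] = field(default_factory=list)
    supporting_reads: list[str] = field(default_factory=list)
    contig_has_other_models: bool = False

    @property
    def gene_id(self) -> str | None:
        return self.gene_ids[0] if self.gene_ids else None

    @property
    def n_reads(self) -> int:
        return len(self.supporting_reads)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def assign_loci(read_alignments: dict[str, SplicedAlignment],
                gene_models: list[GeneModel]) -> list[LocusCluster]:
    """Cluster high-quality reads into loci and mark them extant or novel.

    A cluster is EXTANT when any member read shares >=1 bp exonic overlap
    with an annotated gene model on the same contig and strand; novel
    clusters are additionally flagged by whether their contig carries any
    other annotated model.
    """
    models_by_key: dict[tuple, list[GeneModel]] = defaultdict(list)
    models_by_contig: dict[str, int] = Counter()
    for gm in gene_models:
        models_by_key[(gm.contig, gm.strand)].append(gm)
        models_by_contig[gm.contig] += 1
    clusters = _cluster_reads(read_alignments)
    out: list[LocusCluster] = []
    for cluster in clusters:
        a0 = read_alignments[cluster[0]]
        contig, strand = a0.contig, a0.strand
        exons = [iv for rid in cluster
                 for iv in read_alignments[rid].exon_intervals()]
        span = (min(s for s, _ in exons), max(e for _, e in exons))
        hit_models: list[str] = []
        for gm in models_by_key.get((contig, strand), []):
            if gm.end <= span[0] or gm.start >= span[1]:
                continue
            if any(_overlap(iv, ge) > 0 for iv in exons for ge in gm.exons):
                hit_models.append(gm.gene_id)
        status = "EXTANT" if hit_models else "NOVEL"
        other = models_by_contig.get(contig, 0) - len(hit_models) > 0
        out.append(LocusCluster(
            locus_id=f"loc_{contig}_{span[0]}_{strand}",
            contig=contig, strand=strand, span=span, status=status,
            gene_ids=sorted(hit_models), supporting_reads=list(cluster),
            contig_has_other_models=other))
    out.sort(key=lambda c: (c.contig, c.span, c.strand))
    return out


def locus_read_support_histogram(clusters: list[LocusCluster]) -> dict:
    """Read-support histogram with the reporting bins 1 / 2-10 / 11-100 / >100."""
    bins = {"1": 0, "2-10": 0, "11-100": 0, ">100": 0}
    for c in clusters:
        n = c.n_reads
        if n <= 1:
            bins["1"] += 1
        elif n <= 10:
            bins["2-10"] += 1
        elif n <= 100:
            bins["11-100"] += 1
        else:
            bins[">100"] += 1
    return bins


# ------------------------------------------------------------------- bridges

@dataclass
class BridgeRecord:
    read_id: str
    contig_a: str
    contig_b: str
    end_distance_a: int
    end_distance_b: int
    ortholog_contig: str | None
    ortholog_contiguous: bool


def _read_interval_forward(aln: SplicedAlignment) -> tuple[int, int]:
    """Aligned read interval in original (pre-orientation) read coordinates."""
    rs, re = aln.blocks[0][0], aln.blocks[-1][1]
    if aln.strand == "-":
        return (aln.read_length - re, aln.read_length - rs)
    return (rs, re)


def detect_contig_bridges(g3_evidence: dict[str, list[SplicedAlignment]],
                          read_seqs: dict[str, str],
                          contig_lengths: dict[str, int],
                          ortholog_index: GenomeIndex | None = None,
                          min_identity: float = 90.0,
                          min_total_coverage: float = 80.0,
                          max_end_distance: int = 600
                          ) -> list[BridgeRecord]:
    """Reads whose two partial alignments abut contig ends (the 600-bp rule)
    and whose orthologous region is contiguous in a relative genome."""
    out: list[BridgeRecord] = []
    for rid in sorted(g3_evidence):
        alns = [a for a in g3_evidence[rid] if a.identity > min_identity]
        contigs = {a.contig for a in alns}
        if len(contigs) != 2 or len(alns) != 2:
            continue
        if alns[0].strand != alns[1].strand:
            continue
        if sum(a.coverage for a in alns) < min_total_coverage:
            continue
        a1, a2 = sorted(alns, key=lambda a: _read_interval_forward(a)[0])
        if contig_lengths.get(a1.contig) is None or \
                contig_lengths.get(a2.contig) is None:
            raise ValueError(f"unknown contig length for bridge read {rid}")
        # upstream segment extends past its inner (3'-ward) genomic end,
        # downstream segment past its inner (5'-ward) genomic start
        if a1.strand == "+":
            d1 = contig_lengths[a1.contig] - a1.genome_end
            d2 = a2.genome_start
        else:
            d1 = a1.genome_start
            d2 = contig_lengths[a2.contig] - a2.genome_end
        if d1 > max_end_distance or d2 > max_end_distance:
            continue
        ortholog_contig = None
        contiguous = False
        if ortholog_index is not None and rid in read_seqs:
            oset = toy_spliced_align(rid, read_seqs[rid], ortholog_index)
            if oset.alignments:
                best = oset.alignments[0]
                if best.coverage >= 80.0 and best.identity >= 80.0:
                    ortholog_contig = best.contig
                    contiguous = True
        out.append(BridgeRecord(read_id=rid, contig_a=a1.contig,
                                contig_b=a2.contig, end_distance_a=int(d1),
                                end_distance_b=int(d2),
                                ortholog_contig=ortholog_contig,
                                ortholog_contiguous=contiguous))
    return out


# --------------------------------------------------------- gene-model merges

@dataclass
class MergeCandidate:
    transcript_id: str
    spanned_gene_ids: list[str]
    contig: str
    orf_length_aa: int
    ortholog_validation: str        # VALIDATED / UNVALIDATED
    ortholog_identity: float = 0.0


def detect_spanning_transcripts(transcripts: list[tuple[str, SplicedAlignment, str]],
                                gene_models: list[GeneModel],
                                ortholog_index: GenomeIndex | None = None,
                                ortholog_models: list[GeneModel] | None = None,
                                min_cov_id: float = 90.0,
                                ortho_min_cov_id: float = 80.0
                                ) -> list[MergeCandidate]:
    """Transcripts whose exons cover 2-3 annotated models on one contig.

    Candidates need unique positive mapping (> ``min_cov_id`` coverage and
    identity) overlapping the exons of >= 2 models; VALIDATED requires a
    reliable (>= ``ortho_min_cov_id``) ortholog alignment to a region with
    exactly one annotated gene.
    """
    models_by_key: dict[tuple, list[GeneModel]] = defaultdict(list)
    for gm in gene_models:
        models_by_key[(gm.contig, gm.strand)].append(gm)
    out: list[MergeCandidate] = []
    for tid, aln, seq in transcripts:
        if aln is None or aln.coverage <= min_cov_id or \
                aln.identity <= min_cov_id:
            continue
        exons = aln.exon_intervals()
        hit = []
        for gm in models_by_key.get((aln.contig, aln.strand), []):
            if any(_overlap(iv, ge) > 0 for iv in exons for ge in gm.exons):
                hit.append(gm.gene_id)
        if not 2 <= len(hit) <= 3:
            continue
        orf = find_longest_orf(seq)
        orf_aa = (orf[1] - orf[0]) // 3 - 1 if orf else 0
        validation = "UNVALIDATED"
        ortho_ident = 0.0
        if ortholog_index is not None and ortholog_models is not None:
            oset = toy_spliced_align(tid, seq, ortholog_index)
            if oset.alignments:
                best = oset.alignments[0]
                if best.coverage >= ortho_min_cov_id and \
                        best.identity >= ortho_min_cov_id:
                    ortho_ident = best.identity
                    span = (best.genome_start, best.genome_end)
                    n_genes = sum(
                        1 for gm in ortholog_models
                        if gm.contig == best.contig and
                        _overlap((gm.start, gm.end), span) > 0)
                    if n_genes == 1:
                        validation = "VALIDATED"
        out.append(MergeCandidate(transcript_id=tid, spanned_gene_ids=hit,
                                  contig=aln.contig, orf_length_aa=orf_aa,
                                  ortholog_validation=validation,
                                  ortholog_identity=ortho_ident))
    return out


# ------------------------------------------------------------------- rescue

@dataclass
class RescueMatch:
    read_id: str
    species: str
    gene_id: str
    coverage: float
    identity: float

    @property
    def rescued(self) -> bool:
        return self.coverage > 90.0 and self.identity > 90.0


def rescue_unmapped(read_seqs: dict[str, str],
                    gene_sets: dict[str, list],
                    min_cov_id: float = 90.0) -> tuple[list[RescueMatch], dict]:
    """Best gapped alignment of each poorly-mapped read against the
    protein-coding gene sets of relative species; a read is rescued when
    both coverage and identity exceed 90%."""
    import edlib

    from .seq import cigar_counts, revcomp

    matches: list[RescueMatch] = []
    indexes = {}
    for sp, genes in gene_sets.items():
        if not genes:
            raise ValueError(f"empty gene set for species {sp}")
        indexes[sp] = GenomeIndex({g.id: g.sequence for g in genes}, k=15)
    for rid in sorted(read_seqs):
        seq = read_seqs[rid]
        best: RescueMatch | None = None
        for sp, idx in sorted(indexes.items()):
            for query in (seq, revcomp(seq)):
                aset = toy_spliced_align(rid, query, idx)
                if not aset.alignments:
                    continue
                # re-score against the full gene with a global alignment
                top = aset.alignments[0]
                gene_seq = idx.contig_seq(top.contig)
                res = edlib.align(query, gene_seq, mode="NW", task="path")
                if res["editDistance"] < 0:
                    continue
                m, x, i, d = cigar_counts(res["cigar"])
                cov = 100.0 * (m + x) / len(query)
                ident = 100.0 * m / max(1, m + x + i + d)
                cand = RescueMatch(read_id=rid, species=sp,
                                   gene_id=top.contig, coverage=cov,
                                   identity=ident)
                if best is None or (cand.coverage * cand.identity >
                                    best.coverage * best.identity):
                    best = cand
        if best is not None:
            matches.append(best)
    per_species = Counter(m.species for m in matches if m.rescued)
    summary = {"n_reads": len(read_seqs),
               "n_rescued": sum(1 for m in matches if m.rescued),
               "per_species": dict(per_species)}
    return matches, summary


# --------------------------------------------------------- ORF completeness

@dataclass
class OrfCompletenessReport:
    n_loci_shared: int
    n_reads: int
    n_complete: int
    excluded_cdnas: list[str] = field(default_factory=list)

    @property
    def percent_complete(self) -> float:
        return round(100.0 * self.n_complete / self.n_reads, 1) \
            if self.n_reads else 0.0


def _read_pos_to_genome(aln: SplicedAlignment, pos: int) -> int | None:
    if aln.strand == "-":
        pos = aln.read_length - 1 - pos
    for rs, re, gs, ge in aln.blocks:
        if rs <= pos < re:
            off = pos - rs
            return gs + min(off, ge - gs - 1)
    return None


def estimate_orf_completeness(flnc_alignments: dict[str, SplicedAlignment],
                              cdna_alignments: dict[str, SplicedAlignment],
                              cdna_seqs: dict[str, str]
                              ) -> OrfCompletenessReport:
    """Fraction of reads spanning the full ORF of a co-located reference cDNA.

    A read at a locus covered by both data sources is complete iff its
    genomic span contains both the start-codon and stop-codon genomic
    positions derived from the co-located cDNA's longest ORF.
    """
    excluded: list[str] = []
    cdna_points: dict[str, tuple[str, str, int, int]] = {}
    for cid, caln in sorted(cdna_alignments.items()):
        seq = cdna_seqs[cid]
        orf = find_longest_orf(seq)
        if orf is None:
            excluded.append(cid)
            continue
        pts = [_read_pos_to_genome(caln, p)
               for p in (orf[0], orf[0] + 2, orf[1] - 3, orf[1] - 1)]
        pts = [p for p in pts if p is not None]
        if len(pts) < 4:
            excluded.append(cid)
            continue
        cdna_points[cid] = (caln.contig, caln.strand, min(pts), max(pts))
    by_key: dict[tuple, list[tuple[str, SplicedAlignment]]] = defaultdict(list)
    for cid, caln in cdna_alignments.items():
        if cid in cdna_points:
            by_key[(caln.contig, caln.strand)].append((cid, caln))
    n_reads = 0
    n_complete = 0
    shared: set[str] = set()
    for rid in sorted(flnc_alignments):
        aln = flnc_alignments[rid]
        cands = []
        for cid, caln in by_key.get((aln.contig, aln.strand), []):
            ov = sum(_overlap(iv, civ) for iv in aln.exon_intervals()
                     for civ in caln.exon_intervals())
            if ov > 0:
                cands.append((ov, cid))
        if not cands:
            continue
        cands.sort(reverse=True)
        cid = cands[0][1]
        shared.add(cid)
        n_reads += 1
        _, _, lo, hi = cdna_points[cid]
        if aln.genome_start <= lo and aln.genome_end >= hi + 1:
            n_complete += 1
    return OrfCompletenessReport(n_loci_shared=len(shared), n_reads=n_reads,
                                 n_complete=n_complete,
                                 excluded_cdnas=excluded)
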