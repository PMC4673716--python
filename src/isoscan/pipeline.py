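"""End-to-end orchestration: CLRs -> FLNC -> mapping -> classification ->
annotation -> isoforms -> expression (-> family search), with a summary
report whose additive identities are enforced.

``run_synthetic`` drives the whole analysis over an in-memory simulated
dataset and returns every intermediate, so tests and the acceptance script
can score each stage against the planted truth.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace

import edlib
import numpy as np

from . import annotation as ann
from . import classify as cls
from . import expression as expr
from . import isoforms as iso
from .flnc import (FlncConfig, FlncRead, Rejection, build_ccs, classify_flnc,
                   correct_with_short_reads, split_subreads)
from .mapping import (AlignmentSet, AlignParams, GenomeIndex,
                      determine_strand, toy_spliced_align)
from .report import check_additive_identities, derive_report
from .shortread import (StageAlignments, map_short_reads,
                        pooled_junction_support)
from .sim import FamilySim, SimConfig, SimData, contig_to_subgenome, simulate
from . import targeted

logger = logging.getLogger("isoscan")

# consensus error shrink factor by pass count (majority-vote heuristic)
_PASS_ERROR_FACTOR = {1: 1.0, 2: 0.9, 3: 0.35, 4: 0.25, 5: 0.15, 6: 0.10}


@dataclass
class PipelineResult:
    sim: SimData
    flnc_config: FlncConfig
    n_subreads: int = 0
    n_ccs_type1: int = 0
    n_type2: int = 0
    flnc_reads: list[FlncRead] = field(default_factory=list)
    rejections: list[Rejection] = field(default_factory=list)
    correction_report: dict = field(default_factory=dict)
    identity_raw_subread: float | None = None
    identity_ccs: float | None = None
    alignment_sets: dict[str, AlignmentSet] = field(default_factory=dict)
    strands: dict[str, str] = field(default_factory=dict)
    assignments: list = field(default_factory=list)
    group_counts: Counter = field(default_factory=Counter)
    g2_patterns: list = field(default_factory=list)
    junction_chains: dict = field(default_factory=dict)
    g1_junctions: list = field(default_factory=list)
    junction_validation: object = None
    stage_alignments: list[StageAlignments] = field(default_factory=list)
    coverage_masks: dict = field(default_factory=dict)
    hq: object = None
    loci: list = field(default_factory=list)
    isoforms: list = field(default_factory=list)
    bridges: list = field(default_factory=list)
    merges: list = field(default_factory=list)
    rescue_matches: list = field(default_factory=list)
    rescue_summary: dict = field(default_factory=dict)
    orf_report: object = None
    expression_records: list = field(default_factory=list)
    expressed_genes: dict = field(default_factory=dict)
    presences: list = field(default_factory=list)
    differential: list = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    derived: dict = field(default_factory=dict)

    @property
    def read_seqs(self) -> dict[str, str]:
        return {r.id: r.sequence for r in self.flnc_reads}


def _identity(a: str, b: str) -> float:
    """Orientation-agnostic global identity (%); subreads keep whatever
    common orientation the CLR splitter chose."""
    from .seq import revcomp

    d = min(edlib.align(a, b, mode="NW")["editDistance"],
            edlib.align(revcomp(a), b, mode="NW")["editDistance"])
    return 100.0 * (1.0 - d / max(len(a), len(b), 1))


def run_flnc_stage(sim: SimData, cfg: FlncConfig,
                   result: PipelineResult,
                   evaluate_sample: int = 400) -> list[FlncRead]:
    """Subread splitting, consensus, FLNC classification, identity tracking."""
    inserts = {}
    templates = {}
    for row in sim.truth.read_rows:
        if row.get("insert"):
            inserts[row["read_id"]] = row["insert"]
        if row.get("template"):
            templates[row["read_id"]] = row["template"]
    raw_idents: list[float] = []
    ccs_idents: list[float] = []
    flnc: list[FlncRead] = []
    error_estimates: dict[str, float] = {}
    n_eval = 0
    for clr in sim.clr_reads:
        subs = split_subreads(clr, sim.adapter, cfg)
        result.n_subreads += len(subs)
        cons = build_ccs(subs, cfg)
        if cons is None:
            continue
        if cons.type == "I":
            result.n_ccs_type1 += 1
        else:
            result.n_type2 += 1
        ins = inserts.get(clr.id)
        if ins and n_eval < evaluate_sample and subs:
            raw_idents.append(_identity(subs[0].sequence, ins))
            ccs_idents.append(_identity(cons.sequence, ins))
            n_eval += 1
        res = classify_flnc(cons, sim.primer5, sim.primer3, cfg)
        if isinstance(res, Rejection):
            result.rejections.append(res)
        else:
            flnc.append(res)
            # rough consensus-error estimate: subread divergence shrunk by
            # the majority vote, more passes -> cleaner consensus
            e_sub = max(0.0, 1.0 - cons.predicted_accuracy)
            factor = _PASS_ERROR_FACTOR.get(cons.n_passes, 0.08)
            error_estimates[res.id] = min(0.16, e_sub * factor + 0.005)
    if raw_idents:
        result.identity_raw_subread = float(np.mean(raw_idents))
        result.identity_ccs = float(np.mean(ccs_idents))
    pooled_short = [r for lib in sim.short_reads.values() for r in lib]
    corrected, report = correct_with_short_reads(
        flnc, pooled_short, cfg, templates=templates,
        error_estimates=error_estimates)
    for _ in range(max(0, cfg.correction_rounds - 1)):
        # strict polish: the edit budget shrinks to just above each read's
        # observed residual divergence, so only same-locus placements vote;
        # this also reverts any cross-votes homoeologous reads cast earlier
        obs = report.get("per_read_divergence", {})
        strict_cfg = replace(cfg, correction_budget_slack=0.01)
        strict_est = {rid: 0.3 * v for rid, v in obs.items()}
        corrected, report2 = correct_with_short_reads(
            corrected, pooled_short, strict_cfg, templates=templates,
            error_estimates=strict_est)
        report["identity_after"] = report2.get("identity_after",
                                               report.get("identity_after"))
        report["n_corrected"] = report2.get("n_corrected")
        report["per_read_divergence"] = report2.get("per_read_divergence",
                                                    {})
    result.correction_report = report
    result.flnc_reads = corrected
    logger.info("flnc: %d subreads -> %d CCS + %d type II -> %d FLNC",
                result.n_subreads, result.n_ccs_type1, result.n_type2,
                len(corrected))
    return corrected


def run_synthetic(config_or_sim: SimConfig | SimData,
                  flnc_config: FlncConfig | None = None,
                  align_params: AlignParams | None = None,
                  thresholds: cls.ClassifyThresholds | None = None
                  ) -> PipelineResult:
    """Run the full analysis over a synthetic dataset."""
    sim = (config_or_sim if isinstance(config_or_sim, SimData)
           else simulate(config_or_sim))
    cfg = flnc_config or FlncConfig()
    params = align_params or AlignParams()
    th = thresholds or cls.ClassifyThresholds()
    result = PipelineResult(sim=sim, flnc_config=cfg)

    # 1) FLNC derivation + short-read polishing
    reads = run_flnc_stage(sim, cfg, result)

    # 2) spliced mapping to the draft genome
    index = GenomeIndex(sim.draft_contigs, k=params.k)
    dense = replace(params, seed_stride=1, max_kmer_hits=100)
    for r in reads:
        aset = toy_spliced_align(r.id, r.sequence, index, params)
        if not aset.alignments:
            # highly diverged targets leave sparse exact seeds; retry the
            # few seedless reads with every k-mer as a seed
            aset = toy_spliced_align(r.id, r.sequence, index, dense)
        result.alignment_sets[r.id] = aset
        if aset.alignments:
            best = aset.alignments[0]
            competing = next((a for a in aset.alignments
                              if a.strand != best.strand), None)
            result.strands[r.id] = determine_strand(
                best, sim.draft_contigs, params.min_intron, competing,
                params.tie_delta)
        else:
            result.strands[r.id] = "+"

    # 3) G1-G5 classification and G2 patterns
    result.assignments = cls.classify_read_groups(result.alignment_sets,
                                                  result.strands, th)
    result.group_counts = Counter(a.group for a in result.assignments)
    result.g2_patterns = cls.g2_pattern_analysis(result.assignments,
                                                 contig_to_subgenome)
    g1_alignments = {a.read_id: a.evidence[0]
                     for a in result.assignments if a.group == "G1"}
    for rid, aln in g1_alignments.items():
        recs = cls.extract_junctions(aln, sim.draft_contigs,
                                     params.min_intron)
        result.junction_chains[rid] = tuple(
            (j.donor_pos, j.acceptor_pos) for j in recs)
        result.g1_junctions.extend(recs)
    logger.info("groups: %s", dict(result.group_counts))

    # 4) short-read placement per stage (junctions, coverage, counting)
    for stage in sim.config.stages:
        sa = map_short_reads(sim.short_reads.get(stage, []), index,
                             stage=stage, min_intron=params.min_intron,
                             coverage=result.coverage_masks)
        result.stage_alignments.append(sa)
    pooled = pooled_junction_support(result.stage_alignments)
    result.junction_validation = cls.validate_junctions(result.g1_junctions,
                                                        pooled)

    # 5) high-quality filter and locus assignment
    result.hq = ann.filter_high_quality(g1_alignments,
                                        result.junction_chains, pooled,
                                        result.coverage_masks)
    hq_alignments = {rid: g1_alignments[rid] for rid in result.hq.kept}
    result.loci = ann.assign_loci(hq_alignments, sim.gene_models)

    # 6) isoform collapsing
    result.isoforms = iso.collapse_isoforms(result.loci, hq_alignments,
                                            result.junction_chains,
                                            sim.gene_models)

    # 7) annotation improvement: bridges, merges, rescue, ORF completeness
    ortho_index = GenomeIndex(sim.ortholog_genome, k=params.k) \
        if sim.ortholog_genome else None
    read_seqs = result.read_seqs
    g3_evidence = {a.read_id: a.evidence for a in result.assignments
                   if a.group == "G3"}
    result.bridges = ann.detect_contig_bridges(
        g3_evidence, read_seqs, sim.contig_lengths, ortho_index)
    transcripts = [(t.transcript_id,
                    hq_alignments.get(t.representative_read),
                    read_seqs.get(t.representative_read, ""))
                   for t in result.isoforms]
    result.merges = ann.detect_spanning_transcripts(
        transcripts, sim.gene_models, ortho_index, sim.ortholog_models)
    g45 = {a.read_id: read_seqs[a.read_id] for a in result.assignments
           if a.group in ("G4", "G5") and a.read_id in read_seqs}
    if g45 and sim.ortholog_gene_sets:
        result.rescue_matches, result.rescue_summary = ann.rescue_unmapped(
            g45, sim.ortholog_gene_sets)
    cdna_alignments = {}
    cdna_seqs = {}
    for rec in sim.cdna_refs:
        aset = toy_spliced_align(rec.id, rec.sequence, index, params)
        if aset.alignments and aset.alignments[0].coverage > 90 and \
                aset.alignments[0].identity > 90:
            cdna_alignments[rec.id] = aset.alignments[0]
            cdna_seqs[rec.id] = rec.sequence
    result.orf_report = ann.estimate_orf_completeness(
        hq_alignments, cdna_alignments, cdna_seqs)

    # 8) expression: RPKM per gene per stage, isoform presence, differential
    genes = [expr.GeneDef(gene_id=gm.gene_id, contig=gm.contig,
                          exons=gm.exons) for gm in sim.gene_models]
    genes += [expr.GeneDef(gene_id=c.locus_id, contig=c.contig,
                           exons=[c.span]) for c in result.loci
              if c.status == "NOVEL"]
    for sa in result.stage_alignments:
        result.expression_records.extend(expr.stage_expression(sa, genes))
    result.expressed_genes = expr.call_expressed_genes(
        result.expression_records)
    result.presences = expr.isoform_presence(result.isoforms,
                                             result.stage_alignments)
    result.differential = expr.differential_isoform_table(
        result.presences, result.isoforms, sim.config.stages)

    # 9) summary counts + derived figures, with additive identities enforced
    gc = result.group_counts
    n_flnc = len(result.flnc_reads)
    flnc_type2 = sum(1 for r in result.flnc_reads if r.source_type == "II")
    extant_read_ids = {rid for c in result.loci if c.status == "EXTANT"
                       for rid in c.supporting_reads}
    novel_read_ids = {rid for c in result.loci if c.status == "NOVEL"
                      for rid in c.supporting_reads}
    iso_known = [t for t in result.isoforms if t.status == "KNOWN"]
    iso_new_known = [t for t in result.isoforms
                     if t.status == "NOVEL_AT_KNOWN_LOCUS"]
    iso_novel = [t for t in result.isoforms if t.status == "NOVEL_LOCUS"]
    counts = {
        "clr_total": len(sim.clr_reads),
        "subreads": result.n_subreads,
        "ccs": result.n_ccs_type1,
        "flnc_type1": n_flnc - flnc_type2,
        "flnc_type2": flnc_type2,
        "flnc_total": n_flnc,
        "undetermined": gc.get("UNDETERMINED", 0),
        "g1": gc.get("G1", 0), "g2": gc.get("G2", 0),
        "g3": gc.get("G3", 0), "g4": gc.get("G4", 0),
        "g5": gc.get("G5", 0),
        "excluded_reads": (len(result.hq.removed_5prime_truncated) +
                           len(result.hq.removed_unsupported_singletons)),
        "hq_reads": len(result.hq.kept),
        "hq_reads_extant": len(extant_read_ids),
        "hq_reads_novel": len(novel_read_ids),
        "loci_extant": sum(1 for c in result.loci if c.status == "EXTANT"),
        "loci_novel": sum(1 for c in result.loci if c.status == "NOVEL"),
        "transcripts_confirmed": len(iso_known),
        "transcripts_new_at_known": len(iso_new_known),
        "transcripts_known_loci": len(iso_known) + len(iso_new_known),
        "transcripts_novel_loci": len(iso_novel),
        "transcripts_total": len(result.isoforms),
        "novel_transcripts": len(iso_new_known) + len(iso_novel),
        "loci_total": len(result.loci),
        "orf_reads_total": result.orf_report.n_reads,
        "orf_reads_complete": result.orf_report.n_complete,
        "junctions_total": result.junction_validation.n_junctions,
        "junctions_supported": result.junction_validation.n_supported,
    }
    # the flnc-total/group-sum identity needs reads lost at mapping zero;
    # all FLNC reads are classified (empty alignment sets -> G5)
    check_additive_identities(counts)
    result.counts = counts
    result.derived = derive_report(counts)
    return result


# --------------------------------------------------------------- gene family

@dataclass
class FamilyResult:
    flnc_reads: list[FlncRead]
    hits: list = field(default_factory=list)
    transcripts: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)


def run_family_analysis(fam: FamilySim,
                        flnc_config: FlncConfig | None = None
                        ) -> FamilyResult:
    """FLNC derivation + correction + family search on a family dataset."""
    cfg = flnc_config or FlncConfig()
    flnc: list[FlncRead] = []
    error_estimates: dict[str, float] = {}
    for clr in fam.clr_reads:
        subs = split_subreads(clr, fam.adapter, cfg)
        cons = build_ccs(subs, cfg)
        if cons is None:
            continue
        res = classify_flnc(cons, fam.primer5, fam.primer3, cfg)
        if not isinstance(res, Rejection):
            flnc.append(res)
            e_sub = max(0.0, 1.0 - cons.predicted_accuracy)
            factor = _PASS_ERROR_FACTOR.get(cons.n_passes, 0.08)
            error_estimates[res.id] = min(0.16, e_sub * factor + 0.005)
    corrected, report = correct_with_short_reads(
        flnc, fam.short_reads, cfg, error_estimates=error_estimates)
    for _ in range(max(0, cfg.correction_rounds - 1)):
        obs = report.get("per_read_divergence", {})
        strict_cfg = replace(cfg, correction_budget_slack=0.01)
        strict_est = {rid: 0.3 * v for rid, v in obs.items()}
        corrected, report = correct_with_short_reads(
            corrected, fam.short_reads, strict_cfg,
            error_estimates=strict_est)
    read_seqs = {r.id: r.sequence for r in corrected}
    hits = targeted.search_family(read_seqs, fam.queries,
                                  fam.query_families)
    targeted.annotate_orfs(hits, read_seqs, fam.queries, fam.query_orfs)
    transcripts, summary = targeted.dedupe_family_transcripts(hits,
                                                              read_seqs)
    return FamilyResult(flnc_reads=corrected, hits=hits,
                        transcripts=transcripts, summary=summary)
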