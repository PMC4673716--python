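"""Scoring of pipeline results against the simulator's planted truth.

These helpers are the bridge between the analysis pipeline and the ground
truth carried by :class:`~isoscan.sim.GroundTruth`: precision/recall of
FLNC identification, recovery of planted mapping groups, novel loci,
split-contig bridges, mis-split merges, isoform chains and stage-presence
matrices.  They are used by the validation tests and the acceptance script
alike.
"""
from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np

from .classify import ClassifyThresholds, classify_read_groups
from .mapping import AlignmentSet, SplicedAlignment
from .pipeline import PipelineResult

_BOUNDARIES = (30.0, 40.0, 50.0, 80.0, 90.0)


def _read_rows(result: PipelineResult) -> dict[str, dict]:
    return {r["read_id"]: r for r in result.sim.truth.read_rows}


def flnc_precision_recall(result: PipelineResult) -> tuple[float, float]:
    """Precision/recall of FLNC identification against the planted truth
    (a read should be FLNC iff it is non-chimeric with usable passes)."""
    rows = _read_rows(result)
    called = {r.id for r in result.flnc_reads}
    tp = sum(1 for r in rows.values()
             if r["should_be_flnc"] and r["read_id"] in called)
    fp = sum(1 for rid in called if not rows[rid]["should_be_flnc"])
    fn = sum(1 for r in rows.values()
             if r["should_be_flnc"] and r["read_id"] not in called)
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return precision, recall


def _borderline(assignment) -> bool:
    if not assignment.evidence:
        return False
    a = assignment.evidence[0]
    return any(abs(v - b) < 2.0
               for v in (a.coverage, a.identity) for b in _BOUNDARIES)


def planted_group_accuracy(result: PipelineResult,
                           exclude_borderline: bool = True
                           ) -> tuple[float, Counter]:
    """Fraction of reads assigned their planted G1-G5 group.

    Reads whose measured coverage/identity fall within 2 units of a band
    boundary are excluded when ``exclude_borderline`` (their group is
    genuinely ambiguous at the thresholds).
    """
    rows = _read_rows(result)
    ok = 0
    tot = 0
    confusion: Counter = Counter()
    for a in result.assignments:
        planted = rows[a.read_id]["planted_group"]
        if planted is None:
            continue
        if exclude_borderline and _borderline(a):
            continue
        tot += 1
        ok += planted == a.group
        confusion[(planted, a.group)] += 1
    return (ok / tot if tot else 1.0), confusion


def group_partition_holds(result: PipelineResult) -> bool:
    c = result.group_counts
    return sum(c.values()) == len(result.flnc_reads)


def classification_band_sweep(margin: float = 2.0) -> float:
    """Classifier accuracy on constructed alignment sets whose metrics sit
    at least ``margin`` units inside every band (the deterministic part of
    group recovery; returns the fraction classified correctly)."""
    def aln(cov, ident, contig="c1", start=0):
        rl = 1000
        aligned = int(rl * cov / 100)
        m = int(round(aligned * ident / 100))
        return SplicedAlignment("r", contig, "+",
                                [(0, aligned, start, start + aligned)],
                                m, aligned - m, 0, rl)

    cases = []
    for cov in np.arange(92.5, 100.1, 2.5):
        for ident in np.arange(92.5, 100.1, 2.5):
            cases.append(("G1", [aln(cov, ident)]))
            cases.append(("G2", [aln(cov, ident),
                                 aln(cov, ident, "c2", 5000)]))
    for cov in np.arange(32.5, 78.1, 5):
        for ident in (92.5, 96.0, 99.0):
            cases.append(("G3", [aln(cov, ident),
                                 aln(cov, ident, "c2", 5000)]))
    for cov in np.arange(32.5, 48.1, 5):
        for ident in np.arange(42.5, 88.1, 5):
            cases.append(("G4", [aln(cov, ident)]))
    cases.append(("G5", []))
    ok = 0
    for i, (expected, alns) in enumerate(cases):
        for a in alns:
            a.read_id = f"r{i}"
        out = classify_read_groups({f"r{i}": AlignmentSet(f"r{i}", alns)},
                                   {f"r{i}": "+"})
        ok += out[0].group == expected
    return ok / len(cases)


def novel_locus_precision_recall(result: PipelineResult
                                 ) -> tuple[float, float]:
    """Recovery of planted unannotated loci as NOVEL clusters."""
    truth = result.sim.truth
    rows = _read_rows(result)
    novel_clusters = [c for c in result.loci if c.status == "NOVEL"]
    # a novel cluster is correct iff its reads come from a planted
    # unannotated gene
    tp = 0
    for c in novel_clusters:
        loci = {rows[rid]["locus_id"] for rid in c.supporting_reads
                if rows[rid].get("locus_id")}
        fates = {truth.loci[l].fate for l in loci if l in truth.loci}
        tp += fates == {"novel"}
    precision = tp / len(novel_clusters) if novel_clusters else 1.0
    # recall over planted novel genes with >=2 surviving hq reads
    kept = set(result.hq.kept)
    per_gene: Counter = Counter()
    for rid in kept:
        lt = truth.loci.get(rows[rid].get("locus_id") or "")
        if lt is not None and lt.fate == "novel":
            per_gene[lt.locus_id] += 1
    eligible = {g for g, n in per_gene.items() if n >= 1}
    recovered = set()
    for c in novel_clusters:
        for rid in c.supporting_reads:
            lid = rows[rid].get("locus_id")
            if lid in eligible:
                recovered.add(lid)
    recall = len(recovered) / len(eligible) if eligible else 1.0
    return precision, recall


def split_gene_bridge_recovery(result: PipelineResult
                               ) -> tuple[float, float]:
    """(recall of planted split genes as ortholog-contiguous bridges,
    fraction of their bridges flagged contiguous)."""
    truth = result.sim.truth
    rows = _read_rows(result)
    g3_reads = {a.read_id for a in result.assignments if a.group == "G3"}
    eligible: dict[str, int] = Counter()
    for rid in g3_reads:
        lid = rows[rid].get("locus_id")
        if lid and truth.loci.get(lid) and truth.loci[lid].fate == "split":
            eligible[lid] += 1
    bridges_by_read = {b.read_id: b for b in result.bridges}
    recovered = set()
    contiguous = 0
    n_bridges = 0
    for rid in g3_reads:
        lid = rows[rid].get("locus_id")
        if lid not in eligible:
            continue
        b = bridges_by_read.get(rid)
        if b is not None:
            n_bridges += 1
            contiguous += b.ortholog_contiguous
            if b.ortholog_contiguous:
                recovered.add(lid)
    recall = len(recovered) / len(eligible) if eligible else 1.0
    frac_contiguous = contiguous / n_bridges if n_bridges else 1.0
    return recall, frac_contiguous


def missplit_merge_recall(result: PipelineResult) -> float:
    """Fraction of planted mis-split genes (with surviving reads)
    recovered as VALIDATED merge candidates."""
    truth = result.sim.truth
    rows = _read_rows(result)
    kept = set(result.hq.kept)
    eligible = set()
    for rid in kept:
        lt = truth.loci.get(rows[rid].get("locus_id") or "")
        if lt is not None and lt.fate == "missplit":
            eligible.add(lt.locus_id)
    if not eligible:
        return 1.0
    validated_tids = {m.transcript_id for m in result.merges
                      if m.ortholog_validation == "VALIDATED"}
    iso_by_tid = {t.transcript_id: t for t in result.isoforms}
    recovered = set()
    for tid in validated_tids:
        rep = iso_by_tid[tid].representative_read
        lid = rows[rep].get("locus_id")
        if lid in eligible:
            recovered.add(lid)
    return len(recovered) / len(eligible)


def _expected_chain(tt, template_len: int) -> tuple:
    """The junction chain a (possibly 5'-truncated) read should show.

    A truncated read carries the suffix of its transcript's chain that
    lies downstream of the cut (cut position inferred from the truncated
    template length)."""
    chain = tuple(tt.chain or ())
    if not chain:
        return ()
    full_len = len(tt.seq)
    if template_len >= full_len:
        return chain
    exons = sorted(tt.exon_intervals)
    lens = [e - s for s, e in exons]
    tx_chain = list(chain)
    if tt.strand == "-":
        lens = lens[::-1]
        tx_chain = tx_chain[::-1]
    bounds = np.cumsum(lens)[:-1]
    cut = full_len - template_len
    kept = [j for j, b in zip(tx_chain, bounds) if b > cut]
    return tuple(sorted(kept))


def isoform_chain_recovery(result: PipelineResult,
                           min_reads: int = 2) -> tuple[float, int]:
    """Per-locus exact recovery of planted junction chains.

    For every planted locus with >= ``min_reads`` kept reads: all recovered
    multi-exon chains must be planted chains (or, for surviving truncated
    reads without a full-length sibling, the planted suffix), and every
    planted chain with a kept read must be recovered.  Returns (fraction
    of loci fully recovered, number of eligible loci).
    """
    truth = result.sim.truth
    rows = _read_rows(result)
    kept = set(result.hq.kept)
    reads_per_locus: dict[str, list[str]] = defaultdict(list)
    for rid in kept:
        lid = rows[rid].get("locus_id")
        if lid:
            reads_per_locus[lid].append(rid)
    # recovered chains per planted locus, via the reads supporting them
    rec_chains: dict[str, set] = defaultdict(set)
    for t in result.isoforms:
        lid = rows.get(t.representative_read, {}).get("locus_id")
        if lid:
            rec_chains[lid].add(t.junction_chain)
    n_ok = 0
    n_tot = 0
    for lid, rids in reads_per_locus.items():
        lt = truth.loci.get(lid)
        if lt is None or len(rids) < min_reads:
            continue
        planted = {tuple(truth.transcripts[tid].chain)
                   for tid in lt.transcript_ids
                   if truth.transcripts[tid].chain}
        if not planted:
            continue
        # planted chains represented by kept reads; truncated reads whose
        # full chain is also present collapse onto it (the 5'-truncation
        # filter removes them), otherwise they stand with their suffix
        full = set()
        suffixes = set()
        for rid in rids:
            row = rows[rid]
            tt = truth.transcripts.get(row.get("transcript_id") or "")
            if tt is None or not tt.chain:
                continue
            if not row["is_truncated"]:
                full.add(tuple(tt.chain))
            else:
                ch = _expected_chain(tt, len(row.get("template") or ""))
                if ch:
                    suffixes.add((tuple(tt.chain), ch))
        expected = set(full)
        for full_chain, suffix in suffixes:
            if full_chain not in full:
                expected.add(suffix)
        got = {c for c in rec_chains.get(lid, set()) if c}
        n_tot += 1
        n_ok += got == expected
    return (n_ok / n_tot if n_tot else 1.0), n_tot


def presence_matrix_recovery(result: PipelineResult) -> tuple[float, int]:
    """Exact per-stage presence recovery for resolvable isoforms.

    Each recovered isoform is matched to its planted transcript via its
    representative read; presence calls over stages must equal the planted
    stage matrix.  Only loci whose planted multi-exon chain catalogue was
    fully recovered are compared: junction-specificity (and hence presence)
    is defined relative to the catalogue, so an unsampled sibling isoform
    changes the question, not the answer.  Returns (fraction exact, number
    of isoforms compared).
    """
    truth = result.sim.truth
    rows = _read_rows(result)
    stages = result.sim.config.stages
    complete_loci = _loci_with_full_catalogue(result)
    by_iso: dict[str, dict[str, bool]] = defaultdict(dict)
    resolvable: dict[str, bool] = {}
    for p in result.presences:
        by_iso[p.transcript_id][p.stage] = p.present
        resolvable[p.transcript_id] = p.resolvable
    ok = 0
    tot = 0
    for t in result.isoforms:
        if not resolvable.get(t.transcript_id):
            continue
        row = rows.get(t.representative_read)
        if not row or not row.get("transcript_id"):
            continue
        if row.get("locus_id") not in complete_loci:
            continue
        tt = truth.transcripts[row["transcript_id"]]
        if tt.stage_present is None:
            continue
        got = tuple(by_iso[t.transcript_id].get(s, False) for s in stages)
        want = tuple(bool(x) for x in tt.stage_present)
        tot += 1
        ok += got == want
    return (ok / tot if tot else 1.0), tot


def _loci_with_full_catalogue(result: PipelineResult) -> set[str]:
    """Planted loci whose recovered multi-exon chain set equals the full
    planted chain set (every planted isoform sampled and recovered)."""
    truth = result.sim.truth
    rows = _read_rows(result)
    rec_chains: dict[str, set] = defaultdict(set)
    for t in result.isoforms:
        lid = rows.get(t.representative_read, {}).get("locus_id")
        if lid:
            rec_chains[lid].add(t.junction_chain)
    out = set()
    for lid, lt in truth.loci.items():
        planted = {tuple(truth.transcripts[tid].chain)
                   for tid in lt.transcript_ids
                   if truth.transcripts[tid].chain}
        if planted and {c for c in rec_chains.get(lid, set()) if c} \
                == planted:
            out.add(lid)
    return out


def expressed_set_recovery(result: PipelineResult) -> tuple[float, int]:
    """RPKM-based expressed-gene calls vs the planted stage matrix.

    Compared per annotated draft model of fully-present single-model genes
    (normal fate; mis-split part-models can be too short to capture fully
    contained reads): the model is expressed at a stage iff any planted
    isoform of its locus is present there.  Returns (fraction of
    gene x stage cells matching, number of cells).
    """
    truth = result.sim.truth
    stages = result.sim.config.stages
    model_to_locus = {}
    for lt in truth.loci.values():
        if lt.fate == "normal":
            for mid in lt.model_ids:
                model_to_locus[mid] = lt.locus_id
    expressed = result.expressed_genes
    ok = 0
    tot = 0
    for mid, lid in model_to_locus.items():
        lt = truth.loci[lid]
        if not lt.transcript_ids:
            continue
        for si, stage in enumerate(stages):
            want = any(bool(truth.transcripts[tid].stage_present[si])
                       for tid in lt.transcript_ids)
            got = mid in expressed.get(stage, set())
            tot += 1
            ok += want == got
    return (ok / tot if tot else 1.0), tot
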