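"""Targeted gene-family transcript search (seed-storage-protein style).

Full-length reads are searched against family query sequences by gapped
alignment, each positive read is checked for a complete open reading frame
relative to its best query (intact, disrupted by a premature stop, or
partial), and the complete reads are collapsed into non-redundant
transcripts at 99% identity so that >=3%-diverged homoeologs/paralogs stay
separate while residual sequencing error is absorbed.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import edlib

from .seq import cigar_counts, parse_cigar, translate


@dataclass
class FamilyHit:
    read_id: str
    query_id: str
    family: str
    align_score: int          # matched bases
    identity: float           # percent
    query_coverage: float     # percent
    orf_status: str = "PARTIAL"   # COMPLETE_INTACT/COMPLETE_DISRUPTED/PARTIAL
    orf_span: tuple[int, int] | None = None
    premature_stop_pos: int | None = None


def _align_query(query: str, read: str) -> dict | None:
    res = edlib.align(query, read, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["cigar"]:
        return None
    return res


def search_family(read_seqs: dict[str, str], queries: list,
                  query_families: dict[str, str],
                  min_identity: float = 80.0,
                  min_query_coverage: float = 80.0) -> list[FamilyHit]:
    """Best family assignment per read from gapped query-vs-read alignment.

    A hit needs identity and query coverage at the thresholds; ties between
    queries break by score then query id.
    """
    if not queries:
        raise ValueError("empty query set")
    out: list[FamilyHit] = []
    for rid in sorted(read_seqs):
        read = read_seqs[rid]
        best: FamilyHit | None = None
        for q in queries:
            res = _align_query(q.sequence, read)
            if res is None:
                continue
            m, x, i, d = cigar_counts(res["cigar"])
            ident = 100.0 * m / max(1, m + x + i + d)
            qcov = 100.0 * (m + x) / len(q.sequence)
            if ident < min_identity or qcov < min_query_coverage:
                continue
            hit = FamilyHit(read_id=rid, query_id=q.id,
                            family=query_families[q.id], align_score=m,
                            identity=ident, query_coverage=qcov)
            if best is None or hit.align_score > best.align_score or \
                    (hit.align_score == best.align_score and
                     hit.query_id < best.query_id):
                best = hit
        if best is not None:
            out.append(best)
    return out


def _map_query_pos(cigar: str, tstart: int, qpos_wanted: list[int]
                   ) -> list[int | None]:
    """Map query positions to target (read) positions through a CIGAR."""
    res: dict[int, int | None] = {}
    wanted = sorted(qpos_wanted)
    wi = 0
    qpos, tpos = 0, tstart
    for n, op in parse_cigar(cigar):
        if op in "=XM":
            while wi < len(wanted) and qpos <= wanted[wi] < qpos + n:
                res[wanted[wi]] = tpos + (wanted[wi] - qpos)
                wi += 1
            qpos += n
            tpos += n
        elif op == "I":   # query-only bases
            while wi < len(wanted) and qpos <= wanted[wi] < qpos + n:
                res[wanted[wi]] = tpos
                wi += 1
            qpos += n
        elif op == "D":   # target-only bases
            tpos += n
    return [res.get(p) for p in qpos_wanted]


def check_orf(read_seq: str, query_seq: str, query_orf: tuple[int, int],
              stop_tolerance_codons: int = 2) -> dict:
    """ORF completeness of a read relative to its family query.

    Locates the read position homologous to the query's start codon,
    translates, and compares the first in-frame stop with the homologous
    stop position: at the same position (+-2 codons) = intact; strictly
    earlier = disrupted (premature stop, 0-based codon index reported);
    start/stop region missing from the read = partial.
    """
    res = _align_query(query_seq, read_seq)
    if res is None:
        return {"orf_status": "PARTIAL", "orf_span": None,
                "premature_stop_pos": None}
    tstart = res["locations"][0][0] or 0
    qs, qe = query_orf
    mapped = _map_query_pos(res["cigar"], tstart, [qs, qe - 3])
    start_t, stop_t = mapped
    if start_t is None or stop_t is None:
        return {"orf_status": "PARTIAL", "orf_span": None,
                "premature_stop_pos": None}
    # allow a little end-wobble when hunting for the actual ATG
    start = None
    for d in sorted(range(-4, 5), key=abs):
        p = start_t + d
        if 0 <= p <= len(read_seq) - 3 and read_seq[p:p + 3] == "ATG":
            start = p
            break
    if start is None or stop_t + 3 > len(read_seq):
        return {"orf_status": "PARTIAL", "orf_span": None,
                "premature_stop_pos": None}
    expected_codons = int(round((stop_t - start) / 3))
    aa = translate(read_seq[start:])
    if aa.count("X") > 0.1 * max(1, len(aa)):
        return {"orf_status": "PARTIAL", "orf_span": None,
                "premature_stop_pos": None}
    stop_idx = aa.find("*")
    if stop_idx < 0:
        return {"orf_status": "PARTIAL", "orf_span": None,
                "premature_stop_pos": None}
    span = (start, start + 3 * (stop_idx + 1))
    if abs(stop_idx - expected_codons) <= stop_tolerance_codons:
        return {"orf_status": "COMPLETE_INTACT", "orf_span": span,
                "premature_stop_pos": None}
    if stop_idx < expected_codons - stop_tolerance_codons:
        return {"orf_status": "COMPLETE_DISRUPTED", "orf_span": span,
                "premature_stop_pos": stop_idx}
    return {"orf_status": "PARTIAL", "orf_span": span,
            "premature_stop_pos": None}


def annotate_orfs(hits: list[FamilyHit], read_seqs: dict[str, str],
                  queries: list, query_orfs: dict[str, tuple[int, int]]
                  ) -> list[FamilyHit]:
    qseq = {q.id: q.sequence for q in queries}
    for h in hits:
        info = check_orf(read_seqs[h.read_id], qseq[h.query_id],
                         query_orfs[h.query_id])
        h.orf_status = info["orf_status"]
        h.orf_span = info["orf_span"]
        h.premature_stop_pos = info["premature_stop_pos"]
    return hits


@dataclass
class FamilyTranscript:
    cluster_id: str
    family: str
    representative_read: str
    n_reads: int
    orf_status: str
    premature_stop_pos: int | None


def dedupe_family_transcripts(hits: list[FamilyHit],
                              read_seqs: dict[str, str],
                              identity_threshold: float = 0.99
                              ) -> tuple[list[FamilyTranscript], dict]:
    """Cluster complete-ORF reads at >=99% full-length identity.

    One representative per cluster; the summary counts, per family and
    overall, positive reads, complete-ORF reads, unique transcripts, and
    intact vs disrupted clusters, with the complete-ORF proportion as a
    percentage (1 decimal).
    """
    complete = [h for h in hits if h.orf_status.startswith("COMPLETE")]
    by_family: dict[str, list[FamilyHit]] = defaultdict(list)
    for h in complete:
        by_family[h.family].append(h)
    transcripts: list[FamilyTranscript] = []
    for family in sorted(by_family):
        fam_hits = sorted(by_family[family],
                          key=lambda h: (-len(read_seqs[h.read_id]),
                                         h.read_id))
        reps: list[tuple[str, list[FamilyHit]]] = []
        for h in fam_hits:
            seq = read_seqs[h.read_id]
            placed = False
            for rep_id, members in reps:
                rep_seq = read_seqs[rep_id]
                d = edlib.align(seq, rep_seq, mode="NW")["editDistance"]
                if d >= 0 and 1.0 - d / max(len(seq), len(rep_seq)) >= \
                        identity_threshold:
                    members.append(h)
                    placed = True
                    break
            if not placed:
                reps.append((h.read_id, [h]))
        for ci, (rep_id, members) in enumerate(reps):
            statuses = Counter(m.orf_status for m in members)
            status = statuses.most_common(1)[0][0]
            stop = None
            if status == "COMPLETE_DISRUPTED":
                stops = Counter(m.premature_stop_pos for m in members
                                if m.premature_stop_pos is not None)
                if stops:
                    stop = stops.most_common(1)[0][0]
            transcripts.append(FamilyTranscript(
                cluster_id=f"{family}_t{ci + 1}", family=family,
                representative_read=rep_id, n_reads=len(members),
                orf_status=status, premature_stop_pos=stop))
    per_family = {}
    for family in sorted({h.family for h in hits}):
        fam_all = [h for h in hits if h.family == family]
        fam_complete = [h for h in fam_all
                        if h.orf_status.startswith("COMPLETE")]
        fam_tr = [t for t in transcripts if t.family == family]
        per_family[family] = {
            "n_reads_positive": len(fam_all),
            "n_reads_complete": len(fam_complete),
            "n_unique_transcripts": len(fam_tr),
            "n_intact": sum(1 for t in fam_tr
                            if t.orf_status == "COMPLETE_INTACT"),
            "n_disrupted": sum(1 for t in fam_tr
                               if t.orf_status == "COMPLETE_DISRUPTED"),
        }
    n_pos = len(hits)
    n_comp = len(complete)
    summary = {
        "per_family": per_family,
        "n_reads_positive": n_pos,
        "n_reads_complete": n_comp,
        "n_unique_transcripts": len(transcripts),
        "percent_complete": round(100.0 * n_comp / n_pos, 1) if n_pos else 0.0,
    }
    return transcripts, summary
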