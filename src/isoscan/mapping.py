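"""Spliced alignment of full-length transcript reads to a draft genome.

The aligner is deliberately simple: exact k-mer seeds are chained
colinearly per contig, inter-seed gaps are closed with banded edit-distance
alignment, and genomic gaps of at least ``min_intron`` bases are treated as
introns whose boundaries are shifted (within a small window) onto the
nearest canonical splice motif (GT..AG, then GC..AG, then AT..AC).  It is
meant for toy-scale genomes where transparency and testability matter more
than speed.

Coordinates are 0-based half-open throughout.  For minus-strand alignments
the read coordinates of the blocks refer to the reverse-complemented read
(PSL convention), so blocks ascend on both the read and the genome.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .seq import (align_path, cigar_counts, encode, kmer_hashes, parse_cigar,
                  revcomp)

# canonical intron dinucleotide pairs in priority order, forward orientation
_CANONICAL_FWD = [("GT", "AG"), ("GC", "AG"), ("AT", "AC")]
# the same motifs as seen on the forward genome strand for a minus-strand gene
_CANONICAL_REV = [("CT", "AC"), ("CT", "GC"), ("GT", "AT")]


@dataclass
class SplicedAlignment:
    """A blocked (exon-level) alignment of one read to one contig."""

    read_id: str
    contig: str
    strand: str  # '+', '-' or '?'
    blocks: list[tuple[int, int, int, int]]  # (read_start, read_end, genome_start, genome_end)
    matches: int
    mismatches: int
    indels: int
    read_length: int

    @property
    def aligned_read_length(self) -> int:
        return sum(re - rs for rs, re, _, _ in self.blocks)

    @property
    def coverage(self) -> float:
        """Aligned fraction of the read, percent."""
        return 100.0 * self.aligned_read_length / self.read_length

    @property
    def identity(self) -> float:
        """matches / (matches + mismatches + indels), percent."""
        denom = self.matches + self.mismatches + self.indels
        return 100.0 * self.matches / denom if denom else 0.0

    @property
    def score(self) -> float:
        return self.coverage * self.identity / 100.0

    @property
    def genome_start(self) -> int:
        return self.blocks[0][2]

    @property
    def genome_end(self) -> int:
        return self.blocks[-1][3]

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (_, _, _, ge), (_, _, gs, _) in zip(self.blocks, self.blocks[1:]):
            out.append((ge, gs))
        return out

    def exon_intervals(self) -> list[tuple[int, int]]:
        """Genomic intervals of the blocks, merged when adjacent."""
        out: list[tuple[int, int]] = []
        for _, _, gs, ge in self.blocks:
            if out and gs <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], ge))
            else:
                out.append((gs, ge))
        return out


@dataclass
class AlignmentSet:
    read_id: str
    alignments: list[SplicedAlignment] = field(default_factory=list)

    def sort(self) -> None:
        self.alignments.sort(
            key=lambda a: (-a.score, a.contig, a.genome_start))


@dataclass
class AlignParams:
    k: int = 15
    seed_stride: int = 5
    min_intron: int = 40
    max_intron: int = 6000
    min_report_identity: float = 40.0
    min_report_coverage: float = 30.0
    max_kmer_hits: int = 64
    splice_shift: int = 6
    locus_gap: int = 8000
    max_anchors: int = 200
    tie_delta: float = 0.1


def compute_coverage_identity(alignment: SplicedAlignment,
                              read_length: int | None = None) -> tuple[float, float]:
    """(coverage %, identity %) of an alignment; errors on empty alignments."""
    if read_length is None:
        read_length = alignment.read_length
    aligned = alignment.aligned_read_length
    if aligned <= 0 or read_length <= 0:
        raise ValueError("alignment covers zero bases")
    cov = 100.0 * aligned / read_length
    denom = alignment.matches + alignment.mismatches + alignment.indels
    ident = 100.0 * alignment.matches / denom if denom else 0.0
    return cov, ident


def select_best_locus(aln_set: AlignmentSet, tie_delta: float = 0.1
                      ) -> tuple[SplicedAlignment, list[SplicedAlignment]]:
    """Best alignment by coverage x identity, plus the list of score-ties.

    The tie list always contains the winner; a length > 1 means the read has
    multiple best alignments ("ambiguous" locus assignment).
    """
    if not aln_set.alignments:
        raise ValueError(f"no alignments for read {aln_set.read_id}")
    aln_set.sort()
    best = aln_set.alignments[0]
    tied = [a for a in aln_set.alignments if best.score - a.score < tie_delta]
    return best, tied


class GenomeIndex:
    """Sorted-array exact k-mer index over a set of contigs."""

    def __init__(self, contigs: dict[str, str], k: int = 15):
        self.k = k
        self.contigs = contigs
        self.names = list(contigs)
        sep = "N" * k
        parts = []
        offsets = []
        pos = 0
        for name in self.names:
            offsets.append(pos)
            parts.append(contigs[name])
            pos += len(contigs[name]) + k
            parts.append(sep)
        self.offsets = np.array(offsets, dtype=np.int64)
        self.lengths = np.array([len(contigs[n]) for n in self.names],
                                dtype=np.int64)
        self._name_idx = {n: i for i, n in enumerate(self.names)}
        self._codes = encode("".join(parts))
        hashes = kmer_hashes(self._codes, k)
        valid = np.nonzero(hashes >= 0)[0]
        order = np.argsort(hashes[valid], kind="stable")
        self._sorted_hashes = hashes[valid][order]
        self._sorted_pos = valid[order].astype(np.int64)

    def contig_of(self, gpos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        return self.names[i], int(gpos - self.offsets[i])

    def contig_seq(self, name: str) -> str:
        return self.contigs[name]

    def lookup(self, query_hashes: np.ndarray, max_hits: int
               ) -> tuple[np.ndarray, np.ndarray]:
        """Match query k-mer hashes against the genome.

        Returns (query_indices, genome_positions); k-mers with more than
        ``max_hits`` genomic occurrences are dropped as repeats.
        """
        lo = np.searchsorted(self._sorted_hashes, query_hashes, side="left")
        hi = np.searchsorted(self._sorted_hashes, query_hashes, side="right")
        counts = hi - lo
        keep = (query_hashes >= 0) & (counts > 0) & (counts <= max_hits)
        qi_list = []
        gp_list = []
        for qi in np.nonzero(keep)[0]:
            gp = self._sorted_pos[lo[qi]:hi[qi]]
            qi_list.append(np.full(len(gp), qi, dtype=np.int64))
            gp_list.append(gp)
        if not qi_list:
            return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        return np.concatenate(qi_list), np.concatenate(gp_list)


def _chain_anchors(anchors: list[tuple[int, int]], k: int,
                   params: AlignParams) -> list[tuple[int, int]]:
    """Longest colinear chain of (read_pos, genome_pos) anchors (O(n^2) DP)."""
    if len(anchors) > params.max_anchors:
        idx = np.linspace(0, len(anchors) - 1, params.max_anchors).astype(int)
        anchors = [anchors[i] for i in sorted(set(idx.tolist()))]
    anchors = sorted(anchors)
    n = len(anchors)
    best = [1] * n
    prev = [-1] * n
    for j in range(n):
        rj, gj = anchors[j]
        for i in range(j - 1, -1, -1):
            ri, gi = anchors[i]
            dr = rj - ri
            dg = gj - gi
            if dr <= 0 or dg <= 0:
                continue
            if dg - dr < -50 or dg - dr > params.max_intron + 2000:
                continue
            if best[i] + 1 > best[j]:
                best[j] = best[i] + 1
                prev[j] = i
    end = int(np.argmax(best))
    chain = []
    while end >= 0:
        chain.append(anchors[end])
        end = prev[end]
    chain.reverse()
    return chain


def _segments_from_chain(chain: list[tuple[int, int]], k: int,
                         min_intron: int) -> list[list[int]]:
    """Merge same-diagonal chain anchors into maximal segments.

    Each segment is [read_start, read_end, genome_start, genome_end]; only
    anchors on exactly the same diagonal merge, so a segment's read and
    genome spans are equal (interior non-anchor bases are re-verified by
    direct comparison later).
    """
    segs: list[list[int]] = []
    for rp, gp in chain:
        if segs:
            seg = segs[-1]
            dr = rp - (seg[1] - k)
            dg = gp - (seg[3] - k)
            if 0 <= dr and dg == dr:
                seg[1] = rp + k
                seg[3] = gp + k
                continue
        segs.append([rp, rp + k, gp, gp + k])
    return segs


def _match_profile(a: str, b: str) -> np.ndarray:
    n = min(len(a), len(b))
    if n == 0:
        return np.empty(0, dtype=np.int32)
    return (np.frombuffer(a[:n].encode(), dtype=np.uint8)
            == np.frombuffer(b[:n].encode(), dtype=np.uint8)).astype(np.int32)


def _refine_splice(read_seg: str, genome: str, gl_start: int, gr_end: int,
                   strand: str, shift: int
                   ) -> tuple[int, int, int]:
    """Place a splice point inside an unanchored read segment.

    The read segment sits between two exonic anchors; the left exon continues
    at genome position ``gl_start`` and the right exon ends at ``gr_end``.
    Returns (j, mismatches_left, mismatches_right) where j is the number of
    read bases assigned to the left exon, after shifting the junction (within
    +-shift) onto the highest-priority canonical motif available.
    """
    L = len(read_seg)
    gl = genome[gl_start:gl_start + L]
    gr = genome[max(0, gr_end - L):gr_end]
    left_m = _match_profile(read_seg, gl)
    right_m = _match_profile(read_seg[::-1], gr[::-1])
    pref = np.concatenate([[0], np.cumsum(left_m)])
    suf = np.concatenate([[0], np.cumsum(right_m)])
    # pad if genome windows were clipped at contig edges
    if len(pref) < L + 1:
        pref = np.concatenate([pref, np.full(L + 1 - len(pref), pref[-1])])
    if len(suf) < L + 1:
        suf = np.concatenate([suf, np.full(L + 1 - len(suf), suf[-1])])
    total = pref[:L + 1] + suf[:L + 1][::-1]
    j0 = int(np.argmax(total))
    motifs = _CANONICAL_FWD if strand == "+" else _CANONICAL_REV
    best_j = j0
    best_rank = len(motifs)  # non-canonical
    for delta in sorted(range(-shift, shift + 1), key=abs):
        j = j0 + delta
        if not 0 <= j <= L:
            continue
        donor = genome[gl_start + j:gl_start + j + 2]
        acceptor = genome[gr_end - (L - j) - 2:gr_end - (L - j)]
        for rank, (dm, am) in enumerate(motifs):
            if donor == dm and acceptor == am and rank < best_rank:
                # accept a small score sacrifice for a canonical boundary
                if total[j0] - total[j] <= 3:
                    best_rank = rank
                    best_j = j
    j = best_j
    mm_left = j - int(pref[j])
    mm_right = (L - j) - int(suf[L - j])
    return j, mm_left, mm_right


def _trim_cigar(ops: list[tuple[int, str]], from_end: bool
                ) -> tuple[list[tuple[int, str]], int, int]:
    """Trim low-quality tail ops; returns (ops, read_trim, genome_trim).

    Walking from the chosen end, find the split that maximises
    (matches - 2 x errors) of the kept part; the 2x penalty stops the
    extension from wandering through unrelated sequence, where gapped
    alignment still matches roughly half the columns.
    """
    seq = ops[::-1] if from_end else list(ops)
    score = 0
    best = 0
    best_i = 0
    for i, (n, op) in enumerate(seq):
        score += n if op == "=" else -2 * n
        if score >= best:
            best = score
            best_i = i + 1
    kept = seq[:best_i]
    dropped = seq[best_i:]
    rt = sum(n for n, op in dropped if op in "=XI")
    gt = sum(n for n, op in dropped if op in "=XD")
    kept = kept[::-1] if from_end else kept
    return kept, rt, gt


def _align_segment(read_seg: str, genome_seg: str) -> tuple[int, int, int, str]:
    """Global alignment counts (matches, mismatches, indels, cigar)."""
    if not read_seg and not genome_seg:
        return 0, 0, 0, ""
    if not read_seg:
        return 0, 0, len(genome_seg), f"{len(genome_seg)}D"
    if not genome_seg:
        return 0, 0, len(read_seg), f"{len(read_seg)}I"
    res = align_path(read_seg, genome_seg, mode="NW")
    m, x, i, d = cigar_counts(res["cigar"])
    return m, x, i + d, res["cigar"]


class _BlockBuilder:
    """Accumulates exon blocks while walking a chain left to right."""

    def __init__(self):
        self.blocks: list[list[int]] = []
        self.matches = 0
        self.mismatches = 0
        self.indels = 0

    def extend(self, rs: int, re_: int, gs: int, ge: int,
               m: int, x: int, ind: int) -> None:
        if re_ <= rs and ge <= gs:
            return
        if self.blocks and self.blocks[-1][1] >= rs and self.blocks[-1][3] >= gs:
            self.blocks[-1][1] = max(self.blocks[-1][1], re_)
            self.blocks[-1][3] = max(self.blocks[-1][3], ge)
        else:
            self.blocks.append([rs, re_, gs, ge])
        self.matches += m
        self.mismatches += x
        self.indels += ind

    def result(self) -> tuple[list[tuple[int, int, int, int]], int, int, int]:
        blocks = [tuple(b) for b in self.blocks if b and b[1] > b[0]]
        return blocks, self.matches, self.mismatches, self.indels


def _build_alignment(read_id: str, oriented_read: str, strand: str,
                     contig: str, contig_seq: str,
                     chain: list[tuple[int, int]], params: AlignParams
                     ) -> SplicedAlignment | None:
    k = params.k
    segs = _segments_from_chain(chain, k, params.min_intron)
    bb = _BlockBuilder()
    exon_blocks: list[list[int]] = []

    # left extension before the first segment
    rs0, _, gs0, _ = segs[0]
    ext_len = min(rs0, gs0 + 60)
    cur_rs, cur_gs = rs0, gs0
    if rs0 > 0 and ext_len > 0:
        gwin_start = max(0, gs0 - rs0 - 30)
        rseg = oriented_read[:rs0][::-1]
        gseg = contig_seq[gwin_start:gs0][::-1]
        if gseg:
            res = edlib.align(rseg, gseg, mode="SHW", task="path")
            if res["editDistance"] >= 0 and res["cigar"]:
                ops = parse_cigar(res["cigar"])
                ops, rtrim, gtrim = _trim_cigar(ops, from_end=True)
                rlen = sum(n for n, op in ops if op in "=XI")
                glen = sum(n for n, op in ops if op in "=XD")
                m = sum(n for n, op in ops if op == "=")
                x = sum(n for n, op in ops if op == "X")
                ind = sum(n for n, op in ops if op in "ID")
                cur_rs = rs0 - rlen
                cur_gs = gs0 - glen
                bb.extend(cur_rs, rs0, cur_gs, gs0, m, x, ind)

    prev = None
    for si, (srs, sre, sgs, sge) in enumerate(segs):
        if prev is not None:
            prs, pge = prev  # read end and genome end of previous segment
            gap_r = srs - prs
            gap_g = sgs - pge
            if gap_r < 0 or gap_g < 0:
                # overlapping anchors; trim the incoming segment
                trim = max(-gap_r, -gap_g, 0)
                srs += trim
                sgs += trim
                gap_r = srs - prs
                gap_g = sgs - pge
                if sre - srs < 1 or sge - sgs < 1:
                    continue
            if gap_g - gap_r >= params.min_intron and gap_r <= 450:
                # intron: split the unanchored read bases between the exons.
                # Retract both flanks a little first: an exact anchor can
                # coincidentally extend past the true exon boundary, which
                # would otherwise push the donor/acceptor out of reach.
                pad_l = min(6, prs, pge)
                if bb.blocks:
                    pad_l = min(pad_l, bb.blocks[-1][1] - bb.blocks[-1][0] - 1)
                pad_l = max(0, pad_l)
                pad_r = max(0, min(6, sre - srs - 1))
                if pad_l:
                    bb.blocks[-1][1] -= pad_l
                    bb.blocks[-1][3] -= pad_l
                    bb.matches -= pad_l
                rs0, gl = prs - pad_l, pge - pad_l
                rs1, gr = srs + pad_r, sgs + pad_r
                rseg = oriented_read[rs0:rs1]
                j, mm_l, mm_r = _refine_splice(
                    rseg, contig_seq, gl, gr, strand, params.splice_shift)
                bb.extend(rs0, rs0 + j, gl, gl + j, j - mm_l, mm_l, 0)
                # close current exon, open the next
                nleft = len(rseg) - j
                bb.blocks.append([rs1 - nleft, rs1, gr - nleft, gr])
                bb.matches += nleft - mm_r
                bb.mismatches += mm_r
                srs += pad_r
                sgs += pad_r
            else:
                m, x, ind, _ = _align_segment(
                    oriented_read[prs:srs], contig_seq[pge:sgs])
                fill_cols = m + x + ind
                if fill_cols > 60 and m < 0.7 * fill_cols:
                    # the fill is junk: the anchors on either side belong to
                    # different (or spurious) loci -- keep the heavier side
                    done = sum(b[1] - b[0] for b in bb.blocks if b)
                    todo = sum(s[1] - s[0] for s in segs[si:])
                    if todo > done:
                        bb = _BlockBuilder()   # restart from this segment
                    else:
                        break
                else:
                    bb.extend(prs, srs, pge, sgs, m, x, ind)
        seg_mm = int(np.count_nonzero(
            _match_profile(oriented_read[srs:sre],
                           contig_seq[sgs:sge]) == 0))
        bb.extend(srs, sre, sgs, sge, (sre - srs) - seg_mm, seg_mm, 0)
        prev = (sre, sge)

    # right extension
    rsn, gse = prev
    if rsn < len(oriented_read):
        tail = oriented_read[rsn:]
        gseg = contig_seq[gse:gse + len(tail) + 30]
        if gseg:
            res = edlib.align(tail, gseg, mode="SHW", task="path")
            if res["editDistance"] >= 0 and res["cigar"]:
                ops = parse_cigar(res["cigar"])
                ops, rtrim, gtrim = _trim_cigar(ops, from_end=True)
                rlen = sum(n for n, op in ops if op in "=XI")
                glen = sum(n for n, op in ops if op in "=XD")
                m = sum(n for n, op in ops if op == "=")
                x = sum(n for n, op in ops if op == "X")
                ind = sum(n for n, op in ops if op in "ID")
                if rlen:
                    bb.extend(rsn, rsn + rlen, gse, gse + glen, m, x, ind)

    blocks, m, x, ind = bb.result()
    if not blocks:
        return None
    aln = SplicedAlignment(read_id=read_id, contig=contig, strand=strand,
                           blocks=blocks, matches=m, mismatches=x,
                           indels=ind, read_length=len(oriented_read))
    return aln


def _gather_seeds(seq: str, index: GenomeIndex, params: AlignParams
                  ) -> list[tuple[int, int]]:
    codes = encode(seq)
    hashes = kmer_hashes(codes, params.k)
    if len(hashes) == 0:
        return []
    sel = np.arange(0, len(hashes), params.seed_stride)
    qi, gp = index.lookup(hashes[sel], params.max_kmer_hits)
    rp = sel[qi]
    return list(zip(rp.tolist(), gp.tolist()))


def toy_spliced_align(read_id: str, read_seq: str, index: GenomeIndex,
                      params: AlignParams | None = None) -> AlignmentSet:
    """Seed-chain-extend spliced alignment of one read against the index.

    Both orientations are tried; every locus (seed cluster) whose alignment
    reaches the reporting thresholds is returned, best first.
    """
    params = params or AlignParams()
    out = AlignmentSet(read_id=read_id)
    if len(read_seq) < params.k:
        return out
    for strand, seq in (("+", read_seq), ("-", revcomp(read_seq))):
        seeds = _gather_seeds(seq, index, params)
        if not seeds:
            continue
        # split seeds per contig, then into per-locus clusters by distance
        seeds.sort(key=lambda s: s[1])
        gp_arr = np.array([gp for _, gp in seeds], dtype=np.int64)
        contig_idx = np.searchsorted(index.offsets, gp_arr,
                                     side="right") - 1
        clusters: list[tuple[int, list[tuple[int, int]]]] = []
        for (rp, gp), ci in zip(seeds, contig_idx.tolist()):
            if clusters and clusters[-1][0] == ci and \
                    gp - clusters[-1][1][-1][1] <= params.locus_gap:
                clusters[-1][1].append((rp, gp))
            else:
                clusters.append((ci, [(rp, gp)]))
        for ci, cl in clusters:
            if len(cl) < 2 and len(seeds) > 4:
                continue
            contig = index.names[ci]
            base = index.offsets[ci]
            local = [(rp, int(gp - base)) for rp, gp in cl]
            chain = _chain_anchors(local, params.k, params)
            if not chain:
                continue
            aln = _build_alignment(read_id, seq, strand, contig,
                                   index.contig_seq(contig), chain, params)
            if aln is None or aln.aligned_read_length == 0:
                continue
            cov, ident = compute_coverage_identity(aln)
            if ident >= params.min_report_identity and \
                    cov >= params.min_report_coverage:
                out.alignments.append(aln)
    out.sort()
    return out


def determine_strand(alignment: SplicedAlignment, genome: dict[str, str],
                     min_intron: int = 40,
                     competing: SplicedAlignment | None = None,
                     tie_delta: float = 0.1) -> str:
    """Transcript strand of an alignment.

    Canonical intron motifs vote when the alignment is spliced; otherwise the
    orientation of the (sense-oriented) read is used.  '?' when motifs
    conflict or when a single-exon read aligns equally well in both
    orientations (``competing`` = best opposite-orientation alignment).
    """
    contig_seq = genome[alignment.contig]
    votes = {"+": 0, "-": 0}
    for ds, ae in alignment.introns:
        if ae - ds < min_intron:
            continue
        donor = contig_seq[ds:ds + 2]
        acceptor = contig_seq[ae - 2:ae]
        for dm, am in _CANONICAL_FWD:
            if donor == dm and acceptor == am:
                votes["+"] += 1
        for dm, am in _CANONICAL_REV:
            if donor == dm and acceptor == am:
                votes["-"] += 1
    if votes["+"] or votes["-"]:
        if votes["+"] == votes["-"]:
            return "?"   # balanced conflict
        motif_strand = "+" if votes["+"] > votes["-"] else "-"
        # motif orientation is genomic; transcript strand is the alignment
        # orientation when they agree, '?' when they conflict
        return motif_strand if motif_strand == alignment.strand else "?"
    if competing is not None and \
            abs(alignment.score - competing.score) < tie_delta:
        return "?"
    return alignment.strand
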