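"""Lightweight splice-aware placement of short transcriptomic reads.

This is the package's stand-in for a short-read spliced aligner: exact
k-mer anchors locate candidate placements, contiguous placements are
verified by direct comparison, and diagonal jumps within intron bounds
become splice junctions whose boundaries are refined onto canonical motifs.
The products are exactly what the downstream analyses need: per-stage
junction support counts, exonic coverage masks, and unique placements for
gene-level read counting.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .mapping import GenomeIndex, _refine_splice
from .seq import encode, kmer_hashes, revcomp

_MOTIF_FWD = {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}
_MOTIF_REV = {("CT", "AC"), ("CT", "GC"), ("GT", "AT")}


@dataclass
class ShortReadPlacement:
    contig: str
    blocks: list[tuple[int, int]]
    junctions: list[tuple[int, int]]
    mismatches: int
    clipped: int = 0

    @property
    def cost(self) -> float:
        # soft-clipped bases carry a small penalty so that a clipped
        # same-locus placement outranks a full-length diverged one
        return self.mismatches + 0.08 * self.clipped


@dataclass
class StageAlignments:
    """Alignment summary of one short-read library."""
    stage: str
    n_reads: int = 0
    n_unique: int = 0
    n_multi: int = 0
    n_unmapped: int = 0
    junction_support: Counter = field(default_factory=Counter)
    unique_placements: list[ShortReadPlacement] = field(default_factory=list)

    @property
    def mapped_reads_millions(self) -> float:
        return self.n_unique / 1e6


def _junction_strand(genome_seq: str, donor: int, acceptor: int) -> str:
    pair = (genome_seq[donor:donor + 2], genome_seq[acceptor - 2:acceptor])
    if pair in _MOTIF_FWD:
        return "+"
    if pair in _MOTIF_REV:
        return "-"
    return "."


def _try_place(seq: str, codes: np.ndarray, index: GenomeIndex,
               anchors: list[tuple[int, int]], max_mismatch: int,
               min_intron: int, max_intron: int
               ) -> ShortReadPlacement | None:
    """Verify one candidate placement from a colinear anchor group."""
    anchors = sorted(anchors)
    # merge anchors into diagonal segments
    segs: list[list[int]] = []
    for qp, gp in anchors:
        d = gp - qp
        if segs and segs[-1][2] == d and qp >= segs[-1][0]:
            segs[-1][1] = qp
        elif segs and abs(d - segs[-1][2]) < min_intron:
            return None  # small indel; rare for short reads, skip
        else:
            segs.append([qp, qp, d])
    if len(segs) > 3:
        return None
    contig, _ = index.contig_of(anchors[0][1])
    base = int(index.offsets[index._name_idx[contig]])
    clen = int(index.lengths[index._name_idx[contig]])
    cseq = index.contig_seq(contig)
    L = len(seq)
    blocks: list[tuple[int, int]] = []
    junctions: list[tuple[int, int]] = []
    mism = 0
    # read segment boundaries: split between consecutive diagonal segments
    qbounds = [0]
    gsegs = []
    for i, (q0, q1, d) in enumerate(segs):
        gsegs.append(d - base)
    for i in range(len(segs) - 1):
        qa = segs[i][1]      # last anchor start of left segment
        qb = segs[i + 1][0]  # first anchor start of right segment
        dl = gsegs[i]
        dr = gsegs[i + 1]
        if not 0 < dr - dl <= max_intron:
            return None
        # pad into the anchored flanks: an exact anchor can coincidentally
        # extend a base or two past the true exon boundary
        qa = max(qa - 6, qbounds[-1])
        qb = min(qb + 6, L)
        rseg = seq[qa:qb]
        # refine under both strand motif models and keep the cheaper
        # placement (canonical boundaries break ties)
        best = None
        for strand in ("+", "-"):
            j, mm_l, mm_r = _refine_splice(rseg, cseq, dl + qa, dr + qb,
                                           strand, 6)
            d_ = dl + qa + j
            a_ = dr + qa + j
            canonical = _junction_strand(cseq, d_, a_) != "."
            key = (mm_l + mm_r, not canonical)
            if best is None or key < best[0]:
                best = (key, qa + j, d_, a_)
        _, cut, donor, acceptor = best
        qbounds.append(cut)
        if acceptor - donor < min_intron:
            return None
        junctions.append((donor, acceptor))
    qbounds.append(L)
    gcodes = index._codes
    mism_vecs = []
    for i, d in enumerate(gsegs):
        qs, qe = qbounds[i], qbounds[i + 1]
        gs, ge = d + qs, d + qe
        if gs < 0 or ge > clen:
            return None
        gw = gcodes[base + gs:base + ge]
        vec = gw != codes[qs:qe]
        mism_vecs.append(vec)
        mism += int(vec.sum())
        blocks.append((gs, ge))
    if mism <= max_mismatch:
        return ShortReadPlacement(contig=contig, blocks=blocks,
                                  junctions=junctions, mismatches=mism)
    if len(blocks) == 1:
        # soft-clip: a read hanging over an unmodelled junction mismatches
        # only in its overhang; keep the clean side
        vec = mism_vecs[0]
        pos = np.nonzero(vec)[0]
        keep_left = int(pos[max_mismatch]) if len(pos) > max_mismatch \
            else len(vec)
        keep_right = len(vec) - int(pos[-(max_mismatch + 1)]) - 1 \
            if len(pos) > max_mismatch else len(vec)
        if keep_left >= keep_right:
            kept, clip = keep_left, len(vec) - keep_left
            nb = (blocks[0][0], blocks[0][0] + kept)
            m = int(vec[:kept].sum())
        else:
            kept, clip = keep_right, len(vec) - keep_right
            nb = (blocks[0][1] - kept, blocks[0][1])
            m = int(vec[len(vec) - kept:].sum())
        if kept >= 45 and m <= max_mismatch:
            return ShortReadPlacement(contig=contig, blocks=[nb],
                                      junctions=[], mismatches=m,
                                      clipped=clip)
    return None


def map_short_reads(reads, index: GenomeIndex, stage: str = "S1",
                    sample_stride: int = 10,
                    max_mismatch: int = 6, min_intron: int = 40,
                    max_intron: int = 6000, max_hits: int = 50,
                    coverage: dict[str, np.ndarray] | None = None
                    ) -> StageAlignments:
    """Place a short-read library on the draft genome.

    Junction support, exonic coverage and gene-level counting all use
    uniquely placed reads only: a read tied between near-identical loci
    cannot tell which copy is transcribed.
    ``coverage`` (per-contig boolean masks) is updated in place when given.
    """
    out = StageAlignments(stage=stage)
    k = index.k
    sep = "N" * k
    chunk = 20000
    # batched hashing + index lookups, both orientations per chunk
    for c0 in range(0, len(reads), chunk):
        batch = reads[c0:c0 + chunk]
        per_orient = []
        for oriented in (0, 1):
            joined = sep.join(r.sequence if oriented == 0
                              else revcomp(r.sequence) for r in batch)
            H = kmer_hashes(encode(joined), k)
            lo = np.searchsorted(index._sorted_hashes, H, side="left")
            hi = np.searchsorted(index._sorted_hashes, H, side="right")
            per_orient.append((H, lo, hi))
        off = 0
        for rec in batch:
            n_kmers = max(0, len(rec.sequence) - k + 1)
            _place_read(rec, off, n_kmers, per_orient, index, out,
                        sample_stride, max_mismatch, min_intron,
                        max_intron, max_hits, coverage)
            off += len(rec.sequence) + k
    return out


def _place_read(rec, off0, n_kmers, per_orient, index, out, sample_stride,
                max_mismatch, min_intron, max_intron, max_hits,
                coverage) -> None:
    if True:
        out.n_reads += 1
        placements: list[ShortReadPlacement] = []
        for oriented, (H, LO, HI) in enumerate(per_orient):
            seq = rec.sequence if oriented == 0 else revcomp(rec.sequence)
            codes = encode(seq)
            if n_kmers <= 0:
                continue
            sel = np.arange(0, n_kmers, sample_stride)
            if sel[-1] != n_kmers - 1:
                sel = np.append(sel, n_kmers - 1)
            hsel = H[off0 + sel]
            lo = LO[off0 + sel]
            hi = HI[off0 + sel]
            counts = hi - lo
            keep = (hsel >= 0) & (counts > 0) & (counts <= max_hits)
            if not keep.any():
                continue
            qi_list = []
            gp_list = []
            for j in np.nonzero(keep)[0]:
                g = index._sorted_pos[lo[j]:hi[j]]
                qi_list.append(np.full(len(g), j, dtype=np.int64))
                gp_list.append(g)
            qi = np.concatenate(qi_list)
            gp = np.concatenate(gp_list)
            qpos = sel[qi]
            # cluster anchors into candidate placements by approximate
            # start, never across contig boundaries
            ci_arr = np.searchsorted(index.offsets, gp, side="right") - 1
            order = np.argsort(gp - qpos, kind="stable")
            groups: list[list[tuple[int, int]]] = []
            last_start = None
            last_ci = None
            for oi in order:
                start = int(gp[oi] - qpos[oi])
                ci = int(ci_arr[oi])
                if last_start is not None and ci == last_ci and \
                        0 <= start - last_start <= max_intron:
                    groups[-1].append((int(qpos[oi]), int(gp[oi])))
                else:
                    groups.append([(int(qpos[oi]), int(gp[oi]))])
                last_start = start
                last_ci = ci
            # both orientations are always evaluated: near-identical loci
            # can sit on either strand, and a perfect placement here does
            # not rule out an equally perfect one in the other orientation
            for grp in groups[:12]:
                pl = _try_place(seq, codes, index, grp, max_mismatch,
                                min_intron, max_intron)
                if pl is not None:
                    placements.append(pl)
        if not placements:
            out.n_unmapped += 1
            return
        # uniqueness is judged on mismatches alone: a clipped placement on
        # another (near-identical) locus that explains the read equally
        # well makes the read ambiguous evidence
        min_mism = min(p.mismatches for p in placements)
        ties = [p for p in placements if p.mismatches <= min_mism]
        ties.sort(key=lambda p: p.cost)
        # deduplicate identical placements found via different anchor groups
        seen = set()
        uniq_ties = []
        for p in ties:
            key = (p.contig, tuple(p.blocks))
            if key not in seen:
                seen.add(key)
                uniq_ties.append(p)
        ties = uniq_ties
        if len(ties) == 1:
            p = ties[0]
            out.n_unique += 1
            out.unique_placements.append(p)
            cseq = index.contig_seq(p.contig)
            for donor, acceptor in p.junctions:
                strand = _junction_strand(cseq, donor, acceptor)
                out.junction_support[(p.contig, donor, acceptor, strand)] += 1
            if coverage is not None:
                cov = coverage.get(p.contig)
                if cov is None:
                    cov = np.zeros(len(cseq), dtype=bool)
                    coverage[p.contig] = cov
                for s, e in p.blocks:
                    cov[s:e] = True
        else:
            out.n_multi += 1


def pooled_junction_support(stages: list[StageAlignments]) -> Counter:
    total: Counter = Counter()
    for st in stages:
        total.update(st.junction_support)
    return total
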