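"""From continuous long reads to corrected full-length non-chimeric reads.

Stages: (1) split each CLR at approximate SMRTbell-adapter hits into
subreads and orient them; (2) build a circular consensus (CCS) by per-column
majority vote over pairwise alignments against the longest subread
(single-subread CLRs pass through as "type II"); (3) keep only consensus
reads showing the full cDNA structure — 5' primer, poly(A) tail, 3' primer,
and no internal primer (non-chimeric); (4) polish residual errors by
pileup-majority over short-read alignments.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np

from .io_formats import SeqRecord
from .seq import (cigar_counts, decode, encode, find_all_matches, kmer_hashes,
                  parse_cigar, revcomp)


@dataclass
class FlncConfig:
    mini_length: int = 50
    read_score: float = 0.75
    min_complete_passes: int = 2
    min_predicted_accuracy: float = 0.0
    min_polya: int = 20                  # minimum number of A's in the tail
    polya_purity: float = 0.75           # min A fraction while extending
    primer_max_mismatch_frac: float = 0.2
    adapter_max_mismatch_frac: float = 0.2
    primer_search_window: int = 120      # primer must sit this close to an end
    internal_margin: int = 50            # interior primer hits => chimeric
    correction_min_depth: int = 3
    correction_kmer: int = 15
    correction_stride: int = 8
    correction_base_divergence: float = 0.005
    correction_budget_slack: float = 0.04
    correction_majority: float = 0.7     # supermajority for base changes
    correction_indel_majority: float = 0.4   # indel votes wobble +-1 position
    correction_max_candidates: int = 4
    correction_rounds: int = 2           # loose pass, then strict polish


@dataclass
class Subread:
    parent_id: str
    index: int
    sequence: str
    read_score: float


@dataclass
class ConsensusRead:
    id: str
    sequence: str
    n_passes: int
    predicted_accuracy: float
    type: str  # "I" (>=2 subreads) or "II" (single subread)


@dataclass
class FlncRead:
    id: str
    sequence: str
    polya_len: int
    had_5p_primer: bool = True
    had_3p_primer: bool = True
    source_type: str = "I"
    corrected: bool = False


@dataclass
class Rejection:
    id: str
    reason: str   # no_5p / no_3p / no_polya / chimeric / low_accuracy


def _read_score(qualities: np.ndarray | None, n: int) -> float:
    if qualities is None:
        return 1.0
    err = np.power(10.0, -qualities.astype(float) / 10.0)
    return float(1.0 - err.mean())


def split_subreads(clr: SeqRecord, adapter: str,
                   config: FlncConfig | None = None) -> list[Subread]:
    """Cut a CLR at approximate adapter occurrences and orient the pieces.

    Fragments shorter than ``mini_length`` or with read_score below the
    threshold are dropped; antisense passes are reverse-complemented onto
    the orientation of the first surviving fragment.
    """
    config = config or FlncConfig()
    max_ed = int(len(adapter) * config.adapter_max_mismatch_frac)
    hits = find_all_matches(clr.sequence, adapter, max_ed)
    cuts = [0]
    for s, e, _ in hits:
        cuts.extend([s, e])
    cuts.append(len(clr.sequence))
    frags: list[tuple[int, int]] = []
    for a, b in zip(cuts[::2], cuts[1::2]):
        if b - a > 0:
            frags.append((a, b))
    # a missed adapter leaves a doubled fragment: re-scan outliers with a
    # looser edit budget
    if len(frags) > 1:
        med = sorted(b - a for a, b in frags)[len(frags) // 2]
        loose = int(len(adapter) * 0.32)
        refrags: list[tuple[int, int]] = []
        for a, b in frags:
            if b - a > 1.6 * med:
                sub_hits = find_all_matches(clr.sequence[a:b], adapter,
                                            loose)
                pos = a
                for s, e, _ in sub_hits:
                    if a + s > pos:
                        refrags.append((pos, a + s))
                    pos = a + e
                if b > pos:
                    refrags.append((pos, b))
            else:
                refrags.append((a, b))
        frags = refrags
    kept: list[tuple[str, float]] = []
    for a, b in frags:
        seq = clr.sequence[a:b]
        if len(seq) < config.mini_length:
            continue
        q = clr.qualities[a:b] if clr.qualities is not None else None
        score = _read_score(q, len(seq))
        if score < config.read_score:
            continue
        kept.append((seq, score))
    if not kept:
        return []
    # orient everything against the longest fragment; the shorter sequence
    # goes in as the (whole-)query of an infix alignment so that partial
    # terminal passes orient reliably too
    anchor = max(kept, key=lambda t: len(t[0]))[0]
    out: list[Subread] = []
    for idx, (seq, score) in enumerate(kept):
        if seq is not anchor:
            short, long_ = (seq, anchor) if len(seq) <= len(anchor) \
                else (anchor, seq)
            mode = "HW" if len(short) < 0.9 * len(long_) else "NW"
            k = int(0.45 * len(long_)) + 10
            fwd = edlib.align(short, long_, mode=mode,
                              k=k)["editDistance"]
            rev = edlib.align(revcomp(short), long_, mode=mode,
                              k=k)["editDistance"]
            if rev < fwd and rev >= 0 or (fwd < 0 <= rev):
                seq = revcomp(seq)
        out.append(Subread(parent_id=clr.id, index=idx, sequence=seq,
                           read_score=score))
    return out


def _walk_cigar_votes(cigar: str, tpos0: int, qcodes: np.ndarray,
                      seq: str, R: int, max_ins: int,
                      insertions: dict[int, Counter]
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Collect (target_position, voted_code) pairs from one alignment.

    Deletions relative to the target vote code 4; short insertions are
    tallied separately per target position.  Returns concatenated index and
    code arrays for a single scatter-add.
    """
    idx_parts: list[np.ndarray] = []
    code_parts: list[np.ndarray] = []
    tpos = tpos0
    qpos = 0
    for n, op in parse_cigar(cigar):
        if op in "=XM":
            npos = min(n, R - tpos)
            if npos > 0:
                idx_parts.append(np.arange(tpos, tpos + npos))
                code_parts.append(qcodes[qpos:qpos + npos])
            tpos += n
            qpos += n
        elif op == "D":
            npos = min(n, R - tpos)
            if npos > 0:
                idx_parts.append(np.arange(tpos, tpos + npos))
                code_parts.append(np.full(npos, 4, dtype=np.uint8))
            tpos += n
        elif op == "I":
            if n <= max_ins:
                insertions[tpos][seq[qpos:qpos + n]] += 1
            qpos += n
    if not idx_parts:
        return np.empty(0, np.int64), np.empty(0, np.uint8)
    return np.concatenate(idx_parts), np.concatenate(code_parts)


def _assemble(winners: np.ndarray, insertions: dict[int, str]) -> str:
    """Sequence from per-position winning codes (4 = deleted) plus accepted
    insertions keyed by position."""
    if not insertions:
        return decode(winners[winners != 4])
    parts: list[str] = []
    prev = 0
    for pos in sorted(insertions):
        seg = winners[prev:pos]
        parts.append(decode(seg[seg != 4]))
        parts.append(insertions[pos])
        prev = pos
    seg = winners[prev:]
    parts.append(decode(seg[seg != 4]))
    return "".join(parts)


def _vote_consensus(ref: str, others: list[str]) -> str:
    """Majority-vote consensus of subreads against a reference subread.

    Substitutions and deletions are resolved per reference column; short
    insertions relative to the reference are applied when enough passes
    agree on the same inserted sequence.  Column ties go to the reference
    (the safest full-length subread).
    """
    n_total = 1 + len(others)
    ref_codes = encode(ref)
    R = len(ref_codes)
    votes = np.zeros((R, 5), dtype=np.float32)
    votes[np.arange(R), ref_codes] += 1.4  # tie-break toward the reference
    insertions: dict[int, Counter] = defaultdict(Counter)
    for sub in others:
        mode = "HW" if len(sub) < 0.8 * len(ref) else "NW"
        k = int(0.45 * max(len(sub), len(ref))) + 10
        res = edlib.align(sub, ref, mode=mode, task="path", k=k)
        if res["editDistance"] < 0 or not res["cigar"]:
            continue
        tpos = res["locations"][0][0] if mode == "HW" and res["locations"] \
            else 0
        if tpos is None:
            tpos = 0
        idx, codes = _walk_cigar_votes(res["cigar"], tpos, encode(sub),
                                       sub, R, 5, insertions)
        np.add.at(votes, (idx, codes), 1.0)
    winners = votes.argmax(axis=1).astype(np.uint8)
    accepted = {}
    for pos, ctr in insertions.items():
        s, c = ctr.most_common(1)[0]
        if c > n_total / 3 and c >= 2:
            accepted[pos] = s
    return _assemble(winners, accepted)


def build_ccs(subreads: list[Subread],
              config: FlncConfig | None = None
              ) -> ConsensusRead | None:
    """Consensus read from a CLR's subreads.

    With >= ``min_complete_passes`` subreads a majority-vote consensus is
    built; a single subread passes through as type II.  Returns None for an
    empty subread list or a consensus below ``min_predicted_accuracy``.
    """
    config = config or FlncConfig()
    if not subreads:
        return None
    rid = subreads[0].parent_id
    if len(subreads) < config.min_complete_passes:
        sub = subreads[0]
        return ConsensusRead(id=rid, sequence=sub.sequence, n_passes=1,
                             predicted_accuracy=sub.read_score, type="II")
    # the longest subread is the reference (partial terminal passes are
    # shorter; doubled fragments from missed adapters were re-split
    # upstream); anything still >25% longer is skipped as a leftover double
    by_len = sorted(subreads, key=lambda s: len(s.sequence))
    ref = by_len[-1]
    if len(by_len) >= 3 and \
            len(ref.sequence) > 1.6 * len(by_len[-2].sequence) and \
            len(by_len[-2].sequence) < 1.15 * len(by_len[-3].sequence):
        # two agreeing lengths below a single outlier: the outlier is
        # likely a surviving doubled fragment
        ref = by_len[-2]
    others = [s.sequence for s in subreads
              if s is not ref and len(s.sequence) <= 1.25 * len(ref.sequence)]
    cons = _vote_consensus(ref.sequence, others)
    idents = []
    for s in [ref.sequence] + others:
        a, b = (s, cons) if len(s) <= len(cons) else (cons, s)
        k = int(0.5 * len(a)) + 10
        d = edlib.align(a, b, mode="HW", k=k)["editDistance"]
        if d < 0:
            d = k
        idents.append(1.0 - d / max(1, min(len(s), len(cons))))
    acc = float(np.mean(idents))
    if acc < config.min_predicted_accuracy:
        return None
    return ConsensusRead(id=rid, sequence=cons, n_passes=len(subreads),
                         predicted_accuracy=acc, type="I")


def _find_polya(seq: str, end: int, purity: float) -> tuple[int, int]:
    """Scan left from ``end`` for a poly(A) tract; returns (start, n_A).

    Local-scoring scan: A scores +1, anything else scores
    ``-purity/(1-purity)`` (break-even at the configured A fraction), so
    isolated errors are absorbed but random cDNA sequence quickly
    terminates the tract; the tract start is the leftmost position
    achieving the maximum score.
    """
    penalty = purity / max(1e-9, 1.0 - purity)
    score = 0.0
    best_score = 0.0
    best_start, best_a = end, 0
    n_a = 0
    i = end - 1
    while i >= 0:
        if seq[i] == "A":
            score += 1
            n_a += 1
        else:
            score -= penalty
        if score >= best_score:
            best_score = score
            best_start = i
            best_a = n_a
        if score < best_score - 6:
            break
        i -= 1
    n_in_tract = sum(1 for c in seq[best_start:end] if c == "A")
    return best_start, n_in_tract


def classify_flnc(consensus: ConsensusRead, primer5: str, primer3: str,
                  config: FlncConfig | None = None
                  ) -> FlncRead | Rejection:
    """Full-length non-chimeric test: 5' primer + poly(A) + 3' primer, with
    no additional interior primer hit.  The returned read is sense-oriented
    and primer/poly(A)-trimmed."""
    config = config or FlncConfig()
    max5 = int(len(primer5) * config.primer_max_mismatch_frac)
    max3 = int(len(primer3) * config.primer_max_mismatch_frac)
    best = None
    for seq in (consensus.sequence, revcomp(consensus.sequence)):
        h5 = find_all_matches(seq, primer5, max5)
        h3 = find_all_matches(seq, primer3, max3)
        lead5 = [h for h in h5 if h[0] <= config.primer_search_window]
        tail3 = [h for h in h3
                 if h[1] >= len(seq) - config.primer_search_window]
        score = (1 if lead5 else 0) + (1 if tail3 else 0)
        if best is None or score > best[0]:
            best = (score, seq, h5, h3, lead5, tail3)
    _, seq, h5, h3, lead5, tail3 = best
    if not lead5:
        return Rejection(id=consensus.id, reason="no_5p")
    if not tail3:
        return Rejection(id=consensus.id, reason="no_3p")
    start = lead5[0][1]
    end3 = tail3[-1][0]
    polya_start, n_a = _find_polya(seq, end3, config.polya_purity)
    if n_a < config.min_polya:
        return Rejection(id=consensus.id, reason="no_polya")
    lo = start + config.internal_margin
    hi = polya_start - config.internal_margin
    for s, e, _ in h5 + h3:
        if s >= lo and e <= hi:
            return Rejection(id=consensus.id, reason="chimeric")
    return FlncRead(id=consensus.id, sequence=seq[start:polya_start],
                    polya_len=n_a, source_type=consensus.type)


# ----------------------------------------------------------------- polishing

class _FlncKmerIndex:
    def __init__(self, reads: list[FlncRead], k: int, stride: int = 2):
        self.k = k
        hashes = []
        ridx = []
        pos = []
        for i, r in enumerate(reads):
            h = kmer_hashes(encode(r.sequence), k)
            sel = np.arange(0, len(h), stride)
            keep = h[sel] >= 0
            sel = sel[keep]
            hashes.append(h[sel])
            ridx.append(np.full(len(sel), i, dtype=np.int32))
            pos.append(sel.astype(np.int32))
        h = np.concatenate(hashes) if hashes else np.empty(0, np.int64)
        self.ridx = np.concatenate(ridx) if ridx else np.empty(0, np.int32)
        self.pos = np.concatenate(pos) if pos else np.empty(0, np.int32)
        order = np.argsort(h, kind="stable")
        self.h = h[order]
        self.ridx = self.ridx[order]
        self.pos = self.pos[order]

    def candidates_from(self, lo: np.ndarray, hi: np.ndarray,
                        valid: np.ndarray, max_cand: int,
                        weights: np.ndarray | None = None
                        ) -> list[tuple[int, int]]:
        """Top (read_idx, diagonal) candidates from precomputed lookups.

        ``lo``/``hi`` are searchsorted bounds for every query k-mer (one
        per query position), ``valid`` masks k-mers containing non-ACGT.
        Every query k-mer participates: the indexed reads may carry >10%
        error, so matching k-mers are sparse and none can be spared.
        ``weights`` (expected clean-k-mer fraction per indexed read) makes
        the ranking fair between clean and error-rich reads, so that
        high-error reads still attract their share of placements.
        """
        sel = np.nonzero(valid)[0]
        if len(sel) == 0:
            return []
        lo = lo[sel]
        hi = hi[sel]
        counts = hi - lo
        keep = (counts > 0) & (counts <= 200)
        if not keep.any():
            return []
        l = lo[keep]
        c = counts[keep]
        qp = sel[keep]
        flat = np.repeat(l, c) + (np.arange(int(c.sum())) -
                                  np.repeat(np.cumsum(c) - c, c))
        ri = self.ridx[flat].astype(np.int64)
        dg = (self.pos[flat].astype(np.int64) -
              np.repeat(qp, c)) // 8
        key = ri * (1 << 22) + (dg + (1 << 20))
        uniq, cnt = np.unique(key, return_counts=True)
        best: dict[int, tuple[float, int]] = {}
        for k_, v in zip(uniq.tolist(), cnt.tolist()):
            if v < 2:
                continue
            r = k_ >> 22
            d = (k_ & ((1 << 22) - 1)) - (1 << 20)
            score = v / weights[r] if weights is not None else float(v)
            if r not in best or score > best[r][0]:
                best[r] = (score, d * 8)
        ranked = sorted(best.items(), key=lambda kv: -kv[1][0])[:max_cand]
        return [(r, d) for r, (v, d) in ranked]


def correct_with_short_reads(flnc_reads: list[FlncRead],
                             short_reads: list[SeqRecord],
                             config: FlncConfig | None = None,
                             templates: dict[str, str] | None = None,
                             error_estimates: dict[str, float] | None = None
                             ) -> tuple[list[FlncRead], dict]:
    """Pileup-majority polishing of FLNC reads with short reads.

    Each short read is seeded onto candidate FLNC reads (k-mer votes) and
    aligned; placements whose edit distance exceeds the read's expected
    divergence budget are discarded so that ~3%-diverged homoeologous reads
    do not cross-vote.  Positions with depth >= ``correction_min_depth``
    take the pileup majority (substitutions, deletions and short insertions).

    When ``templates`` maps read ids to their true cDNA, the report carries
    the mean alignment identity to the templates before and after.
    """
    config = config or FlncConfig()
    k = config.correction_kmer
    index = _FlncKmerIndex(flnc_reads, k, 1)
    L = [len(r.sequence) for r in flnc_reads]
    votes = [np.zeros((n, 5), dtype=np.int16) for n in L]
    insertions: list[dict[int, Counter]] = [defaultdict(Counter) for _ in L]
    budgets = []
    for r in flnc_reads:
        est_err = config.correction_base_divergence
        if error_estimates and r.id in error_estimates:
            est_err = max(est_err, error_estimates[r.id] +
                          config.correction_budget_slack)
        budgets.append(est_err)

    obs_dist = np.zeros(len(flnc_reads))
    obs_n = np.zeros(len(flnc_reads))
    kmer_weights = np.array(
        [max(0.05, (1.0 - b) ** config.correction_kmer) for b in budgets])

    def place(seq: str, lo: np.ndarray, hi: np.ndarray,
              valid: np.ndarray) -> int:
        cands = index.candidates_from(lo, hi, valid,
                                      config.correction_max_candidates,
                                      kmer_weights)
        hits = []
        for ri, dg in cands:
            target = flnc_reads[ri].sequence
            a = max(0, dg - 25)
            b = min(len(target), dg + len(seq) + 25)
            if b - a < len(seq) // 2:
                continue
            max_ed = int(len(seq) * budgets[ri]) + 2
            res = edlib.align(seq, target[a:b], mode="HW", task="path",
                              k=max_ed)
            if res["editDistance"] < 0 or not res["cigar"]:
                continue
            # excess = edits beyond what the target's own error explains;
            # a diverged (homoeologous) placement carries extra edits and
            # must not vote when a better-explained placement exists
            excess = res["editDistance"] - budgets[ri] * len(seq)
            hits.append((excess, ri, a, res))
        if not hits:
            return 0
        min_excess = min(h[0] for h in hits)
        placed = 0
        for excess, ri, a, res in hits:
            if excess > min_excess + 2.0:
                continue
            target = flnc_reads[ri].sequence
            tpos = a + res["locations"][0][0]
            obs_dist[ri] += res["editDistance"] / max(1, len(seq))
            obs_n[ri] += 1
            idx, vcodes = _walk_cigar_votes(res["cigar"], tpos, encode(seq),
                                            seq, len(target), 3,
                                            insertions[ri])
            np.add.at(votes[ri], (idx, vcodes), 1)
            placed += 1
        return placed

    # batch the k-mer hashing and index lookups over chunks of the library
    k = config.correction_kmer
    chunk = 20000
    sep = "N" * k
    for c0 in range(0, len(short_reads), chunk):
        batch = short_reads[c0:c0 + chunk]
        for oriented in (0, 1):
            if oriented == 0:
                joined = sep.join(r.sequence for r in batch)
                pending = list(range(len(batch)))
            else:
                if not pending:
                    break
                joined = sep.join(revcomp(batch[i].sequence)
                                  for i in pending)
            H = kmer_hashes(encode(joined), k)
            lo = np.searchsorted(index.h, H, side="left").astype(np.int64)
            hi = np.searchsorted(index.h, H, side="right").astype(np.int64)
            valid = H >= 0
            off = 0
            still = []
            idxs = pending if oriented else list(range(len(batch)))
            for bi in idxs:
                seq = batch[bi].sequence if oriented == 0 \
                    else revcomp(batch[bi].sequence)
                n_kmers = len(seq) - k + 1
                if n_kmers > 0:
                    ok = place(seq, lo[off:off + n_kmers],
                               hi[off:off + n_kmers],
                               valid[off:off + n_kmers])
                else:
                    ok = 0
                off += len(seq) + k   # next read's slice start
                if oriented == 0 and not ok:
                    still.append(bi)
            if oriented == 0:
                pending = still

    corrected: list[FlncRead] = []
    for ri, r in enumerate(flnc_reads):
        v = votes[ri]
        depth = v.sum(axis=1)
        touched = bool((depth >= config.correction_min_depth).any())
        if not touched:
            corrected.append(FlncRead(id=r.id, sequence=r.sequence,
                                      polya_len=r.polya_len,
                                      source_type=r.source_type,
                                      corrected=False))
            continue
        codes = encode(r.sequence)
        maj = config.correction_majority
        imaj = config.correction_indel_majority
        sub_winner = v[:, :4].argmax(axis=1).astype(np.uint8)
        sub_counts = v[:, :4].max(axis=1)
        use_sub = (depth >= config.correction_min_depth) & \
                  (sub_counts > maj * (depth - v[:, 4]))
        use_del = (depth >= config.correction_min_depth) & \
                  (v[:, 4] > imaj * depth)
        winners = np.where(use_sub, sub_winner, codes)
        winners[use_del] = 4
        accepted = {}
        for pos, ctr in insertions[ri].items():
            if pos >= len(depth):
                continue
            s, c = ctr.most_common(1)[0]
            if c >= config.correction_min_depth and c > imaj * depth[pos]:
                accepted[pos] = s
        corrected.append(FlncRead(id=r.id,
                                  sequence=_assemble(winners, accepted),
                                  polya_len=r.polya_len,
                                  source_type=r.source_type, corrected=True))

    report: dict = {"n_reads": len(flnc_reads),
                    "n_corrected": sum(1 for r in corrected if r.corrected),
                    "per_read_divergence": {
                        r.id: float(obs_dist[i] / obs_n[i])
                        for i, r in enumerate(flnc_reads) if obs_n[i]}}
    if templates:
        before, after = [], []
        for old, new in zip(flnc_reads, corrected):
            t = templates.get(old.id)
            if not t:
                continue
            d0 = edlib.align(old.sequence, t, mode="NW")["editDistance"]
            d1 = edlib.align(new.sequence, t, mode="NW")["editDistance"]
            before.append(1 - d0 / max(len(t), len(old.sequence)))
            after.append(1 - d1 / max(len(t), len(new.sequence)))
        if before:
            report["identity_before"] = float(np.mean(before)) * 100
            report["identity_after"] = float(np.mean(after)) * 100
    return corrected, report
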