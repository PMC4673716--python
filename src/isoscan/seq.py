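"""Low-level nucleotide-sequence utilities shared by the whole pipeline.

Sequences are plain upper-case strings over {A,C,G,T,N}; the numeric side
(2-bit codes, rolling k-mer hashes) is numpy-based so that seeding and
pileup operations stay vectorised.
"""
from __future__ import annotations

import re

import edlib
import numpy as np

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = {}


def _build_codon_table() -> None:
    from Bio.Seq import Seq

    bases = "TCAG"
    for a in bases:
        for b in bases:
            for c in bases:
                codon = a + b + c
                _CODON_TABLE[codon] = str(Seq(codon).translate())


def encode(seq: str) -> np.ndarray:
    """2-bit-encode a sequence (A=0,C=1,G=2,T=3, anything else=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling 2-bit hash of every k-mer; windows containing non-ACGT get -1.

    Returns an int64 array of length ``len(codes) - k + 1`` (empty when the
    sequence is shorter than k).
    """
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64)
    m = n - k + 1
    h = np.zeros(m, dtype=np.int64)
    for j in range(k):
        h = (h << 2) | codes[j:m + j].astype(np.int64)
    bad = (codes > 3).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    h[(cs[k:] - cs[:-k]) > 0] = -1
    return h


_CIG_RE = re.compile(r"(\d+)([=XIDM])")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIG_RE.findall(cigar)]


def cigar_counts(cigar: str) -> tuple[int, int, int, int]:
    """Return (matches, mismatches, insertions, deletions) of an extended CIGAR.

    Insertions/deletions are counted in bases and are relative to the query
    (I = base present in query only, D = base present in target only).
    """
    m = x = i = d = 0
    for n, op in parse_cigar(cigar):
        if op == "=":
            m += n
        elif op == "X":
            x += n
        elif op == "I":
            i += n
        elif op == "D":
            d += n
    return m, x, i, d


def align_path(query: str, target: str, mode: str = "NW") -> dict:
    """edlib alignment with extended-CIGAR path; raises on failure."""
    res = edlib.align(query, target, mode=mode, task="path")
    if res["editDistance"] < 0 or res["cigar"] is None:
        raise RuntimeError("alignment failed")
    return res


def identity_to(query: str, target: str) -> float:
    """Global alignment identity in [0,1]: matches / alignment columns."""
    if not query or not target:
        return 0.0
    res = align_path(query, target, mode="NW")
    m, x, i, d = cigar_counts(res["cigar"])
    cols = m + x + i + d
    return m / cols if cols else 0.0


def find_all_matches(seq: str, pattern: str, max_edits: int) -> list[tuple[int, int, int]]:
    """All non-overlapping approximate occurrences of ``pattern`` in ``seq``.

    Iteratively takes the best edlib infix hit and masks it out, until no hit
    with edit distance <= max_edits remains.  Returns (start, end, edits)
    tuples sorted by start; end is exclusive.
    """
    hits: list[tuple[int, int, int]] = []
    work = bytearray(seq.encode("ascii"))
    while True:
        res = edlib.align(pattern, bytes(work).decode("ascii"), mode="HW",
                          task="locations", k=max_edits)
        if res["editDistance"] < 0 or not res["locations"]:
            break
        s, e = res["locations"][0]
        e += 1  # edlib end is inclusive
        hits.append((s, e, res["editDistance"]))
        work[s:e] = b"#" * (e - s)
    hits.sort()
    return hits


def translate(seq: str) -> str:
    """Translate in frame 0; ambiguous codons become 'X'."""
    if not _CODON_TABLE:
        _build_codon_table()
    aa = []
    for i in range(0, len(seq) - 2, 3):
        aa.append(_CODON_TABLE.get(seq[i:i + 3], "X"))
    return "".join(aa)


def find_longest_orf(seq: str) -> tuple[int, int] | None:
    """Longest ATG..stop ORF on the forward strand.

    Returns (start, end) half-open, end includes the stop codon; None when no
    complete ORF exists.
    """
    best: tuple[int, int] | None = None
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                if best is None or (i + 3 - start) > (best[1] - best[0]):
                    best = (start, i + 3)
                start = None
    return best
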