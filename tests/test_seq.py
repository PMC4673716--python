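import numpy as np
import pytest

from isoscan.seq import (cigar_counts, encode, find_all_matches,
                         find_longest_orf, kmer_hashes, revcomp, translate)


def test_revcomp_involution():
    s = "ACGTTGCANN"
    assert revcomp(revcomp(s)) == s
    assert revcomp("ACGT") == "ACGT"
    assert revcomp("AAGG") == "CCTT"


def test_kmer_hashes_match_exact_kmers(rng):
    seq = "".join(rng.choice(list("ACGT"), 60))
    h = kmer_hashes(encode(seq), 5)
    # identical k-mers hash identically, different ones differ
    kmers = [seq[i:i + 5] for i in range(len(seq) - 4)]
    for i, a in enumerate(kmers):
        for j, b in enumerate(kmers):
            assert (h[i] == h[j]) == (a == b)


def test_kmer_hashes_flag_ambiguous_windows():
    h = kmer_hashes(encode("ACGTNACGTACGT"), 4)
    assert (h[1:5] == -1).all()
    assert h[0] >= 0 and (h[5:] >= 0).all()


def test_cigar_counts():
    assert cigar_counts("10=2X3I1D") == (10, 2, 3, 1)


def test_find_all_matches_locates_every_occurrence():
    seq = "TTTT" + "ACGTACGTAC" + "GGGG" + "ACGTACGTAC" + "TT"
    hits = find_all_matches(seq, "ACGTACGTAC", 1)
    assert [(s, e) for s, e, _ in hits] == [(4, 14), (18, 28)]
    assert all(d == 0 for *_, d in hits)


def test_find_all_matches_tolerates_edits():
    pat = "ACGTACGTACGTACGT"
    seq = "TT" + pat[:7] + "A" + pat[8:] + "TTTT"  # one substitution
    hits = find_all_matches(seq, pat, 3)
    assert len(hits) == 1 and hits[0][2] <= 2


def test_find_longest_orf_and_translate():
    orf = "ATG" + "GCT" * 10 + "TAA"
    seq = "CCCC" + orf + "GGGG"
    span = find_longest_orf(seq)
    assert span == (4, 4 + len(orf))
    aa = translate(seq[span[0]:span[1]])
    assert aa == "M" + "A" * 10 + "*"


def test_find_longest_orf_none_without_stop():
    assert find_longest_orf("ATGGCTGCTGCT") is None
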