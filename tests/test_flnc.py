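import numpy as np
import pytest

from isoscan.flnc import (FlncConfig, FlncRead, Rejection, build_ccs,
                          classify_flnc, correct_with_short_reads,
                          split_subreads, Subread)
from isoscan.io_formats import SeqRecord
from isoscan.seq import revcomp
from isoscan.sim import (PRIMER_3P, PRIMER_5P, SMRTBELL_ADAPTER,
                         inject_errors, random_seq)

ADAPTER = SMRTBELL_ADAPTER


def _clr(insert, n_passes, quals=40):
    parts = []
    for p in range(n_passes):
        parts.append(insert if p % 2 == 0 else revcomp(insert))
        if p < n_passes - 1:
            parts.append(ADAPTER)
    seq = "".join(parts)
    return SeqRecord("clr", seq, np.full(len(seq), quals, dtype=np.int16))


def test_split_subreads_counts_passes(rng):
    insert = random_seq(rng, 800)
    subs = split_subreads(_clr(insert, 3), ADAPTER)
    assert len(subs) == 3
    # all oriented to a common strand
    assert all(s.sequence in (insert, ) for s in subs) or \
        all(s.sequence == revcomp(insert) for s in subs)


def test_split_subreads_drops_short_fragments(rng):
    insert = random_seq(rng, 40)  # below miniLength = 50
    subs = split_subreads(_clr(insert, 2), ADAPTER)
    assert subs == []


def test_split_subreads_drops_low_quality(rng):
    insert = random_seq(rng, 500)
    clr = _clr(insert, 2, quals=2)   # read_score ~0.37 < 0.75
    assert split_subreads(clr, ADAPTER) == []


def test_split_subreads_no_adapter_single_pass(rng):
    insert = random_seq(rng, 600)
    subs = split_subreads(_clr(insert, 1), ADAPTER)
    assert len(subs) == 1
    assert subs[0].sequence == insert


def _subs(seqs):
    return [Subread("x", i, s, 0.9) for i, s in enumerate(seqs)]


def test_ccs_identical_subreads(rng):
    s = random_seq(rng, 300)
    cons = build_ccs(_subs([s, s, s]))
    assert cons.sequence == s
    assert cons.n_passes == 3 and cons.type == "I"
    assert cons.predicted_accuracy == 1.0


def test_ccs_majority_vote_single_column(rng):
    s = random_seq(rng, 200)
    alt = ("A" if s[100] != "A" else "C")
    bad = s[:100] + alt + s[101:]
    cons = build_ccs(_subs([s, s, bad]))
    assert cons.sequence == s


def test_ccs_single_subread_passthrough(rng):
    s = random_seq(rng, 200)
    cons = build_ccs(_subs([s]))
    assert cons.type == "II" and cons.n_passes == 1
    assert cons.sequence == s


def test_ccs_beats_any_single_subread(rng):
    """Consensus of 5 noisy passes is closer to the template than any
    single pass (simulation over many templates)."""
    import edlib

    wins = 0
    n = 60
    for _ in range(n):
        t = random_seq(rng, 400)
        noisy = [inject_errors(t, 0.10, rng) for _ in range(5)]
        cons = build_ccs(_subs(noisy))
        d_cons = edlib.align(cons.sequence, t, mode="NW")["editDistance"]
        d_best = min(edlib.align(s, t, mode="NW")["editDistance"]
                     for s in noisy)
        wins += d_cons < d_best
    assert wins / n > 0.9


def _insert(cdna, polya=30):
    return PRIMER_5P + cdna + "A" * polya + PRIMER_3P


def _cons(seq):
    from isoscan.flnc import ConsensusRead

    return ConsensusRead(id="r", sequence=seq, n_passes=3,
                         predicted_accuracy=0.99, type="I")


def test_classify_flnc_perfect_structure(rng):
    cdna = random_seq(rng, 700)
    res = classify_flnc(_cons(_insert(cdna, polya=30)),
                        PRIMER_5P, PRIMER_3P)
    assert isinstance(res, FlncRead)
    assert res.sequence == cdna
    assert 25 <= res.polya_len <= 33  # trailing cDNA A's may be absorbed


def test_classify_flnc_antisense_input_is_oriented(rng):
    cdna = random_seq(rng, 700)
    res = classify_flnc(_cons(revcomp(_insert(cdna))),
                        PRIMER_5P, PRIMER_3P)
    assert isinstance(res, FlncRead)
    assert res.sequence == cdna


def test_classify_flnc_missing_polya(rng):
    cdna = random_seq(rng, 700)
    res = classify_flnc(_cons(PRIMER_5P + cdna + PRIMER_3P),
                        PRIMER_5P, PRIMER_3P)
    assert isinstance(res, Rejection) and res.reason == "no_polya"


def test_classify_flnc_missing_primers(rng):
    cdna = random_seq(rng, 700)
    res = classify_flnc(_cons(cdna + "A" * 30 + PRIMER_3P),
                        PRIMER_5P, PRIMER_3P)
    assert isinstance(res, Rejection) and res.reason == "no_5p"
    res = classify_flnc(_cons(PRIMER_5P + cdna + "A" * 30),
                        PRIMER_5P, PRIMER_3P)
    assert isinstance(res, Rejection) and res.reason == "no_3p"


def test_classify_flnc_internal_primer_is_chimeric(rng):
    a = random_seq(rng, 400)
    b = random_seq(rng, 500)
    chimera = _insert(a) + _insert(b)
    res = classify_flnc(_cons(chimera), PRIMER_5P, PRIMER_3P)
    assert isinstance(res, Rejection) and res.reason == "chimeric"


def _flnc(seq, rid="f0"):
    return FlncRead(id=rid, sequence=seq, polya_len=30)


def _tile(seq, rl=101, stride=10):
    return [SeqRecord(f"s{i}", seq[i:i + rl])
            for i in range(0, len(seq) - rl + 1, stride)]


def test_correction_fixes_planted_error(rng):
    t = random_seq(rng, 400)
    bad = t[:200] + ("A" if t[200] != "A" else "C") + t[201:]
    corrected, _ = correct_with_short_reads([_flnc(bad)], _tile(t))
    assert corrected[0].sequence == t
    assert corrected[0].corrected


def test_correction_depth_threshold(rng):
    t = random_seq(rng, 400)
    bad = t[:200] + ("A" if t[200] != "A" else "C") + t[201:]
    # only 2 reads over the error site with min depth 3
    reads = [SeqRecord("a", t[150:251]), SeqRecord("b", t[160:261])]
    corrected, _ = correct_with_short_reads([_flnc(bad)], reads)
    assert corrected[0].sequence == bad


def test_correction_no_coverage_passthrough(rng):
    t = random_seq(rng, 300)
    corrected, rep = correct_with_short_reads([_flnc(t)], [])
    assert corrected[0].sequence == t
    assert not corrected[0].corrected


def test_correction_improves_identity_directionally(rng):
    """At 12% raw error and deep short-read tiling, mean identity to the
    template increases after correction."""
    templates = {}
    reads = []
    shorts = []
    for i in range(8):
        t = random_seq(rng, 500)
        rid = f"f{i}"
        templates[rid] = t
        reads.append(FlncRead(id=rid, sequence=inject_errors(t, 0.12, rng),
                              polya_len=30))
        shorts.extend(_tile(t, stride=4))
    est = {r.id: 0.13 for r in reads}
    corrected, rep = correct_with_short_reads(
        reads, shorts, templates=templates, error_estimates=est)
    assert rep["identity_after"] > rep["identity_before"]
    assert rep["identity_after"] > 97.0
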