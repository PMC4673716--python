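from collections import Counter

import numpy as np
import pytest

from isoscan.classify import (ClassifyThresholds, classify_read_groups,
                              extract_junctions, g2_pattern_analysis,
                              validate_junctions, GroupAssignment)
from isoscan.io_formats import JunctionRecord
from isoscan.mapping import AlignmentSet, SplicedAlignment
from isoscan.sim import random_seq


def _aln(cov, ident, contig="c1", start=0, strand="+", read_length=1000):
    aligned = int(read_length * cov / 100)
    m = int(aligned * ident / 100)
    return SplicedAlignment(read_id="r", contig=contig, strand=strand,
                            blocks=[(0, aligned, start, start + aligned)],
                            matches=m, mismatches=aligned - m, indels=0,
                            read_length=read_length)


def _classify_one(alignments, strand="+"):
    sets = {"r": AlignmentSet("r", list(alignments))}
    out = classify_read_groups(sets, {"r": strand})
    assert len(out) == 1
    return out[0]


@pytest.mark.parametrize("alignments,expected", [
    ([_aln(95, 96)], "G1"),
    ([_aln(92, 94), _aln(92, 94, "c2", 5000)], "G2"),
    ([], "G5"),
    ([_aln(45, 95), _aln(40, 95, "c2", 5000)], "G3"),
    ([_aln(40, 70)], "G4"),
    ([_aln(20, 95)], "G5"),          # coverage below every band
    ([_aln(95, 96), _aln(60, 80, "c2", 5000)], "G1"),  # clear best wins
])
def test_cascade_examples(alignments, expected):
    assert _classify_one(alignments).group == expected


def test_unresolved_strand_is_set_aside():
    assert _classify_one([_aln(95, 96)], strand="?").group == "UNDETERMINED"


def test_g2_requires_both_metrics_in_and_mode():
    # two best-tied alignments but coverage < 90: falls through the cascade
    a = _classify_one([_aln(85, 95), _aln(85, 95, "c2", 5000)])
    assert a.group == "G4"
    # OR-mode accepts the same pair as G2
    sets = {"r": AlignmentSet("r", [_aln(85, 95),
                                    _aln(85, 95, "c2", 5000)])}
    out = classify_read_groups(sets, {"r": "+"},
                               ClassifyThresholds(g2_mode="or"))
    assert out[0].group == "G2"


def test_partition_and_order_independence(rng):
    """Every read lands in exactly one group, independent of input order."""
    sets = {}
    for i in range(120):
        n = int(rng.integers(0, 4))
        alns = []
        for j in range(n):
            cov = float(rng.uniform(10, 100))
            ident = float(rng.uniform(35, 100))
            alns.append(_aln(cov, ident, contig=f"c{j}", start=j * 4000))
        sets[f"r{i:03d}"] = AlignmentSet(f"r{i:03d}", alns)
    strands = {rid: "+" for rid in sets}
    out1 = classify_read_groups(sets, strands)
    assert len(out1) == len(sets)
    counts = Counter(a.group for a in out1)
    assert sum(counts.values()) == len(sets)
    shuffled = dict(reversed(list(sets.items())))
    out2 = classify_read_groups(shuffled, strands)
    assert {a.read_id: a.group for a in out1} == \
        {a.read_id: a.group for a in out2}


SUBMAP = {"c_a": "A", "c_a2": "A", "c_b": "B", "c_d": "D"}


def _g2(alignments):
    return GroupAssignment("r", "G2", list(alignments))


def test_g2_patterns():
    one_best = _g2([_aln(95, 95, "c_a"), _aln(95, 95, "c_d")])
    within = _g2([_aln(95, 95, "c_b"), _aln(95, 95, "c_b", 6000),
                  _aln(95, 95, "c_b", 12000)])
    across = _g2([_aln(95, 95, "c_a"), _aln(95, 95, "c_a2"),
                  _aln(95, 95, "c_d")])
    pats = g2_pattern_analysis([one_best, within, across], SUBMAP)
    assert [p.pattern for p in pats] == [
        "ONE_BEST_PER_SUBGENOME", "MULTI_WITHIN_ONE_SUBGENOME",
        "MULTI_ACROSS_SUBGENOMES"]


def test_g2_pattern_unknown_subgenome_flagged():
    pats = g2_pattern_analysis(
        [_g2([_aln(95, 95, "weird"), _aln(95, 95, "odd", 9000)])],
        {}.get)
    assert pats[0].pattern == "UNKNOWN_SUBGENOME"


def _genome_with_intron(rng, motif=("GT", "AG")):
    e1, e2 = random_seq(rng, 120), random_seq(rng, 130)
    intron = motif[0] + random_seq(rng, 96) + motif[1]
    genome = {"c1": e1 + intron + e2}
    aln = SplicedAlignment(
        read_id="r", contig="c1", strand="+",
        blocks=[(0, 120, 0, 120), (120, 250, 220, 350)],
        matches=250, mismatches=0, indels=0, read_length=250)
    return genome, aln


def test_extract_junctions_forward_motif(rng):
    genome, aln = _genome_with_intron(rng)
    recs = extract_junctions(aln, genome)
    assert len(recs) == 1
    assert recs[0].motif == "GT-AG"
    assert (recs[0].donor_pos, recs[0].acceptor_pos) == (120, 220)


def test_extract_junctions_minus_strand_adjusted(rng):
    genome, aln = _genome_with_intron(rng, motif=("CT", "AC"))
    aln.strand = "-"
    recs = extract_junctions(aln, genome)
    assert recs[0].motif == "GT-AG"


def test_extract_junctions_noncanonical_is_other(rng):
    genome, aln = _genome_with_intron(rng, motif=("TT", "AG"))
    assert extract_junctions(aln, genome)[0].motif == "other"


def test_extract_junctions_skips_small_gaps(rng):
    genome, aln = _genome_with_intron(rng)
    aln.blocks = [(0, 120, 0, 120), (120, 250, 140, 270)]  # 20 bp gap
    assert extract_junctions(aln, genome) == []


def test_validate_junctions_exact_match_rule():
    j1 = JunctionRecord("c1", 100, 200, "+", motif="GT-AG")
    j2 = JunctionRecord("c1", 101, 200, "+", motif="GT-AG")  # off by one
    support = {("c1", 100, 200, "+"): 5}
    rep = validate_junctions([j1, j2], support)
    assert rep.n_junctions == 2
    assert rep.n_supported == 1
    assert rep.motif_counts == {"GT-AG": 2}


def test_validate_junctions_occurrence_weighting():
    j = JunctionRecord("c1", 100, 200, "+", motif="GT-AG")
    rep = validate_junctions([j, j, j], {("c1", 100, 200, "+"): 1})
    assert rep.n_junctions == 3 and rep.n_supported == 3
    assert rep.n_unique == 1 and rep.n_unique_supported == 1
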