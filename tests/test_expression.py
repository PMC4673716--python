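from collections import Counter

import pytest

from isoscan.expression import (GeneDef, IsoformPresence, compute_rpkm,
                                call_expressed_genes, count_exon_reads,
                                differential_isoform_table,
                                isoform_presence, specific_junctions)
from isoscan.isoforms import TranscriptIsoform
from isoscan.shortread import ShortReadPlacement, StageAlignments


def test_rpkm_formula():
    r = compute_rpkm("g", "S1", 1000, 10_000_000, 2000)
    assert r.rpkm == 50.0


def test_rpkm_zero_reads():
    assert compute_rpkm("g", "S1", 0, 1_000_000, 1000).rpkm == 0.0


def test_rpkm_exactly_one_not_expressed():
    r = compute_rpkm("g", "S1", 1, 1_000_000, 1000)
    assert r.rpkm == 1.0
    assert not r.expressed          # strict > 1 rule
    assert compute_rpkm("g", "S1", 2, 1_000_000, 1000).expressed


def test_rpkm_zero_exon_length_errors():
    with pytest.raises(ValueError):
        compute_rpkm("g", "S1", 10, 1_000_000, 0)


def test_rpkm_linear_in_reads():
    a = compute_rpkm("g", "S1", 500, 5_000_000, 1500).rpkm
    b = compute_rpkm("g", "S1", 1000, 5_000_000, 1500).rpkm
    assert b == 2 * a


def _stage(placements, stage="S1", junctions=None):
    sa = StageAlignments(stage=stage)
    sa.unique_placements = placements
    sa.n_unique = len(placements)
    sa.n_reads = len(placements)
    if junctions:
        sa.junction_support = Counter(junctions)
    return sa


def _pl(contig, s, e):
    return ShortReadPlacement(contig=contig, blocks=[(s, e)],
                              junctions=[], mismatches=0)


def test_count_exon_reads_unique_overlap_only():
    genes = [GeneDef("g1", "c1", [(0, 500)]),
             GeneDef("g2", "c1", [(400, 900)])]
    placements = [_pl("c1", 10, 111),     # g1 only
                  _pl("c1", 450, 480),    # overlaps both -> neither
                  _pl("c1", 700, 801),    # g2 only
                  _pl("c1", 2000, 2101)]  # intergenic
    counts, assigned, unassigned = count_exon_reads(_stage(placements),
                                                    genes)
    assert counts == {"g1": 1, "g2": 1}
    assert assigned == 2 and unassigned == 2
    assert assigned + unassigned == len(placements)


def test_call_expressed_per_stage():
    recs = [compute_rpkm("g1", "S1", 100, 1_000_000, 1000),
            compute_rpkm("g1", "S2", 0, 1_000_000, 1000),
            compute_rpkm("g2", "S1", 1, 1_000_000, 1000)]
    sets = call_expressed_genes(recs)
    assert sets["S1"] == {"g1"}
    assert "S2" not in sets or sets["S2"] == set()


def _iso(tid, locus, chain, support=5):
    return TranscriptIsoform(
        transcript_id=tid, locus_id=locus, contig="c1", strand="+",
        junction_chain=chain, exons=[(0, 100)], span=(0, 1000),
        length_bp=1000, status="KNOWN", representative_read="r",
        n_supporting_reads=support)


def test_specific_junctions():
    a = _iso("a", "L", ((100, 200), (300, 400)))
    b = _iso("b", "L", ((100, 200), (350, 400)))
    spec = specific_junctions([a, b])
    assert spec["a"] == ((300, 400),)
    assert spec["b"] == ((350, 400),)


def test_isoform_presence_and_unresolvable():
    a = _iso("a", "L", ((100, 200), (300, 400)), support=10)
    b = _iso("b", "L", ((100, 200), (350, 400)), support=4)
    twins = [_iso("x", "M", ((10, 20),)), _iso("y", "M", ((10, 20),))]
    st1 = _stage([], "S1", {("c1", 300, 400, "+"): 3})
    st2 = _stage([], "S2", {("c1", 350, 400, "+"): 1})
    pres = isoform_presence([a, b] + twins, [st1, st2])
    tab = {(p.transcript_id, p.stage): p for p in pres}
    assert tab[("a", "S1")].present and not tab[("a", "S2")].present
    assert not tab[("b", "S1")].present and tab[("b", "S2")].present
    assert not tab[("x", "S1")].resolvable
    assert not tab[("y", "S2")].resolvable


def test_presence_monotone_in_depth():
    a = _iso("a", "L", ((100, 200),))
    st = _stage([], "S1", {("c1", 100, 200, "+"): 1})
    p1 = isoform_presence([a], [st])[0]
    st.junction_support[("c1", 100, 200, "+")] += 10
    p2 = isoform_presence([a], [st])[0]
    assert p2.present >= p1.present


def test_differential_table_and_labels():
    a = _iso("a", "L", ((100, 200), (300, 400)), support=10)
    b = _iso("b", "L", ((100, 200), (350, 400)), support=4)
    stages = ["S1", "S2", "S3", "S4"]
    sts = []
    for i, st in enumerate(stages):
        support = {("c1", 300, 400, "+"): 1} if i < 3 else {}
        support[("c1", 350, 400, "+")] = 1
        sts.append(_stage([], st, support))
    pres = isoform_presence([a, b], sts)
    diff = differential_isoform_table(pres, [a, b], stages)
    assert len(diff) == 1
    g = diff[0]
    assert g.isoform_labels == {"a": "a", "b": "b"}  # by support order
    assert g.presence["a"] == (True, True, True, False)
    assert g.presence["b"] == (True, True, True, True)


def test_constant_presence_not_differential():
    a = _iso("a", "L", ((100, 200),))
    stages = ["S1", "S2"]
    sts = [_stage([], s, {("c1", 100, 200, "+"): 2}) for s in stages]
    pres = isoform_presence([a], sts)
    assert differential_isoform_table(pres, [a], stages) == []
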