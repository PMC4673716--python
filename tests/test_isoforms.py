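import pytest

from isoscan.annotation import LocusCluster
from isoscan.io_formats import GeneModel
from isoscan.isoforms import (collapse_isoforms, locus_support_histogram,
                              transcript_length_stats)
from isoscan.mapping import SplicedAlignment


def _aln(rid, blocks, contig="c1", strand="+"):
    rl = sum(e - s for s, e, *_ in blocks)
    return SplicedAlignment(read_id=rid, contig=contig, strand=strand,
                            blocks=blocks, matches=rl, mismatches=0,
                            indels=0, read_length=rl)


def _cluster(reads, status="EXTANT", gene_ids=()):
    return LocusCluster(locus_id="L1", contig="c1", strand="+",
                        span=(0, 1000), status=status,
                        gene_ids=list(gene_ids),
                        supporting_reads=list(reads))


CHAIN = ((100, 200), (300, 400), (500, 600))


def _reads_with_chain():
    # same 3-junction chain, different 5' starts
    a = _aln("a", [(0, 100, 0, 100), (100, 200, 200, 300),
                   (200, 300, 400, 500), (300, 400, 600, 700)])
    b = _aln("b", [(0, 60, 40, 100), (60, 160, 200, 300),
                   (160, 260, 400, 500), (260, 360, 600, 700)])
    chains = {"a": CHAIN, "b": CHAIN}
    return {"a": a, "b": b}, chains


def test_same_chain_different_ends_collapse_to_one():
    reads, chains = _reads_with_chain()
    isos = collapse_isoforms([_cluster(reads)], reads, chains, [])
    assert len(isos) == 1
    assert isos[0].n_supporting_reads == 2
    assert isos[0].representative_read == "a"   # the longest read


def test_chain_differing_at_one_acceptor_stays_separate():
    reads, chains = _reads_with_chain()
    chains = dict(chains)
    chains["b"] = ((100, 204), (300, 400), (500, 600))
    isos = collapse_isoforms([_cluster(reads)], reads, chains, [])
    assert len(isos) == 2


def test_single_exon_reads_collapse_per_locus():
    reads = {f"r{i}": _aln(f"r{i}", [(0, 300, 50 * i, 50 * i + 300)])
             for i in range(5)}
    isos = collapse_isoforms([_cluster(reads)], reads,
                             {r: () for r in reads}, [])
    assert len(isos) == 1
    assert isos[0].n_supporting_reads == 5


def test_status_known_requires_exact_chain_match():
    reads, chains = _reads_with_chain()
    gm = GeneModel("g1", "c1", "+", [(0, 100), (200, 300), (400, 500),
                                     (600, 700)],
                   transcripts={"g1.t1": [(0, 100), (200, 300),
                                          (400, 500), (600, 700)]})
    isos = collapse_isoforms([_cluster(reads, gene_ids=["g1"])],
                             reads, chains, [gm])
    assert isos[0].status == "KNOWN"
    # a different chain at the same locus is novel-at-known-locus
    chains["a"] = chains["b"] = ((100, 200), (300, 400))
    isos = collapse_isoforms([_cluster(reads, gene_ids=["g1"])],
                             reads, chains, [gm])
    assert isos[0].status == "NOVEL_AT_KNOWN_LOCUS"


def test_status_novel_locus():
    reads, chains = _reads_with_chain()
    isos = collapse_isoforms([_cluster(reads, status="NOVEL")],
                             reads, chains, [])
    assert all(i.status == "NOVEL_LOCUS" for i in isos)


def test_support_conservation_and_idempotence(tiny_result):
    res = tiny_result
    total = sum(i.n_supporting_reads for i in res.isoforms)
    assert total == len(res.hq.kept)
    # collapsing the representatives reproduces the same chain set
    reps = {i.representative_read for i in res.isoforms}
    rep_alns = {r: a for r, a in
                ((i.representative_read,
                  None) for i in res.isoforms)}
    chains_before = sorted((i.locus_id, i.junction_chain)
                           for i in res.isoforms)
    # rebuild using only representative reads
    from isoscan.annotation import assign_loci
    from isoscan.isoforms import collapse_isoforms as collapse

    g1 = {a.read_id: a.evidence[0] for a in res.assignments
          if a.group == "G1"}
    rep_alns = {r: g1[r] for r in reps}
    clusters = assign_loci(rep_alns, res.sim.gene_models)
    isos2 = collapse(clusters, rep_alns, res.junction_chains,
                     res.sim.gene_models)
    chains_after = sorted((i.junction_chain) for i in isos2)
    assert sorted(i.junction_chain for i in res.isoforms) == chains_after


def test_length_stats():
    out = transcript_length_stats([575, 4537, 2187], [671, 4105])
    assert out["novel"]["min"] == 575
    assert out["novel"]["max"] == 4537
    assert out["known"]["mean"] == 2388
    assert out["mean_difference"] == 2433 - 2388
    with pytest.raises(ValueError):
        transcript_length_stats([], [1])


def test_length_stats_single_element():
    out = transcript_length_stats([100], [100])
    assert out["novel"]["mean"] == 100


def test_locus_support_histogram_edges():
    out = locus_support_histogram([3, 5, 7, 150])
    assert out["bins"] == {"2-10": 3, "11-100": 0, ">100": 1}
    assert out["percent"]["2-10"] == 75.0
    out = locus_support_histogram([10, 2, 2])
    assert out["bins"]["2-10"] == 3  # inclusive upper edge
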