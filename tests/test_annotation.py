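from collections import Counter

import numpy as np
import pytest

from isoscan.annotation import (BridgeRecord, LocusCluster, _cluster_reads,
                                assign_loci, detect_contig_bridges,
                                detect_spanning_transcripts,
                                estimate_orf_completeness,
                                filter_high_quality,
                                locus_read_support_histogram,
                                rescue_unmapped)
from isoscan.io_formats import GeneModel, SeqRecord
from isoscan.mapping import SplicedAlignment
from isoscan.sim import mutate_substitutions, random_seq


def _aln(rid, blocks, contig="c1", strand="+", read_length=None,
         matches=None):
    rl = read_length or sum(e - s for s, e, *_ in blocks)
    m = matches if matches is not None else rl
    return SplicedAlignment(read_id=rid, contig=contig, strand=strand,
                            blocks=blocks, matches=m, mismatches=0,
                            indels=0, read_length=rl)


def _simple(rid, gstart, gend, contig="c1", strand="+"):
    n = gend - gstart
    return _aln(rid, [(0, n, gstart, gend)], contig, strand)


# ------------------------------------------------------------- hq filtering

def test_truncated_suffix_chain_removed():
    # full read with 3 junctions, truncated read with the last 2 only
    full = _aln("full", [(0, 100, 0, 100), (100, 200, 200, 300),
                         (200, 300, 400, 500), (300, 400, 600, 700)])
    trunc = _aln("tr", [(0, 80, 220, 300), (80, 180, 400, 500),
                        (180, 280, 600, 700)])
    chains = {"full": ((100, 200), (300, 400), (500, 600)),
              "tr": ((300, 400), (500, 600))}
    support = {("c1", d, a, "+"): 3 for d, a in chains["full"]}
    res = filter_high_quality({"full": full, "tr": trunc}, chains, support)
    assert res.removed_5prime_truncated == ["tr"]
    assert res.kept == ["full"]


def test_supported_unique_chain_kept():
    a = _aln("a", [(0, 100, 0, 100), (100, 200, 200, 300)])
    chains = {"a": ((100, 200),)}
    res = filter_high_quality({"a": a}, chains,
                              {("c1", 100, 200, "+"): 2})
    assert res.kept == ["a"]


def test_unsupported_singleton_removed():
    a = _aln("a", [(0, 100, 0, 100), (100, 200, 200, 300)])
    res = filter_high_quality({"a": a}, {"a": ((100, 200),)}, {})
    assert res.removed_unsupported_singletons == ["a"]


def test_single_exon_singleton_needs_coverage():
    a = _simple("a", 50, 400)
    masks = {"c1": np.zeros(1000, dtype=bool)}
    res = filter_high_quality({"a": a}, {"a": ()}, {}, masks)
    assert res.removed_unsupported_singletons == ["a"]
    masks["c1"][100:150] = True
    res = filter_high_quality({"a": a}, {"a": ()}, {}, masks)
    assert res.kept == ["a"]


# ------------------------------------------------------------ locus clusters

def _models():
    return [GeneModel("g1", "c1", "+", [(100, 300), (500, 700)]),
            GeneModel("g2", "c2", "+", [(0, 500)])]


def test_assign_loci_extant_and_support():
    reads = {f"r{i}": _simple(f"r{i}", 120 + i * 10, 650) for i in range(3)}
    clusters = assign_loci(reads, _models())
    assert len(clusters) == 1
    c = clusters[0]
    assert c.status == "EXTANT" and c.gene_id == "g1"
    assert c.n_reads == 3


def test_assign_loci_novel_on_model_free_contig():
    reads = {"a": _simple("a", 100, 500, contig="c9"),
             "b": _simple("b", 300, 700, contig="c9")}
    clusters = assign_loci(reads, _models())
    assert len(clusters) == 1
    assert clusters[0].status == "NOVEL"
    assert not clusters[0].contig_has_other_models


def test_assign_loci_novel_on_contig_with_other_models():
    reads = {"a": _simple("a", 5000, 5600)}
    clusters = assign_loci(reads, _models())
    assert clusters[0].status == "NOVEL"
    assert clusters[0].contig_has_other_models


def test_assign_loci_strand_separates_clusters():
    reads = {"a": _simple("a", 100, 400, strand="+"),
             "b": _simple("b", 100, 400, strand="-")}
    clusters = assign_loci(reads, [])
    assert len(clusters) == 2


def test_assign_loci_order_independent_and_idempotent():
    reads = {f"r{i}": _simple(f"r{i}", 100 + 50 * i, 400 + 50 * i)
             for i in range(6)}
    c1 = assign_loci(reads, _models())
    c2 = assign_loci(dict(reversed(list(reads.items()))), _models())
    key = lambda cs: sorted((c.locus_id, tuple(c.supporting_reads))
                            for c in cs)
    assert key(c1) == key(c2)
    assigned = [rid for c in c1 for rid in c.supporting_reads]
    assert sorted(assigned) == sorted(reads)  # each read exactly once


def test_support_histogram_bins():
    counts = [1, 3, 5, 10, 11, 100, 150]
    clusters = [LocusCluster("l", "c", "+", (0, 1), "EXTANT",
                             supporting_reads=["x"] * n) for n in counts]
    bins = locus_read_support_histogram(clusters)
    assert bins == {"1": 1, "2-10": 3, "11-100": 2, ">100": 1}


# ----------------------------------------------------------------- bridges

def _bridge_case(d1=120, d2=300, identity=99.0, lengths=(2000, 1500)):
    m = int(500 * identity / 100)
    a1 = SplicedAlignment("r", "cA", "+", [(0, 500, 1400, 1900)],
                          m, 500 - m, 0, 1000)
    a2 = SplicedAlignment("r", "cB", "+", [(500, 1000, d2, d2 + 500)],
                          m, 500 - m, 0, 1000)
    a1.blocks = [(0, 500, lengths[0] - d1 - 500, lengths[0] - d1)]
    return {"r": [a1, a2]}, {"cA": lengths[0], "cB": lengths[1]}


def test_bridge_detected_within_600bp():
    ev, clens = _bridge_case(d1=120, d2=300)
    out = detect_contig_bridges(ev, {}, clens)
    assert len(out) == 1
    b = out[0]
    assert (b.end_distance_a, b.end_distance_b) == (120, 300)
    assert not b.ortholog_contiguous  # no ortholog genome supplied


def test_bridge_rejected_beyond_600bp():
    ev, clens = _bridge_case(d1=900, d2=100)
    assert detect_contig_bridges(ev, {}, clens) == []


def test_bridge_requires_high_identity():
    ev, clens = _bridge_case(identity=85.0)
    assert detect_contig_bridges(ev, {}, clens) == []


def test_bridge_ortholog_contiguity(rng):
    """A read split over two draft contigs maps contiguously to the
    ortholog genome and is flagged contiguous."""
    from isoscan.mapping import GenomeIndex

    gene = random_seq(rng, 1200)
    part1, part2 = gene[:600], gene[600:]
    clens = {"cA": 800, "cB": 800}
    a1 = _aln("r", [(0, 600, 200, 800)], "cA")
    a2 = _aln("r", [(600, 1200, 0, 600)], "cB")
    a1.read_length = a2.read_length = 1200
    ortho = {"rel_chr": random_seq(rng, 300) +
             mutate_substitutions(gene, 0.01, rng) + random_seq(rng, 300)}
    out = detect_contig_bridges({"r": [a1, a2]}, {"r": gene}, clens,
                                GenomeIndex(ortho, k=15))
    assert len(out) == 1
    assert out[0].ortholog_contiguous
    assert out[0].ortholog_contig == "rel_chr"


# --------------------------------------------------------------- merges

def test_spanning_transcript_candidate_and_validation(rng):
    from isoscan.mapping import GenomeIndex

    seq = "ATG" + random_seq(rng, 600)
    models = [GeneModel("gA", "c1", "+", [(100, 300)]),
              GeneModel("gB", "c1", "+", [(400, 600)])]
    aln = _aln("t1", [(0, 250, 80, 330), (250, 600, 380, 730)])
    aln.read_length = 600
    ortho_gene = mutate_substitutions(seq, 0.01, rng)
    ortho = {"rel": random_seq(rng, 200) + ortho_gene + random_seq(rng, 200)}
    ortho_models = [GeneModel("og", "rel", "+", [(200, 200 + len(seq))])]
    out = detect_spanning_transcripts([("t1", aln, seq)], models,
                                      GenomeIndex(ortho, k=15),
                                      ortho_models)
    assert len(out) == 1
    assert out[0].spanned_gene_ids == ["gA", "gB"]
    assert out[0].ortholog_validation == "VALIDATED"


def test_spanning_transcript_two_ortholog_genes_unvalidated(rng):
    from isoscan.mapping import GenomeIndex

    seq = random_seq(rng, 600)
    models = [GeneModel("gA", "c1", "+", [(100, 300)]),
              GeneModel("gB", "c1", "+", [(400, 600)])]
    aln = _aln("t1", [(0, 600, 80, 680)])
    ortho = {"rel": random_seq(rng, 200) +
             mutate_substitutions(seq, 0.01, rng) + random_seq(rng, 200)}
    ortho_models = [GeneModel("og1", "rel", "+", [(200, 500)]),
                    GeneModel("og2", "rel", "+", [(520, 800)])]
    out = detect_spanning_transcripts([("t1", aln, seq)], models,
                                      GenomeIndex(ortho, k=15),
                                      ortho_models)
    assert out[0].ortholog_validation == "UNVALIDATED"


def test_spanning_transcript_single_model_not_candidate():
    models = [GeneModel("gA", "c1", "+", [(100, 300)])]
    aln = _aln("t1", [(0, 200, 100, 300)])
    assert detect_spanning_transcripts([("t1", aln, "A" * 200)],
                                       models) == []


# ----------------------------------------------------------------- rescue

def test_rescue_thresholds(rng):
    gene = random_seq(rng, 900)
    gene_sets = {"Au": [SeqRecord("gene1", gene)]}
    near = mutate_substitutions(gene, 0.02, rng)
    far = mutate_substitutions(gene, 0.15, rng)
    matches, summary = rescue_unmapped({"good": near, "bad": far},
                                       gene_sets)
    by_id = {m.read_id: m for m in matches}
    assert by_id["good"].rescued
    assert "bad" not in by_id or not by_id["bad"].rescued
    assert summary["per_species"].get("Au") == 1


def test_rescue_empty_gene_set_errors():
    with pytest.raises(ValueError):
        rescue_unmapped({"r": "ACGT" * 100}, {"Au": []})


# ------------------------------------------------------- ORF completeness

def test_orf_completeness_span_rule():
    # cDNA with a known ORF aligned at genomic 100..700
    orf = "ATG" + "GCA" * 60 + "TAA"
    cdna = "T" * 50 + orf + "G" * 50
    caln = _aln("cdna1", [(0, len(cdna), 100, 100 + len(cdna))])
    # read A spans the whole cDNA region; read B starts inside the ORF
    ra = _aln("a", [(0, 600, 100, 700)])
    rb = _aln("b", [(0, 400, 200, 600)])
    rep = estimate_orf_completeness({"a": ra, "b": rb}, {"cdna1": caln},
                                    {"cdna1": cdna})
    assert rep.n_reads == 2
    assert rep.n_complete == 1
    assert rep.n_loci_shared == 1


def test_orf_completeness_percentage_formula():
    from isoscan.annotation import OrfCompletenessReport

    rep = OrfCompletenessReport(n_loci_shared=1347, n_reads=28599,
                                n_complete=21326)
    assert rep.percent_complete == 74.6


def test_orf_completeness_excludes_cdna_without_orf():
    cdna = "TTTTTTGGGGGGCCCCC" * 10  # no ATG..stop
    caln = _aln("c", [(0, len(cdna), 0, len(cdna))])
    rep = estimate_orf_completeness({}, {"c": caln}, {"c": cdna})
    assert rep.excluded_cdnas == ["c"]
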