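import edlib
import numpy as np
import pytest

from isoscan.mapping import (AlignmentSet, AlignParams, GenomeIndex,
                             SplicedAlignment, compute_coverage_identity,
                             determine_strand, select_best_locus,
                             toy_spliced_align)
from isoscan.seq import revcomp
from isoscan.sim import mutate_substitutions, random_seq


def _aln(cov_blocks, matches, mismatches, indels, read_length,
         contig="c1", strand="+"):
    return SplicedAlignment(read_id="r", contig=contig, strand=strand,
                            blocks=cov_blocks, matches=matches,
                            mismatches=mismatches, indels=indels,
                            read_length=read_length)


def test_coverage_identity_formula():
    a = _aln([(0, 950, 0, 950)], 940, 10, 0, 1000)
    cov, ident = compute_coverage_identity(a)
    assert cov == 95.0
    assert round(ident, 2) == 98.95


def test_coverage_identity_perfect():
    a = _aln([(0, 500, 0, 500)], 500, 0, 0, 500)
    assert compute_coverage_identity(a) == (100.0, 100.0)


def test_coverage_identity_partial_band_edge():
    a = _aln([(0, 300, 0, 300)], 300, 0, 0, 1000)
    cov, _ = compute_coverage_identity(a)
    assert cov == 30.0


def test_coverage_identity_zero_aligned_errors():
    a = _aln([(0, 0, 0, 0)], 0, 0, 0, 100)
    with pytest.raises(ValueError):
        compute_coverage_identity(a)


def _scored(score, contig="c1", start=0):
    # build an alignment whose coverage*identity/100 equals `score`
    m = int(score * 10)
    return SplicedAlignment(read_id="r", contig=contig, strand="+",
                            blocks=[(0, 1000, start, start + 1000)],
                            matches=m, mismatches=1000 - m, indels=0,
                            read_length=1000)


def test_select_best_locus_clear_winner():
    s = AlignmentSet("r", [_scored(80.2), _scored(95.0, "c2")])
    best, tied = select_best_locus(s)
    assert best.contig == "c2" and len(tied) == 1


def test_select_best_locus_tie_is_ambiguous():
    s = AlignmentSet("r", [_scored(95.00), _scored(94.95, "c2")])
    best, tied = select_best_locus(s)
    assert len(tied) == 2


def test_select_best_locus_single():
    s = AlignmentSet("r", [_scored(50.0)])
    best, tied = select_best_locus(s)
    assert best is s.alignments[0] and tied == [best]


def test_select_best_locus_empty_errors():
    with pytest.raises(ValueError):
        select_best_locus(AlignmentSet("r", []))


def _two_exon_genome(rng, exon1=300, intron=200, exon2=250):
    e1 = random_seq(rng, exon1)
    e2 = random_seq(rng, exon2)
    intr = "GT" + random_seq(rng, intron - 4) + "AG"
    flank1 = random_seq(rng, 150)
    flank2 = random_seq(rng, 150)
    genome = flank1 + e1 + intr + e2 + flank2
    donor = len(flank1) + exon1
    acceptor = donor + intron
    return {"c1": genome}, e1 + e2, (donor, acceptor)


def test_error_free_two_exon_read_aligns_exactly(rng):
    genome, read, (donor, acceptor) = _two_exon_genome(rng)
    index = GenomeIndex(genome, k=15)
    aset = toy_spliced_align("r", read, index)
    assert len(aset.alignments) >= 1
    a = aset.alignments[0]
    assert a.coverage == 100.0 and a.identity == 100.0
    assert a.introns == [(donor, acceptor)]
    assert a.strand == "+"


def test_minus_strand_read_aligns_with_correct_intron(rng):
    genome, read, (donor, acceptor) = _two_exon_genome(rng)
    # gene on the minus strand of the stored contig
    genome = {"c1": revcomp(genome["c1"])}
    L = len(genome["c1"])
    index = GenomeIndex(genome, k=15)
    aset = toy_spliced_align("r", read, index)
    a = aset.alignments[0]
    assert a.strand == "-"
    assert a.introns == [(L - acceptor, L - donor)]
    assert determine_strand(a, genome) == "-"


def test_homoeolog_pair_identities(rng):
    """A read from one member of a ~3%-diverged pair aligns to both, with
    identities matching an edit-distance oracle."""
    genome, read, _ = _two_exon_genome(rng)
    hom = mutate_substitutions(genome["c1"], 0.03, rng)
    index = GenomeIndex({"c1": genome["c1"], "c2": hom}, k=15)
    aset = toy_spliced_align("r", read, index)
    by_contig = {a.contig: a for a in aset.alignments}
    assert set(by_contig) == {"c1", "c2"}
    assert by_contig["c1"].identity == 100.0
    a2 = by_contig["c2"]
    assert 93.0 < a2.identity < 99.5
    # oracle: edit distance of read vs the homoeologous exon sequence
    ex = a2.exon_intervals()
    hom_cdna = "".join(hom[s:e] for s, e in ex)
    d = edlib.align(read, hom_cdna, mode="NW")["editDistance"]
    oracle_ident = 100.0 * (1 - d / len(read))
    assert abs(a2.identity - oracle_ident) < 1.5


def test_random_sequence_does_not_align(rng):
    genome, _, _ = _two_exon_genome(rng)
    index = GenomeIndex(genome, k=15)
    aset = toy_spliced_align("r", random_seq(rng, 400), index)
    assert aset.alignments == []


def test_read_shorter_than_k_gives_empty(rng):
    genome, _, _ = _two_exon_genome(rng)
    index = GenomeIndex(genome, k=15)
    assert toy_spliced_align("r", "ACGTACGT", index).alignments == []


def test_single_exon_identity_matches_banded_dp_oracle(rng):
    """On short single-exon reads, aligner identity agrees with a direct
    global-alignment oracle within one unit."""
    for _ in range(10):
        gene = random_seq(rng, 200)
        genome = {"c1": random_seq(rng, 100) + gene + random_seq(rng, 100)}
        read = mutate_substitutions(gene, 0.05, rng)
        index = GenomeIndex(genome, k=15)
        aset = toy_spliced_align("r", read, index)
        assert aset.alignments
        a = aset.alignments[0]
        d = edlib.align(read, gene, mode="NW")["editDistance"]
        oracle = 100.0 * (1 - d / len(read))
        assert abs(a.identity - oracle) <= 1.0


def test_coverage_never_exceeds_100(tiny_result):
    for aset in tiny_result.alignment_sets.values():
        for a in aset.alignments:
            cov, ident = compute_coverage_identity(a)
            assert 0 < cov <= 100.0
            assert 0 < ident <= 100.0


def test_determine_strand_conflicting_motifs(rng):
    genome, read, (donor, acceptor) = _two_exon_genome(rng)
    g = genome["c1"]
    # corrupt the motif into the reverse-strand consensus: CT..AC
    g = g[:donor] + "CT" + g[donor + 2:acceptor - 2] + "AC" + g[acceptor:]
    a = SplicedAlignment(
        read_id="r", contig="c1", strand="+",
        blocks=[(0, 300, 150, 450), (300, 550, 650, 900)],
        matches=550, mismatches=0, indels=0, read_length=550)
    assert determine_strand(a, {"c1": g}) == "?"
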