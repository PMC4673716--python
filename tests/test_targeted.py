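import pytest

from isoscan.io_formats import SeqRecord
from isoscan.sim import (mutate_substitutions, random_seq,
                         simulate_family_dataset)
from isoscan.targeted import (annotate_orfs, check_orf,
                              dedupe_family_transcripts, search_family)


def _family(rng, n=3, codons=200, div=0.05):
    orf = "ATG" + "".join("GCA" for _ in range(codons)) + "TAA"
    # randomise codon interiors so members are distinguishable
    body = random_seq(rng, codons * 3)
    body = "".join(body[i:i + 3] if body[i:i + 3] not in
                   ("TAA", "TAG", "TGA") else "GCA"
                   for i in range(0, len(body), 3))
    orf = "ATG" + body + "TAA"
    seq = random_seq(rng, 50) + orf + random_seq(rng, 80)
    orf_span = (50, 50 + len(orf))
    queries = []
    fams = {}
    orfs = {}
    for i in range(n):
        q = mutate_substitutions(seq, div, rng,
                                 protected=set(range(50, 53)) |
                                 set(range(orf_span[1] - 3, orf_span[1])))
        qid = f"q{i}"
        queries.append(SeqRecord(qid, q))
        fams[qid] = "famA"
        orfs[qid] = orf_span
    return queries, fams, orfs


def test_search_family_hit_and_assignment(rng):
    queries, fams, orfs = _family(rng)
    read = mutate_substitutions(queries[1].sequence, 0.01, rng)
    hits = search_family({"r1": read, "junk": random_seq(rng, 700)},
                         queries, fams)
    assert len(hits) == 1
    h = hits[0]
    assert h.read_id == "r1" and h.query_id == "q1"
    assert h.identity > 97


def test_search_family_empty_queries_error():
    with pytest.raises(ValueError):
        search_family({"r": "ACGT"}, [], {})


def test_check_orf_intact(rng):
    queries, fams, orfs = _family(rng, n=1)
    q = queries[0]
    read = mutate_substitutions(
        q.sequence, 0.01, rng,
        protected=set(range(orfs["q0"][0], orfs["q0"][0] + 3)))
    info = check_orf(read, q.sequence, orfs["q0"])
    assert info["orf_status"] == "COMPLETE_INTACT"


def test_check_orf_premature_stop_reported_at_codon(rng):
    queries, fams, orfs = _family(rng, n=1)
    q = queries[0]
    s, e = orfs["q0"]
    codon_idx = 70
    p = s + 3 * codon_idx
    read = q.sequence[:p] + "TAG" + q.sequence[p + 3:]
    info = check_orf(read, q.sequence, orfs["q0"])
    assert info["orf_status"] == "COMPLETE_DISRUPTED"
    assert info["premature_stop_pos"] == codon_idx


def test_check_orf_truncated_is_partial(rng):
    queries, fams, orfs = _family(rng, n=1)
    q = queries[0]
    read = q.sequence[orfs["q0"][0] + 30:]  # starts inside the ORF
    info = check_orf(read, q.sequence, orfs["q0"])
    assert info["orf_status"] == "PARTIAL"


def test_dedupe_collapses_near_identical_reads(rng):
    queries, fams, orfs = _family(rng, n=2, div=0.05)
    reads = {}
    for i, q in enumerate(queries):
        for j in range(4):
            rid = f"r{i}_{j}"
            reads[rid] = mutate_substitutions(q.sequence, 0.002, rng)
    hits = search_family(reads, queries, fams)
    annotate_orfs(hits, reads, queries, orfs)
    transcripts, summary = dedupe_family_transcripts(hits, reads)
    assert len(transcripts) == 2      # one per diverged member
    assert summary["n_reads_positive"] == 8
    assert summary["n_unique_transcripts"] == 2


def test_summary_percentage_arithmetic():
    from isoscan.report import percent

    assert percent(1211, 1577, 1) == 76.8


def test_family_dataset_divergence_and_premature_stop():
    fam = simulate_family_dataset(seed=3, n_reads_per_allele=2)
    import edlib

    seqs = [a.sequence for a in fam.alleles]
    n = len(seqs)
    for i in range(n):
        for j in range(i + 1, n):
            d = edlib.align(seqs[i], seqs[j], mode="NW")["editDistance"]
            assert d / max(len(seqs[i]), len(seqs[j])) >= 0.03
    aid, codon = fam.premature_stop
    allele = next(a for a in fam.alleles if a.id == aid)
    qid = f"q_{aid}"
    q_orf = fam.query_orfs[qid]
    p = q_orf[0] + 3 * codon
    assert allele.sequence[p:p + 3] in ("TAA", "TAG", "TGA")
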