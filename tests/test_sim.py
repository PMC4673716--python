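from collections import Counter

import numpy as np
import pytest

from isoscan.io_formats import SeqRecord
from isoscan.seq import encode
from isoscan.sim import (SimConfig, inject_errors, mutate_substitutions,
                         simulate, simulate_clr_reads, simulate_genome,
                         contig_to_subgenome)


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(contig_split_fraction=1.5)
    with pytest.raises(ValueError):
        SimConfig(per_base_error=0.6)


def test_inject_errors_zero_rate_identity(rng):
    s = "ACGT" * 50
    assert inject_errors(s, 0.0, rng) == s


def test_inject_errors_rate_is_respected(rng):
    import edlib

    s = "".join(rng.choice(list("ACGT"), 4000))
    noisy = inject_errors(s, 0.12, rng)
    d = edlib.align(noisy, s, mode="NW")["editDistance"]
    assert 0.08 < d / len(s) < 0.16


def test_mutate_substitutions_preserves_length_and_protected(rng):
    s = "ACGT" * 100
    protected = set(range(0, 20))
    m = mutate_substitutions(s, 0.5, rng, protected)
    assert len(m) == len(s)
    assert m[:20] == s[:20]
    assert m != s


def test_simulate_genome_plants_requested_fates():
    cfg = SimConfig(seed=5, n_true_genes=40, contig_split_fraction=0.1,
                    unannotated_fraction=0.2)
    sim = simulate_genome(cfg)
    fates = Counter(lt.fate for lt in sim.truth.loci.values()
                    if lt.fate != "normal")
    base_fates = Counter()
    seen = set()
    for lt in sim.truth.loci.values():
        if lt.base_gene not in seen:
            seen.add(lt.base_gene)
            base_fates[lt.fate] += 1
    assert base_fates["split"] == 4          # 10% of 40 genes
    assert base_fates["novel"] == 8          # 20% of 40 genes
    for lt in sim.truth.loci.values():
        if lt.fate == "split":
            assert len(lt.contigs) == 2      # each split gene on 2 contigs
        if lt.fate == "novel":
            # present in the draft contigs but absent from the GFF3
            assert lt.contigs and not lt.model_ids
        if lt.fate == "missplit":
            assert 2 <= len(lt.model_ids) <= 3


def test_missplit_models_partition_exons():
    cfg = SimConfig(seed=5, n_true_genes=40)
    sim = simulate_genome(cfg)
    models = {m.gene_id: m for m in sim.gene_models}
    for lt in sim.truth.loci.values():
        if lt.fate != "missplit":
            continue
        t = sim.truth.transcripts[lt.transcript_ids[0]]
        union = sorted(iv for mid in lt.model_ids
                       for iv in models[mid].exons)
        assert union == sorted(t.exon_intervals)


def test_chimera_rate_one_marks_every_read():
    cfg = SimConfig(seed=3, n_true_genes=12, n_clr_reads=30,
                    chimera_rate=1.0, per_base_error=0.0)
    sim = simulate(cfg)
    assert all(r["is_chimera"] for r in sim.truth.read_rows)


def test_zero_error_subreads_match_template():
    cfg = SimConfig(seed=3, n_true_genes=12, n_clr_reads=20,
                    per_base_error=0.0, chimera_rate=0.0,
                    truncation_rate=0.0, partial_pass_prob=0.0,
                    low_quality_pass_rate=0.0)
    sim = simulate(cfg)
    rows = {r["read_id"]: r for r in sim.truth.read_rows}
    for clr in sim.clr_reads[:5]:
        ins = rows[clr.id]["insert"]
        assert clr.sequence.startswith(ins)


def test_determinism_identical_seed_bytes():
    a = simulate(SimConfig(seed=9, n_true_genes=10, n_clr_reads=15,
                           short_read_depth=2))
    b = simulate(SimConfig(seed=9, n_true_genes=10, n_clr_reads=15,
                           short_read_depth=2))
    assert a.draft_contigs == b.draft_contigs
    assert [r.sequence for r in a.clr_reads] == \
        [r.sequence for r in b.clr_reads]
    assert [(r.id, r.sequence) for r in a.short_reads["S1"]] == \
        [(r.id, r.sequence) for r in b.short_reads["S1"]]


def test_stage_absent_transcripts_get_no_reads(tiny_sim):
    sim = tiny_sim
    for si, stage in enumerate(sim.config.stages):
        allowed = set()
        for tid, tt in sim.truth.transcripts.items():
            if tt.stage_present[si]:
                allowed.add(tt.seq)
        # every read must be a substring of a present transcript
        for rec in sim.short_reads[stage][:200]:
            from isoscan.seq import revcomp
            assert any(rec.sequence in s or revcomp(rec.sequence) in s
                       for s in allowed)


def test_tiling_reads_cover_every_junction():
    cfg = SimConfig(seed=4, n_true_genes=10, n_clr_reads=10,
                    per_base_error=0.0, tiling_stride=20)
    sim = simulate(cfg)
    rl = cfg.short_read_length
    for tid, tt in sim.truth.transcripts.items():
        if not tt.chain or len(tt.seq) < rl:
            continue
        present_stages = np.nonzero(tt.stage_present)[0]
        stage = sim.config.stages[present_stages[0]]
        lib = [r.sequence for r in sim.short_reads[stage]]
        # enumerate junction positions on the transcript and require a
        # spanning read with >= 20 bases on both sides
        exon_lens = [e - s for s, e in sorted(tt.exon_intervals)]
        if tt.strand == "-":
            exon_lens = exon_lens[::-1]
        bounds = np.cumsum(exon_lens)[:-1]
        for b in bounds:
            spanning = [s for s in lib
                        if s in tt.seq and
                        tt.seq.index(s) <= b - 20 and
                        tt.seq.index(s) + rl >= b + 20]
            # reads are emitted in both orientations; check via revcomp too
            from isoscan.seq import revcomp
            spanning += [s for s in lib if revcomp(s) in tt.seq and
                         tt.seq.index(revcomp(s)) <= b - 20 and
                         tt.seq.index(revcomp(s)) + rl >= b + 20]
            assert spanning, f"junction at {b} in {tid} not tiled"


def test_depth_zero_gives_empty_libraries():
    cfg = SimConfig(seed=4, n_true_genes=8, n_clr_reads=5,
                    short_read_depth=0.0)
    sim = simulate(cfg)
    assert all(len(lib) == 0 for lib in sim.short_reads.values())


def test_contig_names_encode_subgenome(tiny_sim):
    for name, sub in tiny_sim.truth.contig_subgenome.items():
        assert contig_to_subgenome(name) == sub
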