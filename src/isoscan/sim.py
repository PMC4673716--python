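"""Synthetic wheat-like dataset with planted ground truth.

The generator emulates the situation of a hexaploid grain transcriptome
sequenced with multi-pass long reads and mapped onto a fragmented draft
genome: three subgenomes with ~3%-diverged homoeologous gene copies, draft
contigs that split single genes at introns, adjacent mis-split gene models,
unannotated (novel) loci, diverged or missing loci, multi-pass long reads
with 5'/3' primers and poly(A) tails, chimeras, and stage-specific short-read
libraries.  Every planted feature is recorded in a :class:`GroundTruth` so
each pipeline stage can be scored against what was actually simulated.

All randomness flows from one ``numpy`` Generator seeded by ``SimConfig.seed``;
identical seeds give byte-identical outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneModel, SeqRecord
from .seq import STOP_CODONS, decode, encode, revcomp

# Fixed library chemistry defaults (configurable at call sites).  The adapter
# is the standard SMRTbell hairpin; the 5' primer is the SMARTer template-
# switch oligo; the 3' primer is an arbitrary anchor sequence.
SMRTBELL_ADAPTER = "ATCTCTCTCTTTTCCTCCTCCTCCGTTGTTGTTGTTGAGAGAGAT"
PRIMER_5P = "AAGCAGTGGTATCAACGCAGAGTACATGGG"
PRIMER_3P = "GTAATACGACTCACTATAGGGAGAGGTTT"

_SUBGENOMES = ["A", "B", "D"]
_RELATIVE_SPECIES = {"A": "Au", "B": "Srel", "D": "Dt"}


@dataclass
class SimConfig:
    seed: int = 0
    n_true_genes: int = 200
    n_subgenomes: int = 3
    homoeolog_divergence: float = 0.03
    contig_split_fraction: float = 0.05
    model_missplit_fraction: float = 0.05
    unannotated_fraction: float = 0.10
    g2_identical_fraction: float = 0.05
    g4_fragment_fraction: float = 0.03
    g5_absent_fraction: float = 0.03
    g4_divergence: float = 0.14
    n_clr_reads: int = 5000
    per_base_error: float = 0.12
    chimera_rate: float = 0.02
    truncation_rate: float = 0.08
    polya_length: int = 30
    n_stages: int = 4
    short_read_length: int = 101
    short_read_depth: float = 8.0
    short_read_error: float = 0.003
    tiling_stride: int | None = None
    ortholog_divergence: float = 0.015
    single_pass_fraction: float = 0.12
    mean_extra_passes: float = 4.0
    low_quality_pass_rate: float = 0.02
    partial_pass_prob: float = 0.35
    cdna_reference_fraction: float = 0.4
    constitutive_fraction: float = 0.5
    stage_on_prob: float = 0.6

    def __post_init__(self):
        for name in ("contig_split_fraction", "model_missplit_fraction",
                     "unannotated_fraction", "g2_identical_fraction",
                     "g4_fragment_fraction", "g5_absent_fraction",
                     "chimera_rate", "truncation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_subgenomes < 1 or self.n_subgenomes > 3:
            raise ValueError("n_subgenomes must be 1..3")
        if not 0.0 <= self.per_base_error < 0.5:
            raise ValueError("per_base_error must be in [0, 0.5)")

    @property
    def stages(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_stages)]


# --------------------------------------------------------------- ground truth

@dataclass
class TranscriptTruth:
    transcript_id: str
    locus_id: str
    seq: str                       # sense cDNA, no poly(A)
    contig: str | None
    strand: str | None
    chain: tuple[tuple[int, int], ...] | None  # junctions on the draft contig
    exon_intervals: list[tuple[int, int]] | None
    stage_present: np.ndarray | None = None
    abundance: np.ndarray | None = None


@dataclass
class LocusTruth:
    locus_id: str
    base_gene: str
    subgenome: str
    fate: str       # normal / g2 / split / missplit / novel / g4 / g5
    strand: str
    contigs: list[str]
    model_ids: list[str]
    transcript_ids: list[str]
    orf_span_contig: tuple[int, int] | None = None
    g2_kind: str | None = None
    novel_shared_contig: bool = False


@dataclass
class GroundTruth:
    loci: dict[str, LocusTruth] = field(default_factory=dict)
    transcripts: dict[str, TranscriptTruth] = field(default_factory=dict)
    read_rows: list[dict] = field(default_factory=list)
    contig_subgenome: dict[str, str] = field(default_factory=dict)
    stages: list[str] = field(default_factory=list)

    @property
    def read_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.read_rows)

    @property
    def stage_presence(self) -> pd.DataFrame:
        rows = {}
        for tid, tt in self.transcripts.items():
            if tt.stage_present is not None:
                rows[tid] = tt.stage_present.astype(bool)
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=self.stages)


@dataclass
class SimData:
    config: SimConfig
    draft_contigs: dict[str, str]
    gene_models: list[GeneModel]
    ortholog_genome: dict[str, str]
    ortholog_models: list[GeneModel]
    ortholog_gene_sets: dict[str, list[SeqRecord]]
    cdna_refs: list[SeqRecord]
    truth: GroundTruth
    adapter: str = SMRTBELL_ADAPTER
    primer5: str = PRIMER_5P
    primer3: str = PRIMER_3P
    clr_reads: list[SeqRecord] = field(default_factory=list)
    short_reads: dict[str, list[SeqRecord]] = field(default_factory=dict)

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.draft_contigs.items()}


# ------------------------------------------------------------- sequence noise

def random_seq(rng: np.random.Generator, n: int) -> str:
    return decode(rng.integers(0, 4, n).astype(np.uint8))


def inject_errors(seq: str, rate: float, rng: np.random.Generator,
                  sub_frac: float = 0.4, ins_frac: float = 0.3) -> str:
    """i.i.d. substitution/insertion/deletion noise (default 40:30:30)."""
    if rate <= 0 or not seq:
        return seq
    codes = encode(seq).copy()
    n = len(codes)
    err = rng.random(n) < rate
    kind = rng.random(n)
    sub = err & (kind < sub_frac)
    ins = err & (kind >= sub_frac) & (kind < sub_frac + ins_frac)
    dele = err & (kind >= sub_frac + ins_frac)
    if sub.any():
        codes[sub] = (codes[sub] +
                      rng.integers(1, 4, int(sub.sum())).astype(np.uint8)) % 4
    rep = np.ones(n, dtype=np.int64)
    rep[dele] = 0
    rep[ins] = 2
    out = codes[np.repeat(np.arange(n), rep)]
    starts = np.cumsum(rep) - rep
    ins_pos = starts[ins]
    if len(ins_pos):
        out[ins_pos] = rng.integers(0, 4, len(ins_pos)).astype(np.uint8)
    return decode(out)


def mutate_substitutions(seq: str, rate: float, rng: np.random.Generator,
                         protected: set[int] | None = None) -> str:
    """Substitution-only divergence, optionally sparing given positions."""
    if rate <= 0:
        return seq
    codes = encode(seq).copy()
    hit = np.nonzero(rng.random(len(codes)) < rate)[0]
    if protected:
        hit = np.array([p for p in hit if p not in protected], dtype=np.int64)
    if len(hit):
        codes[hit] = (codes[hit] +
                      rng.integers(1, 4, len(hit)).astype(np.uint8)) % 4
    return decode(codes)


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(math.log(lo), math.log(hi))))


# ----------------------------------------------------------- gene structures

@dataclass
class _GeneStructure:
    base_gene: str
    template: str                       # locus genomic template ('+' sense)
    exons: list[tuple[int, int]]        # template coords
    isoform_exons: list[list[tuple[int, int]]]  # per isoform (first=primary)
    orf_transcript: tuple[int, int]     # on the primary transcript
    protected: set[int]                 # template positions spared by mutation

    def transcript_seq(self, iso: int) -> str:
        return "".join(self.template[s:e] for s, e in self.isoform_exons[iso])

    def exonic_fraction_prefix(self, n_exons: int) -> float:
        tot = sum(e - s for s, e in self.exons)
        part = sum(e - s for s, e in self.exons[:n_exons])
        return part / tot


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    codons = []
    while len(codons) < n_codons:
        c = decode(rng.integers(0, 4, 3).astype(np.uint8))
        if c not in STOP_CODONS:
            codons.append(c)
    stop = ["TAA", "TAG", "TGA"][int(rng.integers(0, 3))]
    return "ATG" + "".join(codons) + stop


def _make_gene(rng: np.random.Generator, name: str) -> _GeneStructure:
    while True:
        n_exons = int(rng.choice(np.arange(1, 13),
                                 p=_EXON_COUNT_P))
        exon_lens = [int(_loguniform(rng, 80, 600)) for _ in range(n_exons)]
        tlen = sum(exon_lens)
        if 575 <= tlen <= 4600:
            break
    utr5 = int(rng.integers(60, 150))
    utr3 = int(rng.integers(80, 200))
    orf_len = ((tlen - utr5 - utr3 - 6) // 3) * 3
    if orf_len < 240:
        utr5 = 40
        utr3 = 50
        orf_len = ((tlen - utr5 - utr3 - 6) // 3) * 3
    orf = _random_orf(rng, orf_len // 3 - 2)
    pad = tlen - utr5 - len(orf)
    transcript = random_seq(rng, utr5) + orf + random_seq(rng, max(0, pad))
    transcript = transcript[:tlen]
    orf_t = (utr5, utr5 + len(orf))

    # carve the transcript into exons and interleave introns
    exons: list[tuple[int, int]] = []
    parts: list[str] = []
    protected: set[int] = set()
    pos = 0
    tpos = 0
    intron_motifs: list[tuple[str, str]] = []
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el))
        parts.append(transcript[tpos:tpos + el])
        tpos += el
        pos += el
        if i < n_exons - 1:
            ilen = int(_loguniform(rng, 60, 2000))
            r = rng.random()
            if r < 0.9851:
                dm, am = "GT", "AG"
            elif r < 0.9851 + 0.0129:
                dm, am = "GC", "AG"
            elif r < 0.9851 + 0.0129 + 0.0011:
                dm, am = "AT", "AC"
            else:
                dm, am = "CC", "TG"
            intron = dm + random_seq(rng, ilen - 4) + am
            # a second donor 9 nt in, for alternative-donor isoforms
            if ilen >= 80:
                intron = intron[:9] + "GT" + intron[11:]
            parts.append(intron)
            for p in (pos, pos + 1, pos + 9, pos + 10,
                      pos + ilen - 2, pos + ilen - 1):
                protected.add(p)
            intron_motifs.append((dm, am))
            pos += ilen
    template = "".join(parts)
    # protect start and stop codons of the ORF (they live in the first/last
    # exons only if the ORF is not split; map transcript->template)
    tmap = []
    for s, e in exons:
        tmap.extend(range(s, e))
    for p in (list(range(orf_t[0], orf_t[0] + 3)) +
              list(range(orf_t[1] - 3, orf_t[1]))):
        protected.add(tmap[p])

    iso_exons = [list(exons)]
    if n_exons >= 3:
        r = rng.random()
        if r < 0.5:
            skip = int(rng.integers(1, n_exons - 1))
            iso_exons.append([iv for i, iv in enumerate(exons) if i != skip])
        if r < 0.15 and n_exons >= 4:
            j = int(rng.integers(0, n_exons - 1))
            s, e = exons[j]
            nxt = exons[j + 1]
            if nxt[0] - e >= 80:   # the +9 alternative donor fits
                alt = list(exons)
                alt[j] = (s, e + 9)
                iso_exons.append(alt)
    return _GeneStructure(base_gene=name, template=template, exons=exons,
                          isoform_exons=iso_exons, orf_transcript=orf_t,
                          protected=protected)


_EXON_COUNT_P = np.array([0.08, 0.10, 0.16, 0.18, 0.16, 0.12,
                          0.08, 0.05, 0.03, 0.02, 0.01, 0.01])


# ------------------------------------------------------------------- layout

@dataclass
class _Placement:
    contig: str
    offset: int
    strand: str
    tlen: int

    def interval(self, s: int, e: int) -> tuple[int, int]:
        if self.strand == "+":
            return (self.offset + s, self.offset + e)
        return (self.offset + self.tlen - e, self.offset + self.tlen - s)


def _chain_on_contig(iso_exons: list[tuple[int, int]], pl: _Placement
                     ) -> tuple[tuple[int, int], ...]:
    juncs = []
    for (s1, e1), (s2, e2) in zip(iso_exons, iso_exons[1:]):
        a, b = pl.interval(e1, s2)
        juncs.append((a, b))
    return tuple(sorted(juncs))


class _ContigFactory:
    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.contigs: dict[str, str] = {}
        self.subgenome: dict[str, str] = {}
        self._n = 0

    def new_name(self, subgenome: str) -> str:
        self._n += 1
        chrom = int(self.rng.integers(1, 8))
        arm = "SL"[int(self.rng.integers(0, 2))]
        return f"{chrom}{subgenome}{arm}_{self._n:05d}"

    def add(self, subgenome: str, seq: str) -> str:
        name = self.new_name(subgenome)
        self.contigs[name] = seq
        self.subgenome[name] = subgenome
        return name


def contig_to_subgenome(name: str) -> str:
    """Subgenome letter from an arm-style contig name, e.g. '1AL_00012' -> A."""
    arm = name.split("_")[0]
    return arm[1] if len(arm) >= 2 else "?"


# ------------------------------------------------------------ genome builder

def _assign_fates(rng: np.random.Generator, genes: list[_GeneStructure],
                  cfg: SimConfig) -> dict[str, str]:
    n = len(genes)
    want = {
        "split": round(cfg.contig_split_fraction * n),
        "missplit": round(cfg.model_missplit_fraction * n),
        "novel": round(cfg.unannotated_fraction * n),
        "g2": round(cfg.g2_identical_fraction * n),
        "g4": round(cfg.g4_fragment_fraction * n),
        "g5": round(cfg.g5_absent_fraction * n),
    }

    def split_ok(g: _GeneStructure) -> bool:
        return any(0.34 <= g.exonic_fraction_prefix(i) <= 0.66
                   for i in range(1, len(g.exons)))

    def g4_ok(g: _GeneStructure) -> bool:
        # the fragment band sits clear of the 30% coverage boundary even
        # after alignment-edge losses at high divergence
        return any(0.37 <= g.exonic_fraction_prefix(i) <= 0.46 and
                   sum(e - s for s, e in g.exons[:i]) >= 450
                   for i in range(1, len(g.exons)))

    eligible = {
        "split": split_ok,
        "missplit": lambda g: len(g.exons) >= 3,
        "novel": lambda g: True,
        "g2": lambda g: True,
        "g4": g4_ok,
        "g5": lambda g: True,
    }
    fates = {g.base_gene: "normal" for g in genes}
    order = list(rng.permutation(n))
    for fate in ("split", "g4", "missplit", "g2", "novel", "g5"):
        need = want[fate]
        for gi in order:
            if need == 0:
                break
            g = genes[gi]
            if fates[g.base_gene] == "normal" and eligible[fate](g):
                fates[g.base_gene] = fate
                need -= 1
        if need > 0:
            raise ValueError(
                f"infeasible config: could not place {want[fate]} "
                f"genes with fate {fate}")
    return fates


def simulate_genome(config: SimConfig,
                    rng: np.random.Generator | None = None) -> SimData:
    """Build the true loci, the fragmented draft genome + annotation, the
    contiguous relative-species genomes, and the ground-truth tables."""
    rng = rng or np.random.default_rng(config.seed)
    genes = [_make_gene(rng, f"g{i:04d}")
             for i in range(config.n_true_genes)]
    fates = _assign_fates(rng, genes, config)
    factory = _ContigFactory(rng)
    truth = GroundTruth(stages=list(SimConfig.stages.fget(config)))
    subs = _SUBGENOMES[:config.n_subgenomes]

    gene_models: list[GeneModel] = []
    ortho_parts: dict[str, list[str]] = {s: [] for s in subs}
    ortho_models: dict[str, list[tuple[str, int, str, list]]] = \
        {s: [] for s in subs}  # (locus_id, offset placeholder handled below)
    ortho_sets: dict[str, list[SeqRecord]] = \
        {_RELATIVE_SPECIES[s]: [] for s in subs}
    cdna_refs: list[SeqRecord] = []
    pending_novel: list[tuple[LocusTruth, str, _GeneStructure, _Placement]] = []

    def flank() -> str:
        return random_seq(rng, int(rng.integers(200, 600)))

    def register_locus(lt: LocusTruth, g: _GeneStructure,
                       placements: list[_Placement],
                       mutated_template: str | None = None) -> None:
        """Fill transcript truth for a locus with a single full placement."""
        pl = placements[0] if placements else None
        for iso_i, iso in enumerate(g.isoform_exons):
            tid = f"{lt.locus_id}.{iso_i + 1}"
            if mutated_template is not None:
                seq = "".join(mutated_template[s:e] for s, e in iso)
            else:
                seq = g.transcript_seq(iso_i)
            chain = None
            exon_iv = None
            if pl is not None and lt.fate not in ("split", "g4", "g5"):
                chain = _chain_on_contig(iso, pl)
                exon_iv = sorted(pl.interval(s, e) for s, e in iso)
            truth.transcripts[tid] = TranscriptTruth(
                transcript_id=tid, locus_id=lt.locus_id, seq=seq,
                contig=pl.contig if pl else None,
                strand=pl.strand if pl else None,
                chain=chain, exon_intervals=exon_iv)
            lt.transcript_ids.append(tid)
        if pl is not None and lt.fate not in ("split", "g4", "g5"):
            tmap = []
            for s, e in g.exons:
                tmap.extend(range(s, e))
            os_, oe = g.orf_transcript
            a = pl.interval(tmap[os_], tmap[os_] + 1)
            b = pl.interval(tmap[oe - 1], tmap[oe - 1] + 1)
            span = (min(a[0], b[0]), max(a[1], b[1]))
            lt.orf_span_contig = span

    def add_draft_model(locus_id: str, model_id: str, contig: str,
                        strand: str, exon_iv: list[tuple[int, int]]) -> None:
        gene_models.append(GeneModel(
            gene_id=model_id, contig=contig, strand=strand,
            exons=sorted(exon_iv),
            transcripts={model_id + ".t1": sorted(exon_iv)}))

    def add_ortholog_copy(lt: LocusTruth, g: _GeneStructure) -> None:
        """Place the full locus contiguously on the relative-species genome."""
        sub = lt.subgenome
        mut = mutate_substitutions(g.template, config.ortholog_divergence,
                                   rng, g.protected)
        fl = flank()
        offset = sum(len(p) for p in ortho_parts[sub]) + len(fl)
        ortho_parts[sub].append(fl)
        ortho_parts[sub].append(mut)
        ortho_parts[sub].append(flank())
        exon_iv = [(offset + s, offset + e) for s, e in g.exons]
        chrom = f"{_RELATIVE_SPECIES[sub]}_chr1"
        ortho_models[sub].append((lt.locus_id, chrom, exon_iv))
        cdna = "".join(mut[s:e] for s, e in g.exons)
        ortho_sets[_RELATIVE_SPECIES[sub]].append(
            SeqRecord(id=f"{_RELATIVE_SPECIES[sub]}_{lt.locus_id}",
                      sequence=cdna))

    for g in genes:
        fate = fates[g.base_gene]
        if fate == "normal":
            for sub in subs:
                locus_id = f"{g.base_gene}{sub}"
                strand = "+-"[int(rng.integers(0, 2))]
                mut = mutate_substitutions(
                    g.template, config.homoeolog_divergence, rng, g.protected)
                fl = flank()
                body = mut if strand == "+" else revcomp(mut)
                seqc = fl + body + flank()
                contig = factory.add(sub, seqc)
                pl = _Placement(contig, len(fl), strand, len(mut))
                lt = LocusTruth(locus_id=locus_id, base_gene=g.base_gene,
                                subgenome=sub, fate="normal", strand=strand,
                                contigs=[contig], model_ids=[],
                                transcript_ids=[])
                model_id = f"m_{locus_id}"
                exon_iv = [pl.interval(s, e) for s, e in g.exons]
                add_draft_model(locus_id, model_id, contig, strand, exon_iv)
                lt.model_ids.append(model_id)
                truth.loci[locus_id] = lt
                register_locus(lt, g, [pl], mut)
                add_ortholog_copy(lt, g)
        elif fate == "g2":
            kind = ["across_single", "within", "across_multi"][
                int(rng.integers(0, 3))]
            if kind == "across_single":
                copy_subs = list(subs)
            elif kind == "within":
                s0 = subs[int(rng.integers(0, len(subs)))]
                copy_subs = [s0, s0]
            else:
                s0, s1 = rng.choice(len(subs), 2, replace=False)
                copy_subs = [subs[int(s0)], subs[int(s0)], subs[int(s1)]]
            strand = "+-"[int(rng.integers(0, 2))]
            for ci, sub in enumerate(copy_subs):
                locus_id = f"{g.base_gene}{sub}c{ci}"
                fl = flank()
                body = g.template if strand == "+" else revcomp(g.template)
                contig = factory.add(sub, fl + body + flank())
                pl = _Placement(contig, len(fl), strand, len(g.template))
                lt = LocusTruth(locus_id=locus_id, base_gene=g.base_gene,
                                subgenome=sub, fate="g2", strand=strand,
                                contigs=[contig], model_ids=[],
                                transcript_ids=[], g2_kind=kind)
                model_id = f"m_{locus_id}"
                exon_iv = [pl.interval(s, e) for s, e in g.exons]
                add_draft_model(locus_id, model_id, contig, strand, exon_iv)
                lt.model_ids.append(model_id)
                truth.loci[locus_id] = lt
                if ci == 0:
                    register_locus(lt, g, [pl])
                    add_ortholog_copy(lt, g)
        elif fate == "split":
            sub = ["A", "D"][int(rng.integers(0, 2))] \
                if config.n_subgenomes >= 3 else subs[0]
            locus_id = f"{g.base_gene}{sub}"
            # choose the split intron
            cand = [i for i in range(1, len(g.exons))
                    if 0.34 <= g.exonic_fraction_prefix(i) <= 0.66]
            ix = cand[int(rng.integers(0, len(cand)))]
            intron_s = g.exons[ix - 1][1]
            intron_e = g.exons[ix][0]
            keep = min(300, (intron_e - intron_s) // 2)
            fl1, fl2 = flank(), flank()
            part1 = g.template[:intron_s + keep]
            part2 = g.template[intron_e - keep:]
            c1 = factory.add(sub, fl1 + part1)
            c2 = factory.add(sub, part2 + fl2)
            lt = LocusTruth(locus_id=locus_id, base_gene=g.base_gene,
                            subgenome=sub, fate="split", strand="+",
                            contigs=[c1, c2], model_ids=[],
                            transcript_ids=[])
            m1 = f"m_{locus_id}_p1"
            m2 = f"m_{locus_id}_p2"
            add_draft_model(locus_id, m1, c1, "+",
                            [(len(fl1) + s, len(fl1) + e)
                             for s, e in g.exons[:ix]])
            off2 = -(intron_e - keep)
            add_draft_model(locus_id, m2, c2, "+",
                            [(off2 + s, off2 + e) for s, e in g.exons[ix:]])
            lt.model_ids += [m1, m2]
            truth.loci[locus_id] = lt
            register_locus(lt, g, [])
            add_ortholog_copy(lt, g)
        elif fate == "missplit":
            sub = subs[int(rng.integers(0, len(subs)))]
            locus_id = f"{g.base_gene}{sub}"
            strand = "+-"[int(rng.integers(0, 2))]
            fl = flank()
            body = g.template if strand == "+" else revcomp(g.template)
            contig = factory.add(sub, fl + body + flank())
            pl = _Placement(contig, len(fl), strand, len(g.template))
            lt = LocusTruth(locus_id=locus_id, base_gene=g.base_gene,
                            subgenome=sub, fate="missplit", strand=strand,
                            contigs=[contig], model_ids=[],
                            transcript_ids=[])
            n_models = 2 if len(g.exons) < 5 else int(rng.integers(2, 4))
            cuts = sorted(rng.choice(np.arange(1, len(g.exons)),
                                     n_models - 1, replace=False).tolist())
            bounds = [0] + cuts + [len(g.exons)]
            for mi in range(n_models):
                mid = f"m_{locus_id}_x{mi}"
                sub_exons = g.exons[bounds[mi]:bounds[mi + 1]]
                add_draft_model(locus_id, mid, contig, strand,
                                [pl.interval(s, e) for s, e in sub_exons])
                lt.model_ids.append(mid)
            truth.loci[locus_id] = lt
            register_locus(lt, g, [pl])
            add_ortholog_copy(lt, g)
        elif fate == "novel":
            sub = subs[int(rng.integers(0, len(subs)))]
            locus_id = f"{g.base_gene}{sub}"
            strand = "+-"[int(rng.integers(0, 2))]
            body = g.template if strand == "+" else revcomp(g.template)
            lt = LocusTruth(locus_id=locus_id, base_gene=g.base_gene,
                            subgenome=sub, fate="novel", strand=strand,
                            contigs=[], model_ids=[], transcript_ids=[])
            pending_novel.append((lt, body, g, strand))
            continue
        elif fate == "g4":
            sub = ["A", "D"][int(rng.integers(0, 2))] \
                if config.n_subgenomes >= 3 else subs[0]
            locus_id = f"{g.base_gene}{sub}"
            cand = [i for i in range(1, len(g.exons))
                    if 0.37 <= g.exonic_fraction_prefix(i) <= 0.46 and
                    sum(e - s for s, e in g.exons[:i]) >= 450]
            m = cand[int(rng.integers(0, len(cand)))]
            frag = g.template[:g.exons[m - 1][1] + 100]
            frag = mutate_substitutions(frag, config.g4_divergence, rng,
                                        g.protected)
            fl = flank()
            contig = factory.add(sub, fl + frag + flank())
            lt = LocusTruth(locus_id=locus_id, base_gene=g.base_gene,
                            subgenome=sub, fate="g4", strand="+",
                            contigs=[contig], model_ids=[],
                            transcript_ids=[])
            mid = f"m_{locus_id}"
            add_draft_model(locus_id, mid, contig, "+",
                            [(len(fl) + s, len(fl) + e)
                             for s, e in g.exons[:m]])
            lt.model_ids.append(mid)
            truth.loci[locus_id] = lt
            register_locus(lt, g, [])
            add_ortholog_copy(lt, g)
        elif fate == "g5":
            sub = ["A", "D"][int(rng.integers(0, 2))] \
                if config.n_subgenomes >= 3 else subs[0]
            locus_id = f"{g.base_gene}{sub}"
            lt = LocusTruth(locus_id=locus_id, base_gene=g.base_gene,
                            subgenome=sub, fate="g5", strand="+",
                            contigs=[], model_ids=[], transcript_ids=[])
            truth.loci[locus_id] = lt
            register_locus(lt, g, [])
            add_ortholog_copy(lt, g)

    # novel loci: half share a contig with an annotated gene, half sit
    # alone.  Split-gene contigs are never extended: their defining
    # property is that the gene part reaches the contig end.
    split_contigs = {c for lt in truth.loci.values()
                     if lt.fate == "split" for c in lt.contigs}
    annotated_contigs = [m.contig for m in gene_models
                         if m.contig not in split_contigs]
    for i, (lt, body, g, strand) in enumerate(pending_novel):
        if i % 2 == 0 and annotated_contigs:
            host = annotated_contigs[int(rng.integers(0,
                                                      len(annotated_contigs)))]
            gap = random_seq(rng, int(rng.integers(300, 700)))
            offset = len(factory.contigs[host]) + len(gap)
            factory.contigs[host] = factory.contigs[host] + gap + body \
                + flank()
            contig = host
            lt.novel_shared_contig = True
        else:
            fl = flank()
            offset = len(fl)
            contig = factory.add(lt.subgenome, fl + body + flank())
        pl = _Placement(contig, offset, strand, len(g.template))
        lt.contigs = [contig]
        truth.loci[lt.locus_id] = lt
        register_locus(lt, g, [pl])
        add_ortholog_copy(lt, g)

    # stage expression patterns and abundances
    n_st = config.n_stages
    for tt in truth.transcripts.values():
        if rng.random() < config.constitutive_fraction or n_st == 1:
            pres = np.ones(n_st, dtype=bool)
        else:
            while True:
                pres = rng.random(n_st) < config.stage_on_prob
                if pres.any() and not pres.all():
                    break
        tt.stage_present = pres
        ab = np.exp(rng.uniform(math.log(0.5), math.log(2.0), n_st))
        tt.abundance = np.where(pres, ab, 0.0)

    # reference full-length cDNA set (error-free primary transcripts)
    ok_fates = {"normal", "missplit", "novel"}
    cands = [lt for lt in truth.loci.values() if lt.fate in ok_fates]
    n_cdna = round(config.cdna_reference_fraction * len(cands))
    pick = rng.permutation(len(cands))[:n_cdna]
    for i in sorted(pick.tolist()):
        lt = cands[i]
        tid = lt.transcript_ids[0]
        cdna_refs.append(SeqRecord(id=f"cdna_{lt.locus_id}",
                                   sequence=truth.transcripts[tid].seq))

    ortholog_genome = {f"{_RELATIVE_SPECIES[s]}_chr1": "".join(ortho_parts[s])
                       for s in subs if ortho_parts[s]}
    ortholog_models = []
    for s in subs:
        for locus_id, chrom, exon_iv in ortho_models[s]:
            ortholog_models.append(GeneModel(
                gene_id=f"o_{locus_id}", contig=chrom, strand="+",
                exons=sorted(exon_iv),
                transcripts={f"o_{locus_id}.t1": sorted(exon_iv)}))

    truth.contig_subgenome = dict(factory.subgenome)
    return SimData(config=config, draft_contigs=factory.contigs,
                   gene_models=gene_models, ortholog_genome=ortholog_genome,
                   ortholog_models=ortholog_models,
                   ortholog_gene_sets=ortho_sets, cdna_refs=cdna_refs,
                   truth=truth)


# ----------------------------------------------------------------- CLR reads

_FATE_GROUP = {"normal": "G1", "missplit": "G1", "novel": "G1",
               "g2": "G2", "split": "G3", "g4": "G4", "g5": "G5"}


def _phred(rate: float) -> int:
    return int(round(-10 * math.log10(max(rate, 1e-4))))


def simulate_clr_reads(config: SimConfig, sim: SimData,
                       rng: np.random.Generator | None = None
                       ) -> list[SeqRecord]:
    """Multi-pass continuous long reads with primer/poly(A)/adapter structure.

    Each CLR alternates sense/antisense copies of
    ``5'primer + cDNA + polyA + 3'primer`` separated by the SMRTbell adapter;
    errors are injected independently per pass.  Chimeras concatenate two
    inserts (internal primers).  The ground-truth read table is extended.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    truth = sim.truth
    tids = []
    weights = []
    for tid, tt in truth.transcripts.items():
        # only g2 copy-0 transcripts are registered; reads from identical
        # copies are indistinguishable anyway
        tids.append(tid)
        weights.append(float(tt.abundance.sum()))
    weights = np.array(weights)
    weights /= weights.sum()
    reads: list[SeqRecord] = []
    for i in range(config.n_clr_reads):
        read_id = f"clr_{i:06d}"
        is_chimera = rng.random() < config.chimera_rate
        t1 = tids[int(rng.choice(len(tids), p=weights))]
        tt1 = truth.transcripts[t1]
        lt1 = truth.loci[tt1.locus_id]
        is_trunc = False
        polya = "A" * int(config.polya_length + rng.integers(-8, 12))
        if is_chimera:
            t2 = t1
            while t2 == t1:
                t2 = tids[int(rng.choice(len(tids), p=weights))]
            seq2 = truth.transcripts[t2].seq
            insert = (sim.primer5 + tt1.seq + polya + sim.primer3 +
                      sim.primer5 + seq2 + polya + sim.primer3)
            template = None
            group = None
        else:
            cdna = tt1.seq
            chain = tt1.chain
            if (lt1.fate == "normal" and chain and
                    rng.random() < config.truncation_rate):
                # cut inside an internal exon so the junction chain becomes a
                # strict suffix of the full chain
                iso_exons = tt1.exon_intervals
                n_ex = len(chain) + 1
                e_idx = int(rng.integers(1, n_ex))
                # transcript-coordinate exon boundaries
                # reconstruct exon lengths from the cDNA via the chain count
                bounds = np.cumsum(
                    [0] + [iv[1] - iv[0] for iv in
                           sorted(iso_exons)]) if iso_exons else None
                if bounds is not None and lt1.strand == "-":
                    lens = [iv[1] - iv[0] for iv in sorted(iso_exons)][::-1]
                    bounds = np.cumsum([0] + lens)
                if bounds is not None:
                    lo = int(bounds[e_idx]) + 2
                    hi = int(bounds[e_idx + 1]) - 10
                    if hi > lo:
                        cut = int(rng.integers(lo, hi))
                        cdna = cdna[cut:]
                        is_trunc = True
            insert = sim.primer5 + cdna + polya + sim.primer3
            template = cdna
            group = _FATE_GROUP[lt1.fate]
        if rng.random() < config.single_pass_fraction:
            n_passes = 1
        else:
            n_passes = 2 + int(rng.poisson(config.mean_extra_passes))
            n_passes = min(n_passes, 12)
        segs: list[str] = []
        quals: list[np.ndarray] = []
        all_low = True

        def emit(seq: str, force_low: bool | None = None) -> None:
            nonlocal all_low
            low = (rng.random() < config.low_quality_pass_rate
                   if force_low is None else force_low)
            rate = 0.45 if low else config.per_base_error
            noisy = inject_errors(seq, rate, rng)
            segs.append(noisy)
            q = 2 if low else _phred(config.per_base_error)
            quals.append(np.full(len(noisy), q, dtype=np.int16))
            if not low:
                all_low = False

        def emit_adapter() -> None:
            noisy = inject_errors(sim.adapter, config.per_base_error, rng)
            segs.append(noisy)
            quals.append(np.full(len(noisy), _phred(config.per_base_error),
                                 dtype=np.int16))

        if n_passes > 1 and rng.random() < config.partial_pass_prob:
            frac = rng.uniform(0.2, 0.8)
            m = int(len(insert) * frac)
            emit(revcomp(insert)[-m:], force_low=False)
            emit_adapter()
        for p in range(n_passes):
            s = insert if p % 2 == 0 else revcomp(insert)
            emit(s)
            if p < n_passes - 1:
                emit_adapter()
        if n_passes > 1 and rng.random() < config.partial_pass_prob:
            frac = rng.uniform(0.2, 0.8)
            m = int(len(insert) * frac)
            nxt = insert if n_passes % 2 == 0 else revcomp(insert)
            emit_adapter()
            emit(nxt[:m], force_low=False)
        seq = "".join(segs)
        qual = np.concatenate(quals)
        reads.append(SeqRecord(id=read_id, sequence=seq, qualities=qual))
        truth.read_rows.append(dict(
            read_id=read_id, transcript_id=None if is_chimera else t1,
            locus_id=None if is_chimera else tt1.locus_id,
            is_chimera=is_chimera, is_truncated=is_trunc,
            n_passes=n_passes, planted_group=group,
            should_be_flnc=(not is_chimera) and not
            (n_passes == 1 and all_low),
            template=template, insert=None if is_chimera else insert))
    sim.clr_reads = reads
    return reads


# ---------------------------------------------------------------- short reads

def simulate_short_reads(config: SimConfig, sim: SimData,
                         rng: np.random.Generator | None = None
                         ) -> dict[str, list[SeqRecord]]:
    """Stage-specific short-read libraries sampled from present transcripts.

    With ``tiling_stride`` set, reads start at every stride-th position and
    are error-free (deterministic full coverage); otherwise read counts per
    transcript follow depth x abundance.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    rl = config.short_read_length
    out: dict[str, list[SeqRecord]] = {}
    for si, stage in enumerate(config.stages):
        lib: list[SeqRecord] = []
        n = 0
        for tid, tt in sim.truth.transcripts.items():
            if tt.stage_present is None or not tt.stage_present[si]:
                continue
            seq = tt.seq
            if len(seq) < rl:
                continue
            if config.tiling_stride:
                starts = range(0, len(seq) - rl + 1, config.tiling_stride)
            else:
                count = int(round(config.short_read_depth *
                                  tt.abundance[si] * len(seq) / rl))
                starts = rng.integers(0, len(seq) - rl + 1,
                                      count).tolist()
            for st in starts:
                r = seq[st:st + rl]
                if not config.tiling_stride and config.short_read_error > 0:
                    r = mutate_substitutions(r, config.short_read_error, rng)
                if rng.random() < 0.5:
                    r = revcomp(r)
                lib.append(SeqRecord(id=f"{stage}_r{n:07d}", sequence=r))
                n += 1
        out[stage] = lib
    sim.short_reads = out
    return out


def simulate(config: SimConfig) -> SimData:
    """Full dataset: genome + CLRs + stage libraries, deterministically."""
    rng = np.random.default_rng(config.seed)
    sim = simulate_genome(config, rng)
    simulate_clr_reads(config, sim, rng)
    simulate_short_reads(config, sim, rng)
    return sim


# ------------------------------------------------------------ gene families

@dataclass
class FamilySim:
    queries: list[SeqRecord]
    query_families: dict[str, str]
    query_orfs: dict[str, tuple[int, int]]
    alleles: list[SeqRecord]
    allele_families: dict[str, str]
    clr_reads: list[SeqRecord]
    read_allele: dict[str, str]
    short_reads: list[SeqRecord]
    premature_stop: tuple[str, int]   # (allele id, 0-based codon index)
    adapter: str = SMRTBELL_ADAPTER
    primer5: str = PRIMER_5P
    primer3: str = PRIMER_3P


def _codon_safe_mutate(seq: str, orf: tuple[int, int], rate: float,
                       rng: np.random.Generator) -> str:
    """Substitution divergence that never creates or destroys stop codons
    inside the ORF and spares the start/stop codons."""
    codes = list(seq)
    s, e = orf
    n = len(seq)
    hits = np.nonzero(rng.random(n) < rate)[0]
    for p in hits.tolist():
        if s <= p < s + 3 or e - 3 <= p < e:
            continue
        old = codes[p]
        for _ in range(4):
            new = "ACGT"[int(rng.integers(0, 4))]
            if new == old:
                continue
            codes[p] = new
            if s <= p < e:
                ci = (p - s) // 3
                codon = "".join(codes[s + 3 * ci:s + 3 * ci + 3])
                if codon in STOP_CODONS:
                    codes[p] = old
                    continue
            break
    return "".join(codes)


def simulate_family_dataset(seed: int = 0,
                            families: dict[str, int] | None = None,
                            n_reads_per_allele: int = 100,
                            orf_codons: int = 500,
                            allele_divergence: float = 0.025,
                            query_divergence: float = 0.01,
                            per_base_error: float = 0.02,
                            premature_stop_codon: int | None = None,
                            tiling_stride: int = 20) -> FamilySim:
    """Single-exon gene-family dataset (seed-storage-protein style).

    One family member ("allele" here loosely, for homoeologs/paralogs alike)
    carries a planted premature stop codon; queries are ~1%-diverged database
    counterparts with intact reading frames.
    """
    rng = np.random.default_rng(seed)
    families = families or {"HMW-GS": 6}
    utr5, utr3 = 60, 100
    queries: list[SeqRecord] = []
    q_fams: dict[str, str] = {}
    q_orfs: dict[str, tuple[int, int]] = {}
    alleles: list[SeqRecord] = []
    a_fams: dict[str, str] = {}
    premature: tuple[str, int] | None = None
    if premature_stop_codon is None:
        premature_stop_codon = orf_codons // 2
    first_family = True
    for fam, n_alleles in families.items():
        orf = _random_orf(rng, orf_codons)
        ancestor = (random_seq(rng, utr5) + orf + random_seq(rng, utr3))
        orf_span = (utr5, utr5 + len(orf))
        for ai in range(n_alleles):
            aid = f"{fam}_a{ai + 1}"
            allele = _codon_safe_mutate(ancestor, orf_span,
                                        allele_divergence, rng)
            query = _codon_safe_mutate(allele, orf_span,
                                       query_divergence, rng)
            if first_family and ai == 0:
                ci = premature_stop_codon
                p = orf_span[0] + 3 * ci
                allele = allele[:p] + "TAG" + allele[p + 3:]
                premature = (aid, ci)
            alleles.append(SeqRecord(id=aid, sequence=allele))
            a_fams[aid] = fam
            qid = f"q_{aid}"
            queries.append(SeqRecord(id=qid, sequence=query))
            q_fams[qid] = fam
            q_orfs[qid] = orf_span
        first_family = False

    cfg = SimConfig(seed=seed, per_base_error=per_base_error,
                    single_pass_fraction=0.0, mean_extra_passes=3.0,
                    low_quality_pass_rate=0.0, chimera_rate=0.0,
                    partial_pass_prob=0.2)
    clrs: list[SeqRecord] = []
    read_allele: dict[str, str] = {}
    n = 0
    for al in alleles:
        for _ in range(n_reads_per_allele):
            rid = f"fam_{n:05d}"
            n += 1
            polya = "A" * int(cfg.polya_length + rng.integers(-5, 6))
            insert = PRIMER_5P + al.sequence + polya + PRIMER_3P
            # seed-storage transcripts are short; their molecules run many
            # full passes, so two-pass (no-vote) consensi are not modelled
            n_passes = 3 + int(rng.poisson(cfg.mean_extra_passes))
            segs = []
            for p in range(n_passes):
                s = insert if p % 2 == 0 else revcomp(insert)
                segs.append(inject_errors(s, per_base_error, rng))
                if p < n_passes - 1:
                    segs.append(inject_errors(SMRTBELL_ADAPTER,
                                              per_base_error, rng))
            seq = "".join(segs)
            q = np.full(len(seq), _phred(per_base_error), dtype=np.int16)
            clrs.append(SeqRecord(id=rid, sequence=seq, qualities=q))
            read_allele[rid] = al.id
    shorts: list[SeqRecord] = []
    rl = 101
    m = 0
    for al in alleles:
        for st in range(0, len(al.sequence) - rl + 1, tiling_stride):
            shorts.append(SeqRecord(id=f"fs_{m:06d}",
                                    sequence=al.sequence[st:st + rl]))
            m += 1
    assert premature is not None
    return FamilySim(queries=queries, query_families=q_fams,
                     query_orfs=q_orfs, alleles=alleles,
                     allele_families=a_fams, clr_reads=clrs,
                     read_allele=read_allele, short_reads=shorts,
                     premature_stop=premature)
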