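"""Partition mapped reads into the five genome-mapping groups (G1-G5),
analyse multi-mapping (G2) patterns across subgenomes, and validate splice
junctions against short-read evidence.

The groups follow an ordered cascade over read-relative coverage and
alignment identity:

* G1 - one unique best location, coverage > 90 and identity > 90;
* G2 - multiple best-tied alignments at >= 90 (both metrics by default);
* G3 - partial mapping (coverage 30-80, identity >= 90) on >= 2 contigs;
* G4 - any remaining significant alignment (identity >= 40, coverage >= 30);
* G5 - no significant mapping.

Reads whose strand cannot be resolved are set aside as UNDETERMINED before
the cascade.  Every read lands in exactly one group.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .io_formats import JunctionRecord
from .mapping import AlignmentSet, SplicedAlignment, select_best_locus
from .seq import revcomp

GROUPS = ["G1", "G2", "G3", "G4", "G5", "UNDETERMINED"]


@dataclass
class ClassifyThresholds:
    g1_min: float = 90.0        # strict (>) for both coverage and identity
    g2_min: float = 90.0        # inclusive (>=)
    g2_mode: str = "and"        # "and": both metrics >= 90; "or": either
    g3_identity: float = 90.0
    g3_cov_lo: float = 30.0
    g3_cov_hi: float = 80.0
    g4_identity: float = 40.0
    g4_coverage: float = 30.0
    tie_delta: float = 0.1


@dataclass
class GroupAssignment:
    read_id: str
    group: str
    evidence: list[SplicedAlignment] = field(default_factory=list)


@dataclass
class G2Pattern:
    read_id: str
    pattern: str     # ONE_BEST_PER_SUBGENOME / MULTI_WITHIN_ONE_SUBGENOME /
    # MULTI_ACROSS_SUBGENOMES / UNKNOWN_SUBGENOME
    subgenomes_hit: tuple[str, ...] = ()


def classify_read_groups(alignment_sets: dict[str, AlignmentSet],
                         strands: dict[str, str] | None = None,
                         thresholds: ClassifyThresholds | None = None
                         ) -> list[GroupAssignment]:
    """Apply the G1-G5 cascade to every read, in a read-order-independent way.

    ``strands`` carries the resolved transcript strand per read ('?' sends
    the read to UNDETERMINED before the cascade).
    """
    th = thresholds or ClassifyThresholds()
    out: list[GroupAssignment] = []
    for read_id in sorted(alignment_sets):
        aset = alignment_sets[read_id]
        if strands is not None and strands.get(read_id) == "?":
            out.append(GroupAssignment(read_id, "UNDETERMINED",
                                       aset.alignments[:1]))
            continue
        if not aset.alignments:
            out.append(GroupAssignment(read_id, "G5"))
            continue
        best, tied = select_best_locus(aset, th.tie_delta)
        if len(tied) == 1 and best.coverage > th.g1_min and \
                best.identity > th.g1_min:
            out.append(GroupAssignment(read_id, "G1", [best]))
            continue
        if len(tied) >= 2:
            if th.g2_mode == "and":
                good = [a for a in tied if a.identity >= th.g2_min
                        and a.coverage >= th.g2_min]
            else:
                good = [a for a in tied if a.identity >= th.g2_min
                        or a.coverage >= th.g2_min]
            if len(good) >= 2:
                out.append(GroupAssignment(read_id, "G2", good))
                continue
        partial = {}
        for a in aset.alignments:
            if a.identity >= th.g3_identity and \
                    th.g3_cov_lo <= a.coverage <= th.g3_cov_hi:
                cur = partial.get(a.contig)
                if cur is None or a.score > cur.score:
                    partial[a.contig] = a
        if len(partial) >= 2:
            out.append(GroupAssignment(read_id, "G3",
                                       sorted(partial.values(),
                                              key=lambda a: -a.score)))
            continue
        sig = [a for a in aset.alignments
               if a.identity >= th.g4_identity and
               a.coverage >= th.g4_coverage]
        if sig:
            out.append(GroupAssignment(read_id, "G4", sig[:1]))
        else:
            out.append(GroupAssignment(read_id, "G5"))
    return out


def g2_pattern_analysis(assignments: list[GroupAssignment],
                        contig_to_subgenome) -> list[G2Pattern]:
    """Categorise each G2 read's tied best alignments across subgenomes.

    ``contig_to_subgenome`` is a mapping or callable contig -> letter.
    """
    getter = contig_to_subgenome if callable(contig_to_subgenome) \
        else contig_to_subgenome.get
    out: list[G2Pattern] = []
    for ga in assignments:
        if ga.group != "G2":
            continue
        per_sub: Counter = Counter()
        unknown = False
        for a in ga.evidence:
            sub = getter(a.contig)
            if sub is None or sub == "?":
                unknown = True
            else:
                per_sub[sub] += 1
        if unknown and not per_sub:
            out.append(G2Pattern(ga.read_id, "UNKNOWN_SUBGENOME"))
            continue
        subs = tuple(sorted(per_sub))
        if len(per_sub) >= 2 and any(c >= 2 for c in per_sub.values()):
            pat = "MULTI_ACROSS_SUBGENOMES"
        elif len(per_sub) == 1 and max(per_sub.values()) >= 2:
            pat = "MULTI_WITHIN_ONE_SUBGENOME"
        elif len(per_sub) >= 2:
            pat = "ONE_BEST_PER_SUBGENOME"
        else:
            pat = "UNKNOWN_SUBGENOME" if unknown else \
                "MULTI_WITHIN_ONE_SUBGENOME"
        out.append(G2Pattern(ga.read_id, pat, subs))
    return out


_MOTIF_CLASS = {("GT", "AG"): "GT-AG", ("GC", "AG"): "GC-AG",
                ("AT", "AC"): "AT-AC"}


def extract_junctions(alignment: SplicedAlignment, genome: dict[str, str],
                      min_intron: int = 40) -> list[JunctionRecord]:
    """One JunctionRecord per inter-block genomic gap >= ``min_intron``.

    The motif is read from the genome and strand-adjusted, so a minus-strand
    gene showing CT..AC on the forward genome classifies as GT-AG.
    """
    cseq = genome[alignment.contig]
    out = []
    for donor, acceptor in alignment.introns:
        if acceptor - donor < min_intron:
            continue
        d2 = cseq[donor:donor + 2]
        a2 = cseq[acceptor - 2:acceptor]
        if alignment.strand == "-":
            pair = (revcomp(a2), revcomp(d2))
        else:
            pair = (d2, a2)
        motif = _MOTIF_CLASS.get(pair, "other")
        out.append(JunctionRecord(contig=alignment.contig, donor_pos=donor,
                                  acceptor_pos=acceptor,
                                  strand=alignment.strand, motif=motif))
    return out


@dataclass
class JunctionValidation:
    n_junctions: int              # junction sites in reads (occurrences)
    n_supported: int
    motif_counts: dict[str, int]  # occurrence-weighted
    n_unique: int = 0
    n_unique_supported: int = 0

    @property
    def supported_fraction(self) -> float:
        return self.n_supported / self.n_junctions if self.n_junctions else 0.0

    @property
    def motif_percent(self) -> dict[str, float]:
        tot = sum(self.motif_counts.values())
        return {m: 100.0 * c / tot for m, c in self.motif_counts.items()} \
            if tot else {}


def validate_junctions(long_read_junctions: list[JunctionRecord],
                       short_read_support: dict | Counter
                       ) -> JunctionValidation:
    """Support check of long-read junction sites against short-read ones.

    A junction is supported iff an identical (contig, donor, acceptor,
    strand) short-read junction exists with support count >= 1.  Fractions
    and motif frequencies are occurrence-weighted (each site counted once
    per read that shows it); distinct-site counts are carried alongside.
    """
    n = len(long_read_junctions)
    supported = sum(1 for j in long_read_junctions
                    if short_read_support.get(j.key, 0) >= 1)
    motifs = Counter(j.motif for j in long_read_junctions)
    uniq: dict[tuple, str] = {j.key: j.motif for j in long_read_junctions}
    uniq_support = sum(1 for key in uniq
                       if short_read_support.get(key, 0) >= 1)
    return JunctionValidation(n_junctions=n, n_supported=supported,
                              motif_counts=dict(motifs),
                              n_unique=len(uniq),
                              n_unique_supported=uniq_support)
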