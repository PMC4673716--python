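# Methods

`isoscan` re-implements, at desk scale, the analysis chain used to
characterise full-length transcripts of a polyploid grain transcriptome
sequenced with multi-pass single-molecule reads and mapped onto a
fragmented draft genome.  This note records the models, the tunable
parameters, the synthetic data the pipeline is exercised on, and the
numerical choices made where the design was open.

## The analysis chain

1. **Subread splitting.** Each continuous long read (CLR) is cut at
   approximate occurrences of the SMRTbell hairpin adapter (edit distance
   ≤ 20% of the adapter length; fragments that would be twice the median
   length are re-scanned at 32%, since one missed adapter leaves a doubled
   fragment).  Fragments shorter than `mini_length = 50` or with a
   quality-derived read score below `read_score = 0.75` are dropped; the
   survivors are oriented against the longest fragment using infix
   alignment, so partial terminal passes orient reliably.

2. **Consensus (CCS).** With ≥ `min_complete_passes = 2` subreads, the
   median-length subread serves as the reference (partials and doubled
   fragments are outliers); all other subreads are aligned to it and a
   per-column majority vote resolves substitutions and deletions, with
   short insertions applied when more than a third of passes agree on the
   same inserted string.  Ties go to the reference base.  This is a
   deliberate simplification of a partial-order-alignment consensus:
   adequate at toy scale, and its residual error (≈ 4% for 3 passes at 12%
   raw error, < 1% for 6+ passes) is what the short-read polishing step
   then removes.  A single-subread CLR passes through as "type II".

3. **Full-length non-chimeric (FLNC) classification.** A consensus is
   FLNC iff it shows the 5' primer near one end, the 3' primer near the
   other, a poly(A) tract of ≥ `min_polya = 20` A's directly upstream of
   the 3' primer, and no additional primer hit in the interior (≥ 50 nt
   from either end ⇒ chimeric).  The poly(A) scan is local-scoring
   (A: +1, non-A: −purity/(1−purity) with purity 0.75), i.e. it tolerates
   up to ~25% interspersed non-A while never extending through random
   sequence.  The tolerance is deliberately set above the raw single-pass
   error rate: single-pass reads reach this detector uncorrected, and a
   tighter bound would reject a large share of them for no structural
   reason.

4. **Short-read polishing.** Short reads are seeded onto candidate FLNC
   reads by shared 15-mers; candidate ranking divides seed votes by each
   target's expected clean-k-mer fraction so that error-rich reads attract
   their share of placements.  A placement may vote only when its edit
   distance is within each target's error budget *and* within 2 edits of
   the best-explained placement of that short read ("excess" ranking) —
   this blocks ~3%-diverged homoeologous reads from cross-voting.
   Positions with pileup depth ≥ 3 take the majority (70% supermajority
   for base changes, 40% for indels, whose votes wobble by ±1 position).
   Two rounds run: a loose pass sized by the consensus error estimate,
   then a strict pass whose budget shrinks to just above each read's
   observed residual divergence.  The acceptance surface of this step is
   directional (identity to template strictly increases raw subread →
   consensus → polished read), not equivalence with any particular
   published corrector.

5. **Spliced mapping.** A seed–chain–extend aligner over an exact 15-mer
   index: same-diagonal anchors merge into verified segments, inter-anchor
   gaps are closed by global alignment, genomic gaps ≥ `min_intron = 40`
   become introns whose boundaries shift (≤ 6 nt, sacrificing ≤ 3 matched
   bases) onto the nearest canonical motif (GT..AG, then GC..AG, AT..AC).
   Both flanks of the refinement window are retracted a few bases first,
   because an exact anchor can coincidentally extend past the true exon
   boundary.  End extensions and gap fills are trimmed/abandoned when the
   kept part would fall below ~2 matches per error — a gapped alignment
   through unrelated sequence still matches about half its columns, so a
   net-positive rule is not enough.  Reads with no reported alignment are
   retried with every k-mer as a seed (dense mode), which recovers
   fragments of highly diverged loci whose clean seeds are sparse.
   Coverage is read-relative (aligned read fraction); identity is
   matches/(matches+mismatches+indels).

6. **G1–G5 classification.** An ordered cascade after setting aside reads
   with unresolved strand: unique best alignment with coverage > 90 and
   identity > 90 → G1; ≥ 2 score-tied alignments (Δscore < 0.1) with both
   metrics ≥ 90 → G2 (an OR-mode flag exists); identity ≥ 90 with
   coverage 30–80 on ≥ 2 contigs → G3; any remaining alignment with
   identity ≥ 40 and coverage ≥ 30 → G4; else G5.  The published band
   definitions leave gaps; the cascade (with G4 as catch-all) is the only
   reading under which the five groups exhaust the reads.  G2 reads are
   further categorised by subgenome multiplicity of their tied alignments.

7. **Short-read placement.** A miniature splice-aware mapper (two-anchor
   diagonals, junction refinement shared with the long-read aligner,
   soft-clipping of junction overhangs).  Junction support, exonic
   coverage and gene counting use uniquely placed reads only, where
   uniqueness is judged on mismatches alone: a clipped placement on a
   near-identical locus that explains the read equally well makes it
   ambiguous evidence.  Both orientations are always evaluated because
   near-identical loci may sit on either strand.

8. **High-quality filtering, loci, isoforms.** 5'-truncated reads (chain a
   strict suffix of a same-locus read's chain, 5' end downstream) and
   singletons without any short-read support are removed.  Reads cluster
   into loci by single-linkage ≥ 1 bp exonic overlap (same contig and
   strand); a cluster is NOVEL when no annotated model overlaps it.
   Isoforms are exact junction-chain classes per locus (single-exon reads:
   one isoform per locus and strand); KNOWN status requires exact chain
   equality with an annotated transcript.

9. **Annotation improvement.**  Cross-contig bridges: a partially mapped
   read whose two segments (identity > 90, summed coverage ≥ 80) end
   within 600 bp of the respective contig ends, validated by a contiguous
   (coverage ≥ 80, identity ≥ 80, single-contig) alignment to a relative
   genome.  Gene merges: transcripts overlapping the exons of 2–3 models
   on one contig at > 90/90, VALIDATED when the ≥ 80/80 ortholog region
   holds exactly one annotated gene.  Rescue: G4/G5 reads against relative
   protein-coding gene sets at > 90/90.  ORF completeness: a read at a
   locus shared with a reference cDNA is complete iff its genomic span
   contains the start- and stop-codon positions of the cDNA's longest ORF
   (span containment is robust to residual read error; no re-calling).

10. **Expression.**  RPKM = exon reads / (uniquely mapped reads in
    millions × exon length in kb), expressed iff RPKM > 1 (strict); reads
    overlapping the exons of more than one gene count for none (strictest
    union mode).  Isoform presence per stage: ≥ 1 uniquely placed read on
    ≥ 1 isoform-specific junction; isoforms without specific junctions are
    UNRESOLVABLE and excluded from differential calling, which is
    presence/absence only (no statistical test, by design).

11. **Family search.**  Gapped alignment of reads against family queries
    (identity and query coverage ≥ 80); ORF status relative to the best
    query (intact / disrupted by a premature stop, reported as a 0-based
    codon index / partial, with ± 2 codons of end-wobble tolerance);
    non-redundant transcripts by greedy clustering at ≥ 99% full-length
    identity — separating ≥ 3%-diverged family members while absorbing
    ≤ 1% residual error.

## The synthetic data

The generator emulates the study conditions this pipeline was built for: a
hexaploid genome (subgenomes A/B/D) whose draft assembly is fragmented and
incompletely annotated.  Defaults (all configurable): 200 base genes;
normal genes carry three homoeologous copies diverged by 3% substitutions
(splice dinucleotides, start/stop codons spared, so gene structure is
conserved); exons are drawn log-uniformly from 80–600 bp, introns from
60–2000 bp, 1–12 exons, transcripts constrained to 575–4600 bp with a
planted ATG..stop ORF; junction motifs are planted at 98.51% GT-AG,
1.29% GC-AG, 0.11% AT-AC.  Planted fates (assigned to single-subgenome
genes so their signal is not absorbed by intact homoeologs): genes split
across two contigs at an intron with ≤ 300 bp of retained intron at each
contig end (5%), genes mis-annotated as 2–3 adjacent part-models (5%),
unannotated novel genes (10%, half sharing a contig with an annotated
gene), fragmentary 14%-diverged loci (3%, exonic fraction 37–46% so the
planted mapping band clears its boundaries even after alignment-edge
losses), and absent loci (3%).  Identical-copy genes (5%) plant the
multi-mapping (G2) patterns.  Relative-species genomes carry every gene
contiguously at 1.5% divergence, with single-gene annotations and
per-subgenome transcript sets.

CLRs alternate sense/antisense passes of
`5' primer + cDNA + poly(A)~30 + 3' primer` around SMRTbell adapters, with
12% i.i.d. errors (40:30:30 substitution:insertion:deletion) injected per
pass; 12% of CLRs are single-pass, the rest carry 2 + Poisson(4) full
passes (mean ≈ 6, matching the subreads-per-consensus ratio of the study
context) plus optional partial terminal passes; 2% of reads are chimeric
concatemers and 8% are 5'-truncated.  Four stage libraries sample 101-bp
reads from transcripts present at each stage (half constitutive, half with
a random non-constant on/off vector) at depth 8× scaled by a 0.5–2×
abundance; a deterministic "tiling" mode emits error-free reads at every
stride-th position for the exact-recovery checks.

What the simulation does *not* model — and what passing tests therefore do
not show about real data: polymerase-kinetics error profiles (errors here
are i.i.d.), genomic repeats and transposons, sequence-dependent coverage
bias, intron retention or genuine antisense transcription, and real
homoeolog expression imbalance beyond the 0.5–2× range.

## Problem sizes and experiment design

The validation suite and the acceptance script run: (a) the full pipeline
at the default conditions (200 genes / ~530 loci / ~2 Mb draft genome,
5000 CLRs, ~270k short reads, 12% raw error); (b) the same scale with
zero injected error through the FLNC stage, where identification must be
perfect; (c) a 60-gene, 1200-CLR error-free run with tiled short reads
(stride 20) and no identical-copy genes, on which isoform chains, stage
presence and RPKM-expressed sets must be recovered exactly; (d) a
six-allele single-exon family at 2.5% mutual divergence (so pairwise
≥ 3%), 100 reads each at 2% raw error with a minimum of three full passes
(short seed-storage transcripts run many passes, and a two-pass consensus
cannot out-vote anything), one allele carrying a premature stop.  Stage
presence in (c) is scored on loci whose full planted chain catalogue was
recovered, because junction specificity — and hence presence — is defined
relative to the recovered catalogue.

## Numerical choices and known limitations

* Coordinates are 0-based half-open everywhere; conversion happens only at
  format boundaries (GFF3, PSL).  PSL blocks are ungapped, so within-exon
  indels survive a PSL round trip only in the gap-count columns.
* Score ties (Δ < 0.1 on coverage × identity / 100) define "multiple best
  alignments"; deterministic tie-breaks order by (contig, genome start).
* The identity denominator includes indels; the coverage numerator is the
  aligned read fraction, so partial mapping reads the same way regardless
  of contig lengths.
* Rounding is half-up and applied at reporting time only.
* Residual consensus error of ~1.5% after polishing leaves a tail of reads
  below the 90% identity band and some wobbled junctions (visible as
  non-canonical motifs); at 12% raw error, group recovery is therefore
  ≥ 95% rather than exact, and junction-support percentages sit below the
  error-free values.  Three-pass consensi are the main contributors.
* A short read whose window is conserved between homoeologs is ambiguous
  by construction; treating such reads as multi-mapped (and excluding
  them from counting and junction support) trades a little sensitivity
  for exactness of stage-presence calls.
* The decisions the published procedure left open — AND-semantics for
  the G2 band, read-relative coverage, the 1-read junction-support
  threshold, single-isoform-per-locus collapsing of single-exon reads,
  99% family clustering — are noted inline above, each with its rationale.
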