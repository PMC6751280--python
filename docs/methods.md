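# Methods

This note records the models, definitions, numerical choices and known
limitations behind each analysis stage, and what the synthetic-data
generator does and does not emulate.

## Coordinates and core objects

All genomic coordinates are 1-based inclusive (GTF convention); BED exports
convert to half-open 0-based. Transcripts are exon chains on a named
chromosome with a mandatory `+`/`−` strand — unstranded models are rejected
because every downstream definition (donor vs acceptor, 5′ vs 3′) depends
on orientation. Exons within a transcript must be non-overlapping and
non-adjacent, so each gap is an intron of length ≥ 1. Genomes may contain
N; splice-site dinucleotides containing N are treated as non-canonical.

## Isoform collapse and catalog classification

Collapse operates on genome-anchored exon chains rather than alignments
(the 85 % coverage / 90 % identity filters of alignment-based collapse are
upstream concerns):

* multi-exon transcripts with identical intron chains merge; the
  representative spans the union of member 5′/3′ extents;
* a transcript whose chain is a strand-aware 5′-truncated suffix of a
  longer chain, with the same 3′ terminal coordinate, is absorbed into the
  longer transcript — provided its 5′-terminal exon stays inside the longer
  transcript's matching exon. Without that guard an intron-retaining
  isoform (whose chain is also a chain prefix/suffix) would be swallowed;
* mono-exon transcripts merge when they overlap.

Representative ids take the lexicographically smallest member id, which
makes the operation deterministic and idempotent.

Classification against an annotation is strand-aware: *known* means an
exact intron-chain match (mono-exon: containment in an annotated exon);
*novel isoform of a known gene* means same-strand exonic overlap without a
chain match; everything else, including antisense overlap, is a *novel
locus*. Exact-chain "known" is the strict reading; any-overlap alternatives
would only shuffle counts between the first two classes.

## AS event definitions

Events are detected per gene by exhaustive pairwise isoform comparison and
deduplicated by `(type, coordinate signature)`, so one biological event
supported by many isoform pairs counts once. With introns written `(s, e)`:

* **IR** — intron `(s, e)` of one isoform with a single exon of another
  isoform containing `[s−1, e+1]`. Both retained-intron boundaries must be
  splice sites of the spliced form, which excludes 5′/3′-end artifacts.
* **ES** — internal exon whose two flanking introns appear fused into one
  intron (same outer boundaries) of another isoform.
* **A5SS / A3SS** — two introns from different isoforms sharing exactly one
  boundary, with the additional requirement that the exons flanking the
  differing boundary overlap between the two isoforms. The refinement is
  what distinguishes a genuine junction shift from the junction differences
  that every ES or MEE configuration also produces; without it those events
  would be double-counted. Labels are strand-aware: a shift at the intron's
  genomic-left boundary is a donor (A5SS) choice on `+` and an acceptor
  (A3SS) choice on `−`.
* **MEE** — two non-overlapping internal exons, one per isoform, whose
  flanking introns share both outer boundaries, with no isoform of the gene
  containing both exons.

Stage attribution: an event is present at a stage iff each of its two forms
has at least one supporting isoform with replicate-mean FPKM ≥ 0.1 there
(threshold configurable; presence is monotone in the threshold by
construction).

## Retained introns, splice strength, ORFs and the 50-nt rule

Retained-intron position is `(intron start − gene start) / gene length` in
transcript orientation (0 = 5′ end of the gene, mirrored on `−`). Splice
strength is reported as PWM log-odds (`pwm_logodds`), not MaxEnt: a
position probability matrix is trained on the input's non-retained introns
(donor window 3 exonic + 6 intronic nt; acceptor window 20 intronic + 3
exonic nt; pseudocount 0.5; background = pooled window base frequencies)
and sites are scored `Σ log2(P(base|pos)/bg(base))` in bits. This is a
self-contained, monotone surrogate that preserves the retained-vs-spliced
strength contrast; absolute values are not comparable to MaxEnt scores.

ORF search is sense-strand only (transcripts are oriented): the longest
ATG-initiated ORF ending at the first in-frame stop, over the three frames,
ties resolved to the 5′-most start. The PTC rule is strict: a stop codon is
premature iff `(last junction position) − (stop codon's last base) > 50` in
spliced-transcript coordinates, so a distance of exactly 50 is not a PTC.
The distance is measured from the stop codon's **last** base; measuring
from the first base would shift every distance by 2 nt, and the rule's
literature statement does not disambiguate — this choice is fixed here and
recorded in outputs. Transcripts whose retained intron lies outside of, or
overlapping, the representative transcript's coding span are excluded from
PTC calling (reasons reported); the representative is the gene's longest
annotated transcript.

The Mann–Whitney test used for retained-vs-spliced contrasts enumerates the
exact null over all group assignments when n ≤ 10 (midranks, ties handled)
and otherwise uses the normal approximation with tie correction; constant
pooled data returns p = 1.

## IRT values and clustering

`IRT(gene, stage) = Σ FPKM(IR transcripts) / Σ FPKM(all transcripts)` on
replicate-mean FPKM; undefined (NaN) where the gene is silent. Genes with
any undefined stage are excluded from clustering rather than zero-filled —
zero-filling would fabricate a "stable low IR" cluster out of silent genes.
Clustering is Lloyd's k-means with k-means++ seeding (scikit-learn), best
of 10 restarts, deterministic under a fixed seed; k = 9 for IRT
trajectories and k = 10 for expression trajectories, fixed rather than
selected. By default only genes owning ≥ 1 IR transcript are clustered
(configurable), since an all-genes clustering is dominated by the IRT = 0
mass.

## APA

Cleavage records are clustered per (chromosome, strand) by single-linkage
chaining with a 20-nt gap, absorbing poly(A) microheterogeneity. The
cluster representative is the position with maximal read support, ties
resolved to the 3′-most position (favoring distal cleavage). Clusters below
2 supporting records are treated as low-confidence and dropped from
per-gene summaries (configurable). Gene assignment extends each gene 1 kb
downstream of its 3′ end. Cross-stage "same site" comparisons reuse the
20-nt tolerance.

Signal discovery replaces a general motif finder with an exhaustive 6-mer
scan: for each of the 4096 hexamers, the number of 50-nt upstream windows
containing it is compared against an order-0 expectation from each window's
own base composition (presence probability `1 − (1 − p)^45`, p-value =
upper binomial tail at the mean per-window probability, ranked by p then
count). The scan is deterministic and dependency-free and targets exactly
the canonical-signal question; it cannot find variable-length or gapped
motifs. Calibration note: the binomial model assumes windows do not share
sequence — overlapping windows (sites closer than the window length)
correlate counts and inflate significance, so upstream deduplication by the
20-nt clustering matters.

## Fusion criteria

Alignment segments on one chromosome are first merged into loci when closer
than a 1-kb merge window; the six criteria are then evaluated on loci:
(a) ≥ 2 loci; (b) all on placed chromosomes (name-pattern based, rejecting
scaffold/contig accessions, configurable); (c) each locus ≥ 5 % of
transcript length; (d) total ≥ 95 %; (e) same-chromosome locus pairs ≥ 10 kb
apart (gap between nearest ends); (f) ≥ 1 junction-spanning short read.
The merge window is deliberately smaller than the 10-kb distance threshold:
merging at 10 kb would make criterion (e) vacuously true (any surviving
same-chromosome pair would already be ≥ 10 kb apart), collapsing two
distinct published criteria into one. With a 1-kb window, nearby segments
form one locus (criterion a), while loci separated by 1–10 kb remain
distinct and fail the distance criterion. Coverage fractions are of
transcript length, not alignment blocks.

## Expression dynamics

Sample correlations are Pearson on log2(FPKM+1) (zero-variance samples
yield undefined correlations, reported as NaN). Differential expression
between stages uses gene-level FPKM (sum of transcript FPKM), a
**pooled-variance** two-sample t on log2(FPKM+1) with a variance floor of
1e-3, BH adjustment across genes, and the thresholds |log2FC| > 1 (stage
means + 1 pseudocount) and FDR < 0.01. Pooled rather than Welch variance is
a deliberate choice: with three replicates per stage the Welch–Satterthwaite
degrees of freedom collapse toward 2 whenever one stage's variance estimate
dominates by chance, and the resulting heavy tails destroy power at
stringent FDR levels; both stages share one noise model here, so pooling is
also the better-specified estimator. Temporal clustering z-scores each
gene's stage-mean log2(FPKM+1) profile (shape, not level), drops constant
profiles, filters to genes with max stage-mean FPKM ≥ 0.1, and delegates to
the same k-means.

## Synthetic data: what it emulates, and what it does not

The generator plants, per AS mode, boundary-matched two-isoform
constructions (e.g. IR: spliced A = e1–e2–e3 vs retaining B = e1–[e2+i2+e3])
whose event signatures are unambiguous, writes every splice site into the
genome as GT…AG (optionally degenerate CA…GG for a fraction of retained
introns, to emulate weak sites), and adds single-isoform control genes.
The retained intron is always the transcript-3′ intron of its gene
(strand-aware), emulating the 3′ positional bias of retained introns, so
directional position-ratio checks have a planted signal to find.
Gene geometry is fixed (120-nt exons, 150-nt introns, 2-kb spacing) —
enough to make coordinates and strand logic non-trivial, not a model of
real gene architecture.

Expression follows designed archetypes: nine IRT trajectories (rising,
falling, stable high/mid/low, mid-peak, mid-dip, early/late step) and ten
expression trajectories (a bump per stage plus rising and falling ramps)
over the eight stages, assigned round-robin so archetype counts are
balanced. Stage totals are `base_fpkm × archetype`; the IR transcript's
share equals the IRT archetype exactly before noise; replicate noise is
multiplicative log-normal (`numpy` convention: σ on the natural-log scale),
reflecting the heavy-tailed, multiplicative character of FPKM replicates.
Defaults (`base_fpkm` 50, `noise_sd` 0.2, 3 replicates) produce clearly
recoverable but non-trivial trajectories. The DE-calibration generator
plants 8-fold changes on 50 of 2050 single-transcript genes at `noise_sd`
0.1 with log-normally varying baselines.

Poly(A) sites are planted ≥ 40 nt apart (validated) with integer jitter
truncated at ±9 nt so microheterogeneity never bridges the 20-nt clustering
window — cluster counts are therefore exactly recoverable by construction.
An AATAAA is written 15–30 nt upstream of a configurable fraction of sites.
Fusion panels contain all-pass candidates plus candidates violating exactly
one criterion each.

What passing on this data shows: coordinate arithmetic, strand handling,
event definitions, estimator wiring and calibration of the statistical
procedures are correct. What it does not show: behavior on real catalogs
with truncated/degraded isoforms, overlapping genes, non-canonical splice
sites beyond the planted ones, realistic FPKM dispersion-mean
relationships, or APA microheterogeneity heavier than the truncated jitter.

## Problem sizes used in validation

The validation suite uses 5 planted events per AS mode (35 genes) for
recovery, 500 random genes (≤ 4 isoforms, ≤ 6 exons on a shared coordinate
grid) for brute-force event-oracle equivalence, 1000 random 300-mers for
ORF-oracle equivalence, 9 IRT archetypes × 40 genes at noise 0.2 for
cluster recovery (ARI ≥ 0.8 expected; observed 1.0), 100-seed nulls for
hexamer calibration, and 50 planted 8-fold genes among 2000 nulls for DE
calibration. All of it runs in well under a minute on one CPU.

## Known limitations

* Short-read junction support for AS events is accepted as an input column,
  never recomputed (no read-level processing of any kind).
* No PSI quantification; event presence is a thresholded FPKM statement.
* PWM splice scores are relative within a dataset; no cross-dataset scale.
* The hexamer test's order-0 background understates clustered low-complexity
  sequence; genome-wide it is calibrated only for well-separated windows.
* k for both clusterings is fixed, not selected; cluster labels are
  arbitrary (compare partitions with ARI, not label equality).
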