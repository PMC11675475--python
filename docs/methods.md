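# Methods

`leafatac` reimplements, as a tested pipeline over synthetic data with
planted ground truth, the analysis arc of a two-replicate, three-stage
(BBCH_11 / BBCH_13 / BBCH_17) ATAC-seq + RNA-seq study of maize leaf
development.  Real raw sequencing data are not consumed: every analysis step
runs on data produced by the package's own generator, whose planted structure
makes each step's correctness *measurable* (recall of planted labels,
calibration of planted nulls) rather than merely plausible.  This note
records the models, the defaults and why they were chosen, and what the
synthetic data do and do not establish about real data.

## Coordinate and classification conventions

All internal coordinates are 0-based half-open (BED convention); GFF3 is
converted at the parsing/writing boundary.  The promoter window is the 2 kb
strand-upstream of the TSS, half-open and ending at the TSS, clipped at
chromosome edges.  Every genomic position belongs to exactly one feature
category under the precedence promoter > 5'UTR > 3'UTR > exon > intron >
intergenic; a peak is classified at its summit (midpoint when no summit is
recorded).  Classification by a single position keeps the category map a
total function and makes feature proportions sum to one; classifying a peak
by any-overlap would double-count peaks spanning boundaries.  Peak–peak
operations use a ≥1 bp overlap criterion, and bookended intervals merge at
`max_gap=0`, matching common merge-tool behaviour.

The category index is a per-base uint8 array per chromosome, painted in
ascending precedence.  Memory is one byte per base — appropriate for the
simulated megabase genomes this package analyses, and the reason the
annotation container is not suited, as-is, to a full 2.1 Gb maize genome.

## Synthetic data generator

A single integer seed drives everything through a `numpy` `SeedSequence`
spawn: the genome, peak placement, counts, expression, fragments and
sequences each consume an independent child stream, so outputs are
byte-reproducible and regenerating one artifact never perturbs another.

**Genome.** Two chromosomes (1.2 Mb + 0.8 Mb) carry 300 non-overlapping
stranded gene models (1.5–3.5 kb, 1–4 exons, terminal UTRs) separated by
≥2 kb so promoter windows never intrude into neighbouring gene bodies.
Genes are allocated to chromosomes proportionally to length.

**ACRs.** 500 shared peaks plus (60, 20, 20) stage-specific peaks are
planted with chromosome probability proportional to length, feature category
drawn from {promoter 0.25, intron 0.28, intergenic 0.30, exon 0.07, 5'UTR
0.05, 3'UTR 0.05}, and category-dependent Gaussian lengths (3'UTR longest at
600±120 bp, intergenic shortest at 200±40 bp) — the qualitative landscape
the analysis expects.  Each peak appears in both replicates of its active
stages with independent ≤20 bp edge jitter; a 45 bp exclusion buffer (>2×
jitter) guarantees distinct planted peaks never touch, so replicate
consolidation at ≥1 bp overlap links exactly the true replicate pairs.

**Counts.** Tn5 counts are negative binomial with Var = μ + αμ², α = 0.05,
per-sample means scaled by library-size factors (geometric mean one).  Peak
base means are log-normal (log2 mean 7.6, sd 1.0; median ≈ 200).  Shared
peaks receive per-stage log2 intensity drift ~ N(0, 0.8) — the biological
stage-to-stage variability that makes the intensity–expression correlation
measurable — and a 25% subset additionally a ±2.5 log2 shift in one
designated stage (the planted differential-intensity effects).
Stage-specific peaks keep 5% of their base signal off-stage.

**Expression.** Mean log2 FPKM per gene and stage is baseline + coupling ×
accessibility + archetype offset.  The accessibility score of a gene sums,
over its promoter ACRs, `(length/400) × (1.5 + log2((μ_stage + 20) / 220))`:
a level term (promoter ACR presence lifts expression, more/longer ACRs lift
it more) plus a log-ratio term with near-unit slope in log2 intensity, so
expression responds symmetrically to intensity gains and losses.  The
coupling defaults to 1.0 (expression proportional to accessibility on the
log scale).  An earlier `log2(1 + μ/100)` form was rejected during design
because it compresses downward intensity changes below the |log2FC| > 1
detection threshold.

Eight expression archetypes are the eight distinct z-score shapes available
over three stages (each single-stage up/down plus the two monotone ramps),
scaled to a per-gene stage-sd of 2.5 log2 units; after per-gene z-scoring
they sit at distinct angles on the circle that 3-point z-profiles inhabit,
with a minimum separation comfortably above the measurement noise — which is
what makes k-means recovery (ARI ≥ 0.9) achievable.  140 genes receive
archetypes; genes hosting stage-specific promoter ACRs join the
stage-matched archetype with probability 0.8 (C1 for BBCH_11, C8 for
BBCH_13, C7 for BBCH_17), which plants the cluster-overlap association the
integration stage must find.  Remaining archetype slots are filled from
genes *without* shared promoter ACRs: archetypes model programme-driven
regulation, and keeping them off the accessibility-coupled stratum keeps the
two planted mechanisms separable (and the intensity–expression summary
interpretable).

Fifteen discordant genes are drawn from hosts of exactly one promoter ACR
carrying a planted intensity effect; their coupling sign is flipped —
accessibility up, expression down — emulating repressor binding without
modelling TF kinetics.  They draw baselines from the expressed stratum
(log2 FPKM 3.5 ± 0.6) because a repressed gene still has to clear the
expressed-gene filter to be observable as a DEG.  Restricting to
single-peak hosts avoids masking by a second, independently drifting
promoter peak (a failure mode observed during design).

Raw exon counts are NB draws around FPKM × exonic-kb × library-size / 1e6,
and the reported FPKM is recomputed from the sampled counts
(FPKM = 1e9 × count / (exonic length × library size)), so the two expression
surfaces are mutually consistent by construction.

**Fragments and sequences.** Fragment midpoints mix uniform background
(25%), peak-centred Gaussians weighted by stage intensity with promoter
peaks up-weighted 1.5× (55%), and an expression-weighted TSS pile-up (20%,
sd 150 bp); 40,000 fragments per sample.  The genome FASTA is uniform
random ACGT with IUPAC consensus motifs (TGACCA for archetype-1 genes,
CACGTG for archetype-7) instantiated in 80% of target promoter ACRs.

## Analysis methods

**Consolidation and specificity.** A stage's representative ACR set keeps
peaks overlapping (≥1 bp) between replicates, merged to union intervals with
per-sample counts summed.  Stage specificity labels overlap-connected
components of the tri-stage union by the set of stages contributing peaks:
one stage → specific, all three → common, exactly two → partial.  The
component formulation makes the three classes an exact partition of the
merged union.

**Permutation enrichment.** Observed category counts are compared with the
mean over permutations in which the observed regions are re-placed uniformly
(chromosome ∝ length, start uniform such that the region fits), with lengths
matched to the observed multiset (a fixed-width mode is provided, since a
real study might have used either).  One-sided empirical p-values use the +1
correction, so p ≥ 1/(n+1) and is never zero.  Placement does not mask
observed loci — with ACRs covering ~10% of the genome the induced bias on
the null mean is small, and masking is a documented non-goal.

**Chromosome density.** Normalized chromatin length = total peak count ×
chromosome length / genome length; Pearson r (and r²) against per-chromosome
peak counts.  On the default two-chromosome genome r is a trivial two-point
statistic, so density calibration uses five-chromosome simulations.

**Differential testing.** A self-contained DESeq2-style workflow:
median-of-ratios size factors rescaled to geometric mean one (library-size
fallback when no feature is everywhere-positive); per-feature pooled
within-group method-of-moments NB dispersions, shrunk 50/50 in log space
toward a log-linear mean–dispersion trend and floored at 1e-8; a Wald test
on the log fold change with delta-method standard errors; BH adjustment over
tested (not all-zero) features.  Significance requires adjusted p < 0.05 and
|log2FC| > 1; a 0.5 pseudocount enters only when a group mean is zero.  With
two replicates per group the dispersion estimate has one within-group degree
of freedom per group — the trend shrinkage is what keeps the null
calibrated (flagged fraction ≪ 5% in the null simulation); exact parity
with DESeq2's MAP estimator, Cook's filtering and independent filtering are
non-goals.  Differential peak intensity is tested on the *common* ACRs;
differential expression applies the same machinery to exon counts after the
expressed-gene filter (FPKM > 1 in all replicates of at least one stage; a
three-samples-overall variant is selectable).

**Promoter linkage.** An ACR is assigned to a gene when its classification
position falls in that gene's promoter window; overlapping-window conflicts
go to the nearest TSS (exact ties to all tied genes, flagged).  Group
comparisons use the two-sample Wilcoxon rank-sum test — the gene groups are
independent, so the paired signed-rank variant does not apply — with exact
enumeration for combined samples ≤12 and a tie- and continuity-corrected
normal approximation otherwise.  Length tertiles of single-ACR genes sort
stably by (length desc, gene id) and redistribute tie runs that straddle a
group boundary round-robin across the straddled groups, preserving group
sizes and input-order invariance.  Group comparisons in the analysis
scripts summarise each gene by its median FPKM across samples: the median is
robust to the archetype stage patterns, whose high stages would otherwise
inflate mean FPKM of ACR-less programme-driven genes.

**Clustering and integration.** The DEG union's per-gene stage means of
log2(FPKM+1) are z-scored and clustered by k-means (k = 8, 10 seeded starts,
best inertia); cluster numbers are mapped onto the configured archetype
patterns by Hungarian assignment of centroids to z-scored archetypes, making
labels deterministic and semantically stable.  Overlap of stage-specific-ACR
gene sets with clusters uses one-sided Fisher tests over the DEG union as
universe.  The DPI × DEG integration places each gene with ≥1 significant
promoter peak change and a significant expression call into a quadrant by
the two signs; genes with promoter peaks significant in both directions are
excluded and reported.  Motif enrichment scans IUPAC consensus strings
(both strands, 0 mismatches by default) over target vs background promoter
ACR sequences with a one-sided Fisher test at α = 0.01 — consensus scanning
replaces de novo discovery, which is out of scope; a PWM scanner is the
natural extension point.

## Numerical and degenerate-case choices

* Empirical p-values, BH adjustment and the hypergeometric tail all share
  fixed conventions (+1 correction; BH over tested features only; upper-tail
  `sf(k-1)`), each pinned by an oracle test.
* Fragments outside chromosome bounds are skipped with a counted warning;
  empty peak sets yield empty results with warnings rather than errors;
  zero-variance vectors raise rather than returning NaN correlations.
* The exact rank-sum branch enumerates all labelings (ties included) and
  reports 2·min(tails), capped at 1; the asymptotic branch applies tie and
  continuity corrections.  For a lattice statistic no smooth approximation
  attains uniform *relative* tail accuracy; the test suite therefore checks
  the asymptotic branch against exhaustive enumeration at 10% relative plus
  a 0.005 absolute guard, over every attainable 6v6 U value.
* K-means receives a fixed `random_state`; all pipeline randomness descends
  from explicit seeds, and two runs at the same seed are byte-identical.

## Problem sizes

The default dataset — 2 Mb genome, 300 genes, 600 planted ACRs, six samples,
240k fragments — generates in seconds and carries enough events per planted
structure (100 stage-specific peaks, 125 intensity effects, 140 archetype
genes, 15 discordant genes) for recovery rates to be meaningful.
Calibration studies use 2000-feature count matrices and 2000 permutations;
at those sizes Monte-Carlo standard errors are small relative to every
tolerance tested.

## What passing does and does not show

The generator plants exactly the structures the analysis is designed to
detect, under the analysis's own model family (NB counts, log-linear
coupling, Gaussian drift).  Passing therefore demonstrates correctness of
the implementations and adequate power/calibration at the stated effect
sizes — not robustness to real-data pathologies the generator omits: Tn5
sequence bias, duplicate and organellar reads, GC/mappability structure,
peak-calling artifacts, isoform switching, or batch effects.  Recovery rates
near one reflect the deliberately well-separated planted effects (jitter far
below peak spacing, |log2FC| well above threshold); they are upper bounds,
not forecasts, for real libraries.
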