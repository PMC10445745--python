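# Methods

`ovfield` reconstructs, as a tested pipeline, the computational analysis of
an eye-field (EF) cell-state transition in optic-vesicle organoid
differentiation: time-course bulk RNA-seq (days 0–5, triplicates, with a
GFP reporter sort at days 4–5) integrated with time-course ATAC-seq
(days 0, 1, 2, 3 and 5) to nominate the transcription factors (TFs) and
candidate cis-regulatory elements (CREs) driving the transition.  Because
the pipeline's statistical behaviour cannot be validated without ground
truth, the package ships a first-class synthetic-data generator that plants
known gene programmes, TF roles, peak dynamics and per-bp footprints, and
every downstream stage is scored against that truth table.

## Analysis stages

**Expression gating.**  Counts are normalized with median-of-ratios size
factors (per-sample factor = median over genes, expressed in all samples,
of the count over the gene's geometric mean; factors re-scaled to unit
geometric mean).  Differential expression is a deliberately transparent
engine: log2 fold changes of pseudocounted group means, Welch's t-test on
log2(normalized + 1) per replicate, and Benjamini–Hochberg FDR.  This
replaces a negative-binomial GLM with shrunk fold changes; the gating
semantics (thresholds on FDR and log2FC) are identical, but absolute gene
counts from an NB-GLM engine on real data would differ.  EF-up genes must
pass *all three* sorted contrasts — day 3 vs day 4 GFP+, day 4 GFP− vs
GFP+, day 5 GFP− vs GFP+ — at FDR < 0.001 and log2FC > 1.5 (both strict);
EF-down genes are the mirror image.  Housekeeping genes satisfy
|log2FC| < 0.1 for every successive-day comparison (GFP+ branch at days
4–5) and mean normalized expression > 30.

**Trajectory clustering.**  Replicate-averaged log2 trajectories of the
EF-up ∪ EF-down genes are z-scored per gene; for each k in 2–10 a
full-covariance Gaussian mixture is fitted with 20 seeded initializations
(ridge 1e-6, escalated on singular fits), k is chosen by minimum mean BIC,
and final labels come from consensus over the per-seed partitions
(co-association matrix, average-linkage cut at k).  Consensus is invariant
to per-seed label permutations by construction.  Cluster mean trajectories
are mapped to three qualitative patterns with an explicit rule (δ = 0.5
z-units): steep post-day-3 rise peaking at the end (`up_after_d3`); a rise
to an interior peak at or before day 3 followed by repression
(`transient`); otherwise `gradual_down`.  A monotone decline peaks at day
0 and is therefore gradual, not transient.

**Chromatin landscape.**  Consensus peaks are the union-merge of per-day
peak sets (touching intervals merge), minus blacklist overlaps.
Accessibility is library-scaled per day to a fixed total (so rescaling one
day's signal leaves its normalized values unchanged), logged, and
de-trended for GC content and peak width: the covariate trend is the
median of the *across-day mean* log signal per (GC-decile × width-decile)
bin, subtracted uniformly from every day and re-centred.  Estimating the
trend on the time-mean rather than per day keeps within-peak day-to-day
differences — the quantity every downstream stage consumes — exactly
intact while removing static sequence-composition bias; sparse 2-D bins
fall back to marginal decile corrections.  Dynamic peaks between days 3
and 5 use |Δlog2| > 1.5 (strict); the motif-importance model uses a looser
|Δlog2| > 1 universe.  Peaks are annotated promoter → exonic → intronic →
intergenic in that precedence (promoter = TSS ± 1 kb, configurable).
TADs are inputs; gaps between adjacent TADs are synthesized as first-class
regions (genes can and do fall between TAD calls), peaks join regions by
midpoint and genes by TSS, and a region carries every class label whose
gene set it intersects — a region holding both up- and down-regulated
genes is dual-labelled, and "pure" housekeeping regions (housekeeping
label only) serve as backgrounds.  Region–gene links use a
basal-plus-extension rule: 5 kb upstream / 1 kb downstream basal domains,
extended to the nearest neighbouring basal domain, capped at 1 Mb.

**Motif analysis.**  PWMs are log2((PFM + 0.1)/column total / background)
with uniform background by default.  Scanning reports, per position, the
best strand (max-strand semantics) with an exact p-value computed by
dynamic programming over the integer-rounded score distribution (~1000-bin
lattice); the DP tail probabilities equal exhaustive 4^w enumeration on
the same lattice, which the tests verify.  TFs count as expressed if
replicate-mean normalized expression exceeds 50 (strict) at any timepoint.
Per-TF presence collapses all of a TF's motifs into one binary feature per
peak.  Enrichment is a hypergeometric upper tail of presence in
opening (or closing) peaks against pure-housekeeping-TAD peaks, with
Haldane's +0.5 odds-ratio correction for empty cells.  Motif importance is
an L2 logistic model predicting opening vs closing peaks: λ chosen from 13
log-spaced values in [1e-3, 1e3] by mean held-out log-loss over stratified
5-fold CV with balanced class weights, then coefficients averaged over 10
seeded refits on all peaks.

**Expression–accessibility correlation.**  For each expressed TF and each
peak containing its motif, Pearson r between the TF's replicate-mean
expression and the peak's normalized accessibility over the matched days
{0, 1, 2, 3, 5} (GFP+ branch at day 5; day 4 has no accessibility).
Pearson on five matched points follows the linear-correlation framing of
the approaches this stage mirrors; it is a config choice.  Per TAD class,
each TF's correlations are split by sign and each side is tested
(two-sided Wilcoxon rank-sum) against the same TF's correlations in pure
housekeeping TADs; activator-like requires median positive-side r > 0.5
and p < 1e-10, repressor-like the mirror.  An expression-permutation null
(timepoint labels shuffled) is available as a second background; the
housekeeping-TAD null is the default for calls.

**Footprinting.**  From per-bp bias-corrected tracks (assumed corrected
upstream; the generator produces them corrected by construction), the
central region is ±12 bp around the motif centre (centre = offset +
width // 2; minus-strand windows reversed), flanking accessibility is the
mean over the 60 bp either side, and footprint depth is central mean minus
flanking accessibility (bound sites are depletions, depth < 0).
Aggregate profiles average ±100 bp windows across occurrences.  The
per-occurrence score is an explicit monotone substitute for a
binding-score framework that is used only ordinally downstream:
score = 0.3·norm_llr + 0.7·(flank − centre), with norm_llr the motif's
log-likelihood ratio min–max scaled over its occurrence set; weights are
configurable.  Bound/unbound classification fits a two-component 1-D
Gaussian mixture per motif per day (posterior > 0.5; degenerate or
effectively unimodal fits call everything unbound).  Differential binding
standardizes per-motif mean score changes across motifs (z mean 0, sd 1 by
construction) with a normal tail p.  Footprint–expression correlation is
the per-motif median Pearson r of occurrence-score trajectories against
TF expression, reported separately for EF-up-TAD and genome-wide
occurrences.

**CRE prioritization.**  For a target gene, the change matrix restricts to
peaks in the gene's TAD or gap region, with per-peak, per-key-TF median
occurrence-score changes between two days (key TFs default to Rax, Pax6,
Lhx2, Sox2, Otx2, Tcf3, Tcf7, Tcf7l2; absent motifs are flagged, not
zero-filled), plus accessibility change and signed TSS distance.  The
ranking score — sum of positive key-TF changes, ties broken by
accessibility change then TSS proximity — is an explicit formalization of
what is, in practice, expert inspection of such heatmaps; external
evidence boosts are out of scope.  It is invariant to any uniform
increasing rescaling of the changes.  Deletion intervals minimally cover
the selected motif instances, padded 10 bp (enough for core plus flanking
bases of the disrupted motifs) and clipped to the peak; all coordinates
are 0-based half-open, so interval length is end − start, consistent with
the 113 bp and 140 bp candidate deletions.  WT vs perturbed expression is
compared with Welch's two-sided t-test on replicate log2 values and the
percent change of mean log2 expression.

## Synthetic data: what it emulates, and what it does not

The generator builds 15 TADs of 64 kb on 5 chromosomes (12 kb inter-TAD
gaps), 30 genes and 48 peaks per TAD, and plants, by TAD type: EF-up TADs
(steeply upregulated genes, 80% opening peaks), EF-down TADs (gradually
downregulated plus transient genes, 80% closing peaks) and housekeeping
TADs (stable genes, static peaks).  A 12-TF panel carries planted roles —
activators Rax/Pax6/Lhx2 (upregulated), repressors Pou5f1/Nanog/Zfp42
(downregulated), and six inert broadly-expressed TFs (Sox2, Otx2, Tcf3,
Tcf7, Tcf7l2, Six3) — each with a fixed width-8 consensus motif (Rax has
two, to exercise per-TF collapse), embedded as exact consensus copies so
scan recovery is unambiguous.  Embedding rates (activator motifs in 75% of
opening vs 15% of closing peaks; repressors 55%/90%; inert 50% of dynamic
and 35% of static peaks) were chosen so that every statistic the pipeline
computes has a planted effect comfortably above its decision threshold at
the realized sample sizes.  One target gene per activator TF carries a
dedicated wide (1.2 kb) planted CRE whose six key-TF motifs are bound at
day 5; the Rax gene and its CRE sit in an inter-TAD gap, exercising the
gap-region path.  Bound motif instances are spaced ≥150 bp apart so one
footprint never contaminates another's measurement windows.

Noise models: negative-binomial counts (mean–dispersion parameterization,
dispersion 2e-4) with log-normal per-sample library factors; log-normal
multiplicative peak-signal noise with a planted GC bias and width effect
(removed by normalization); Poisson per-bp track noise around the day
level, with bound occurrences carrying a central depletion (80% of the
planted depth) and flanking boost (20%), so recorded depth equals the
expected centre-minus-flank measurement.  All randomness flows from one
`numpy.random.default_rng` (PCG64) seed through `SeedSequence` spawning;
identical seeds give byte-identical outputs.

Deliberate departures from real data, and hence limits on what green tests
show: counts are far less overdispersed than real RNA-seq (dispersion 2e-4
vs typical 0.01–0.1) because the transparent Welch-based DE engine lacks
the variance moderation of an NB-GLM — planted contrasts are designed to
be decisively detectable with triplicates, so passing tests validate the
gating logic, not the engine's power on noisy data.  Motifs are embedded
as exact consensus (no PWM sampling, no degenerate sites); peaks never
overlap; fragment-level ATAC simulation, Tn5 sequence bias and day-4
accessibility batch effects are not modelled (day 4 is simply absent, as
in the study design).  Planted effect magnitudes are preset parameters,
not claims about real organoid data.

## Numerical choices

Strict inequalities at every published gate (a gene at FDR exactly 0.001
or |log2FC| exactly 1.5 fails).  Pseudocount 1 normalized count keeps fold
changes finite.  Welch p-values are NaN-guarded to 1 for identical groups.
Mann–Whitney tests use exact enumeration for groups of ≤8 and the
tie-corrected normal approximation otherwise.  Zero-variance trajectories
are excluded from clustering and reported; constant accessibility or
expression vectors are dropped from correlation with a counter.  GMM
singular fits retry with ridge 1e-3 then 1e-1.  Peak–region membership by
midpoint guarantees a unique region per peak; a midpoint on a half-open
boundary belongs to the region starting there.  Deletion-interval clipping
to the peak is logged.

## Problem sizes

The default preset (15 TADs × 48 peaks, 466 genes, ~340 kb of peak
sequence, five per-bp tracks) runs the full pipeline in well under a
minute on one core; the CRE-stability analysis repeats the
simulation-and-rank path over 20 seeds.  The `small` preset (6 TADs,
14 genes and 12 peaks per TAD) exercises every code path in about a
second and backs the cheaper tests.

## Known limitations

The DE engine and the footprint score are documented substitutes: ordinal
conclusions (rankings, signs, threshold calls) transfer; absolute values
do not.  The consensus-clustering cut and the three-pattern rule are this
package's formalizations of verbally described procedures.  The
expression–accessibility background and the CRE ranking rule are module
choices surfaced in config, since no canonical definition exists for
either.  Correlations on five timepoints are individually unstable; the
pipeline only ever interprets their distributions, never single values.
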