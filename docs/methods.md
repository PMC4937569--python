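# Methods

## Enrichment calling from oligo(dT)-capture proteomics

UV irradiation covalently fixes proteins to the RNA they touch; oligo(dT)
beads then pull down poly(A)+ RNA together with crosslinked proteins, while
a non-irradiated control measures what sticks to beads and RNA without a
covalent bond.  The filter calls a protein RNA-bound in one method when it
has at least `min_peptides` (default 2) unique peptides in the crosslinked
sample and a CL/noCL intensity ratio strictly greater than `fold_threshold`
(default 10; "greater than 10-fold" means the ratio of exactly 10 fails).
Ratios are computed on raw intensities, not logs.

**Missing-value policy.**  MS missingness is left-censored detection, so an
undetected measurement is an absent record, never a zero.  A protein
detected in CL (with enough peptides) but absent or zero in the noCL
control passes the ratio criterion: absence from the control is the
strongest enrichment evidence a censored measurement can give.  Callers who
prefer finite ratios can pass `pseudocount`, which switches to
`cl / (noncl + pseudocount)` with missing noCL treated as zero.

**iBAQ enrichment classes.**  Abundance enrichment is the per-method
`ibaq_pulldown / ibaq_whole` ratio averaged over the methods where both
values exist — arithmetic mean by default ("mean" alone does not determine
the kind; geometric is available via `mean="geometric"`).  Class boundaries
partition the ratio axis: high strictly above 10, middle the closed
interval [1, 10], low strictly below 1; a protein never detected in the
whole-embryo proteome is `undetermined` rather than being forced into a
class.

## RBP classification and term enrichment

The cascade is evaluated in fixed order — known (RBD or RNA-binding GO),
then inferred (interactome ortholog, census ortholog, or RNA-related GO),
then new — so every gene gets exactly one label and the first branch that
matches wins.  The RBD domain list and the RNA-binding / RNA-related GO
term lists are *input vocabularies* (TSV), not hard-coded: they come from
curated external catalogs in real use, and `AnnotationCatalog.from_annotations`
derives the boolean flags from raw GO/Pfam sets plus those vocabularies.

Enrichment tests are one-sided (enrichment direction) Fisher exact tests;
published enrichment figures in this field report the enrichment tail, and
a two-sided flag is available.  The 2×2 table for a term is (foreground
carriers, foreground non-carriers, background-only carriers,
background-only non-carriers); fold change is foreground frequency over
(inclusive) background frequency and `recovery_pct` is foreground carriers
over all background carriers.  Terms with zero background count are skipped
(undefined contingency).  Domain tests are Bonferroni-corrected (few,
strongly dependent tests), GO tests Benjamini–Hochberg (many tests, FDR
scale), both via `statsmodels.multipletests`.

## Isoelectric point

Net charge at a given pH sums Henderson–Hasselbalch terms over the
ionizable side chains (C, D, E, H, K, R, Y) and the two termini; the pI is
the unique zero crossing in [0, 14], found by bisection to |charge| < 1e-4
(configurable — note the charge curve is nearly flat around neutral pI, so
a charge tolerance of 1e-4 localizes the pH only to about ±0.01).  The pKa
table is a parameter with EMBOSS defaults; published tables differ by a few
tenths of a unit, and since the score is used comparatively (RBPs skew
basic relative to the whole proteome) the choice shifts all values
together.

## Temporal clustering and the specificity score

Profiles are z-scored genewise on FPKM+1 with the sample (n−1) standard
deviation; a `--log2` option z-scores log2(FPKM+1) instead, since absolute
expression is usually displayed on the log scale and both inputs are
defensible for clustering.  Zero-variance genes cannot be standardized and
are excluded (and reported) rather than imputed.

`FuzzyCMeans` implements Bezdek's alternating optimization: memberships
`u_ik = 1 / Σ_j (d_ik/d_jk)^(2/(m−1))` with Euclidean distance, centers as
`u^m`-weighted means, stopping when the largest center displacement falls
below `tol` (1e-6).  The fuzzifier default m = 1.23 gives hard, condensed
clusters (the membership exponent 2/(m−1) ≈ 8.7); c defaults to 6.
Initialization draws c distinct data rows under the seed, with 5 restarts
keeping the lowest objective, because fuzzy c-means is only locally
convergent.  The objective Σ u^m d² is mathematically non-increasing under
the alternating updates, and `fit` asserts this every iteration as a guard
against implementation error.  A point coincident with one or more centers
splits its membership equally among the coincident centers (the limit of
the update rule).  Hard assignment is argmax membership with ties broken
toward the lowest cluster index.

**Two-step cluster enrichment.**  MS detection favors highly expressed
genes, so asking directly "are mRBPome genes over-represented in cluster
k of the transcriptome?" confounds RNA binding with abundance.  Step 1
tests proteome membership against cluster membership over the
transcriptome (capturing the detection bias); step 2 tests mRBPome
membership over the proteome only, so step 2's background already carries
the bias.  P-values are BH-adjusted across clusters within each step.
The exact contingency construction is this package's definition.

**DSSS.**  With x_i = FPKM_i + 1 and p_i = x_i/Σx, DSSS = log2(N) − H(p).
The +1 shift bounds the score: an all-zero gene gives a uniform x, hence
DSSS = 0, and a single-stage spike approaches but never reaches log2(N)
(4.907 bits for a 10⁶-FPKM spike over 30 stages, under the 5-bit ceiling
quoted for N = 30).  The stage-specific threshold is inclusive (DSSS ≥ 1).

## Localization enrichment

Per (term, window): observed is the subset's carrier count, expected is
subset size × database carrier frequency, fold = observed/expected.  The
empirical P is `(#{null samples with count ≥ observed} + 1) / (n_samples + 1)`
with null subsets drawn uniformly *without replacement* from the annotated
database at the subset's size — the subset is itself a fixed set of genes,
so sampling without replacement from the annotation frame is the matching
null.  The inclusive ≥ and add-one correction are the standard permutation
conventions (P is never 0 and never anti-conservative).  Subset genes
absent from the database are dropped and logged; output headers record
`n_samples` and the seed.

A consequence of the inclusive add-one convention: when the carrier-count
statistic is coarse (small subsets, rare terms), the empirical P is
noticeably conservative and its null distribution is a coarse step
function, not uniform.  Calibration tests therefore use configurations
where the statistic has fine granularity (balanced term frequencies, large
subsets); with coarse statistics one should expect conservative, not
uniform, null P-values.

Odds ratios between two subsets use the 2×2 (carriers/non-carriers ×
subset A/subset B) sample odds ratio with the Haldane–Anscombe +0.5
correction applied to all cells when any cell is zero.

## Simplified CLIP statistics

Reads are assigned exactly one category by a fixed priority
(mRNA_exon > mRNA_intron > lincRNA > tRNA > snRNA > snoRNA > miRNA >
TES_downstream > intergenic) using any-overlap on the matching strand;
reads on unannotated contigs are intergenic.  The hierarchy is this
package's reproducible definition — exons outrank introns so that
junction-spanning reads count as mature mRNA, and the downstream-of-TES
window (default 500 bases, strand-aware) captures nascent-transcript
binding past annotated ends.  RPM ratios use a 1-RPM pseudocount; RPKM
ratios (length-normalized, so category length cancels in the ratio) use a
0.01-RPKM pseudocount; both are recorded in the outputs.  k-mer analysis
samples reads without replacement, counts overlapping k-mers, and reports
frequencies per 10⁶ sampled bases.  GTF-derived indexes take
protein-coding exons, the gaps between consecutive exons as introns, TES
windows per transcript, and whole gene spans for noncoding biotypes.

## Synthetic data: what it emulates and what it does not

The MS generator draws a log-normal baseline per protein (ln-scale mean 21,
sd 1.5 — raw intensities around 10⁸–10¹⁰), gives true RBPs (default 25% of
2000 proteins) a log-scale crosslink enrichment around ln 50 (sd 0.5)
shared between the two methods through a single latent factor
(`method_correlation`, default 0.77), and leaves contaminants (5%) and
background at CL≈noCL parity.  Per-measurement log-noise
(`measurement_noise_sd` = 0.2) keeps the intensity clouds realistic; note
it dilutes the *observed* ratio correlation below the latent parameter.
Unique peptide counts are 1 + Poisson(rate − 1), so detection implies at
least one peptide; dropout removes whole records per table, plus the noCL
measurement independently, mirroring censored detection.  Under the
default strong-signal, no-dropout configuration the 2-peptide/10-fold
filter recovers ≥ 95% of true RBPs with ≤ 1% contaminant false positives
(bounds estimated by direct Monte-Carlo simulation over 10 seeds at
n = 2000 and frozen in the tests).

The annotation generator is *constructive*: it places flags so that the
cascade reproduces requested class counts exactly, which turns
classification arithmetic into a checkable identity.  The expression
generator uses six staggered Gaussian-bump prototypes over twelve 2-h
windows (amplitude 50 FPKM, truncated at 0) plus optional single-stage
spike genes; the localization generator assigns one multinomial term per
gene per window (early window 88% ubiquitous, later window 58%,
matching the qualitative early-vs-late restriction pattern of embryonic
in situ databases) with an optional planted subset whose term probability
is multiplied by a fold factor.

None of the generators emulate: peptide-level identification noise, shared
peptides, between-run normalization drift, correlated GO/domain
co-annotation structure, autocorrelated expression noise, or multi-term
localization patterns per window.  Passing tests therefore demonstrate the
*statistical machinery* — filters, set logic, exact tests, resampling,
clustering — under the model's assumptions, not robustness to every
artifact of real MS or FISH data.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to make sampling
error small relative to the tested margins: 2000-protein MS simulations
(10 seeds for the sensitivity bound), 500-replicate calibration with
199-sample empirical P on a 5000-gene database, exhaustive Fisher checks
over all 2×2 tables with total ≤ 30, 10⁵ random profiles for the DSSS
bound, and exhaustive C(8,3) enumeration for the resampling-P oracle.
Floating-point comparisons in tests use absolute tolerances stated inline
(1e-10 for entropy identities, 1e-9 for membership row sums).

## Known limitations

- The enrichment filter has no variance model; a single noisy intensity
  pair decides a call.  The original-scale analysis inherits the same
  property.
- Fuzzy c-means at m close to 1 behaves nearly like k-means and can lock
  onto duplicated rows; initialization from distinct rows plus restarts
  mitigates but does not remove local minima.
- GO terms are flat sets (no ontology propagation); enrichment of parent
  terms must be provided pre-propagated in the catalog.
- The CLIP module is an explicitly simplified re-definition: no peak
  calling, no crosslink-site diagnostics, and a documented but arbitrary
  category hierarchy.
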