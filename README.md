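# rbpome

Analysis pipeline for **mRNA interactome capture** experiments in early
*Drosophila* embryos (and, in general, any two-method UV-crosslink /
oligo(dT)-capture proteomics design): calling RNA-bound proteins from
crosslinked vs non-crosslinked pull-down intensities, classifying them as
known / inferred / new RNA-binding proteins (RBPs), clustering their
developmental expression, scoring stage specificity, and measuring
enrichment of embryonic transcript-localization terms.  A synthetic-data
module generates every input with the statistical structure the analysis
assumes, so the whole pipeline runs end to end without any downloads.

## What it computes

- **Enrichment calling** (`rbpome.interactome`).  A protein is called
  RNA-bound in one crosslinking method (conventional 254-nm cCL, or
  4SU-enhanced 365-nm PAR-CL) when it has ≥ 2 unique peptides in the
  crosslinked (CL) sample and > 10-fold CL/noCL intensity (absence from
  the noCL control counts as enrichment).  Per-method call sets combine by
  set logic into the high-confidence intersection ("mRBPome"), the union,
  and the unique (symmetric-difference) set.  Proteins are graded by their
  mean pull-down/whole-embryo iBAQ ratio into high (> 10×), middle
  (1–10×), and low (< 1×) abundance-enrichment classes.
- **RBP classification** (`rbpome.classify`).  Cascade: *known* = carries
  an RNA-binding domain (Pfam RBD catalog) or the RNA-binding GO term;
  *inferred* = mammalian mRNA-interactome/census ortholog or RNA-related
  GO; *new* = neither.  GO and Pfam enrichment of a foreground against an
  expressed-gene background uses one-sided Fisher exact tests with
  Benjamini–Hochberg (GO) or Bonferroni (domains) correction.
- **Sequence features** (`rbpome.features`).  Isoelectric point by
  Henderson–Hasselbalch bisection over a configurable pKa table, and
  amino-acid composition including the combined R+K+G fraction.
- **Temporal dynamics** (`rbpome.temporal`).  Genewise z-scoring of
  FPKM+1 profiles, fuzzy c-means clustering (`FuzzyCMeans`, a
  scikit-learn-style estimator; default c = 6, fuzzifier m = 1.23),
  two-step Fisher cluster enrichment (proteome vs transcriptome, then
  mRBPome vs proteome, to absorb MS abundance bias), and the
  **Developmental Stage Specificity Score**

  ```
  DSSS = log2(N) − H_obs ,   H_obs = −Σ p_i log2 p_i ,   p_i = (FPKM_i + 1) / Σ (FPKM_j + 1)
  ```

  which is 0 for uniform expression and approaches log2(N) for a
  single-stage spike (≤ 5 bits for N = 30 stages).
- **Localization enrichment** (`rbpome.localization`).  Per
  (term, stage-window): fold change vs database frequency and an add-one
  empirical P from random same-size subsets drawn without replacement;
  subset-vs-subset odds ratios with Haldane–Anscombe correction.
- **CLIP profiles** (`rbpome.clip`).  Simplified CLIP-vs-input statistics:
  per-RNA-class RPM ratios, per-category RPKM ratios, and 5-mer
  enrichment of sampled reads, with a fixed category priority
  (mRNA exon > intron > lincRNA > tRNA > snRNA > snoRNA > miRNA >
  TES-downstream > intergenic).

## Worked example

```sh
cat > config.yaml <<'EOF'
ms: {n_proteins: 2000, seed: 11}
annotations: {class_counts: [285, 56, 36, 99], rbd_within_known: 273, go_within_rbd: 137, seed: 11}
expression: {n_genes: 1200, frac_specific: 0.03, seed: 11}
localization: {n_genes: 4767, planted_subset_size: 100, planted_fold: 5.0, seed: 11}
EOF
rbpome simulate --config config.yaml --outdir sim
rbpome call-rbps --ccl sim/quant_cCL.tsv --parcl sim/quant_PARCL.tsv \
                 --whole sim/whole_proteome.tsv --out rbps.tsv
rbpome classify  --catalog sim/catalog.tsv --genes genes.txt --out classes.tsv
rbpome cluster   --expr sim/expression.tsv -c 6 --seed 7 --out clusters.tsv
rbpome dsss      --expr sim/expression.tsv --out dsss.tsv
rbpome loc-enrich --db sim/localization.tsv --subset sim/planted_subset.txt \
                  --n-samples 1000 --seed 11 --out loc.tsv
```

prints

```
cCL=527 PAR-CL=529 mRBPome=431 union=625 unique=194
known=285 inferred=92 new=99
clustered 1200 genes into 6 clusters (m=1.23, seed=7, 0 zero-variance excluded, converged=True)
352 genes (29.3%) with DSSS >= 1.0
stages_1-3: 16 restricted (16.0%)
stages_4-5: 59 restricted (59.0%)
```

Reading: of 2000 simulated proteins (25% true RBPs), 527 and 529 pass the
two-peptide / > 10-fold filter per method and 431 in both — the synthetic
mRBPome.  A 476-gene catalog built with counts (285, 56, 36, 99) classifies
back to exactly those class sizes.  The planted localization subset shows
~5-fold posterior enrichment with empirical P ≈ 0.001 (the floor at 1000
samples):

```
term       window      observed  expected  fold     p_emp
posterior  stages_4-5  38        7.38      5.15     0.000999
```

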