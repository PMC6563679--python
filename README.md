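# dcoexnet

Differential co-expression network analysis for two-phenotype expression
cohorts, with dense-module detection and survival-based prognosis.

The motivating problem is the invasive versus non-invasive contrast in
non-functioning pituitary adenoma: invasion into surrounding structures is
what makes an otherwise benign tumor recur and resist treatment, and single
differentially expressed genes have not produced reliable prognostic
markers. The alternative pursued here is *differential co-expression*:
gene pairs whose correlation changes between phenotypes point to regulatory
rewiring, and dense clusters of such pairs form candidate prognostic
modules. `dcoexnet` implements that full analysis as a tested, reusable
pipeline for anyone with a gene × sample intensity matrix and a two-group
phenotype label — plus a synthetic-data generator with planted structure so
every stage can be validated against ground truth.

## Method

Starting from a quantile-normalized matrix `X` (genes × samples) with
phenotype labels and follow-up data:

1. **Differential expression.** Per-gene moderated t-test on log2 values
   (empirical-Bayes variance shrinkage, with a Welch t-test as
   cross-check), Benjamini–Hochberg FDR; genes with adjusted p < 0.05 and a
   linear fold change outside [0.9, 1.1] are the DEGs.
2. **Phenotype-specific networks.** For every DEG pair, the Pearson
   correlation r and its two-sided p-value are computed separately in each
   phenotype's samples (p-values BH-adjusted over all pairs within a
   phenotype). A pair is co-expressed in a phenotype when |r| ≥ 0.80 and
   adjusted p ≤ 0.05, and differentially co-expressed when

   D = |(r_noninv − r_inv) / r_inv| ≥ 1

   (infinite, and kept, when r_inv = 0). Pairs that are co-expressed in a
   phenotype *and* pass the D criterion form that phenotype's network
   (ICON for invasive, NICON for non-invasive), summarized by degree,
   betweenness, clustering coefficient, Freeman degree centralization, and
   hub genes.
3. **Module detection.** A from-scratch re-implementation of MCODE
   (vertex weight = core level × density of the closed neighborhood's
   highest k-core; greedy seeded expansion at vertex-weight percentage 0.2;
   haircut; 2-core filter). Modules are kept when they have ≥ 10 genes,
   average within-module connectivity ≥ 10, and clustering coefficient
   ≥ 0.5.
4. **Core module.** Selected modules are merged and their edges recomputed
   at a tightened cutoff |r| ≥ 0.90 in the phenotype where they are active;
   the largest connected component of the surviving edges is the core
   module.
5. **Prognosis.** Samples are projected on the principal components of the
   core genes' expression (components retained to ≥ 85% variance),
   clustered by k-means (k = 3 on the first 3 PCs), and compared by
   Kaplan–Meier curves, the k-sample log-rank test, and a Cox
   proportional-hazards fit between the extreme clusters (lowest vs highest
   mean PC1). A signature-based prognostic index (Cox linear predictor,
   median split into low/high risk) supports validation on external
   cohorts.
6. **Enrichment.** One-sided hypergeometric over-representation of any gene
   list against local GMT collections, BH-adjusted, significant at adjusted
   p < 0.01.

## Worked example

Simulate a 2,000-gene cohort (22 invasive / 18 non-invasive samples) with a
planted 15-gene block co-expressed at r = 0.9 in the non-invasive group and
r = 0.1 in the invasive group, 10% DEGs at 1.5-fold, then run the full
pipeline:

```bash
dcoexnet simulate --n-genes 2000 --seed 1 --block 15,0.9,0.1 \
    --deg-fraction 0.1 --true-hr 3.0 --out sim
dcoexnet run-all sim/expression.tsv sim/metadata.tsv --seed 1 --out results
```

```
dcoexnet INFO normalized 2000 genes x 40 samples
dcoexnet INFO DEG stage: 191 of 2000 genes called
dcoexnet INFO ICON: 0 links among 0 genes
dcoexnet INFO NICON: 99 links among 17 genes
dcoexnet INFO modules: 1 detected, 1 pass filters
dcoexnet INFO core module: 13 genes at |r| >= 0.90
bundle written to results/bundle.json
core module genes: 13
```

Reading `results/bundle.json`: 191 genes pass the DEG gates (the 200
planted DEGs minus misses, plus a few false calls at the controlled FDR);
the non-invasive network contains 17 genes — the planted block plus two
stragglers — while the invasive network is empty, exactly the planted
asymmetry; one module passes the filters, and tightening the cutoff to 0.90
leaves a 13-gene core, all members of the planted block (ids `G00000` …
`G00014`). PC1 of the core explains 82.3% of the variance and separates
the phenotypes (silhouette 0.35). With only 40 samples the extreme-cluster
hazard ratio is estimated very noisily (HR 1.35, CI [0.45, 4.00]); the
survival machinery's calibration and power are measured at larger n by the
reproduction script below.

Every stage is also callable as a library function
(`dcoexnet.preprocess`, `.coexnet`, `.moddetect`, `.coremod`,
`.prognosis`, `.enrich`, `.simdata`) or as an individual subcommand
(`normalize`, `deg`, `network`, `modules`, `core`, `prognosis`, `enrich`).

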