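# Methods

## Model and procedure

The pipeline treats differential co-expression as the primary signal: a
gene pair's Pearson correlation is estimated separately within each
phenotype's samples, and the relative change

    D = |(r_noninv − r_inv) / r_inv|

quantifies rewiring between the non-invasive and invasive state. The
analysis assumes (i) a single two-group contrast on linear-scale,
non-negative intensities; (ii) enough samples per phenotype (≥ 4) for the
correlation t-transform p-value, `t = r·sqrt((n−2)/(1−r²))` on n−2 df, to
be meaningful; and (iii) that hard thresholding of |r| — not soft
WGCNA-style weighting — defines edges.

Stage order and the rules that are not forced by the statistics:

- **DEG gate before network construction.** Only genes passing the
  adjusted-p and fold-change gates enter the pair scoring. Fold change is
  the linear-scale ratio of group means (invasive/non-invasive) so that the
  10%-change gates (0.9/1.1) act on ratios, while the tests run on
  log2(x+1), which stabilizes variances. The moderated t follows the
  standard empirical-Bayes formulation: per-gene pooled variances are
  shrunk toward an inverse-chi-square prior whose degrees of freedom and
  scale are estimated by moment matching on log variances (trigamma
  inversion by Newton iteration; when the observed variances show no excess
  dispersion the prior df is infinite and the prior scale is the mean
  variance, and the total df is capped at the pooled residual df). The
  implementation is cross-checked against Bioconductor limma through
  Rscript in the test suite and agrees to machine precision.
- **BH pool for edge p-values** = all scored DEG pairs within one
  phenotype. Scoring pools per phenotype keeps the two networks'
  multiplicity corrections independent, which is what the phenotype-specific
  network construction implies.
- **Network membership**: an edge enters a phenotype's network iff it is
  co-expressed in *that* phenotype (|r| ≥ 0.80, adjusted p ≤ 0.05, absolute
  r for the gate, signed r inside D) *and* passes D ≥ 1. This single
  differential edge set, restricted per phenotype, is what produces the
  characteristic asymmetry between the two networks when a module is active
  in only one state.
- **r_inv = 0 policy**: D is treated as +∞ and the pair kept — a pair
  uncorrelated in one state and co-expressed in the other is maximally
  differential.

## MCODE

Re-implemented from its published description with the Cytoscape defaults
(vertex weight percentage 0.2, haircut on, fluff off, minimum core 2, depth
limit 100). Weight(v) = k_max × density of the highest k-core of v's closed
neighborhood. Complexes grow greedily from the highest-weight unvisited
seed, admitting neighbors whose weight exceeds seed_weight × (1 − vwp);
each vertex joins at most one complex, and a vertex examined and rejected
for one complex remains available as a later seed. After the 2-core check
and haircut, a complex that has become disconnected is reduced to its
largest component so every reported module induces a connected subgraph.
All tie-breaks are (weight descending, gene id ascending), making the
output independent of edge input order. The complex score is density ×
size. Module statistics (average connectivity, clustering coefficient) are
computed on the module's induced subgraph: "average connectivity of a
module" most naturally refers to the subgraph its members span, not their
degrees in the parent network.

## Core module and subtype projection

The union of the selected modules is re-scored at |r| ≥ 0.90 in the
phenotype where the modules are active (non-invasive by default,
configurable), still requiring the differential criterion; the core module
is the node set of the largest connected component (ties broken by the
lexicographically smallest member). "Largest connected component" is the
concrete realization of "the minimal gene set retaining the discrimination
ability": it keeps the genes that remain mutually co-expressed at the
tighter cutoff and drops satellites. The refinement is monotone in the
cutoff (raising r_min can only shrink the edge set), which the tests assert.

PCA is computed on per-gene-centered expression of the gene set (samples as
observations, full SVD); components are sign-fixed so the
largest-magnitude loading is positive, and the retained prefix is the
smallest reaching 85% cumulative variance. Phenotype separation is scored
by the mean silhouette in retained-PC space — a quantitative stand-in for
"clearly separable in the PCA plot"; samples in singleton classes score 0.

## Survival analysis

Patients are clustered by k-means (k = 3, first 3 PCs, 25 restarts, best
inertia) and relabeled by increasing mean PC1, so cluster 0 is the low-PC1
extreme. Kaplan–Meier curves, the k-sample log-rank test (hypergeometric
variance), and Cox proportional-hazards fits use lifelines with Efron tie
handling (follow-up recorded in years produces ties); the extreme-cluster
hazard ratio contrasts cluster 0 against the highest cluster, oriented so
that HR > 1 means the low-PC1 cluster (invasive-like) has the higher
hazard. Monotone likelihood is flagged and the coefficient capped at |β| =
20. The survival event is recurrence/progression; records without an event
are administratively censored at their follow-up time.

The signature risk split computes a per-sample prognostic index Σ β_g·x_g
over standardized log2 signature-gene expression and splits the cohort at
the median. The β may come from a multivariate Cox fit on the cohort
itself, or be supplied as prespecified coefficients. These are *not*
equivalent inferentially: when the weights are refit on the same cohort
that is then split, the split direction is optimized against the cohort's
own survival noise, and simulation shows the downstream log-rank/Cox
inference is markedly optimistic (null CI coverage ~60–70% instead of
95%) — at any sample size, because the optimism comes from reusing the
data, not from estimation error. Calibrated inference therefore requires
weights learned elsewhere (the external-validation use case), and the test
suite asserts calibration exactly there while a companion test documents
the in-sample optimism.

## Synthetic data

The generator emulates a two-phenotype microarray cohort: 22 invasive and
18 non-invasive samples by default, follow-up uniform on 3–10.5 years,
gene count scalable (2,000 default as a scaled-down stand-in for a ~30k
feature array). Per-gene baseline log intensities are uniform on
[log 50, log 500]; intensities are exponentiated Gaussians, so they are
strictly positive and fold changes are multiplicative. Planted blocks use a
shared latent factor, x = sqrt(r)·z_block + sqrt(1−r)·ε, giving exact
compound symmetry at the target correlation per phenotype (negative r is
drawn by Cholesky and rejected when compound symmetry would be
non-positive-definite, r < −1/(m−1)). Planted DEGs shift the invasive
group's log mean by ±log(fc); block genes are down-regulated in the
invasive group, because the planted module plays the role of a program
active in the non-invasive state — this also puts the invasive samples at
the low-PC1 end, matching the orientation of the extreme-cluster contrast.
Survival times are exponential with hazard `baseline × HR^(risk group)`,
risk group = phenotype, censored by the uniform follow-up; tumor grade is
deterministic in the risk group (IV vs II).

Parameter defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| noise_sd | 0.3 (natural-log scale, ≈ 0.43 log2 SD) | typical within-group microarray spread; makes a 1.5-fold change reliably detectable at n = 22/18, consistent with the emulated platform resolving such effects |
| fc_effect | 1.5 | a moderate DEG effect at the gate scale (well outside the 0.9/1.1 gates) |
| deg_fraction | 0.1 | a tenth of the transcriptome responding, of the order seen in tumor contrasts |
| event_rate_baseline | 0.15 / year | moderate recurrence hazard: most low-risk patients remain event-free over a 3–10.5-year follow-up |
| true_hr | 1.0 | no survival signal unless the scenario plants one |

What the generator does **not** emulate: probe-level artifacts (dye bias,
spatial effects, background), heavy-tailed intensity noise, correlated
null structure beyond the planted blocks, non-proportional hazards, or
informative censoring. Passing tests therefore demonstrate that the
machinery recovers the structure it is designed for under idealized noise —
not that real cohorts of this size will yield equally clean modules.

## Numerical choices

- Quantile normalization maps average ranks onto the across-sample mean of
  order statistics; tied values receive the mean of their tied quantile
  values (linear interpolation at half-ranks), so a fully tied sample
  collapses to a constant.
- Correlations are clipped to [−1, 1] before the t-transform; |r| = 1 gives
  p = 0. Zero-variance genes are excluded from pair scoring with a warning,
  never silently dropped.
- Welch t with zero variance in both groups: p = 1 when the means agree,
  otherwise a variance floor (1e−12) is applied.
- BH adjustment delegates to statsmodels (`fdr_bh`), the standard step-up.
- k-means uses 25 restarts with a fixed seed; cluster labels are made
  deterministic by the PC1-mean relabeling.
- Cox fits: lifelines Newton solver; on convergence failure the fit is
  retried with a small ridge penalty (0.1) and flagged.
- Degree centralization uses Freeman's normalization
  Σ(d_max − d_v)/((N−1)(N−2)) and is reported as missing for N < 3; the
  network clustering coefficient averages local coefficients over nodes
  with degree ≥ 2.

## Test and reproduction problem sizes

The suite exercises the pipeline at desk scale: 2,000-gene cohorts for
end-to-end recovery (10 seeds), 100 sixty-node graphs for the MCODE/oracle
comparison, 1,000 replicates for log-rank calibration, 100 replicates of
500-per-arm cohorts for Cox coverage, 20 structureless cohorts for the null
control. These sizes give stable Monte-Carlo estimates while keeping a
full run in tens of seconds; all oracles (naive peeling, Goldberg max-flow
densest subgraph, permutation nulls, enumeration of hypergeometric tables,
limma via Rscript) are independent of the implementation paths they check.

## Known limitations

- The module filters (≥10 genes, average connectivity ≥10, CC ≥ 0.5) are
  strict for small modules: a fully recovered 15-gene block with ~85% edge
  survival sits near the connectivity boundary, so individual seeds can
  legitimately report no module; recovery claims are therefore made on
  medians over seeds.
- Module selection for the core merge ("similar discriminatory behavior")
  is not algorithmic; by default all filtered modules are merged, and the
  caller can restrict to specific module ids.
- The enrichment background defaults to all genes on the platform after
  collapse; other background choices change the hypergeometric margins.
- No multi-factor designs, partial correlations, overlapping (fluff)
  complexes, competing risks, or time-varying covariates.
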