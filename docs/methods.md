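# Methods

This note documents the statistical models, defaults and numerical choices
behind `nrf_targetscope`, and what the synthetic-data validation does and
does not establish about real data.

## Differential expression

Each gene is tested between two conditions with the two-sample
unequal-variance (Welch) t-test. With group variances s²₁, s²₂ and sizes
n₁, n₂,

    t = (x̄₂ − x̄₁) / √(s²₁/n₁ + s²₂/n₂),
    ν = (s²₁/n₁ + s²₂/n₂)² / [ (s²₁/n₁)²/(n₁−1) + (s²₂/n₂)²/(n₂−1) ],

with two-sided p from the t distribution at ν degrees of freedom. Tests run
on log2(abundance + pseudocount) — the log transform stabilizes the
multiplicative variance of RPKM-like data and makes the tested contrast the
same quantity as the reported log2 fold change,
log2((mean_alt + c)/(mean_ref + c)). The pseudocount c defaults to 1 RPKM.

Significance uses strict inequalities p < 0.05 and |log2FC| > 0.075. These
are deliberately raw-p thresholds: the calling rule this pipeline replicates
predates routine FDR gating, so BH q-values are attached as an informational
column but do not affect calls. Consequence: with ~90% null genes, roughly
4–5% of them pass both thresholds, and the called set's precision is capped
near 0.7–0.8 — it is the cross-study and protein tiers downstream that
remove those false positives.

Numerical choices:

* **Variance floor.** When both groups are numerically constant the squared
  standard error is floored at 1e-12 and the gene is flagged `degenerate`
  rather than dropped, keeping output rows aligned with input genes. Equal
  means still give t = 0, p = 1; unequal constant means give the
  variance-floor (effectively zero) p.
* **Active-transcriptome filter.** A gene is "active" when its maximum
  abundance over all samples exceeds `min_expression` (default 0, i.e. any
  evidence of expression). The definition is configurable because no single
  RPKM cutoff is canonical.
* **Known limitation — calibration at n = 3.** The Welch–Satterthwaite
  approximation estimates ν from the same two sample variances it divides
  by; at triplicate sample size this makes the test conservative: across
  10,000 null genes (both groups N(0,1), n = 3 vs 3) the empirical type-I
  error at p < 0.05 is ≈ 0.034, not 0.05, and the null p distribution is
  measurably non-uniform (our implementation is numerically identical to
  `scipy.stats.ttest_ind(equal_var=False)` on these inputs). The test is
  never anticonservative, so calls remain valid; power and Jaccard numbers
  quoted elsewhere already include this conservatism.

The comparative-Ct utility implements ΔCt = mean Ct(target) − mean Ct(reference)
per condition, ΔΔCt = ΔCt(condition) − ΔCt(control), relative abundance
= 2^−ΔΔCt (control ≡ 1).

## Consensus construction

Two studies' significant calls are intersected directionally; sign
concordance across studies is required by default so a gene up in one study
and down in the other cannot enter a directional consensus set (such genes
are reported in a separate `discordant` set so the five output sets
partition the union of significant genes). Gene symbols match upper-cased;
no alias resolution is attempted.

Fold-change concordance is ordinary least squares of study B's log2FC on
study A's over the shared genes; r² is reported as the squared Pearson
correlation of the free-intercept fit, which is symmetric in the two studies
(the slope is not, and both are reported). The RNA + Protein tier keeps
shared genes with protein p < 0.05 (the same p_max as RNA — no separate
protein threshold is defined) and, by default, a protein fold-change sign
matching the RNA direction.

## Enrichment

**GSEA.** For a ranked list of N genes with metric values r_i and a gene set
with N_hit members in the universe, the running sum increments by
|r_i|^w / Σ_hits |r_j|^w at hits and decrements by 1/(N − N_hit) at misses;
the enrichment score is the signed maximum deviation. w defaults to 1 (the
standard weighted form); w = 0 gives the classic Kolmogorov–Smirnov form
used in the oracle tests.

* **Tie rule.** Exact ties between the positive and negative extrema of the
  running sum are structural, not exotic: immediately after the final hit
  the sum equals 1 − m/(N − N_hit) (m = remaining misses) regardless of the
  weights, so symmetric hit placements produce exact ±x ties. Ties resolve
  to the positive extremum, with a 1e-9 comparison band so the choice is
  robust to floating-point accumulation order. The same rule is applied in
  the brute-force enumeration oracle the engine is tested against.
* **Degenerate weights.** If every hit metric is exactly 0 at w > 0, hit
  weights fall back to equal weighting (the w = 0 form) so the score stays
  defined.
* **Permutation null.** Null ES values come from random same-size gene
  subsets of the universe (gene-label permutation), not phenotype
  permutation: with triplicates per arm only C(6,3)/2 = 10 distinct
  phenotype relabelings exist, far too few to resolve nominal p ≈ 0.002.
  The nominal p is sign-stratified and additively smoothed,
  p = (1 + #{null, same sign, |ES_null| ≥ |ES|}) / (1 + #{null, same sign}),
  so it is never exactly 0; NES = ES / mean(|ES_null| of the same sign).
  Defaults: 1000 permutations, minimum 100.

**ORA.** One-sided hypergeometric upper tail P(X ≥ k) for overlap k between
a query of size n and a term of size K in a background of size N, after
intersecting each term with the background; BH correction across the term
list. The DAVID/EASE variant (k − 1) is available but off by default.

## Tissue co-expression

Per tissue, Pearson correlations (Spearman available) between all pairs of
gene-set members are computed on log2(abundance + 1) across donors;
zero-variance and unmeasured genes are dropped and logged, and the matrix is
forced exactly symmetric with a unit diagonal. Each gene's feature vector is
its full row of correlation coefficients (the constant diagonal entry does
not affect Euclidean distances between rows); k-means with k = 3 and 50
restarts keeps the best-inertia solution, with average-linkage hierarchical
clustering as an alternative. Cluster labels are renumbered by descending
mean intra-cluster correlation so label 1 is always the most coherent
("core") cluster, which also makes labelings comparable across runs.

The correlated/anti-correlated classification is this package's
operationalization (no published rule exists): a gene is *correlated* when
its mean correlation to core-cluster genes (self excluded) is ≥ τ₊ = 0.3,
*anti-correlated* when ≤ τ₋ = −0.1, else *unclassified*. The asymmetry
reflects that positive co-regulation through a shared driver produces large
correlations while antagonistic regulation is typically weaker. At 200
donors the sampling noise of a background gene's mean correlation to the
core is ≈ 0.07, so a few percent of background genes fall below τ₋; the
planted coherent and anti modules themselves classify essentially perfectly.

Cross-tissue comparison re-indexes every tissue's matrix to the reference
tissue's order (cluster label, then descending mean correlation to own
cluster, then gene id) and tabulates each gene's cluster and class per
tissue.

## Synthetic data

All generators simulate on the log2 scale and exponentiate, so abundances
are positive and RPKM-like, and every generator is a pure function of its
arguments and seed (NumPy `default_rng`; tissue panels use spawned
`SeedSequence` children per tissue).

* **Overexpression experiment** (defaults: 5000 genes, triplicates, 10% DE,
  effects N(1.5, 0.25) log2 units with Bernoulli(½) signs, baseline
  N(6, 1.5) log2 RPKM, replicate noise 0.25 log2 units). Effect sizes around
  1.5 log2 units with ~0.25 residual noise mirror a strong transgene
  induction; baselines spanning ~±3 sd give a realistic dynamic range while
  keeping the +1 pseudocount negligible.
* **Companion study.** A fraction `overlap_fraction` of planted genes is
  reported significant with log2FC = truth + N(0, fc_noise_sd); 2% of null
  genes become study-specific decoy calls. Every other gene receives a
  calibrated null entry: a z-draw mapped to p = 2·Φ̄(|z|) (exactly
  Uniform(0,1)) with log2FC = 0.01·z, so a non-called gene essentially never
  crosses the joint (p, fold-change) threshold. Called genes get the p
  implied by their fold change at standard error max(noise, 0.05).
* **Proteome.** Genes are detected independently with probability
  `coverage`; detected planted genes get log2FC = attenuation × RNA effect
  + N(0, noise_sd). Attenuation (default 0.7) encodes the well-known
  damping of protein-level responses relative to mRNA.
* **Tissue panels.** A donor-level latent factor f ~ N(0,1) drives
  log2 expression; coherent genes load +λ with λ = σ·√(r/(1−r)) so the
  expected within-module correlation is `r_within`, anti genes load
  −`anti_loading`·λ, background 0; membership is re-drawn per tissue.
  `anti_loading` defaults to 0.5: at 1.0 the anti module's internal
  coherence would equal the coherent module's and the "core = most coherent
  cluster" rule would be a coin flip between them; at 0.5 the core is
  identifiable while anti genes still correlate ≈ −0.8 with it.

What passing the planted-truth tests shows: the pipeline's operations invert
their own generative assumptions at realistic sizes (recall ≥ 0.9, consensus
Jaccard ≥ 0.98, ARI = 1 at r = 0.9 with 200 donors). What it does not show:
robustness to library-size artifacts, batch effects, count overdispersion,
annotation errors or non-Gaussian noise — none of which the generators
emulate (read-level simulation and normalization are out of scope).

## Problem sizes and runtime

The validation suite uses the sizes it reports: 10,000 null genes × 3 seeds
for test calibration; exhaustive ES enumeration over all rankings of 2–12
genes × all subsets of size ≤ 4 (4724 cases, both weights); 5000-gene
simulations for consensus recovery; 20 seeds × 1000 genes for attenuation
recovery; 3 tissues × 200 donors × 60 genes for co-expression; 500 trials ×
200 permutations for GSEA null calibration. The whole acceptance script
completes in well under a minute on one CPU; the full test suite in a few
seconds.

## Reproducibility

Randomness enters only through named per-stage seeds; the pipeline manifest
records the configuration and SHA-256 of every output, and rerunning a
configuration reproduces all outputs bit-identically (floats are written
with a fixed `%.10g` format to make text outputs stable).
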