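# Methods

## Model and procedure

The package tests, for each gene set in a collection, whether the set's genes
are more differentially expressed between two sample groups than random genes,
with the twist that a gene's contribution is weighted by how specific it is to
the set being scored.

**Gene-level statistic.** Per gene, a two-sample t-score on log expression:
pooled-variance unpaired t (df = n₁+n₂−2) or, when pairing blocks are present,
a one-sample t on within-block differences (df = blocks−1). The moderated
variant shrinks each gene's residual variance s²_g toward a prior s₀² with
prior degrees of freedom d₀, both estimated by empirical Bayes: under the
hierarchical model s²_g ~ s₀²·F(df, d₀), the mean and variance of log s²_g
identify (d₀, s₀²) through digamma/trigamma identities; the trigamma equation
is inverted by Newton iteration (tolerance 1e-8, ≤50 steps; the iterate is the
near-linear 1/trigamma scale, so convergence takes a handful of steps). The
shrunken variance is the posterior mean (d₀s₀² + df·s²_g)/(d₀+df). d₀ = 0
reproduces the ordinary t exactly; d₀ = ∞ gives a common-variance t whose
ordering equals the |effect| ordering. When the dispersion of log s² is at or
below its theoretical sampling floor trigamma(df/2), d₀ = ∞; with exactly
equal variances the prior is that common value (the chi-square bias correction
is skipped — there is no sampling noise to correct). With fewer than 10 usable
variances the estimator falls back to no shrinkage, logged. The implementation
is verified against the reference R implementation (limma) in the test suite.

**Weights.** f(g) counts the analysed sets containing g, computed *after*
restricting the collection to measured genes (frequencies describe the
analysed universe). Frequencies above the 0.99 quantile are capped at that
quantile value — curated pathway collections have heavy-tailed sharing and the
cap keeps a few hub genes from flattening everyone else's weights. Weights are
w = 1 + ((f_max−f)/(f_max−f_min))^α ∈ [1, 2], non-increasing in f. The
exponent α defaults to 0.5 — a concave profile that drops quickly at low
frequencies, where the specificity signal lives — with α = 1 (linear) a
configuration flag. Weights depend only on the collection, never on sample
labels, so they are fixed across permutations.

**Set score and standardization.** S₀ = mean of |T|·w over the set's genes.
Because S₀ is a mean, the null of "a random set of N genes" has mean equal to
the G-wide mean of |T|·w and sd equal to the G-wide sd divided by √N (central
limit theorem) — the first standardization uses these closed forms instead of
resampling gene sets. The second standardization z-scores the resulting
values across the collection. If all standardized scores within a labelling
coincide (degenerate), they are set to 0 with a warning.

**Permutation p.** For unpaired designs the case labels are reassigned
uniformly at random preserving group sizes; paired designs swap labels
independently within blocks. The identity labelling is excluded; when the
space of distinct labellings is no larger than the request, all distinct
non-identity labellings are enumerated (the engine then agrees exactly with
brute-force enumeration, which the tests assert). Every permutation is a full
re-analysis: gene statistics, the variance prior, both standardizations.
p = #(S*_perm ≥ S*_obs)/N_perm — the literal count, so p may be 0; a
`(b+1)/(N+1)` option exists for downstream FDR safety. Comparisons use a
relative tolerance of 1e-9 so exact theoretical ties (e.g. the complement
labelling, which yields the identical statistic) count as ties regardless of
floating-point noise; ties count against significance. q-values are
step-up Benjamini–Hochberg (via statsmodels).

## Comparators

**Maxmean with restandardization.** Per set, max(Σz⁺/n, Σ|z⁻|/n) on ordinary
t-scores, both sums divided by the full set size n. Observed and permuted
scores are restandardized against the null of a random same-size gene set
drawn from that labelling's catch-all score distribution: writing a = max(z,0)
and b = max(−z,0), the two set means are asymptotically bivariate normal with
cov(ā, b̄) = −E[a]E[b]/n (since a·b ≡ 0), and the mean and sd of their maximum
follow from Clark's moment formulas for the maximum of two jointly normal
variables. This replaces Monte-Carlo gene-set draws with closed forms; the
normal approximation runs a few percent light-tailed at small n, identically
for observed and permuted scores, so p-values remain calibrated (verified
against random draws and by the false-positive study). The restandardized
maxmean is non-negative-oriented: one ≥ test flags sets shifted in either
direction.

**Weighted-KS enrichment.** Genes ranked by signal-to-noise
(m₁−m₂)/(sd₁+sd₂) with the conventional 0.2·|mean| floor on each sd
(moderated t available via flag); running sum increments at member genes
proportional to |metric|¹ and decrements 1/(G−n) at non-members; ES is the
extremum. NES divides ES by the mean |ES| of same-sign permutations, and p is
computed within the observed sign class. This is a faithful-algorithm
implementation of the published procedure, validated against a brute-force
running-sum oracle, not a port of any particular codebase.

Both comparators can consume the same permutation engine instance as the
main method, so method contrasts are free of Monte-Carlo labelling noise.

## Simulation studies (the study conditions)

**Sensitivity.** 1000 genes × 100 samples (50/50), i.i.d. N(0,1); 50 sets of
20 genes partitioning the genome; the first set GS1 receives a group-2 mean
shift under five scenarios — (up, down, δ) = (15, 0, 0.3), (10, 5, 0.3),
(8, 7, 0.3), (7, 3, 0.4), (5, 5, 0.4) — plus an optional pure-null scenario 0.
Three overlap setups: I, disjoint sets; II, GS1's shifted genes also placed in
GS50; III, GS1's unshifted genes also placed in GS50. 50 replicate datasets
per cell, 1000 permutations each; the shifted set's p is aggregated by mean
and median (both emitted; the mean is the headline since the skewed,
zero-inflated replicate distribution collapses medians to 0 in strong-effect
cells). Within a replicate all methods and setups share the dataset and the
permutation stream. Frequency capping is disabled here: the simulated
frequency distribution takes only the values 1 and 2, and a 0.99-quantile cap
would erase the overlap structure under study. For the same reason α is
inert in these simulations (only two frequency levels), so the sensitivity
results do not depend on the weight exponent choice.

**Specificity.** Pure-noise N(0,1) replicas at 24 realistic dataset shapes
(5000 genes; group sizes drawn once, uniformly from 10–60, from the study
seed) analysed against a fixed synthetic collection with heavy-tailed gene
sharing (80 sets, log-uniform sizes 20–200, membership sampled with Zipf-like
gene popularity — a stand-in, labelled synthetic, for a curated pathway
collection, which cannot be bundled). The pooled fraction of set p-values
below α estimates the false-positive rate; at 500 permutations the finest
attainable p is 0.002, so rates at α = 0.01 are intrinsically discrete. A
second design permutes the labels of caller-supplied datasets before analysis
and summarises target-set p-values and percentile ranks, whose null
expectations are 0.5 and ~50.

What the generators do *not* emulate: inter-gene correlation, heteroscedastic
or heavy-tailed expression noise, batch structure, and set-size–expression
dependence. Passing the calibration tests on independent Gaussian noise
therefore does not certify calibration under strong co-expression — that is
precisely the situation restandardization (for maxmean) and sample-label
permutation (for all methods) are designed to protect, but the simulations
here only exercise the independent case.

## Benchmark framework

Per dataset, the target set's p, q and percentile rank i/N_GS·100 (average
rank on ties) are collected; summaries report the geometric mean (zero p
floored at 1/(2·N_perm)), median, % p<0.05, % q<0.05, and rank mean/median.
Method-vs-reference comparison: one-tailed paired Wilcoxon signed-rank on
ranks (exact null for n ≤ 30 when ties permit; identical ranks degenerate to
p = 0.5, flagged), and optionally a linear mixed-effects model
rank ~ method + dataset with a random intercept per target pathway (fitted by
statsmodels; one-tailed Wald p on the method coefficient). A packaged table
maps 24 public GEO accessions to their target KEGG pathway identifiers; the
expression data are deliberately not bundled, so the real-data benchmark is a
framework the user feeds with their own `padog run` outputs.

## Numerical and design choices

- Row-standardization denominator sd/√N, as the CLT dictates for a mean.
- Minimum analysable set size 3 (configurable): smaller sets make the √N
  standardization degenerate; dropped with a warning, as are sets losing all
  genes on restriction to the measured universe.
- Zero-variance genes get an infinite-t sentinel and a flag; under shrinkage
  (d₀ > 0) they become finite. Where a raw |t| enters a set score unshrunken,
  infinities are clipped to the largest finite magnitude so one degenerate
  gene cannot poison a set.
- Identity permutation excluded from the null; sampled labellings may repeat
  (standard Monte-Carlo permutation practice).
- Problem sizes in the packaged studies: sensitivity at the full published
  design (50 replicates × 1000 permutations per cell, ~10 s/cell vectorised);
  specificity at 96 replicas × 500 permutations. The vectorised engine
  computes all permutations of a dataset with a handful of matrix products.

## Known limitations

- Two-group designs only; no covariates, multi-group contrasts, or robust/
  trend variants of the variance shrinkage.
- Gene identifiers are opaque strings; probe-to-gene collapsing (e.g. keeping
  the probe with the smallest p per gene) must happen upstream.
- The enrichment comparator implements nominal permutation p only, not the
  NES-histogram FDR machinery of the original tool.
- The maxmean comparator's restandardization constants are analytic
  approximations; at set sizes below ~10 the light-tailed sd approximation
  grows, though calibration is preserved by symmetry between observed and
  permuted scores.
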