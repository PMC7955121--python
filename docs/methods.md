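# Methods

This note documents the statistical models and the numerical choices made
where the design was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Marker detection

Cells are filtered on nFeature (number of genes with count > 0), then
counts are normalized as `ln(1 + c_gj / N_j · s)` with scale factor
`s = 10⁴` (column sums of `exp(value) − 1` equal `s` exactly, which the
tests verify). Each cluster is tested one-vs-rest per gene with the
Wilcoxon rank-sum test: the exact null distribution when both groups have
≤ 8 observations and no ties (where it matches full enumeration), the
tie-corrected normal approximation otherwise. Genes with zero variance in
both groups get p = 1.

Choices the underlying tooling ecosystem leaves open, fixed here:

* **Fold change** uses a +1 pseudocount on de-logged group means,
  `log₂((mean(expm1(in)) + 1) / (mean(expm1(out)) + 1))` — finite and
  monotone for all-zero groups.
* **Bonferroni family** = genes × clusters tested (configurable via the
  inputs; the family size is reported in the records as the implied
  `p_adj / p` ratio).
* **min_pct applies to max(pct_in, pct_out)** so that down-markers of a
  cluster remain detectable.
* The likelihood-ratio ("bimod") test variant is deliberately not
  implemented; results are test-dependent and Wilcoxon is the
  deterministic, assumption-light default.

Module scores bin all genes into 24 equal-occupancy bins by mean
expression and subtract, per cell, the mean of up to 100 control genes
drawn (seeded, without replacement) from each set gene's bin. When the
requested control count reaches the bin size the whole bin is used, which
makes the degenerate self-control case exactly zero.

Silhouette widths are computed directly from the O(n²) Euclidean distance
matrix with the convention that singleton-cluster cells get width 0.

## Prototype Ranked Lists

Per (drug, cell line), gene scores are the weighted mean fold change over
conditions (weights default to 1; the database format accepts a weight
column, since real perturbation catalogs weight conditions unevenly but do
not publish the weights). Rankings are merged hierarchically: the closest
pair of lists under the Spearman footrule distance on rank vectors is
merged by Borda mean rank (ties broken lexicographically on gene id, as
everywhere in the package) until one list remains. Lists are processed in
a canonical order (sorted by list id), which makes the merge invariant to
input order. Merging within cell line first and across cell lines second
gives every cell line equal weight regardless of how many conditions it
contributed.

The final PRL carries **centered rank scores** `(N − 2·rank + 1)/N ∈
(−1, 1)`. An earlier design used `(N − rank + 1)/N ∈ (0, 1]`; because
those weights are monotone top-to-bottom, every gene-set-permutation null
enrichment score came out positive under the weighted statistic, leaving a
down-regulated set with an empty same-sign null and an undefined NES. The
centered form restores the U-shaped |score| profile of real fold-change
rankings and a two-sided null.

## Preranked GSEA

Walking the ranked list, hits increment the running sum by
`|score|^w / Σ_hits |score|^w` (uniform when `w = 0` or scores are
absent) and misses decrement by `1/(N − |hits|)`; ES is the running-sum
value of maximal |deviation|, the leading edge the hits at or before
(ES > 0) / after (ES < 0) the extremum. Defaults: `w = 1`,
`n_perm = 1000`.

The null permutes **gene sets** (random same-size sets from the list's
universe), not phenotypes — a consensus ranking has no sample-level
replicates to permute. NES divides ES by the mean |ES| of same-sign null
values; p carries the +1 permutation correction,
`p = (1 + #{same-sign null at least as extreme}) / (1 + #{same-sign
null})`, and can never be 0. If no null value shares the observed sign
(possible for extreme planted effects at small n_perm), p is guarded to 1
and NES is normalized against the whole null so its sign is preserved.

Drug-family FDR follows the classic tail-ratio estimator on the pooled
normalized null: `q = (frac of same-sign null |NES| ≥ obs) / (frac of
same-sign observed |NES| ≥ obs)`, clipped to [0, 1] and monotonized so q
is non-increasing in |NES| within a sign class. `−log₁₀(q)` is floored at
`1/(n_perm · n_drugs)` to keep plots finite.

## SLEA and survival

For each sample, the observed mean expression of the marker set is
compared to the means of `n_rand = 10,000` random same-size gene sets.
The random sets are drawn **once and shared across samples** — a paired
null that removes between-sample Monte-Carlo noise — and are drawn in
lexicographically sorted gene-id space, so the z-scores are exactly
invariant to the storage order of the matrix rows. z gets a two-sided
normal p (matching the 1.96 threshold convention), BH correction across
the cohort, and the three-way class up / down / ns at z ± 1.96, q < 0.05.
Expression is not per-gene standardized before set means (exposed as a
choice for the caller by pre-transforming the matrix). A sample whose
null SD is at machine-precision scale (a constant expression vector) gets
z = 0.

Survival groups are "high" (class up) versus "rest". The two-group
log-rank statistic is computed directly from the pooled event-time table
(hypergeometric variance, χ² with 1 df) and is oracle-tested against an
independent implementation; the univariate Cox hazard ratio and Wald CI
delegate to lifelines. Kaplan–Meier curves are direct product-limit
estimates with at-risk counts.

## Overlap enrichment

Right-tail binomial: with n background markers in a module and an
annotation set covering fraction p₀ of the background,
`p = P(X ≥ k), X ~ Binomial(n, p₀)` via the survival function (k = 0
gives exactly 1). The sampling-with-replacement binomial is the primary
model because that is the named test in the reporting convention this
module follows, even though its figure legends also say "two-sided"; a
hypergeometric option is available for comparison. BH is applied across
the full module × set family of one invocation. The heatmap filter keeps
sets with background size > 20 that reach overlap ≥ 10 and p < 10⁻⁵ in a
module of interest while staying above p = 10⁻³ in every designated
contrast module (defaults mirror the reporting convention; all four
thresholds are parameters).

## Synthetic data: what it emulates, and what it does not

* **Single cell** — negative binomial via a gamma–Poisson mixture with
  shared dispersion θ = 2 (var = μ + μ²/θ), baseline mean 0.5
  counts/gene, and log-normal library-size factors with CV 0.3 (mean 1),
  which exercises the normalization nontrivially. Defaults: 2,000 genes,
  5 clusters × 300 cells, fifty 4-fold (log₂ effect 2) markers planted in
  cluster 2. Not modeled: doublets, ambient RNA, batch effects,
  cell-cycle structure, gene–gene correlation.
* **Perturbation database** — fold changes i.i.d. Normal(0, 1) per gene
  per experiment; the planted drug's 50 target genes are shifted by −2 in
  all 9 of its experiments (3 cell lines × 3 conditions, 50 drugs). Real
  catalogs have correlated responses across related drugs and doses;
  passing recovery tests here shows the ranking machinery works, not that
  real signatures are this clean.
* **Cohort** — expression Normal(0, 1); ~51 of 126 samples (mirroring a
  51/75 split) carry a +1.0 shift on the 30 marker genes; survival times
  are exponential with hazard 0.1 · exp(ln 2 · enriched); censoring is a
  Bernoulli(0.25) indicator with censoring time Uniform(0, T_event),
  which hits the target censor fraction exactly in expectation (this is
  the one place the censoring mechanism is informative-in-form; for
  exponential event times it does not bias the group comparison the tests
  measure). Microarray-style noise structure, covariates and
  non-proportional hazards are not modeled.

Every generator is a pure function of its config including the seed;
identical configs produce bit-identical outputs.

## Problem sizes and determinism

The test suite and acceptance script use the default study-scale
configurations above; replicated checks use 10–20 seeds per criterion and
1,000-trial calibration runs, sizes chosen so the whole suite completes
in a few minutes on a single CPU while keeping Monte-Carlo error well
inside the asserted bands. The pipeline derives every stage seed from the
single run seed via `SeedSequence`, writes only plain-text artifacts, and
reruns byte-identically (the manifest records wall time and is excluded
from the byte-identity contract).

## Known limitations

* Cluster labels and embeddings are inputs: graph clustering, t-SNE/UMAP,
  trajectory and velocity analyses are out of scope.
* The PRL merge fixes the footrule/Borda details left open by the
  "hierarchical majority-voting" description; other published rank
  aggregators (e.g. Kruskal-type or Markov-chain schemes) would order
  near-tied drugs differently.
* GSEA weight exponent, permutation depth, and whether FDR pools nulls
  across drugs are exposed parameters; defaults are stated above.
* The binomial overlap test treats marker draws as independent; for
  marker lists that are a large fraction of the background the
  hypergeometric flag is the better-calibrated choice.
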