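# Methods

This note documents the models implemented in `hierflux`, their
assumptions, the parameters that matter, and what the synthetic-data
generators do and do not emulate.

## Dominance scoring

A group's agonistic record is reduced to a win/loss sociomatrix `W` with
`W[i, j]` the number of contests `i` won against `j`. David's Scores use
the *chance-corrected* dyadic index `D_ij = P_ij − (P_ij − 0.5)/(n_ij + 1)`
rather than the raw win proportion `P_ij`: the correction shrinks
small-sample dyads toward 0.5, and it is the variant under which the scores
sum exactly to zero (checked to 1e-9 on every input; the suite also checks
antisymmetry under matrix transposition). Uncontested dyads contribute zero
to all four summands — a convention, since no information exists for them.
Ranks are assigned by descending DS with ties broken by total wins and then
lexicographic id; the tie-break is arbitrary but deterministic, which we
prioritize for reproducibility.

Directional consistency is `DC = Σ_d (H_d − L_d) / Σ_d (H_d + L_d)` over
contested dyads. Its significance test re-assigns the direction of every
individual interaction independently with probability ½ within its dyad —
the exchangeable null for a group with no rank structure. Event-level
(rather than dyad-level) flipping is the finer-grained randomization and is
the documented choice. P-values use the add-one estimator
`(1 + #{DC_perm ≥ DC_obs}) / (B + 1)`, which cannot return zero and is
exactly valid (slightly conservative) under the null.

The day-2 stability test counts, per rank `r`, the animals that lost more
fights than they won against lower-ranked animals (`k` of `n`) and reports
the lower binomial tail at p₀ = 0.5. Worked values: `k = 0, n = 24` gives
`2⁻²⁴ ≈ 6.0e-8`; `k = 3, n = 24` gives `2325/2²⁴ ≈ 1.4e-4`.

## Group-of-origin randomization test

The statistic is the total, over origin groups, of pairwise absolute
differences of achieved post-reorganization ranks ({1,1,4,4} → 12;
{1,2,3,4} → 10; all equal → 0). The null shuffles achieved post-ranks among
individuals *within each prior-rank cohort*, which preserves both the
post-rank multiset of every cohort and the design constraint that only
equal-status animals were regrouped. Clustered outcomes give small sums, so
the p-value is the lower tail (add-one corrected). The lower tail is the
only direction under which a clustered outcome can be significant, and the
test is exact under the design's exchangeability.

## Differential expression

The pipeline is: low-count filter (summed count across all samples < 10;
the per-sample reading of the threshold would discard nearly the whole
matrix and is rejected) → TMM normalization → log2-CPM → cell-means linear
model → permutation eFDR.

*TMM.* The reference sample is the one whose upper-quartile count fraction
is closest to the across-sample mean. For each sample, gene-wise log-ratios
to the reference (M) and average abundances (A) are computed over genes
positive in both; the M values are trimmed 30% from each tail and the A
values 5% from each tail; the factor is the inverse-variance weighted mean
of the surviving M values (delta-method binomial variances), exponentiated,
and all factors are rescaled to geometric mean 1. These are the canonical
published defaults; the implementation matches edgeR's `calcNormFactors`
to well under 1% on composition-biased data (tested via Rscript).
Degenerate samples (too few shared expressed genes, or no variation in M)
get factor 1 with a warning.

*log-CPM.* `log2((count + 0.5) / (lib·factor + 1) · 1e6)`. The fixed prior
count of 0.5 stabilises zeros; it makes log-CPM (and hence downstream
calls) invariant to global library rescaling only up to a small boundary
effect, which the suite bounds explicitly.

*Contrasts.* For every gene a linear model with one mean per social
condition is fit; the contrast estimate is the difference of the two
condition means (this closed form is verified against per-gene OLS), and
the t statistic uses the residual variance pooled across all six
conditions (df = N − #conditions). Precision weights (the voom approach)
are deliberately **not** used: with error control delegated to the
permutation null below, the simpler homoscedastic model is valid by
construction under its own permutation distribution, at some cost in power
for extremely low-count genes.

*Empirical FDR.* Condition labels are permuted across all samples (5000 by
default; no stratification, since the design gives no batch structure to
preserve), the same model is refit, and null p-values are pooled across
genes and permutations: `eFDR(p) = E_perm #{null p ≤ p} / #{obs p ≤ p}`,
clipped to [0, 1] and monotonized by a cumulative minimum from the largest
observed p downward. Pooling across genes is the standard choice at this
scale (thousands of genes × thousands of permutations) and is the reason a
modest permutation count suffices. A DEG requires `|log2FC| ≥ 0.2` at
eFDR < 0.05; inventory tables bin calls at 0.20–0.75 (closed), 0.75–1.50,
and > 1.50, so the three bins sum to the ≥ 0.20 total.

## Concordance statistics

The overlap test draws, per replicate, two *independent* uniform subsets
without replacement (sizes n1, n2) from the N-gene universe — matching the
generating description rather than a single hypergeometric draw, though the
expectation `n1·n2/N` is identical and is reported as an analytic
cross-check. With n1 = 2255, n2 = 1357, N = 15184 the null mean is ≈ 201.5.
Upper-tail add-one p-values; an estimate below 1/(B+1) is impossible by
construction.

Direction concordance uses the Yates continuity-corrected chi-square
`Σ max(|O − E| − 0.5, 0)² / E` on the 2×2 up/down cross-tabulation (the
clamp at zero is the standard form and the implementation matches
`scipy.stats.chi2_contingency` exactly on an exhaustive sweep of small
tables). Two phi coefficients are reported because both conventions are
common: `φ = √(χ²_corrected/n)` and the classic
`(ad − bc)/√((a+b)(c+d)(a+c)(b+d))`; on the table (5,0;0,3) these give
0.73 and 1.00 respectively, so neither subsumes the other. The chi-square
is insensitive to how discordant genes split between the two off-diagonal
cells (the suite verifies < 2% movement across all splits of 13 and 14
discordant genes), which matters because only the discordant *total* is
usually reported.

The IEG direction test takes one contrast's DEG calls, restricts to the
curated immediate-early-gene list intersected with the filtered gene
universe, and tests #up against #down with a two-sided exact binomial at
p₀ = 0.5.

## Co-expression modules

Signed-hybrid adjacency `a_ij = max(cor(x_i, x_j), 0)^β` with Pearson
correlation (biweight midcorrelation is not used) and β = 4 by default. The
scale-free criterion (`soft_threshold_scan`) bins connectivity into 10
equal-width bins and regresses log₁₀ frequency on log₁₀ k; the selection
rule takes the smallest power with signed R² ≥ 0.8, else the fallback 4.
TOM is the standard `(Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)`.

Module detection replaces dynamic tree cut with average-linkage clustering
on `1 − TOM`, a flat cut at height 0.99, and a minimum module size (50 for
all-sample networks, 100 for reorganized-only networks). Because a flat cut
lets weakly attached background genes ride along with real modules, one
round of the canonical membership refinement follows: each clustered
gene must retain a correlation of at least 0.3 with its module eigengene
or it returns to the unassigned pool (modules falling below the minimum
size afterwards dissolve). Module eigengenes are the first principal
component of the standardized within-module expression, unit-norm and
sign-oriented so the mean gene–eigengene correlation is positive; module
membership is the gene–eigengene Pearson correlation, and hub genes require
own-module MM strictly above 0.8.

Eigengene–condition association fits OLS of the eigengene on condition with
group id as a *fixed* blocking covariate — a documented simplification of
the random-intercept mixed model: with at most seven groups per condition
the random-effect variance is weakly identified, and the fixed-effect
contrast targets the same estimand. Designs in which condition is nested in
group are rejected as non-identifiable; in paired designs the aliased block
columns are dropped automatically, so cross-pair contrasts absorb
inestimable block differences (their estimates are conditional on that
absorption).

## Synthetic data

The generators encode the study conditions as defaults: 65 groups of 4
animals with ~82 agonistic interactions per group; six conditions with
n = {7,7,7,7,6,6}; ~15,000 genes after filtering; library sizes 4–6 million
reads (≈5M target).

*Events.* Latent ranks 1–4 per group; contest opponents are drawn uniformly
and the higher-ranked animal wins with probability
`logistic(steepness · rank difference)`. The logistic is the minimal
monotone choice given that no generative model is observable from data; the
default steepness 4.0 gives an adjacent-rank upset probability of ~2%,
which reproduces the near-unidirectional aggression (median DC ≈ 0.98) of
stable murine hierarchies. `steepness = 0` gives direction-exchangeable
fighting — the null used throughout the calibration suites.

*Reorganization.* Origin groups are blocked into sets of four; the four
rank-r animals of a block form one new group (one animal per origin, equal
prior status). Achieved post-rank orders a latent score
`origin_effect · u(origin) + ε` with standard-normal `u` and `ε`, so
`origin_effect = 0` is the exchangeable null and large values force former
cage-mates to identical post-ranks.

*Counts.* Gene-wise log2 means are normal around a baseline (default 5.0,
SD 2.0 in log2 units — a realistic bulk dynamic range); planted DEGs shift
the first-named condition of their comparison by the given log2 fold
change; planted transition genes shift DES and ASC together by
`± transition_lfc`; planted modules add a per-sample standard-normal latent
factor times its loading to member genes' log2 means. Expression is
converted to per-sample proportions and counts are negative-binomial with
fixed dispersion (default 0.05, i.e. a ~22% biological CV — typical of
well-controlled inbred bulk tissue). What this emulates well: mean–variance
inflation, library-size variation, compositional coupling (planting a
module induces small negative correlations with the rest of the
transcriptome, which the suite treats as expected). What it does not:
batch effects, gene–gene correlation beyond the planted factors, gene-wise
dispersion trends, outlier samples. Recovery results on this generator
therefore demonstrate algorithmic correctness, not robustness to those
real-data pathologies.

## Numerical and design choices

- All randomness flows through a single explicit integer seed per call
  (numpy `default_rng`); identical seed + configuration reproduces
  byte-identical outputs.
- Permutation p-values everywhere use the add-one estimator; they are
  discrete and slightly conservative, so calibration is asserted as "no
  anti-conservative deviation" (one-sided KS) plus rejection at the nominal
  rate within Monte-Carlo error, not as exact two-sided uniformity.
- eFDR monotonization guarantees `eFDR` non-decreasing in raw p; clipping
  bounds it in [0, 1].
- Degenerate inputs are signalled, not silently absorbed: all-zero
  sociomatrices warn and return zero scores; DC is undefined without
  contested dyads; an empty post-filter count matrix, zero residual df,
  zero-margin 2×2 tables, and confounded association designs raise.
- Test problem sizes (2,000 genes, 200–500 permutations, 500 calibration
  replicates) are chosen so the full suite completes in well under a minute
  of compute per property while keeping Monte-Carlo error far below every
  asserted tolerance.

## Known limitations

- The flat-cut-plus-refinement module detector is not module-for-module
  identical to dynamic tree cut; parity with the original WGCNA software is
  explicitly out of scope (planted-module recovery is the acceptance
  standard). Module merging by eigengene similarity is not implemented.
- No moderated-variance (empirical Bayes) shrinkage and no precision
  weights; for very low counts the per-gene t statistics are noisier than
  limma-voom's, which the permutation eFDR absorbs into its null.
- The group-of-origin test assumes the regrouping design (equal-status
  groups of four); other designs need a different permutation unit.
- Latency-to-fight models, corticosterone mixed models and GO enrichment
  are out of scope.
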