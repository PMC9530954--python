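# Methods

This note documents the models, defaults and numerical choices behind
`adsubtypes`, and what the synthetic-cohort tests do and do not demonstrate
about real data.

## Synthetic cohorts

The generator emulates a merged multi-platform collection of post-mortem
brain expression profiles. For gene g, sample j in batch i:

    Y_ijg = mu_g + effect * 1[g is a marker of j's subtype] + gamma_ig + delta_ig * eps_jg

with `mu_g ~ N(7, 1)` (log2 intensity scale), `eps ~ N(0, noise_sd²)`,
additive batch offsets `gamma_ig ~ N(0, batch_location_sd²)` and
multiplicative noise scales `delta_ig ~ U(batch_scale_range)` drawn per
(batch, gene). Expression noise is Gaussian on the log2 scale, which is the
working assumption for log2-transformed microarray intensities, and the
additive/multiplicative batch structure is exactly the location/scale family
the empirical-Bayes correction assumes — the generator is the generative
model being tested.

Defaults (units in parentheses):

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | matrix rows |
| `n_marker_genes_per_subtype` | 50 | disjoint upregulated block per subtype |
| `batches` | 3 batches, 240 AD + 160 ND | 40% controls, matching large merged cohorts |
| `subtype_proportions` | (1/3, 1/3, 1/3) | multinomial subtype labels for AD samples |
| `marker_effect` | 1.0 (log2) | mean shift of a subtype's markers in its own samples |
| `batch_location_sd` | 0.5 (log2) | spread of additive batch offsets |
| `batch_scale_range` | (0.8, 1.25) | multiplicative noise scale interval |
| `noise_sd` | 0.5 (log2) | residual noise before batch scaling |

Clinical traits are truncated Gaussians (sex is Bernoulli) with ND baselines
and per-subtype offsets chosen so that subtypes I and III carry high
CDR/Braak/NFT, all AD subtypes share elevated CERAD/NPD (plaque burden) and
lowered tissue pH, and subtype III is slightly younger — the qualitative
pattern reported for real AD subgroups. Truncation bounds sit at least ~2 sd
from every group mean so the truncation bias is small relative to sampling
error at the cohort sizes used. One integer seed drives four deterministic
sub-streams (assignment, expression, batch effects, traits).

What the generator does *not* emulate: probe-level intensity models,
platform-specific noise, gene–gene correlation beyond the planted blocks,
missingness beyond an optional uniform dropout, or partially overlapping
marker programs. Passing recovery tests therefore show the pipeline is
correct under its own modeling assumptions at realistic effect sizes — not
that real cohorts will split as cleanly.

## Batch correction

Parametric empirical-Bayes location/scale adjustment in three steps.
Standardization estimates per-gene least-squares coefficients on a design of
batch indicators plus protected covariates (by default the AD/ND condition
indicator, so disease signal is re-added after correction); the grand mean
is the batch-size-weighted combination of batch coefficients and sigma² is
the pooled residual variance (divisor N). Per-batch delta²_ig uses the
sample variance (ddof 1), the convention of the reference parametric scheme;
the no-shrinkage oracle used in tests mirrors the same divisors so the
equivalence is exact.

Hyperpriors are moment-matched per batch: gamma_bar/tau_bar² are the mean
and variance of gamma_hat across genes, and the inverse-gamma parameters
solve mean = theta/(lambda−1), variance = theta²/((lambda−1)²(lambda−2)),
giving lambda = (m² + 2s²)/s², theta = m(m² + s²)/s². The two posterior
equations are solved by fixed-point iteration to a relative tolerance of
1e-10 (cap 500, warn on cap) — tight enough that the converged estimates
reproduce both equations to well below 1e-6 when substituted back. A batch
whose hyperprior variance degenerates to zero (e.g. a single gene) falls
back to no shrinkage with a warning. Genes with zero pooled variance are
excluded from fitting and passed through unchanged. With a single batch the
input is returned as-is. `shrink=False` (CLI `--no-eb`) disables shrinkage,
making the adjustment exactly per-batch location/scale standardization
restored to the pooled scale; this is also the mode in which batch means are
equalized to machine precision — with shrinkage on, the sampling noise of
batch means (sd ≈ noise·sqrt(2/n)) is deliberately only partially removed,
which is the empirical-Bayes compromise, not a defect.

The PCA check reports the batch-membership R² (between-batch over total sum
of squares) of the first two principal-component scores of the gene-centered
matrix; identically distributed batches sit near 0.

## Consensus subtyping

For each K in 2..k_max (default 10), 100 resamples draw 80% of AD samples
without replacement and cluster them with K-means (Euclidean distance over
genes standardized to zero mean/unit variance). Samples are first embedded
exactly into the rank-min(N, G) row space of the standardized matrix via
SVD; pairwise Euclidean distances are preserved to machine precision, so
this is purely an implementation speedup. K-means runs **once** per resample
with a fresh seeded initialization (no best-of-many-inits): consensus
clustering relies on run-to-run perturbation to expose over-partitioning,
and a base clusterer made deterministic by multi-start selection inflates
the apparent stability of spurious finer splits. A deterministic
average-linkage base clusterer is available behind a flag.

The consensus matrix divides co-clustering counts by co-resampling counts
(pairs never co-resampled score 0 with a logged notice); final assignments
come from average-linkage hierarchical clustering of 1 − M. Cluster
consensus m(k) is the mean consensus over within-cluster pairs; a singleton
scores 1 by convention (logged). The chosen subgroup count is the largest K
whose minimum m(k) exceeds the threshold (default 0.8) — when several K
qualify, finer structure is preferred. Because the singleton convention
would let a K that merely splits off one outlier qualify, the pipeline
additionally requires every cluster of a qualifying K to have at least 2
members; the bare rule remains available in the library. If no K qualifies,
downstream stages refuse to run unless `force_k` is set.

## Differential expression and signatures

Rank-sum tests use the exact null distribution when both groups have ≤ 8
observations and no ties, and otherwise the normal approximation with
midrank tie correction and continuity correction. Two groups with entirely
identical values give p = 1 with a warning. BH adjustment is applied within
each comparison (each pair of groups), not across the union of comparisons —
matching how per-comparison thresholds are phrased. A gene is significant
only under the dual rule (adjusted P < alpha and |mean difference| > delta;
defaults 0.05 and 0.2 log2, reference mean subtracted).

Subgroup-specific upregulated signatures require a gene to pass the dual
threshold upward against *every* other subgroup (all-pairwise rule), which
yields disjoint signatures; a pooled-rest alternative sits behind a flag.
Each subgroup is also compared against ND as a companion table, but the
subgroup-vs-subgroup signatures are what feed the enrichment stage (they are
the "subgroup-specific databases").

## Enrichment, hubs, ORA

The ranking metric is signal-to-noise, (mean_a − mean_b)/(sd_a + sd_b), with
each sd floored at max(0.2·|group mean|, 1e-8) — the floor guards
near-constant genes and is the convention of the reference GSEA
implementation; a signed Welch-t option exists since ranking by t-based
p-values is an equally defensible reading of common practice. Ties are
broken by gene id so the ranking is total and deterministic. The enrichment
score uses hit weight |metric|^p with p = 1 by default (p = 0 retained for
oracle tests); hit increments are normalized over hits and miss decrements
over non-members, so the running sum returns exactly to zero.

Significance uses phenotype-label permutations (not gene-set permutation):
each permutation regenerates the metric and ES. When the number of distinct
label splits is at most the requested permutation count, all splits are
enumerated exhaustively. Nominal p is add-one smoothed over same-sign
permuted ES; NES divides ES by the mean |same-sign permuted ES|; the FDR q
across a collection is the standard NES-ratio estimate on pooled normalized
permutation scores. The leading edge is the set members at or before the
running-sum maximum (mirrored for negative ES), and hub panels take the top
10 leading-edge genes by |metric| (ties by gene id). The ORA test is an
upper-tail hypergeometric with BH across the collection, a database-free
replacement for web-backed pathway enrichment: gene sets come from
user-supplied GMT files.

## Clinical association

All trait analyses are pairwise-complete; missing values are never imputed
(real cohorts report different n per trait). The female fraction uses the
pooled two-proportion chi-square without continuity correction by default
(flag to enable). Spearman p-values use the t approximation except for n ≤ 7
without ties, where the exact permutation null is enumerated. The module
eigengene is the first right-singular vector of the standardized signature
block, sign-oriented so its mean correlation with member genes is
non-negative; eigengene–trait correlations are computed across AD samples
(an option includes ND). Stars follow the usual convention (* < 0.05,
** < 0.01, *** < 0.001).

## Diagnostic panels

All 2^k − 1 non-empty subsets per hub panel (guarded at k ≤ 20) are fitted
as unpenalized maximum-likelihood logistic scores on the training split; on
non-convergence — the lbfgs signature of perfect separation — the fit falls
back to a ridge-stabilized logistic model with a notice. AUC is the
Mann–Whitney probability that a positive sample outranks a negative one
(ties ½), evaluated on a stratified 30% holdout to avoid the optimism of
in-sample best-subset selection. Positives for a subgroup's panels are that
subgroup's AD samples versus ND controls: a subgroup's markers are planted
only in its own samples, so its panel is a classifier for that molecular
subtype, and an AD-wide positive class would bound the attainable synthetic
AUC near (1 + 2·0.5)/3. Ties in the best-panel choice favor smaller panels,
then lexicographic gene order.

## Problem sizes used in the checks

The recovery checks run at 2,000 genes with 80 AD samples per subtype and
120 ND across three batches (consensus over K = 2..10, 100 resamples, five
seeds); differential-expression calibration uses 1,000 genes at 50 vs 50
over 20 seeds; panel recovery uses 1,000 genes, 180 AD + 90 ND and a 30%
holdout; the byte-identity check runs the full pipeline twice at 800 genes,
120 AD + 80 ND, 40 resamples, K ≤ 6, 200 permutations. These sizes are the
package's chosen test conditions: large enough that the planted effects are
identifiable at realistic effect sizes, small enough to keep the suite fast.

## Known limitations

* Parametric priors only; no nonparametric empirical-Bayes mode, reference
  batch, or missing-value EM.
* The consensus stage offers no CDF/delta-area diagnostics or item-consensus
  pruning; selection rests entirely on the cluster-consensus rule.
* In the end-to-end pipeline the subgroup labels of validation samples come
  from consensus clustering of the full corrected matrix, so the panel
  holdout guards against panel-selection optimism but not against
  subtype-assignment leakage; a fully external validation cohort (as in the
  intended use) removes this.
* Gene identifiers are matched as exact trimmed strings; no alias or
  cross-platform symbol resolution.
* No GO/KEGG database clients, figure rendering beyond raw tables, or GEO
  download machinery.
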