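# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical conventions that make runs reproducible.

## Differential expression

Expression counts are transformed to log2 counts-per-million,
`y_gs = log2((c_gs + 0.5)/(L_s + 1) × 1e6)` with `L_s` the column library
size; the 0.5/1 offsets keep zero counts finite. Matrices that are not raw
counts (`value_scale ≠ counts`) are used as-is, with a warning — the DE model
only assumes an approximately log-scale response.

Each gene is fit with a two-group (optionally precision-weighted) linear
model: group means, `log2FC = mean_case − mean_control`, residual variance
`s²` on `S − 2` degrees of freedom. Variances are moderated empirically:
assuming `s²_g | σ²_g ~ σ²_g χ²_df/df` and a scaled inverse chi-square prior
`σ²_g ~ s0² d0/χ²_{d0}`, the prior is estimated by method of moments on
`log s²` using the digamma/trigamma closed forms, with the trigamma
inversion done by Newton iteration (100 steps; non-convergence falls back to
`d0 = ∞`, i.e. every gene gets the pooled variance — this branch also covers
exactly-identical variances). Posterior variances
`s̃² = (d0·s0² + df·s²)/(d0 + df)` give moderated t statistics on `d0 + df`
degrees of freedom. Under a Gaussian two-group null this test is calibrated:
the acceptance suite measures a p < 0.05 rate of ≈ 0.050 (2,000 genes,
10 + 10 samples, 20 seeds).

The volcano bi-filter uses **raw** p-values (up: p < 0.05 and FC > 2; down:
p < 0.05 and FC < 0.5). Benjamini–Hochberg q-values are reported in the DE
table for transparency but do not drive the filter; fold change is
`2^log2FC` of log-scale group means (a geometric-mean fold change).

Voom-style precision weights are available but off by default: a lowess
trend (span 0.5) of sqrt(residual sd) against mean log-CPM is evaluated at
each observation's fitted value (clamped to the trend's range) and inverted
to a weight `trend^-4`. They are off by default because the downstream
clustering consumes ranks and z-scores, where the weights have no effect;
they matter only for the DE stage on strongly heteroscedastic counts.

Ordering note: gene-wise standardization and count normalization do not
compose in either order without loss — voom-style weighting is only defined
on counts, and clustering wants scale-free profiles. The pipeline therefore
tests DE on log-CPM (of counts) and clusters the z-scored log-CPM of the
DEG rows; the z-score step drops constant rows (logged as
`n_dropped_constant`).

## Cluster-number selection

For a candidate cluster number K and a clustering backend A, stability is
measured against bootstrap perturbation: A clusters the full genes × samples
z-score matrix once (the reference); each of R replicates resamples genes
with replacement, clusters the resample with a replicate-specific seed, and
is compared to the reference on the unique genes drawn (a duplicated gene's
replicate label is taken from its first occurrence). A replicate drawing
fewer than K unique genes is redrawn (at most 10 times). The objective is
the mean agreement over replicates. Comparing replicate-to-reference (rather
than replicate-to-replicate) needs only R + 1 clusterings per (K, A) and
keeps every objective a mean of i.i.d.-conditioned terms.

Agreement indices, all in [0, 1], from the pair counts N11/N10/N01/N00
(pairs co-clustered in both/only one/neither partition):

- **Jaccard** `N11/(N11+N10+N01)`, **Fowlkes–Mallows**
  `N11/√((N11+N10)(N11+N01))` (0 on empty denominators);
- **MCA** (maximum cluster alignment): the fraction of objects covered by
  the best one-to-one matching of clusters, computed by maximum-weight
  assignment on the contingency table;
- **CQS**: a chance-corrected agreement — the adjusted Rand index mapped to
  [0, 1] via `(ARI+1)/2`, computed from the same pair counts. The exact
  index is pluggable (`cqs_fn`) so an alternative quality score can be
  substituted without touching the bootstrap protocol.

Backends: k-means (Lloyd, k-means++ seeding, best of 10 restarts); online
neural gas (Martinetz–Schulten: prototypes sorted by distance to each
presented sample and pulled with strength `ε(t)·exp(−rank/λ(t))`, `ε`
decaying 0.5 → 0.005 and `λ` K/2 → 0.01 exponentially over 100 epochs;
nearest-prototype assignment; empty prototypes repaired from the farthest
points); single linkage cut to exactly K clusters by replaying the first
n − K merges (a height-threshold cut cannot guarantee K clusters under tied
merge heights). All labels are canonicalized by first occurrence. The
neural-gas inner loop is JIT-compiled when numba is importable; the
pure-numpy fallback performs the identical arithmetic.

The 3 × 4 objectives for K = k_min..k_max form the objective matrix
(default k_max = min(15, n/10), bounded by n/2). K dominates K′ when it is
≥ on all twelve objectives and > on at least one; the non-dominated K are
ranked by **total dominance count** (the sum over other candidates of the
number of objectives strictly won), ties broken toward smaller K. The full
dominance-count matrix is written out so any alternative ordering can be
recomputed from the artifact. Per-(K, backend) bootstrap seeds are derived
as `(seed·1009 + 101·K + 17·algo_index) mod 2³¹`, making the matrix
bit-reproducible; all four indices of a (K, backend) cell are computed from
the same bootstrap clusterings.

## Signature extraction and ranking

Modules are extracted at the selected K with k-means on the z-scored DEG
matrix. Each module's score is the mean Spearman correlation (Pearson on
mid-ranks, average ranks for ties) over all unordered within-module gene
pairs, computed across all samples with both groups pooled; pairs involving
a constant gene vector are excluded from the mean (zero-filling would bias
degenerate modules downward) and singletons are unscorable. The best module
(ties → larger module, then smaller cluster id) is the signature.

## Nearest-shrunken-centroid validation

For gene i and class k: `d_ik = (x̄_ik − x̄_i)/(m_k (s_i + s0))` with pooled
within-class sd `s_i` (n − 2 df), fudge `s0 = median_i s_i`, and
`m_k = √(1/n_k − 1/n)`. Soft-thresholding `d'_ik = sign(d)·max(|d| − Δ, 0)`
yields shrunken centroids `x̄'_ik = x̄_i + m_k (s_i + s0) d'_ik`; samples are
classified by `argmin_k Σ_i (x_i − x̄'_ik)²/(s_i + s0)² − 2 log π_k` with
empirical priors `π_k` (ties → control). Δ is chosen per training set as the
**largest** value on a 30-point grid `[0, max|d_ik|]` minimizing stratified
CV error — the sparsest model at equal error. Evaluation is repeated
stratified 10-fold CV (folds attach to sorted sample IDs, so results are
invariant to input column order); each repeat pools its test-fold
predictions into one confusion matrix, and means/sds over repeats are
reported for sensitivity, specificity, precision and accuracy with the case
group positive. Stratification is not optional: with a 22-vs-253 imbalance,
unstratified folds routinely lose the minority class entirely.

## Synthetic data

The generator plants K* gene modules via one latent factor per module: a
member gene's log2 expression is
`baseline_g + √ρ·f_m(sample) + √(1−ρ)·σ·ε`, so within-module Pearson
correlation is ρ (at σ = 1); group effects add `±log2_effect` to case
samples of DE genes; counts are Poisson draws around `2^logexpr`
(`lognormal_counts`) or the Gaussian log-values are returned directly
(`gaussian_log`). Everything is a deterministic function of the seed.

Presets:

- `make_paper_shaped(seed)`: 2,000 genes, 22 control + 253 case, five
  35-gene modules — one tight all-up module (ρ = 0.8) and four looser
  up/up/down/down modules (ρ = 0.3), effect 1.5 log2 units, Poisson counts.
  This mirrors the unbalanced two-subtype study shape the pipeline targets.
- `make_planted_k(k_star, seed)`: K* twenty-gene modules, no background, no
  group effect, ρ = 0.95, 40 samples. Under the factor model the
  between-module center separation is `√(2ρS)` versus within-module spread
  `√(1−ρ)` per dimension — ≈ 39× here, comfortably above the ≥ 8× separation
  the preset is meant to provide for cluster-number recovery tests.

What the generator does **not** emulate: library-size and GC biases,
overdispersion beyond Poisson, outlier samples, and module overlap. Two
consequences observed in the shipped runs are worth knowing:

- On the paper-shaped preset the DE shift itself is a strong shared
  component among DEGs, so the most *stable* clustering of the DEG matrix
  is often the coarse up/down split (selected K of 2–3) rather than the
  planted 5. Module-count recovery is therefore exercised on the clean
  planted-K preset, and signature recovery on the paper-shaped preset is
  tested at the planted K; the end-to-end pipeline remains honest about
  which K its stability objectives actually prefer.
- A ρ = 0.8 module has essentially one effective degree of freedom, so the
  shrunken-centroid classifier — which assumes independent genes — can find
  that no threshold beats the majority-class CV error under the 12:1
  imbalance and legitimately collapse toward the prior (specificity near 0
  at some seeds, accuracy ≈ the majority rate). Real signatures with more
  independent information do not trigger this; the classifier's limit
  behaviors are verified separately.

## Problem sizes and numerics

The shipped tests and the acceptance script use: planted-K recovery at
K* ∈ {2,3,4}, 20 genes/module, R = 30 bootstrap replicates over K = 2..8;
paper-shaped runs at 2,000 × 275 with R = 30; CV at 10 repeats × 10 folds
with a 30-point Δ grid — sizes chosen so a full run completes in seconds to
a few minutes on one CPU while leaving every qualitative property of the
method visible. Tolerances: z-score and shrinkage identities at 1e−9;
index/oracle comparisons exact; stability and recovery statements are
fractions over ≥ 10 seeds. Degenerate inputs are handled explicitly:
all-zero/constant genes are dropped and counted, zero variances shrink to
the prior, empty clusters are repaired, and replicates with fewer unique
objects than K are redrawn.
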