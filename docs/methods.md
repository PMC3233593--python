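# Methods

This note documents the models and numerical choices behind `biofilmnet`,
what the synthetic generator does and does not emulate, and the known
limitations.

## Synthetic communities

Abundance profiles live on a latent Gaussian scale. A taxon in planted
module *m* is

    x_i = sqrt(w) · L_m + sqrt(1 − w) · ε_i + σ · η_i,

with `L_m` the module's latent profile (standardized to mean 0, sd 1 per
module), `w = within_module_cor ∈ (0, 1]` the target pairwise correlation
in the noiseless limit, and `ε_i, η_i` iid standard normal (σ =
`noise_sd`, default 0.3). Background taxa are pure standard normal noise.
A constant baseline of 10 is added so values are essentially always
positive, mimicking fluorescence; the pipeline is scale-sensitive only
through Pearson correlation, which the shift leaves untouched. Default
study-scale conditions follow the motivating data: tens to a few hundred
taxa, tens to thousands of samples, with `w = 0.8` a realistic "tight
module" and `w = 0.7, σ = 0.5, n ≥ 100` the stress condition the recovery
guarantee is stated for.

Traits are `Σ_m loading_m · L_m + N(0, 1)`, plus one pure-noise trait
always appended as a negative control for module–trait correlation.

Missingness is missing-completely-at-random with an *exact* masked count
`round(rate · n · p)` rather than Bernoulli draws, which makes counts
testable; one cell per row and per column is protected so BPCA always has
an observation in every margin. Outlier samples are shifted by
`shift × per-taxon sd`, a displacement symmetric in the sign of the shift.

What the generator does **not** emulate: the noise model of checkerboard /
HOMIM fluorescence chemistry (unknown; the Gaussian latent model is a
stand-in, not a claim about the assays), compositional closure of relative
abundances, phylogenetically structured correlation, and
missing-not-at-random detection limits. Passing tests therefore certify
the algorithmic pipeline, not assay-specific robustness.

## BPCA imputation

`bpca_impute` fits a probabilistic PCA model `y = W x + μ + ε` to the
samples (columns, treated as observations of a taxa-dimensional vector) by
variational expectation–maximization with an automatic relevance
determination (ARD) prior on the loading columns. Each iteration computes
the posterior over latent scores from the *observed* coordinates of each
sample, fills the missing coordinates with posterior means `W_m x + μ_m`,
and then updates `W` (ridge-regularized by `diag(α)/τ`), `μ`, the noise
precision τ, and the ARD precisions `α_j = D/‖w_j‖²`. Defaults: `q =
min(n, p) − 1` axes with ARD pruning deciding the effective dimension,
`tol = 1e−6` on the maximum absolute change of any imputed value,
`max_iter = 200`. τ is capped at 1e12 so noiseless (exactly low-rank)
inputs remain numerically stable. Observed entries are copied back
verbatim every iteration — imputation can never alter data. On noiseless
low-rank inputs the change criterion can stay just above `tol` for many
iterations; the estimate is then already accurate (rank-1 RMSE < 1e−3 in
the tests) and `converged=False` simply reports that the cap was hit.

## Outlier samples

Samples are clustered by average-linkage on Euclidean distances between
abundance profiles, and each sample is assigned the height at which it
first joins the dendrogram. The default threshold is
`median + 12 × MAD` of these joining heights (raw, unscaled MAD). The
factor is deliberately large: under average linkage the joining heights of
perfectly homogeneous Gaussian samples have a heavy right tail (late
joiners merge near the root), with maxima around 9–11 raw-MAD units, while
a sample displaced by ten per-taxon standard deviations sits near 80. A
fixed `cut_height` is supported when the threshold should be explicit.
After outlier removal the remaining samples are re-clustered and the tree
cut into `n_clusters` major sample clusters (`maxclust` criterion).

## Network construction

Unsigned throughout: `a_ij = |cor_ij|^β`, β ≥ 1. The scale-free criterion
bins positive connectivities `k_i = Σ_{j≠i} a_ij` into 10 log-spaced bins
and takes R² as the squared Pearson correlation between `log10(frequency)`
and `log10(mean bin connectivity)`; zero connectivities are dropped before
binning, and a degenerate single-bin distribution is an error rather than
a fit. The chosen β is the smallest of 1..20 reaching the target R²
(default 0.85), falling back to the argmax when no candidate reaches it —
small or uniformly correlated networks often cannot achieve scale-free
fit, and the maximum attained value is then reported alongside.

Topological overlap uses the standard unsigned form

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    l_ij = Σ_{u≠i,j} a_iu · a_uj,

with unit diagonal and `dissTOM = 1 − TOM`. Isolated taxa (k = 0) get
overlap 0 by convention (the 0/1 limit). The vectorized implementation is
checked against a brute-force triple loop to 1e−12 in the tests.

## Module detection

Average-linkage clustering on dissTOM; modules are the branches below a
static cut at `0.99 × max merge height` (configurable) containing at least
`min_module_size = 5` leaves — small modules of five taxa are
biologically meaningful in this setting, hence the low default. Everything
else is grey (unassigned); grey is reported with statistics like any
module but flagged with a warning that only a subset of its nodes may be
connected. Colors follow the conventional palette in decreasing size
order; equal sizes break ties by the lexicographically smallest member, so
labeling is deterministic. The dynamic branch-cutting refinement used by
some co-expression pipelines is intentionally out of scope; the static cut
is transparent and sufficient for planted-structure recovery (ARI ≥ 0.9
at `w ≥ 0.7`, ≥ 100 samples).

Eigenspecies are first right-singular vectors of the z-scored member
matrix (unit norm across samples), signed so the mean correlation with
members is positive; variance explained is `s₁²/Σs²`. A single-member
module's eigenspecies is that taxon's standardized profile. Module–trait
association is the Pearson correlation of eigenspecies with traits, with
two-sided p from `t = r·sqrt((n−2)/(1−r²))` on n−2 df; p-values are raw by
default (a Benjamini–Hochberg pass can be applied downstream), matching
how such module–trait grids are usually reported.

### Consensus across datasets

Per-dataset TOMs are rescaled so their 95th percentiles match the smallest
one (removing dataset-scale differences), then combined by elementwise
minimum: a pair is only as connected as its weakest dataset. Because a
static cut always produces branches even in structureless data, a
candidate consensus module must additionally be *cohesive*: its mean
within-module consensus TOM must be at least twice the mean over all
other pairs. If nothing survives, an explicit no-consensus report is
returned — an informative outcome in its own right, since communities
re-associating under different conditions genuinely share no modules.

## Module graphs and statistics

A module's weighted subnetwork is thresholded into a simple graph, either
at a fixed TOM cutoff or at the weight realizing a target density (default
0.3); the threshold used is always recorded in the output, since
published module renderings rarely state their export cutoff. Descriptors:
per-node clustering `C_n = 2e_n/(k_n(k_n−1))` (0 for degree < 2), network
clustering = mean over all nodes including isolated ones; `avg_neighbors =
2E/n`; `density = 2E/(n(n−1))`, identically `avg_neighbors/(n−1)`; degree
centralization `(n/(n−2))·(k_max/(n−1) − density)`, 1 for a star, 0 for a
clique. One published descriptor row prints a density inconsistent with
its own node and neighbor counts (0.05 where the identity gives 0.5); the
identity is treated as authoritative.

## Hubs and helpers

Betweenness is unnormalized (each unordered pair counted once; brute-force
path enumeration is the test oracle on all graphs ≤ 8 nodes). MNC is the
node count of the largest connected component induced on a node's
neighbors; DMNC is that component's `E*/V*^ε` with ε = 1.7, the published
default of the hub-screening scheme this follows; DSS keeps the top
`⌈n/2⌉` nodes by MNC then the top `⌈n/4⌉` of those by DMNC. All ties break
by degree then lexicographic id, making rankings deterministic and
label-permutation-stable.

Helper candidates for an uncultivated target must be cultivable and share
the target's module color in at least `required_clusters` sample clusters;
ranking prefers a direct edge to the target in the module graph, then
breadth of co-occurrence, then centrality (betweenness by default, because
a high-betweenness helper is best placed to bridge the target to the rest
of the module; configurable to degree or DSS membership). The qPCR
fold-change convention is the standard relative quantification
`2^−(Ct_exp − Ct_ctrl)` — the printed formula in the source material is
typographically garbled, and this is the cited convention's reading.

## Pipeline, determinism, problem sizes

All randomness flows from one integer seed in `RunConfig`; reports
serialize with sorted keys and no timestamps, so identical configurations
produce bit-identical report bodies. Every intermediate (imputed matrix,
correlation, TOM, assignments, eigenspecies, stats, hub table, helper
list) is archived in the output directory, and every output table carries
the parameters that produced it.

Test and acceptance problem sizes — 25–300 taxa, 40–150 samples, five
replicate seeds for stochastic guarantees — were chosen as the smallest
communities on which the planted structure is unambiguous; recovery only
improves with the larger sample counts typical of real array studies.

## Known limitations

- Pearson co-occurrence on abundances ignores compositionality; strong
  negative correlations induced by closure are not modeled.
- The static tree cut has no concept of nested modules; deeply nested
  block structure will merge or fragment depending on the cut height.
- Scale-free fit on small (< 40 taxa) networks is unstable and the
  fallback-to-argmax path then effectively picks the best of a bad set —
  the R² in the fit table should always be inspected.
- BPCA assumes a low-rank Gaussian factor structure; heavy-tailed or
  zero-inflated data will be imputed toward the factor model's means.
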