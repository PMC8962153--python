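# Methods

This note documents the models, defaults and numerical choices behind
`cultureshock`, and what the synthetic benchmark does and does not
demonstrate about real data.

## Quality control

Per-cell metrics are `nCount_RNA` (total UMIs), `nFeature_RNA` (genes
with a nonzero count) and `percent_mito` (percentage of UMIs from
`mt-`-prefixed genes, 0 for empty cells).  Filter presets encode the
two-round cleaning used per preparation:

| preset        | clauses (remove if)                                        |
|---------------|------------------------------------------------------------|
| astro_round1  | nCount_RNA > 50 000; percent_mito > 10                     |
| astro_round2  | percent_mito > 5; nCount_RNA < 3 000; nFeature_RNA > 6 000 |
| fresh_round1  | nCount_RNA > 10 000                                        |
| fresh_round2  | percent_mito > 10                                          |
| micro_round1  | nCount_RNA > 10 000; percent_mito > 20                     |
| micro_round2  | percent_mito > 5                                           |

All comparisons are strict; a cell sitting exactly on a threshold is
retained.  This is documented explicitly because subset semantics in
other toolchains differ subtly at boundaries.  Cluster-level removals
(contaminated or empty-droplet clusters) have no objective criterion,
so they are an explicit `drop_clusters` call with a user-supplied list
rather than an automatic rule.  Myeloid selection keeps clusters where
the fraction of cells with at least one count for at least half of the
marker panel (*Hexb*, *Trem2*, *C1qa*, *Ctss*) exceeds a threshold
(default 0.5); the threshold is our choice, exposed as a parameter.

## Normalisation and clustering

Regularised negative-binomial normalisation is replaced by per-cell
depth normalisation to 10,000 counts followed by log1p, per-gene
covariate regression (ordinary least squares) and z-scaling clipped at
±10.  The downstream statistics used here (rank tests,
percentage-of-UMI scores, correlations) do not depend on the
variance-stabilisation specifics, and this keeps the dependency
footprint small.  Clustering uses PCA (default 50 components, top 2,000
variable genes), an SNN graph over the first 30 components (k = 20,
Jaccard weights, pruned below 1/15) and igraph's Louvain
(`community_multilevel`) at the configured resolution with a seeded
RNG; Leiden is available behind a flag.  Cluster ids are relabelled by
descending size.  The SNN k and the variable-feature count are not
externally fixed and are exposed as configuration.

Integration is specified as a contract — cells of the same state from
different batches must mix — and implemented as mutual-nearest-
neighbour correction in PCA space: anchors are MNN pairs (k = 20
each way) between the reference and each incoming batch, and each cell
moves by a Gaussian-kernel-weighted average of its batch's anchor
correction vectors.  Counts are never altered; only the embedding.
UMAP-style layouts are intentionally out of scope (stochastic,
display-only).

## State scoring and classification

A cell's score for a gene set is 100 x (UMIs in set / total UMIs); for
disjoint sets covering the gene universe the per-cell scores sum to
100 exactly.  Overlaps between state lists are resolved by a
user-supplied priority order (`enforce_nonoverlap`), since no canonical
resolution rule exists.  Detection summaries call a gene detected when
it has a nonzero count in at least 10 cells (configurable) and report
percentages rounded to one decimal.  Cluster classification z-scales
per-cluster mean scores **across clusters** within each set (not across
cells; with two clusters the scaled matrix is ±1 by construction) and
assigns each cluster the class of its argmax among class-defining sets;
ties resolve to the configured priority order and are logged.
Average-linkage Euclidean hierarchical clustering of the scaled matrix
is returned for display ordering only.  Between-cluster score tests are
two-tailed two-sample t-tests with Bonferroni correction over the batch.

## Differential expression

Two-group tests are Wilcoxon rank-sum on log-normalised expression with
all cells of a preparation pooled per group ("pseudo-bulk" in the
cell-level sense; true per-sample aggregation is a separate function,
`aggregate_pseudobulk`).  For pooled sizes of twelve cells or fewer the
p-value is the exact two-sided permutation tail computed by enumerating
all group assignments of the midranks; otherwise the tie-corrected
normal approximation is used.  The fold change is
`ln(mean(expm1(norm_a)) + 1) − ln(mean(expm1(norm_b)) + 1)` (natural
log) — stated explicitly because "average logFC" conventions differ
across tools; this matches the convention of the pipeline the presets
mirror.  Adjustment is Bonferroni over the genes tested
(Benjamini–Hochberg behind a flag).  Contrast thresholds: adjusted
p < 0.05 with |logFC| ≥ 0.5 for culture-vs-fresh contrasts and ≥ 0.3
for culture-vs-culture; volcano highlighting uses p < 0.01 and
|logFC| > 1 (strict).  No sample-of-origin covariate is adjusted by
default.

## Co-expression networks

On the per-cluster downsampled matrix (default 400 cells per cluster),
genes expressed in fewer than 10 cells are dropped; pairwise Pearson
correlations (Spearman by flag) are tested with the t transform and
kept at Benjamini–Hochberg FDR < 0.05 — "significant correlation
edges" is otherwise undefined, so edge significance is an explicit
parameter.  Node strength sums |r| over a gene's significant edges
(configurable to signed r or edge counts); |r| keeps strength
non-negative and lets anti-correlated partners contribute
connectivity, with sign entering only through the module-score
convention.  Modules are Louvain communities of the |r|-weighted graph
(a generic substitute for multiscale embedded co-expression
clustering, declared in the network metadata); hubs are genes whose
within-module degree z-score is ≥ 2 (modules smaller than 3, or with
no degree variance, have none).  The weighted module expression of a
cell is the strength-weighted sum of the module genes' log-normalised
expression, each signed by its correlation with the module's
largest-strength gene (ties break alphabetically and are logged).  The
sign of the score is therefore defined only relative to that hub.

## Causal networks and key-driver analysis

Gene selection ranks residual variance of log-normalised expression
after regressing out covariates — percent_mito and the cluster label
(one-hot) — matching the residual-based selection the approach calls
for; the default selection size used in the benchmark is 200.  The
structure learner is greedy score-based search over DAGs with a
decomposable Gaussian score: a forward phase that applies the best
single-parent addition (vectorised via rank-one residual-variance
updates) until none improves, then backward deletion and edge-reversal
phases, iterated to convergence; acyclicity is enforced with an
incremental reachability matrix and a parent cap (default 3).  The
complexity term carries a multiplier of 2 on the BIC penalty
(extended-BIC style): depth-normalised expression is compositionally
coupled, and the plain-BIC solution accumulates a dense tail of weak
edges that slows search and buries real structure.  Externally supplied
directed networks are accepted unchanged.

Effector sets per network: the significant DE genes, each co-expression
module, and each DE-module overlap, all restricted to network nodes —
2M+1 sets for M modules before empty sets are dropped (the identity is
tracked even when empties are removed).  A node's downstream set is
everything reachable within 3 directed layers (the depth is not
externally fixed; it is exposed as a parameter).  Enrichment is the
hypergeometric upper tail with the network's node set as universe —
the only self-consistent choice given node-restricted effector sets —
with BH adjustment across all (node, set) pairs; nomination uses the
adjusted p-value at 0.05.  Cross-network prioritisation is
lexicographic: present in both networks, then summed category count,
then summed nominating-set count, ties alphabetical; the numeric score
(4·both + categories + 0.01·sets) is display-only.

## Synthetic data generator

The generator emulates the study's structure at a desk scale: default
1,500 genes x ~2,000 cells, 4 discrete states with disjoint 20-gene
programs (rate multipliers U(4, 8)), 3 correlated 25-gene modules,
a 150-node regulatory DAG, 60 condition-effect genes (natural-log
effect ±1.0, 70% up), 13 `mt-` genes pinned to ~3% of baseline mass,
and log-normal library sizes (median 6,000, σ = 0.25).  Counts are
gamma-Poisson with dispersion 0.5.  Determinism is per-seed and
byte-identical.

Design choices that make the planted truth recoverable by the methods
under test, rather than only present:

* **Module loadings are all-positive by default** (a
  `neg_loading_frac` parameter reintroduces anti-correlated members).
  Depth normalisation couples every gene to every other through the
  library total, and a negative-loading gene acquires thousands of
  weak positive correlations to the background that outweigh its
  within-module edges under modularity optimisation.
* **Planted-structure genes have floored baselines** (modules ×2,
  DAG ×2, condition genes ×3 with a floor of the median scale), so the
  planted signal is expressed at detectable levels; log1p attenuation
  otherwise hides structure planted on genes with mean counts below
  one.
* **Regulatory propagation is damped**: driver roots draw latents with
  sd 1.2; each child receives 0.8 x the average of its parents plus
  fresh noise with sd 0.45.  With undamped unit coefficients the
  roots would have the *lowest* variance in the DAG block and
  variance-ranked gene selection could never include the drivers.
  Damping makes upstream regulators the most variable genes — the
  premise of top-varying selection.
* **The DAG has contrast**: half of the non-driver nodes form 3-layer
  fan-out subtrees under the 5 driver roots (about half of layer-1
  nodes get a second driver parent, creating colliders that orient the
  driver out-edges); the other half is background regulatory structure
  with no condition effects.  90% of the condition genes are sampled
  stratified across the driver subtrees (the rest outside the DAG).
  Without condition-free background nodes, DE density in a driver's
  downstream set would equal the universe density and hypergeometric
  enrichment would be impossible by construction.

QC artifacts are injected exactly: `round(frac x n)` cells get their
mitochondrial share inflated to 25–45% (above both the 10% and 20%
thresholds) or their library binomially thinned below 3,000 counts,
with ground-truth flags in the metadata.

**What passing the benchmark does and does not show.**  The generator
produces overdispersed counts, library-size variation, correlated
modules, discrete states and causal structure, so it exercises every
pipeline stage with known answers.  It does not emulate ambient RNA,
doublets, batch chemistry, continuous state gradients, realistic
mouse expression magnitudes, or feedback regulation; recovery rates on
this benchmark are upper bounds, not estimates of performance on real
tissue data.

## Benchmark problem sizes

The recovery benchmark uses a single-condition 2,000-cell matrix for
state recovery; a three-preparation 2,004-cell matrix (667 cells per
preparation) for DE, modules and key drivers; 200-gene learned causal
networks per culture preparation; and an 800-gene, 800-cell null for
type-I calibration.  These sizes keep the full suite in the
minutes range on one CPU while leaving each recovery criterion
comfortably powered.

## Pipeline and reproducibility

All stages run from one YAML config with explicit seeds; stage seeds
are derived from the top-level seed.  Every artifact carries a
16-hex-digit SHA-256 config hash (TSVs as a leading comment line, JSON
as a `_config_hash` field), so artifacts from different runs cannot be
mixed silently.  Identical configs produce byte-identical numeric
outputs.  Stage failures abort with the stage name and a cell-metadata
snapshot of the failing stage's input.

## Known limitations

* The correlation-graph module finder is a generic stand-in for
  multiscale embedded co-expression analysis: no planar filtering, no
  multiscale module hierarchy.
* The greedy DAG learner recovers structure only up to Markov
  equivalence where the data do not orient edges; learned-network
  driver recovery is accordingly weaker than with the true graph.
* Bonferroni over genes is conservative for DE; BH is available but
  changes the significant-set semantics.
* Integration is a contract implementation (MNN shift in PCA space),
  not a reimplementation of any specific published integrator.
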