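# Methods

This note documents the models and procedures implemented in
`gams_stratify`, their assumptions, the defaults that matter, and the
deliberate simplifications — in the package's own terms.

## The synthetic data model

The generator emulates a multi-sample droplet scRNA-seq experiment on a
glioma microenvironment.  Counts for gene g in cell c follow a negative
binomial with mean μ_gc and size θ (variance μ + μ²/θ); the default
θ = 2 is realistically over-dispersed for raw UMI-like counts.

Structure is planted in the means:

* **Populations.**  Each configured population (default: GAMs, tumor,
  lymphocytes; 200 cells each) has its own marker genes whose mean is
  `baseline_mean` (0.5 counts/cell) outside the population and
  `marker_effect × baseline_mean` (8 × 0.5 = 4) inside it.
* **Focal gene and programs.**  Every cell carries a latent level
  z ~ N(0, 1).  The focal gene's mean is e^{a + b·z} (a = ln 2, b = 1,
  i.e. a typical moderately-expressed gene whose biological state
  varies one log-unit per latent SD), and each of the 50 positively /
  50 negatively coupled program genes has mean baseline·e^{±c·z} with
  coupling c = 0.8.  This produces a monotone association detectable
  both by rank correlation and by tree-based ranking, without assuming
  linearity on any particular scale.
* **Annotation flags.**  5% / 10% / 0.2% of the 1900 noise genes are
  renamed with the real-world prefixes `mt-`, `Rps`/`Rpl`, `Hb…`, so
  the QC module's name-based annotation path is exercised, and so the
  default dataset passes the published thresholds with realistic
  margins (≈4–5% mitochondrial, ≈9% ribosomal, ≈0.2% RBC content).
* **Samples.**  Cells are assigned round-robin to `n_samples` samples
  that differ only by a multiplicative library-size factor (±20%).
  There is deliberately no batch-effect model: cross-sample integration
  is out of scope, and the clustering stage simply concatenates samples.
* **Documents and channels.**  Marker genes of each population emit
  that population's planted keyword at rate 0.3 in a 40-word document
  drawn from a 2000-term vocabulary (so a keyword appears in ~2% of
  unrelated documents, but in practically every marker document).
  Ligand–receptor channels connect a sender population's marker gene to
  a receiver population's marker gene(s); one planted channel uses a
  two-subunit receptor complex.  Decoy pairs are drawn from unflagged
  noise genes.

What the generator does **not** emulate: batch effects, doublets,
ambient RNA, UMI saturation, gene–gene correlation beyond the single
latent factor, or realistic gene-length/GC biases.  Tests passing on
this data therefore demonstrate that each algorithm recovers the
structure it claims to recover under its own model assumptions — not
that the pipeline is robust to every artifact of real droplet data.

## QC

Percentages are computed on raw counts (the metrics are computed before
any filtering, and reused by every rule).  The filter order is fixed:
min-genes cells → gene support (recomputed on surviving cells) →
percentage screens → max-genes cap, with strict/non-strict inequalities
exactly as configured (<, >, <, ≥, <).  Two intentional reading
choices are worth flagging:

* the "ribosomal percentage > 5%" rule *keeps* cells above 5% — i.e.
  removes low-ribosomal-content cells.  This direction is unusual for
  scRNA-seq QC but is applied as configured; flip `min_pct_ribo` to 0
  to disable it.
* the upper gene cap ("fewer than 3000 detected genes") is interpreted
  as detected genes per cell (a doublet proxy), not total counts.

An empty post-filter matrix raises an explicit error rather than
returning a degenerate object.

## Normalization and clustering

Full regularized per-gene NB regression is replaced by analytic Pearson
residuals with a single global θ (default 100): μ_gc is the product of
the cell and gene margins over the grand total, r = (x − μ)/√(μ + μ²/θ),
clipped at ±√n_cells.  This captures the variance stabilization of the
regularized-regression approach while remaining exactly testable (a
margin-multiplicative matrix has all-zero residuals) and is documented
as an approximation of it.  HVGs are the top genes by residual
variance (default 3000).  PCA is exact SVD on the mean-centered HVG
residuals, with component signs fixed by making each component's
largest-magnitude loading positive, so embeddings are bit-reproducible.
Clustering builds a kNN graph (k = 20, Euclidean in 30-PC space, ties
broken by cell index), weights edges by the Jaccard overlap of
neighbor sets, and runs Leiden modularity optimization (resolution 1.0,
seeded).  The resolution and k are pipeline defaults, not published
values; at the default synthetic conditions they recover the planted
populations with median ARI ≈ 0.94.

Cluster-mean heatmap rows are z-scored across clusters with the sample
SD (ddof = 1, the standard heatmap row-scaling convention; a two-cluster
row with means 1 and 3 maps to ∓0.7071), with 0/0 treated as 0, and
ordered by average-linkage hierarchical clustering on Euclidean
distance.

## Markers

One-vs-rest per cluster on log-normalized expression (library size →
10⁴, log1p).  Presence fractions use value > 0; fold change is
ln(mean_in + ε) − ln(mean_out + ε) (ε = 10⁻⁹) on expm1-backtransformed
values, natural log by convention.  The Wilcoxon rank-sum test uses the
exact null when both arms are ≤20 and tie-free, otherwise the
tie-corrected normal approximation.  BH adjustment runs over all
(gene, cluster) candidates that pass the presence and fold-change
pre-filters — screen-then-adjust, matching the classic marker tool's
order of operations.  Positivity for co-expression percentages
("focal+ among anchor+ cells") is raw count > 0; the threshold is
configurable since no published definition exists.

## Focal-gene association

Discretization uses two increasing cut-points with left-open/right-closed
intervals and the lowest bin extended to −∞.  The published SORL1
cut-points (−0.3428585, 0.8406330] are shipped as named constants but
applied only on request — they are specific to the original dataset's
variance-stabilized scale; by default cut-points are empirical tertiles
(inverse-CDF/type-1 quantiles) of the focal gene's residuals.

The Spearman screen ranks with average ties and uses the t
approximation for p-values; constant genes are reported as NA and
excluded from the BH family.

MCFS relative importance follows a documented stand-in for the cited
Monte-Carlo feature-selection algorithm (whose exact RI formula the
source does not restate): per tree, a gene subset of size
round(3·√n_genes) is drawn without replacement and a 0.66-fraction
bootstrap of cells with replacement; a Gini CART tree (max depth 6, min
leaf 5) is fitted, and every split on gene g adds
wAcc^u · (n_node/n_root)^v to RI(g), with wAcc the mean per-class
recall on out-of-bag cells and u = v = 1 by default (all exponents
configurable).  Final RI is normalized by the number of subsets
containing the gene, so an unsampled gene has RI exactly 0.  Each
(tree, subset, bootstrap) draw is seeded from a counter-based stream
keyed on the canonically name-sorted gene list, which makes the ranking
independent of column order and of evaluation order.

Significance uses the permutation method: the cut-off is the empirical
(1 − α) quantile of the maximum RI over genes across label
permutations.  Being a maximum-based null, this controls family-wise
error and is deliberately conservative: on null data essentially
nothing is called significant (the calibration tests verify ≤ α + 0.03),
and on coupled data the *ranking* is the sensitive readout — the top of
the RI list is dominated by program genes long before the significance
cut-off is reached.  Users scanning for candidate predictors should
read the ranking (as the original analysis did, taking the top 25
genes) and treat the significant set as a high-confidence core.

Classifier validation fits five fixed families — CART, L2 logistic
regression (lbfgs, 1000 iterations), 100-tree random forest, Gaussian
naive Bayes, RBF SVM (C = 1) — on a single stratified 75/25 split,
reporting held-out accuracy.  A single split (not cross-validation) is
used to match the train/validation-set design.

## Keywords

TF-IDF is fixed as raw tf × ln(N/df) with L2 row normalization (no
smoothing, no sublinear tf; both available as options elsewhere in the
API surface deliberately were not added to keep the variant explicit).
Tokenization: lowercase, split on non-alphanumerics, drop tokens
shorter than 3 characters and a built-in English stopword list.  The
description corpus is an input file (two-column TSV or the synthetic
generator's output); no live database queries are made, removing
network and version dependence.  Documents are per gene; cluster-level
keywords aggregate per-gene vectors by the within-cluster mean, and a
term's uniqueness score is that mean minus the best competing cluster's
mean (non-positive scores are dropped).  Document clustering cuts an
average-linkage dendrogram on cosine distance either to a cluster count
or at a height.

## Communication scoring

A minimal faithful mechanism replaces the cited communication-inference
package: arithmetic group means of non-negative expression (expm1 of
log-normalized values) instead of trimeans, geometric-mean collapse of
multi-subunit complexes, the Hill transform P = (L·R)ⁿ/(Khⁿ + (L·R)ⁿ)
with Kh = 0.5 and n = 1, and a label-permutation test with the add-one
estimator p = (1 + #{null ≥ obs})/(n_perm + 1), so p is never 0.  All
constants are configurable.  The focal-gene subgroup bins for GAMs,
[0; 0.5], (0.5; 1.5], (1.5; ∞), are applied on the normalized-expression
scale.  Pathway contribution patterns sum probabilities per sender (or
receiver) over a pathway's pairs and normalize each pathway row by its
maximum; note that normalization means that dropping non-significant
pairs can raise a group's *normalized* score even though unnormalized
totals can only decrease (`normalize=False` exposes the monotone
quantity).

In the pipeline, the cluster → group mapping that a biologist would
curate by eye is either supplied in the run configuration or, on
synthetic runs, derived as each cluster's majority planted population —
a synthetic stand-in for the manual annotation step.

## Pipeline and reproducibility

Stages exchange plain-text artifacts (MatrixMarket + TSV triplets, CSV,
JSON) in a run directory, so every stage is independently runnable and
resumable (`skip` lists, `--stage`).  The global seed propagates to
each stochastic stage with a fixed per-stage offset; `summary.json`
echoes the fully resolved configuration and the SHA-256 checksum of
every output.  Two runs with the same configuration and seed are
byte-identical.

## Problem sizes and numerical choices

Default test-suite and demo sizes — 600 cells × ~2060 genes, 300–500
trees, 20–30 permutations, 100 communication permutations — were chosen
so that each statistical property is measurable with comfortable
margins on a single CPU in minutes; larger values change precision, not
behavior.  Degenerate inputs have defined outcomes throughout: zero
cells after QC and zero grand totals raise, all-zero genes get zero
residuals and NA correlations, all-zero documents sit at cosine
distance 1, empty clusters are skipped with warnings, and fold changes
of 0/0 return 1 with a degeneracy warning.

## Known limitations

* The Pearson-residual normalization uses one global θ, not per-gene
  regularized estimates; strongly depth-confounded designs would need
  the full regression treatment.
* No batch integration — multi-sample data are concatenated.
* The MCFS significance cut-off is family-wise conservative by
  construction (see above); use the ranking for discovery.
* The communication module is a simplified mechanism, suitable for
  method-level reasoning and synthetic benchmarking rather than as a
  drop-in replacement for curated-database analyses.
* UMAP visualization is intentionally untested surface; no guarantees
  attach to any plot coordinates.
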