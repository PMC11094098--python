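# gams-stratify

Stratification of glioma-associated microglia/macrophages (GAMs) by the
expression level of a single *focal gene* (by default called ``SORL1``),
implemented as a tested, reusable single-cell analysis pipeline with a
synthetic data generator that plants known structure and ships its
ground truth.

## Who this is for

Computational biologists who want a desk-scale, fully reproducible
version of a common tumor-microenvironment analysis chain: start from a
sparse gene×cell count matrix, and end with (i) cell clusters and their
marker genes, (ii) the genes whose expression predicts whether a
myeloid cell expresses the focal gene at a low, medium or high level,
(iii) functional keywords characterizing each cluster, and (iv)
ligand–receptor communication scores between cell groups — including
GAMs subgroups split by the focal-gene level.  Because every stage runs
on synthetic data with planted ground truth, every claim the pipeline
makes (cluster recovery, marker recall, screen calibration, channel
detection) is measurable.

## What the pipeline computes

1. **QC** (`gams_stratify.qc`) — per-cell metrics and filters: keep cells
   detecting ≥500 genes and <3000 genes, genes seen in ≥5 cells, and
   cells with mitochondrial counts <15%, ribosomal counts >5% and
   red-blood-cell counts <0.5% of the library.
2. **Normalization & clustering** (`normalize_cluster`) — analytic
   Pearson residuals under a negative-binomial null,
   r = (x − μ)/√(μ + μ²/θ) with μ the product of cell and gene margins
   over the grand total, clipped at ±√n_cells; top-3000
   highest-residual-variance genes; 30 principal components; Leiden
   community detection on a Jaccard-weighted kNN graph.
3. **Markers** (`markers`) — one-vs-rest Wilcoxon rank-sum with the
   classic criteria (presence ≥50% of cluster cells, positive natural-log
   fold change ≥0.25, Benjamini–Hochberg FDR), per-cluster fold change
   of the focal gene, and double-positive co-expression percentages.
4. **Focal-gene association** (`focal_assoc`) — discretize the focal
   gene into low/medium/high (empirical tertiles, or the published
   cut-points (−0.3428585, 0.8406330] when configured); a Spearman
   screen with FDR 0.05; and Monte-Carlo feature selection (MCFS): an
   ensemble of depth-limited CART trees on random gene subsets and
   bootstrap cell samples, accumulating per-gene relative importance
   RI(g) = Σ_splits wAcc^u · (n_node/n_root)^v with wAcc the tree's
   out-of-bag mean per-class recall.  Significance comes from the
   (1−α) quantile of max-RI under label permutations, and the selected
   genes are validated by five classifier families on a stratified
   75/25 split.
5. **Keywords** (`nlp_keywords`) — each gene is a text document; TF-IDF
   weights tf·ln(N/df) with L2 row normalization, cosine-distance
   average-linkage document clustering, and per-group unique keywords
   (within-group mean TF-IDF minus the best competing group).
6. **Communication** (`commscore`) — for every sender group s, receiver
   group r and ligand–receptor pair, P = L·R/(Kh + L·R) (Hill function,
   Kh = 0.5) of the group-mean ligand and receptor expression
   (multi-subunit complexes collapsed by geometric mean), label-permutation
   p-values, and per-pathway outgoing/incoming contribution patterns.
   GAMs cells are split into `GAMs_low` [0; 0.5], `GAMs_med` (0.5; 1.5]
   and `GAMs_hi` (1.5; ∞) by normalized focal expression.
7. **Synthetic data** (`synthdata`) — negative-binomial counts
   (variance μ + μ²/θ, θ = 2) with planted populations and marker
   genes, a latent per-cell level z ~ N(0,1) driving the focal gene
   (mean e^{a+bz}) and its positively/negatively coupled program genes
   (mean baseline·e^{±cz}), prefix-flagged mito/ribo/RBC genes, planted
   document keywords and planted ligand–receptor channels.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from gams_stratify import synthdata, qc
from gams_stratify.normalize_cluster import (
    pearson_residuals, select_hvg, pca_embed, cluster_cells, log_normalize)
from gams_stratify.focal_assoc import (
    discretize_expression, quantile_cutpoints, spearman_screen,
    mcfs_rank, MCFSSettings)

adata, truth = synthdata.generate_dataset(synthdata.SynthConfig(seed=7))
filtered, report = qc.filter_cells_genes(adata)
print(f"QC kept {report.cells_kept}/{report.cells_in} cells "
      f"and {report.genes_kept}/{report.genes_in} genes")

norm = pearson_residuals(filtered, theta=100.0)
emb = pca_embed(norm.subset_genes(select_hvg(norm, n_top=2000)), n_pcs=30)
clusters = cluster_cells(emb, k_neighbors=20, resolution=1.0, seed=7)
ari = adjusted_rand_score(truth.cell_population.loc[filtered.obs_names],
                          clusters.labels)
print(f"Leiden found {clusters.n_clusters} clusters, "
      f"ARI vs planted populations = {ari:.2f}")

expr = log_normalize(filtered)
focal = norm.to_frame()["SORL1"].to_numpy()
cuts = quantile_cutpoints(focal)
bins = discretize_expression(focal, cuts)
print(f"SORL1 cut-points: ({cuts[0]:.3f}, {cuts[1]:.3f}); bins: {bins.counts()}")

screen = spearman_screen(expr, "SORL1", alpha=0.05)
print(f"Spearman screen: {int(screen['pass'].sum())} genes pass FDR <= 0.05")

ranking = mcfs_rank(expr.drop(columns=["SORL1"]), bins,
                    MCFSSettings(n_trees=300), seed=7)
print(ranking.table.sort_values("rank").head(5)[["RI", "rank"]].round(3))
```

prints

```
QC kept 577/600 cells and 2061/2061 genes
Leiden found 5 clusters, ARI vs planted populations = 0.98
SORL1 cut-points: (-1.379, -0.056); bins: {'low': 193, 'medium': 192, 'high': 192}
Spearman screen: 105 genes pass FDR <= 0.05
              RI  rank
gene
ProgPos48  0.389     1
ProgPos33  0.307     2
ProgPos1   0.255     3
ProgPos45  0.241     4
ProgPos18  0.240     5
```

The clusters recover the three planted cell populations almost exactly
(ARI 0.98; small residual clusters account for the gap).  The Spearman
screen passes 105 genes — the 100 planted focal-program genes plus a
handful of chance hits at FDR 0.05 — and the MCFS relative-importance
ranking is headed by planted program genes (``ProgPos*``/``ProgNeg*``),
the genes whose means were coupled to the focal gene's latent level.

The same chain runs from the shell with the bundled demo profile:

```bash
gams-stratify run --out runs/demo --seed 7           # full pipeline
gams-stratify run --out runs/demo --stage markers    # re-run one stage
```

Stage outputs are plain CSV/MTX/JSON in the run directory, and
`summary.json` records the resolved parameters, wall times and SHA-256
checksums of every output; two runs with the same seed produce
identical checksums.

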