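"""Variance stabilization, HVG selection, PCA and graph clustering.

Normalization uses analytic Pearson residuals under a negative-binomial
null with multiplicative gene/cell means: for gene g in cell c,

    mu = rowsum_g * colsum_c / grand_total
    r  = (x - mu) / sqrt(mu + mu^2 / theta)

with residuals clipped to +/- sqrt(n_cells).  A single global
overdispersion ``theta`` (default 100) is used; this is a deliberately
dependency-light variance stabilization in the spirit of regularized NB
regression approaches, documented as an approximation in
docs/methods.md.

Clustering builds a k-nearest-neighbor graph in PC space with Jaccard
shared-neighbor edge weights and runs Leiden modularity community
detection at a configurable resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster import hierarchy

__all__ = [
    "NormMatrix",
    "Embedding",
    "Clustering",
    "log_normalize",
    "pearson_residuals",
    "select_hvg",
    "pca_embed",
    "cluster_cells",
    "cluster_mean_zscores",
]


@dataclass
class NormMatrix:
    """Clipped Pearson residuals (cells x genes) with gene bookkeeping."""

    residuals: np.ndarray  # cells x genes, dense float
    genes: pd.Index
    cells: pd.Index
    theta: float
    clip: float

    def subset_genes(self, genes) -> "NormMatrix":
        idx = self.genes.get_indexer(genes)
        if (idx < 0).any():
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return NormMatrix(
            residuals=self.residuals[:, idx],
            genes=pd.Index(genes),
            cells=self.cells,
            theta=self.theta,
            clip=self.clip,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.residuals, index=self.cells, columns=self.genes)


@dataclass
class Embedding:
    coords: np.ndarray  # cells x n_pcs
    explained_variance_ratio: np.ndarray
    cells: pd.Index


@dataclass
class Clustering:
    labels: np.ndarray  # per-cell small ints, contiguous from 0
    n_clusters: int
    resolution: float
    seed: int
    cells: pd.Index

    def __post_init__(self) -> None:
        u = np.unique(self.labels)
        if not np.array_equal(u, np.arange(len(u))):
            raise ValueError("cluster labels must be contiguous from 0")


def _dense_counts(adata) -> np.ndarray:
    X = adata.X
    return X.toarray().astype(float) if sp.issparse(X) else np.asarray(X, dtype=float)


def log_normalize(adata, target_sum: float = 1e4) -> pd.DataFrame:
    """Library-size normalize to ``target_sum`` counts per cell, then log1p."""
    X = _dense_counts(adata)
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return pd.DataFrame(
        np.log1p(X / totals * target_sum), index=adata.obs_names, columns=adata.var_names
    )


def pearson_residuals(adata, theta: float = 100.0, clip: float | None = None) -> NormMatrix:
    """Analytic Pearson residuals of a count matrix under the NB null."""
    X = _dense_counts(adata)
    n_cells = X.shape[0]
    grand = X.sum()
    if grand == 0:
        raise ValueError("count matrix has zero grand total")
    cell_sums = X.sum(axis=1, keepdims=True)
    gene_sums = X.sum(axis=0, keepdims=True)
    mu = cell_sums @ gene_sums / grand
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (X - mu) / np.sqrt(mu + mu**2 / theta)
    r[mu == 0] = 0.0
    c = np.sqrt(n_cells) if clip is None else clip
    np.clip(r, -c, c, out=r)
    return NormMatrix(
        residuals=r, genes=adata.var_names, cells=adata.obs_names, theta=theta, clip=c
    )


def select_hvg(norm: NormMatrix, n_top: int = 3000) -> list[str]:
    """Top ``n_top`` genes by residual variance (the most informative genes)."""
    var = norm.residuals.var(axis=0)
    if n_top >= len(var):
        if n_top > len(var):
            warnings.warn(
                f"n_top={n_top} exceeds {len(var)} genes; returning all genes"
            )
        return list(norm.genes)
    # stable sort so ties resolve by gene order
    order = np.argsort(-var, kind="stable")[:n_top]
    return list(norm.genes[order])


def pca_embed(norm: NormMatrix, n_pcs: int = 30) -> Embedding:
    """PCA of the (HVG-restricted) residual matrix.

    Genes are mean-centered; component signs are fixed by making the
    largest-magnitude gene loading of each component positive, so the
    embedding is deterministic.
    """
    X = norm.residuals - norm.residuals.mean(axis=0, keepdims=True)
    max_pcs = min(X.shape)
    if n_pcs > max_pcs:
        warnings.warn(f"n_pcs={n_pcs} reduced to {max_pcs}")
        n_pcs = max_pcs
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :n_pcs], S[:n_pcs], Vt[:n_pcs]
    for k in range(n_pcs):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    total_var = (X**2).sum()
    evr = S**2 / total_var if total_var > 0 else np.zeros(n_pcs)
    return Embedding(coords=U * S, explained_variance_ratio=evr, cells=norm.cells)


def _snn_graph(coords: np.ndarray, k_neighbors: int):
    """kNN graph with Jaccard shared-neighbor edge weights."""
    from sklearn.neighbors import NearestNeighbors
    import igraph as ig

    n = coords.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(coords)
    _, idx = nn.kneighbors(coords)  # includes self; ties broken by index
    neigh = [set(row) for row in idx]
    edges, weights = [], []
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j <= i:
                continue
            inter = len(neigh[i] & neigh[j])
            union = len(neigh[i] | neigh[j])
            edges.append((i, j))
            weights.append(inter / union)
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    g.simplify(combine_edges="max")
    return g


def cluster_cells(
    emb: Embedding, k_neighbors: int = 20, resolution: float = 1.0, seed: int = 0
) -> Clustering:
    """Leiden community detection on the shared-nearest-neighbor graph."""
    import leidenalg

    n = emb.coords.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n_cells={n}")
    g = _snn_graph(emb.coords, k_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    raw = np.asarray(part.membership)
    _, labels = np.unique(raw, return_inverse=True)
    return Clustering(
        labels=labels,
        n_clusters=int(labels.max()) + 1,
        resolution=resolution,
        seed=seed,
        cells=emb.cells,
    )


def cluster_mean_zscores(
    norm: NormMatrix, clustering: Clustering, genes: list[str]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Standardized per-cluster mean expression of selected genes.

    Per-cluster means are z-scored per gene across clusters with the
    sample SD (ddof=1, the heatmap row-scaling convention); an all-equal
    row maps to all zeros.  Rows come with an average-linkage
    hierarchical-clustering leaf order on Euclidean distance, matching
    the conventional heatmap view.
    """
    sub = norm.subset_genes(genes)
    k = clustering.n_clusters
    means = np.vstack(
        [sub.residuals[clustering.labels == c].mean(axis=0) for c in range(k)]
    ).T  # genes x clusters
    if k < 2:
        sd = np.zeros((means.shape[0], 1))
    else:
        sd = means.std(axis=1, ddof=1, keepdims=True)
    centered = means - means.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    df = pd.DataFrame(z, index=genes, columns=[f"cluster{c}" for c in range(k)])
    if len(genes) > 1:
        link = hierarchy.linkage(z, method="average", metric="euclidean")
        order = hierarchy.leaves_list(link)
    else:
        order = np.array([0])
    return df, order
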