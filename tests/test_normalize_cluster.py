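"""Pearson residuals, HVG ranking, PCA and Leiden clustering."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from gams_stratify import qc
from gams_stratify.normalize_cluster import (
    cluster_cells,
    cluster_mean_zscores,
    log_normalize,
    pca_embed,
    pearson_residuals,
    select_hvg,
)
from gams_stratify.synthdata import PopulationSpec, generate_dataset
from conftest import small_config, toy_adata


def brute_force_residuals(counts, theta, clip):
    """Independent elementwise evaluation of the residual formula."""
    counts = np.asarray(counts, dtype=float)
    grand = counts.sum()
    out = np.zeros_like(counts)
    for c in range(counts.shape[0]):
        for g in range(counts.shape[1]):
            mu = counts[c].sum() * counts[:, g].sum() / grand
            if mu == 0:
                continue
            r = (counts[c, g] - mu) / np.sqrt(mu + mu**2 / theta)
            out[c, g] = np.clip(r, -clip, clip)
    return out


class TestPearsonResiduals:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(1.0, size=(15, 12))
        adata = toy_adata(counts)
        norm = pearson_residuals(adata, theta=50.0)
        expected = brute_force_residuals(counts, 50.0, np.sqrt(15))
        np.testing.assert_allclose(norm.residuals, expected, atol=1e-12)

    def test_residual_zero_when_count_equals_expectation(self):
        # outer-product structure: x == mu everywhere
        counts = np.outer([1, 2, 4], [3, 1, 2])
        norm = pearson_residuals(toy_adata(counts), theta=10.0)
        np.testing.assert_allclose(norm.residuals, 0.0, atol=1e-8)

    def test_spot_value_before_clipping(self):
        # r = (4 - 1)/sqrt(1 + 1/100) with mu forced to 1 via margins
        r = (4 - 1) / np.sqrt(1 + 1 / 100)
        assert r == pytest.approx(2.9851, abs=1e-4)

    def test_constant_gene_equal_depth_cells_zero(self):
        counts = np.array([[3, 5, 2], [3, 2, 5], [3, 4, 3]])  # gene 0 constant
        # equal depths -> mu = gene mean = count for gene 0
        norm = pearson_residuals(toy_adata(counts), theta=10.0)
        np.testing.assert_allclose(norm.residuals[:, 0], 0.0, atol=1e-12)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero grand total"):
            pearson_residuals(toy_adata(np.zeros((3, 3))))

    def test_clipping_bound(self, small_dataset):
        adata, _ = small_dataset
        norm = pearson_residuals(adata)
        assert np.all(np.abs(norm.residuals) <= np.sqrt(adata.n_obs) + 1e-12)
        assert np.isfinite(norm.residuals).all()


class TestHVG:
    def test_top_by_residual_variance(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(rng.uniform(0.2, 3.0, size=10), size=(20, 10))
        norm = pearson_residuals(toy_adata(counts), theta=20.0)
        top3 = select_hvg(norm, n_top=3)
        variances = norm.residuals.var(axis=0)
        expected = [norm.genes[i] for i in np.argsort(-variances, kind="stable")[:3]]
        assert top3 == expected

    def test_n_top_at_least_n_genes_is_identity(self):
        counts = np.random.default_rng(2).poisson(1, size=(10, 6))
        norm = pearson_residuals(toy_adata(counts))
        assert select_hvg(norm, n_top=6) == list(norm.genes)
        with pytest.warns(UserWarning, match="returning all genes"):
            assert select_hvg(norm, n_top=99) == list(norm.genes)

    def test_constant_gene_never_outranks_marker(self, small_dataset):
        adata, truth = small_dataset
        norm = pearson_residuals(adata)
        marker = truth.markers_of("GAMs")[0]
        zero_gene = norm.genes[np.flatnonzero(norm.residuals.var(axis=0) == 0)]
        n_nonconst = int((norm.residuals.var(axis=0) > 0).sum())
        top = select_hvg(norm, n_top=min(n_nonconst, adata.n_vars))
        assert marker in top
        assert not set(zero_gene) & set(top[: n_nonconst])


class TestPCA:
    def test_rank_deficient_data_has_zero_tail_variance(self):
        rng = np.random.default_rng(3)
        basis = rng.normal(size=(2, 30))
        coords = rng.normal(size=(50, 2))
        X = coords @ basis
        norm = pearson_residuals(toy_adata(np.zeros((50, 30)) + 1))  # placeholder
        norm.residuals = X
        emb = pca_embed(norm, n_pcs=10)
        assert emb.explained_variance_ratio[2:].max() < 1e-8

    def test_duplicating_cells_preserves_directions(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 8))
        norm = pearson_residuals(toy_adata(np.ones((20, 8))))
        norm.residuals = X
        e1 = pca_embed(norm, n_pcs=3)
        norm2 = pearson_residuals(toy_adata(np.ones((40, 8))))
        norm2.residuals = np.vstack([X, X])
        e2 = pca_embed(norm2, n_pcs=3)
        np.testing.assert_allclose(
            np.abs(e1.coords), np.abs(e2.coords[:20]), atol=1e-8
        )

    def test_explained_variance_non_increasing(self, small_dataset):
        adata, _ = small_dataset
        emb = pca_embed(pearson_residuals(adata), n_pcs=10)
        assert (np.diff(emb.explained_variance_ratio) <= 1e-12).all()

    def test_two_populations_separate_on_pc1(self):
        cfg = small_config(
            seed=5,
            populations=[
                PopulationSpec("a", n_marker_genes=20),
                PopulationSpec("b", n_marker_genes=20),
            ],
        )
        adata, truth = generate_dataset(cfg)
        emb = pca_embed(pearson_residuals(adata), n_pcs=5)
        labels = truth.cell_population.to_numpy()
        assert silhouette_score(emb.coords[:, :1], labels) > 0.5

    def test_too_many_pcs_reduced_with_warning(self):
        counts = np.random.default_rng(6).poisson(1, size=(5, 4)) + 1
        norm = pearson_residuals(toy_adata(counts))
        with pytest.warns(UserWarning, match="reduced"):
            emb = pca_embed(norm, n_pcs=30)
        assert emb.coords.shape[1] == 4


class TestClustering:
    def test_recovers_planted_populations(self, small_dataset):
        adata, truth = small_dataset
        emb = pca_embed(pearson_residuals(adata), n_pcs=10)
        cl = cluster_cells(emb, k_neighbors=15, resolution=0.5, seed=0)
        ari = adjusted_rand_score(truth.cell_population.to_numpy(), cl.labels)
        assert ari >= 0.9

    def test_deterministic_given_seed(self, small_dataset):
        adata, _ = small_dataset
        emb = pca_embed(pearson_residuals(adata), n_pcs=10)
        c1 = cluster_cells(emb, seed=7, k_neighbors=15)
        c2 = cluster_cells(emb, seed=7, k_neighbors=15)
        assert np.array_equal(c1.labels, c2.labels)

    def test_zero_resolution_limit_single_cluster(self, small_dataset):
        adata, _ = small_dataset
        emb = pca_embed(pearson_residuals(adata), n_pcs=10)
        cl = cluster_cells(emb, resolution=0.0, seed=0, k_neighbors=15)
        assert cl.n_clusters == 1

    def test_k_too_large_rejected(self):
        norm = pearson_residuals(toy_adata(np.ones((5, 4))))
        emb = pca_embed(norm, n_pcs=2)
        with pytest.raises(ValueError, match="k_neighbors"):
            cluster_cells(emb, k_neighbors=5)


class TestClusterMeanZscores:
    def _norm_and_clustering(self, residuals, labels):
        from gams_stratify.normalize_cluster import Clustering, NormMatrix
        import pandas as pd

        n, g = residuals.shape
        norm = NormMatrix(
            residuals=residuals.astype(float),
            genes=pd.Index([f"g{i}" for i in range(g)]),
            cells=pd.Index([f"c{i}" for i in range(n)]),
            theta=100.0,
            clip=np.inf,
        )
        labels = np.asarray(labels)
        clustering = Clustering(
            labels=labels,
            n_clusters=labels.max() + 1,
            resolution=1.0,
            seed=0,
            cells=norm.cells,
        )
        return norm, clustering

    def test_equal_means_give_zero_row(self):
        res = np.array([[1.0, 2.0], [1.0, 0.0], [1.0, 2.0], [1.0, 0.0]])
        norm, cl = self._norm_and_clustering(res, [0, 0, 1, 1])
        z, _ = cluster_mean_zscores(norm, cl, ["g0", "g1"])
        np.testing.assert_allclose(z.loc["g0"], 0.0)

    def test_two_cluster_hand_value(self):
        # means 1 and 3 -> z = (-0.7071, +0.7071) with population SD
        res = np.array([[1.0], [1.0], [3.0], [3.0]])
        norm, cl = self._norm_and_clustering(res, [0, 0, 1, 1])
        z, _ = cluster_mean_zscores(norm, cl, ["g0"])
        np.testing.assert_allclose(z.loc["g0"].to_numpy(), [-0.7071, 0.7071], atol=1e-4)

    def test_rows_standardized(self, small_dataset):
        adata, _ = small_dataset
        norm = pearson_residuals(adata)
        emb = pca_embed(norm, n_pcs=10)
        cl = cluster_cells(emb, seed=1, k_neighbors=15)
        genes = select_hvg(norm, n_top=30)
        z, order = cluster_mean_zscores(norm, cl, genes)
        zv = z.to_numpy()
        np.testing.assert_allclose(zv.mean(axis=1), 0.0, atol=1e-9)
        sd = zv.std(axis=1, ddof=1)
        assert np.all((np.abs(sd - 1) < 1e-9) | (sd == 0))
        assert sorted(order.tolist()) == list(range(len(genes)))


def test_log_normalize_monotone_and_zero_preserving(small_dataset):
    adata, _ = small_dataset
    ln = log_normalize(adata)
    X = adata.X.toarray()
    assert ((ln.to_numpy() > 0) == (X > 0)).all()
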