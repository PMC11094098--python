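"""Discretization, Spearman screen, MCFS ranking and classifier validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gams_stratify.focal_assoc import (
    MCFSSettings,
    SORL1_CUTPOINTS,
    discretize_expression,
    mcfs_rank,
    permutation_cutoff,
    quantile_cutpoints,
    spearman_screen,
    validate_classifiers,
)


class TestDiscretization:
    def test_published_cutpoints_reproduce_bin_labels(self):
        disc = discretize_expression([-1.0, 0.0, 2.0], SORL1_CUTPOINTS)
        assert disc.bins.tolist() == ["low", "medium", "high"]

    def test_boundary_is_right_closed(self):
        disc = discretize_expression([-0.3428585, 0.8406330], SORL1_CUTPOINTS)
        assert disc.bins.tolist() == ["low", "medium"]

    def test_lowest_bin_extends_to_minus_infinity(self):
        disc = discretize_expression([-10.0], SORL1_CUTPOINTS)
        assert disc.bins.tolist() == ["low"]

    def test_non_increasing_cutpoints_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            discretize_expression([0.0], (1.0, 1.0))

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-50, 50, allow_nan=False))
    def test_bins_partition_the_line(self, v):
        disc = discretize_expression([v], (-0.5, 1.5))
        assert disc.bins[0] in ("low", "medium", "high")

    def test_midpoint_rediscretization_idempotent(self):
        cuts = (-0.5, 1.0)
        values = np.linspace(-4, 4, 101)
        d1 = discretize_expression(values, cuts)
        mid = {"low": -1.5, "medium": 0.25, "high": 2.0}
        d2 = discretize_expression([mid[b] for b in d1.bins], cuts)
        assert d1.bins.tolist() == d2.bins.tolist()


class TestQuantileCutpoints:
    def test_inverse_cdf_order_statistics(self):
        assert quantile_cutpoints(np.arange(1, 10)) == (3.0, 6.0)

    def test_symmetric_distribution_symmetric_cuts(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=20000)
        c1, c2 = quantile_cutpoints(v)
        med = np.median(v)
        assert abs((med - c1) - (c2 - med)) < 0.05

    def test_equal_probs_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            quantile_cutpoints(np.arange(1, 10), probs=(0.5, 0.5))

    def test_degenerate_values_rejected(self):
        with pytest.raises(ValueError):
            quantile_cutpoints([1.0, 1.0, 1.0, 2.0])


class TestSpearmanScreen:
    def _frame(self, cols):
        return pd.DataFrame(cols)

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        df = self._frame({"f": rng.normal(size=30), "g": rng.normal(size=30)})
        out = spearman_screen(df, "f")
        assert out.set_index("gene").loc["f", "rho"] == pytest.approx(1.0)

    def test_hand_computed_rho(self):
        # x=(1,2,3), y=(3,1,2): rho = 1 - 6*sum(d^2)/(n(n^2-1)) = -0.5
        df = self._frame({"f": [1, 2, 3], "g": [3, 1, 2]})
        out = spearman_screen(df, "f").set_index("gene")
        assert out.loc["g", "rho"] == pytest.approx(-0.5)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        df1 = self._frame({"f": x, "g": y})
        df2 = self._frame({"f": np.exp(x), "g": y**3})
        r1 = spearman_screen(df1, "f").set_index("gene").loc["g", "rho"]
        r2 = spearman_screen(df2, "f").set_index("gene").loc["g", "rho"]
        assert r1 == pytest.approx(r2)

    def test_constant_gene_excluded_from_bh_family(self):
        rng = np.random.default_rng(3)
        df = self._frame({"f": rng.normal(size=20), "g": np.ones(20)})
        out = spearman_screen(df, "f").set_index("gene")
        assert np.isnan(out.loc["g", "rho"])
        assert np.isnan(out.loc["g", "fdr"])
        assert not out.loc["g", "pass"]


class TestMCFS:
    def _planted(self, seed, n_noise=40, n_cells=150):
        rng = np.random.default_rng(seed)
        g = rng.normal(size=n_cells)
        X = pd.DataFrame(
            rng.normal(size=(n_cells, n_noise)),
            columns=[f"n{i}" for i in range(n_noise)],
        )
        X["star"] = g
        y = discretize_expression(g, quantile_cutpoints(g))
        return X, y

    def test_deterministic_given_seed(self):
        X, y = self._planted(0)
        st_ = MCFSSettings(n_trees=30)
        r1 = mcfs_rank(X, y, st_, seed=5)
        r2 = mcfs_rank(X, y, st_, seed=5)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_planted_gene_ranks_first(self):
        X, y = self._planted(1)
        rk = mcfs_rank(X, y, MCFSSettings(n_trees=100), seed=0)
        assert rk.table["rank"]["star"] == 1

    def test_unsampled_gene_has_zero_ri(self):
        X, y = self._planted(2, n_noise=30)
        rk = mcfs_rank(X, y, MCFSSettings(n_trees=3, subset_size=2), seed=0)
        assert (rk.ri == 0).any()
        # every zero-RI gene was indeed never split on; RI >= 0 everywhere
        assert (rk.ri >= 0).all()

    def test_column_permutation_equivariance(self):
        X, y = self._planted(3, n_noise=15)
        st_ = MCFSSettings(n_trees=25)
        r1 = mcfs_rank(X, y, st_, seed=9)
        perm = X.sample(frac=1.0, axis=1, random_state=4)
        r2 = mcfs_rank(perm, y, st_, seed=9)
        pd.testing.assert_series_equal(r1.ri.sort_index(), r2.ri.sort_index())

    def test_oversized_subset_rejected(self):
        X, y = self._planted(4, n_noise=5)
        with pytest.raises(ValueError, match="subset_size"):
            mcfs_rank(X, y, MCFSSettings(n_trees=3, subset_size=100), seed=0)

    def test_single_class_rejected(self):
        X, _ = self._planted(5, n_noise=5)
        with pytest.raises(ValueError, match="classes"):
            mcfs_rank(X, np.zeros(len(X)), MCFSSettings(n_trees=3), seed=0)

    def test_ranking_enriched_for_planted_program_genes(self, default_dataset):
        # genes coupled to the focal gene's latent level dominate the top
        # of the relative-importance ranking at the study's default
        # conditions (coupling 0.8, ~2000 genes, 600 cells)
        from gams_stratify.normalize_cluster import log_normalize, pearson_residuals

        adata, truth = default_dataset
        expr = log_normalize(adata)
        fv = pearson_residuals(adata).to_frame()["SORL1"].to_numpy()
        y = discretize_expression(fv, quantile_cutpoints(fv))
        X = expr.drop(columns=["SORL1"])
        rk = mcfs_rank(X, y, MCFSSettings(n_trees=300), seed=0)
        top25 = rk.table.sort_values("rank").head(25).index
        program = set(truth.genes_with_role("program_pos")) | set(
            truth.genes_with_role("program_neg")
        )
        assert np.mean([g in program for g in top25]) >= 0.8

    def test_alpha_one_cutoff_is_null_minimum(self):
        X, y = self._planted(6, n_noise=10)
        st_ = MCFSSettings(n_trees=10)
        with pytest.warns(UserWarning, match="unstable"):
            cut1, maxima = permutation_cutoff(X, y, n_perm=5, alpha=1.0, settings=st_, seed=0)
        assert cut1 == maxima.min()


class TestValidateClassifiers:
    def test_separable_case_tree_is_perfect(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=120)
        X = pd.DataFrame({"g": g, "noise": rng.normal(size=120)})
        y = discretize_expression(g, (-0.5, 0.5))
        rep = validate_classifiers(X[["g"]], y, seed=1)
        assert rep.accuracies["decision_tree"] == 1.0
        assert rep.n_train == 90 and rep.n_test == 30

    def test_pure_noise_accuracy_near_chance(self):
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("abcd"))
            y = np.repeat(["low", "medium", "high"], 100)
            rep = validate_classifiers(X, y, seed=seed)
            accs.extend(rep.accuracies.values())
        assert abs(np.mean(accs) - 1 / 3) < 0.1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(90, 3)), columns=list("abc"))
        y = np.repeat(["low", "medium", "high"], 30)
        r1 = validate_classifiers(X, y, seed=3)
        r2 = validate_classifiers(X, y, seed=3)
        assert r1.accuracies == r2.accuracies
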