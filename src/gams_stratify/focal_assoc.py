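"""Association of genes with a discretized focal gene.

The focal gene's per-cell normalized expression is cut into three
ordered levels (low / medium / high).  Two screens then link every other
gene to that level:

* a Spearman rank-correlation screen with Benjamini-Hochberg control of
  the false discovery rate, and
* a Monte-Carlo feature-selection (MCFS) ranking: an ensemble of
  depth-limited CART trees, each fitted on a random gene subset and a
  bootstrap sample of cells, accumulating for every gene a relative
  importance (RI) that weights each split by the tree's out-of-bag
  balanced accuracy and the node's sample fraction.  Significance of RI
  comes from a permutation null of the maximal RI under shuffled labels.

The significant gene set is finally sanity-checked by five classifier
families (decision tree, logistic regression, random forest, naive
Bayes, SVM) on a single stratified 75/25 train/validation split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LEVELS = ("low", "medium", "high")

#: Cut-points published for SORL1 on the variance-stabilized scale of the
#: original glioblastoma dataset; dataset-specific, applied only when
#: explicitly configured.
SORL1_CUTPOINTS = (-0.3428585, 0.8406330)
#: Printed lower bound of the lowest SORL1 range (the bin itself extends
#: to -inf).
SORL1_RANGE_LOWER = -3.1374856


@dataclass
class Discretization:
    """Three-level binning by two increasing cut-points.

    Intervals are left-open/right-closed: ``low`` is ``(-inf, c1]``,
    ``medium`` is ``(c1, c2]``, ``high`` is ``(c2, +inf)``.
    """

    cut_points: tuple[float, float]
    bins: np.ndarray  # per-cell labels from LEVELS
    labels: tuple[str, str, str] = LEVELS

    def counts(self) -> dict[str, int]:
        return {lv: int((self.bins == lv).sum()) for lv in self.labels}


def discretize_expression(values, cut_points) -> Discretization:
    c1, c2 = float(cut_points[0]), float(cut_points[1])
    if not np.isfinite([c1, c2]).all() or not c1 < c2:
        raise ValueError(f"cut-points must be finite and strictly increasing, got {cut_points}")
    v = np.asarray(values, dtype=float)
    bins = np.where(v <= c1, LEVELS[0], np.where(v <= c2, LEVELS[1], LEVELS[2]))
    return Discretization(cut_points=(c1, c2), bins=bins)


def quantile_cutpoints(values, probs=(1 / 3, 2 / 3)) -> tuple[float, float]:
    """Empirical inverse-CDF (type-1) quantiles used as cut-points."""
    v = np.asarray(values, dtype=float)
    if len(np.unique(v)) < 3:
        raise ValueError("need >= 3 distinct values to place two cut-points")
    p1, p2 = probs
    if not p1 < p2:
        raise ValueError("probs must be strictly increasing")
    c1, c2 = np.quantile(v, [p1, p2], method="inverted_cdf")
    if not c1 < c2:
        raise ValueError("degenerate distribution: cut-points coincide")
    return float(c1), float(c2)


def spearman_screen(expr: pd.DataFrame, focal: str, alpha: float = 0.05) -> pd.DataFrame:
    """Spearman correlation of every gene with the focal gene, BH-adjusted.

    Ties get average ranks.  Constant genes have undefined correlation:
    they are reported with ``rho = NaN`` and excluded from the BH
    family.  ``pass`` is ``fdr <= alpha``.
    """
    if focal not in expr.columns:
        raise KeyError(f"focal gene {focal!r} not in matrix")
    n = expr.shape[0]
    if n < 3:
        raise ValueError("need >= 3 cells")
    ranks = stats.rankdata(expr.to_numpy(), axis=0)
    r0 = ranks[:, expr.columns.get_loc(focal)]
    rc = ranks - ranks.mean(axis=0, keepdims=True)
    r0c = r0 - r0.mean()
    sd = np.sqrt((rc**2).sum(axis=0))
    sd0 = np.sqrt((r0c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = rc.T @ r0c / (sd * sd0)
    rho = np.where(sd > 0, rho, np.nan)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = np.where(np.abs(rho) == 1.0, 0.0, 2 * stats.t.sf(np.abs(t), df=n - 2))
    out = pd.DataFrame({"gene": expr.columns, "rho": rho, "p": p})
    tested = out["rho"].notna()
    out["fdr"] = np.nan
    if tested.any():
        out.loc[tested, "fdr"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    out["pass"] = (out["fdr"] <= alpha).fillna(False)
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo feature selection


@dataclass
class MCFSSettings:
    n_trees: int = 500
    subset_size: int | None = None  # default round(3*sqrt(n_genes))
    bootstrap_frac: float = 0.66
    u: float = 1.0
    v: float = 1.0
    max_depth: int = 6
    min_samples_leaf: int = 5

    def resolve_subset(self, n_genes: int) -> int:
        m = self.subset_size or int(round(3 * np.sqrt(n_genes)))
        if m > n_genes:
            raise ValueError(f"subset_size={m} exceeds n_genes={n_genes}")
        return max(m, 1)


@dataclass
class RIRanking:
    table: pd.DataFrame  # index gene; columns RI, rank, significant
    settings: MCFSSettings
    seed: int
    cutoff: float | None = None

    @property
    def ri(self) -> pd.Series:
        return self.table["RI"]

    def apply_cutoff(self, cutoff: float) -> "RIRanking":
        self.cutoff = float(cutoff)
        self.table["significant"] = self.table["RI"] > self.cutoff
        return self

    def significant_genes(self) -> list[str]:
        if self.cutoff is None:
            raise RuntimeError("no permutation cut-off applied yet")
        return list(self.table.index[self.table["significant"]])


def _tree_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    # counter-based stream: independent of call order and column layout
    return np.random.default_rng(np.random.SeedSequence(entropy=[seed, stream, index]))


def mcfs_rank(
    X: pd.DataFrame,
    y,
    settings: MCFSSettings | None = None,
    seed: int = 0,
) -> RIRanking:
    """Rank genes by Monte-Carlo feature-selection relative importance.

    For each of ``n_trees`` repetitions a gene subset is drawn uniformly
    without replacement (from the canonically name-sorted gene list, so
    the ranking does not depend on column order) together with a
    bootstrap sample of cells; a Gini CART tree is fitted and every
    split on gene ``g`` contributes ``wAcc**u * (n_node/n_root)**v`` to
    ``RI(g)``, where ``wAcc`` is the mean per-class recall on the
    out-of-bag cells.  Final RI is normalized by the number of subsets
    containing the gene; a gene never sampled has RI exactly 0.
    """
    from sklearn.tree import DecisionTreeClassifier

    st = settings or MCFSSettings()
    y = np.asarray(getattr(y, "bins", y))
    if X.shape[0] != len(y):
        raise ValueError("X rows must match y length")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("y must contain >= 2 classes")
    genes = np.array(sorted(X.columns))
    n_genes, n_cells = len(genes), X.shape[0]
    m = st.resolve_subset(n_genes)
    n_boot = max(int(round(st.bootstrap_frac * n_cells)), 1)
    Xv = X.loc[:, genes].to_numpy()

    ri_sum = np.zeros(n_genes)
    subset_count = np.zeros(n_genes, dtype=int)
    for t in range(st.n_trees):
        rng = _tree_rng(seed, 0, t)
        subset = np.sort(rng.choice(n_genes, size=m, replace=False))
        boot = rng.integers(0, n_cells, size=n_boot)
        oob = np.setdiff1d(np.arange(n_cells), boot, assume_unique=False)
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_depth=st.max_depth,
            min_samples_leaf=st.min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(Xv[boot][:, subset], y[boot])
        if len(oob):
            pred = tree.predict(Xv[oob][:, subset])
            y_oob = y[oob]
            recalls = [
                (pred[y_oob == c] == c).mean() for c in classes if (y_oob == c).any()
            ]
            wacc = float(np.mean(recalls)) if recalls else 0.5
        else:
            wacc = 0.5
        tr = tree.tree_
        n_root = tr.n_node_samples[0]
        internal = tr.children_left != -1
        for f, n_node in zip(tr.feature[internal], tr.n_node_samples[internal]):
            g = subset[f]
            ri_sum[g] += (wacc**st.u) * (n_node / n_root) ** st.v
        subset_count[subset] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        ri = np.where(subset_count > 0, ri_sum / np.maximum(subset_count, 1), 0.0)
    table = pd.DataFrame({"RI": ri}, index=pd.Index(genes, name="gene"))
    table["rank"] = (
        table["RI"].rank(ascending=False, method="first").astype(int)
    )
    table["significant"] = pd.NA
    return RIRanking(table=table, settings=st, seed=seed)


def permutation_cutoff(
    X: pd.DataFrame,
    y,
    n_perm: int = 30,
    alpha: float = 0.05,
    settings: MCFSSettings | None = None,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """RI significance cut-off from a permutation null.

    For each permutation of the response the maximal RI over genes is
    recorded; the cut-off is the empirical ``1 - alpha`` quantile of
    those maxima.  Returns the cut-off and the null maxima.
    """
    if n_perm < 20:
        warnings.warn(f"n_perm={n_perm} < 20: the null quantile is unstable")
    y = np.asarray(getattr(y, "bins", y))
    maxima = np.empty(n_perm)
    for p in range(n_perm):
        rng = _tree_rng(seed, 1, p)
        y_perm = rng.permutation(y)
        inner_seed = int(rng.integers(0, 2**31 - 1))
        rk = mcfs_rank(X, y_perm, settings=settings, seed=inner_seed)
        maxima[p] = rk.ri.max()
    cutoff = float(np.quantile(maxima, 1 - alpha, method="higher"))
    return cutoff, maxima


def mcfs_significance(
    X: pd.DataFrame,
    y,
    settings: MCFSSettings | None = None,
    n_perm: int = 30,
    perm_settings: MCFSSettings | None = None,
    alpha: float = 0.05,
    seed: int = 0,
) -> RIRanking:
    """Observed RI ranking with the permutation cut-off applied."""
    ranking = mcfs_rank(X, y, settings=settings, seed=seed)
    cutoff, _ = permutation_cutoff(
        X, y, n_perm=n_perm, alpha=alpha, settings=perm_settings or settings, seed=seed
    )
    return ranking.apply_cutoff(cutoff)


# ---------------------------------------------------------------------------
# classifier validation


@dataclass
class ValidationReport:
    accuracies: dict[str, float]
    n_train: int
    n_test: int
    train_fraction: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "accuracies": dict(self.accuracies),
            "n_train": self.n_train,
            "n_test": self.n_test,
            "train_fraction": self.train_fraction,
            "seed": self.seed,
        }


def validate_classifiers(
    X_top: pd.DataFrame, y, train_fraction: float = 0.75, seed: int = 0
) -> ValidationReport:
    """Held-out accuracy of five classifier families on the selected genes.

    A single stratified split at ``train_fraction`` (default 75% train /
    25% validation).  Hyperparameters are fixed: depth-unlimited CART,
    L2 logistic regression (lbfgs, 1000 iterations), 100-tree random
    forest, Gaussian naive Bayes, RBF-kernel SVM with C=1.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split
    from sklearn.naive_bayes import GaussianNB
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    y = np.asarray(getattr(y, "bins", y))
    if X_top.shape[1] < 1:
        raise ValueError("need at least one selected gene")
    Xtr, Xte, ytr, yte = train_test_split(
        X_top.to_numpy(), y, train_size=train_fraction, stratify=y, random_state=seed
    )
    if len(np.unique(ytr)) < len(np.unique(y)):
        raise ValueError("a class is absent from the training split")
    models = {
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "logistic_regression": LogisticRegression(max_iter=1000),
        "random_forest": RandomForestClassifier(n_estimators=100, random_state=seed),
        "naive_bayes": GaussianNB(),
        "svm": SVC(kernel="rbf", C=1.0, random_state=seed),
    }
    acc = {}
    for name, model in models.items():
        model.fit(Xtr, ytr)
        acc[name] = float((model.predict(Xte) == yte).mean())
    return ValidationReport(
        accuracies=acc,
        n_train=len(ytr),
        n_test=len(yte),
        train_fraction=train_fraction,
        seed=seed,
    )
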