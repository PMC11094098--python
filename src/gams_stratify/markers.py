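"""Marker-gene detection and focal-gene summaries per cluster.

Markers are detected one-vs-rest per cluster on log-normalized
expression with the field's classic criteria: presence in at least
50% of the cluster's cells, positive fold change only, and a natural-log
fold-change threshold of 0.25.  Significance is a two-sided Wilcoxon
rank-sum test with Benjamini-Hochberg adjustment across all candidate
(gene, cluster) rows that pass the pre-filters.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

_EPS = 1e-9

MARKER_COLUMNS = ["gene", "cluster", "pct_in", "pct_out", "logFC", "p", "fdr"]


def _wilcoxon_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p; exact when both arms are small and tie-free."""
    method = "asymptotic"
    if min(len(x), len(y)) <= 20:
        combined = np.concatenate([x, y])
        if len(np.unique(combined)) == len(combined):
            method = "exact"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def find_markers(
    expr: pd.DataFrame,
    labels: np.ndarray,
    min_pct: float = 0.5,
    logfc_min: float = 0.25,
) -> pd.DataFrame:
    """One-vs-rest marker detection on a cells x genes log-normalized matrix.

    ``logFC`` is ``ln(mean_in + eps) - ln(mean_out + eps)`` with the means
    taken on ``expm1``-backtransformed values; presence fractions use
    ``value > 0``.  Clusters with fewer than 3 cells are skipped with a
    warning.  Returns a :data:`MARKER_COLUMNS` table with only the rows
    passing ``pct_in >= min_pct`` and ``logFC >= logfc_min``, BH-adjusted
    within the full retained candidate set.
    """
    labels = np.asarray(labels)
    if len(labels) != expr.shape[0]:
        raise ValueError("labels length must match number of cells")
    values = expr.to_numpy()
    detected = values > 0
    back = np.expm1(values)
    rows = []
    for cl in np.unique(labels):
        in_mask = labels == cl
        n_in = int(in_mask.sum())
        if n_in < 3:
            warnings.warn(f"cluster {cl} has {n_in} cells; skipped")
            continue
        pct_in = detected[in_mask].mean(axis=0)
        pct_out = detected[~in_mask].mean(axis=0)
        mean_in = back[in_mask].mean(axis=0)
        mean_out = back[~in_mask].mean(axis=0)
        logfc = np.log(mean_in + _EPS) - np.log(mean_out + _EPS)
        cand = np.flatnonzero((pct_in >= min_pct) & (logfc >= logfc_min) & (logfc > 0))
        for gi in cand:
            p = _wilcoxon_p(values[in_mask, gi], values[~in_mask, gi])
            rows.append(
                {
                    "gene": expr.columns[gi],
                    "cluster": cl,
                    "pct_in": float(pct_in[gi]),
                    "pct_out": float(pct_out[gi]),
                    "logFC": float(logfc[gi]),
                    "p": p,
                }
            )
    table = pd.DataFrame(rows, columns=MARKER_COLUMNS[:-1])
    if len(table):
        table["fdr"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["fdr"] = pd.Series(dtype=float)
    return table[MARKER_COLUMNS]


def cluster_fold_change(values, labels, cluster) -> float:
    """Ratio of mean expression inside a cluster to the mean elsewhere.

    Returns ``+inf`` when only the cluster expresses the gene and 1.0
    (with a degenerate-case warning) when neither side does.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    in_mask = labels == cluster
    if not in_mask.any():
        raise ValueError(f"cluster {cluster!r} not present")
    num = values[in_mask].mean()
    den = values[~in_mask].mean() if (~in_mask).any() else 0.0
    if den == 0:
        if num > 0:
            return float("inf")
        warnings.warn("gene unexpressed in and out of cluster; fold change degenerate")
        return 1.0
    return float(num / den)


def coexpression_fraction(adata, focal: str, anchor: str) -> float:
    """Percentage of anchor-positive cells that are also focal-positive.

    Positivity is raw count > 0.  Mirrors double-positive percentages
    such as the fraction of SORL1+ cells among AIF1+ cells.
    """
    for g in (focal, anchor):
        if g not in adata.var_names:
            raise KeyError(f"gene {g!r} not in matrix")
    X = adata.X
    fv = np.asarray(X[:, adata.var_names.get_loc(focal)].todense()).ravel() if sp.issparse(X) else np.asarray(X[:, adata.var_names.get_loc(focal)]).ravel()
    av = np.asarray(X[:, adata.var_names.get_loc(anchor)].todense()).ravel() if sp.issparse(X) else np.asarray(X[:, adata.var_names.get_loc(anchor)]).ravel()
    anchor_pos = av > 0
    n_anchor = int(anchor_pos.sum())
    if n_anchor == 0:
        raise ValueError(f"no cells express anchor gene {anchor!r}; fraction undefined")
    both = int((anchor_pos & (fv > 0)).sum())
    return 100.0 * both / n_anchor
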