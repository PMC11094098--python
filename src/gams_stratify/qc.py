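"""Per-cell quality-control metrics and cell/gene filtering.

The filters mirror a standard droplet scRNA-seq intake: cells must
detect a minimum number of genes, genes must be supported by a minimum
number of cells, and cells are screened on the percentage of counts
falling in mitochondrial, ribosomal and red-blood-cell gene sets.
Defaults: keep cells detecting >=500 genes, genes seen in >=5 cells,
cells with mitochondrial percentage <15, ribosomal percentage >5 (cells
below 5% ribosomal content are removed -- an unusual direction, kept
deliberately; see docs/methods.md), red-blood-cell percentage <0.5, and
fewer than 3000 detected genes (a doublet proxy).

Percentages are computed on the raw counts entering the filter, and the
rules are applied in a fixed order: min-genes cells -> gene support
(recomputed) -> percentage screens -> max-genes cap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData


class EmptyFilterError(RuntimeError):
    """Raised when no cells survive QC."""


@dataclass
class QCThresholds:
    min_genes_per_cell: int = 500
    min_cells_per_gene: int = 5
    max_pct_mito: float = 15.0
    min_pct_ribo: float = 5.0
    max_pct_rbc: float = 0.5
    max_genes_per_cell: float = 3000

    def __post_init__(self) -> None:
        for name in (
            "min_genes_per_cell",
            "min_cells_per_gene",
            "max_pct_mito",
            "min_pct_ribo",
            "max_pct_rbc",
            "max_genes_per_cell",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.min_genes_per_cell < self.max_genes_per_cell:
            raise ValueError("min_genes_per_cell must be < max_genes_per_cell")


@dataclass
class QCMetrics:
    cells: pd.DataFrame  # n_genes_detected, total_counts, pct_mito, pct_ribo, pct_rbc
    genes: pd.DataFrame  # n_cells_expressing


@dataclass
class FilterReport:
    cells_in: int
    cells_kept: int
    genes_in: int
    genes_kept: int
    removed: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cells_in": self.cells_in,
            "cells_kept": self.cells_kept,
            "genes_in": self.genes_in,
            "genes_kept": self.genes_kept,
            "removed": dict(self.removed),
        }


def flag_genes_by_prefix(gene_names) -> dict[str, list[str]]:
    """Infer mito/ribo/RBC gene sets from naming conventions.

    Case-insensitive prefixes: ``mt-`` (mitochondrial), ``rps``/``rpl``
    (ribosomal proteins), ``hb`` (hemoglobins).
    """
    mito, ribo, rbc = [], [], []
    for g in gene_names:
        low = str(g).lower()
        if low.startswith("mt-"):
            mito.append(g)
        elif low.startswith(("rps", "rpl")):
            ribo.append(g)
        elif low.startswith(("hba", "hbb", "hbd", "hbg", "hbe", "hbm", "hbq", "hbz")):
            rbc.append(g)
    return {"mito": mito, "ribo": ribo, "rbc": rbc}


def _pct_in_set(X, gene_index: pd.Index, genes: list[str], totals: np.ndarray) -> np.ndarray:
    known = [g for g in genes if g in gene_index]
    unknown = set(genes) - set(known)
    if unknown:
        warnings.warn(f"ignoring {len(unknown)} flagged genes absent from matrix")
    if not known:
        return np.zeros(X.shape[0])
    idx = gene_index.get_indexer(known)
    in_set = np.asarray(X[:, idx].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals > 0, 100.0 * in_set / np.maximum(totals, 1e-300), 0.0)
    return pct


def compute_qc_metrics(
    adata: AnnData,
    mito_genes: list[str] | None = None,
    ribo_genes: list[str] | None = None,
    rbc_genes: list[str] | None = None,
) -> QCMetrics:
    """Compute per-cell and per-gene QC metrics on raw counts.

    Gene sets default to prefix-based flags inferred from ``var_names``.
    Cells with zero total counts get all percentages 0 and
    ``n_genes_detected`` 0.  A gene flagged in more than one set is
    counted in every percentage it belongs to.
    """
    if mito_genes is None or ribo_genes is None or rbc_genes is None:
        auto = flag_genes_by_prefix(adata.var_names)
        mito_genes = auto["mito"] if mito_genes is None else mito_genes
        ribo_genes = auto["ribo"] if ribo_genes is None else ribo_genes
        rbc_genes = auto["rbc"] if rbc_genes is None else rbc_genes
    X = adata.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    cells = pd.DataFrame(
        {
            "total_counts": totals,
            "n_genes_detected": n_genes.astype(int),
            "pct_mito": _pct_in_set(X, adata.var_names, mito_genes, totals),
            "pct_ribo": _pct_in_set(X, adata.var_names, ribo_genes, totals),
            "pct_rbc": _pct_in_set(X, adata.var_names, rbc_genes, totals),
        },
        index=adata.obs_names,
    )
    genes = pd.DataFrame(
        {"n_cells_expressing": np.asarray((X > 0).sum(axis=0)).ravel().astype(int)},
        index=adata.var_names,
    )
    return QCMetrics(cells=cells, genes=genes)


def filter_cells_genes(
    adata: AnnData,
    thresholds: QCThresholds | None = None,
    metrics: QCMetrics | None = None,
) -> tuple[AnnData, FilterReport]:
    """Apply the QC filters in their fixed order and report removals.

    Order: (1) cells with ``n_genes_detected >= min_genes_per_cell``;
    (2) genes with ``n_cells_expressing >= min_cells_per_gene``,
    recomputed on the surviving cells; (3) cells passing
    ``pct_mito < max`` AND ``pct_ribo > min`` AND ``pct_rbc < max``
    (percentages from the input metrics, i.e. raw counts); (4) cells
    with detected-gene count, over the step-2 gene set, strictly below
    ``max_genes_per_cell``.
    """
    thr = thresholds or QCThresholds()
    if metrics is None:
        metrics = compute_qc_metrics(adata)
    cm, gm = metrics.cells, metrics.genes
    cells_in, genes_in = adata.n_obs, adata.n_vars
    removed: dict[str, int] = {}

    keep1 = cm["n_genes_detected"].to_numpy() >= thr.min_genes_per_cell
    removed["min_genes_per_cell"] = int((~keep1).sum())
    sub = adata[keep1]

    support = np.asarray((sub.X > 0).sum(axis=0)).ravel()
    keep_genes = support >= thr.min_cells_per_gene
    removed["min_cells_per_gene"] = int((~keep_genes).sum())
    sub = sub[:, keep_genes]

    cm1 = cm.loc[sub.obs_names]
    keep3 = (
        (cm1["pct_mito"].to_numpy() < thr.max_pct_mito)
        & (cm1["pct_ribo"].to_numpy() > thr.min_pct_ribo)
        & (cm1["pct_rbc"].to_numpy() < thr.max_pct_rbc)
    )
    removed["pct_filters"] = int((~keep3).sum())
    sub = sub[keep3]

    n_det = np.asarray((sub.X > 0).sum(axis=1)).ravel()
    keep4 = n_det < thr.max_genes_per_cell
    removed["max_genes_per_cell"] = int((~keep4).sum())
    sub = sub[keep4]

    if sub.n_obs == 0:
        raise EmptyFilterError("no cells survive QC")
    report = FilterReport(
        cells_in=cells_in,
        cells_kept=sub.n_obs,
        genes_in=genes_in,
        genes_kept=sub.n_vars,
        removed=removed,
    )
    return sub.copy(), report
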