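"""Reading and writing the plain-text exchange formats used between stages.

Counts travel as a 10x-style triplet (``matrix.mtx`` in MatrixMarket
format, genes x cells, plus ``features.tsv`` and ``barcodes.tsv``);
tables as CSV; ground truth and reports as JSON.
"""

from __future__ import annotations

import os

import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData


def write_10x(adata: AnnData, outdir: str | os.PathLike) -> None:
    """Write counts as matrix.mtx (genes x cells) + features.tsv + barcodes.tsv.

    Per-cell metadata (``obs``) is written alongside as ``celltable.csv``
    and per-gene metadata as ``genetable.csv`` so a round trip preserves
    annotations.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    X = sp.csc_matrix(adata.X.T)
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), X, field="integer")
    adata.var_names.to_series().to_csv(
        os.path.join(outdir, "features.tsv"), sep="\t", header=False, index=False
    )
    adata.obs_names.to_series().to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", header=False, index=False
    )
    adata.obs.to_csv(os.path.join(outdir, "celltable.csv"))
    adata.var.to_csv(os.path.join(outdir, "genetable.csv"))


def read_10x(indir: str | os.PathLike) -> AnnData:
    """Read a triplet written by :func:`write_10x` back into AnnData."""
    indir = os.fspath(indir)
    M = scipy.io.mmread(os.path.join(indir, "matrix.mtx"))
    genes = pd.read_csv(
        os.path.join(indir, "features.tsv"), sep="\t", header=None
    )[0].astype(str)
    cells = pd.read_csv(
        os.path.join(indir, "barcodes.tsv"), sep="\t", header=None
    )[0].astype(str)
    obs = pd.DataFrame(index=cells.values)
    var = pd.DataFrame(index=genes.values)
    ct_path = os.path.join(indir, "celltable.csv")
    if os.path.exists(ct_path):
        obs = pd.read_csv(ct_path, index_col=0)
        obs.index = obs.index.astype(str)
    gt_path = os.path.join(indir, "genetable.csv")
    if os.path.exists(gt_path):
        var = pd.read_csv(gt_path, index_col=0, keep_default_na=False)
        var.index = var.index.astype(str)
    adata = AnnData(X=sp.csr_matrix(M.T), obs=obs, var=var)
    adata.obs_names = list(cells.values)
    adata.var_names = list(genes.values)
    return adata


def read_counts_csv(path: str | os.PathLike) -> AnnData:
    """Read a dense gene x cell CSV (genes as rows) into AnnData."""
    df = pd.read_csv(path, index_col=0)
    return AnnData(
        X=sp.csr_matrix(df.to_numpy().T),
        obs=pd.DataFrame(index=df.columns.astype(str)),
        var=pd.DataFrame(index=df.index.astype(str)),
    )
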