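"""Ligand-receptor communication scoring between annotated cell groups.

A simplified cell-cell communication model: for every
(sender group, receiver group, ligand-receptor pair) the interaction
probability is a Hill transform of the product of the sender's mean
ligand expression and the receiver's mean receptor expression,

    P = (L*R)**n / (Kh**n + (L*R)**n)        (Kh=0.5, n=1 by default),

with multi-subunit ligands/receptors collapsed by the geometric mean of
their subunit means.  Significance comes from permuting group labels;
pathway-level outgoing/incoming "pattern contribution" matrices
aggregate probabilities per group and normalize each pathway row by its
maximum.

Cell groups follow the tumor-microenvironment annotation style (GAMs,
tumor, lymphocytes, ...), with the GAMs group optionally split into
low/medium/high focal-gene subgroups at normalized-expression
cut-points (0.5, 1.5].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Focal-gene bin edges on the normalized-expression scale:
#: low [0; 0.5], medium (0.5; 1.5], high (1.5; +inf).
FOCAL_BIN_EDGES = (0.5, 1.5)


def assign_groups(
    base_groups,
    focal_values=None,
    split_group: str = "GAMs",
    bin_edges: tuple[float, float] = FOCAL_BIN_EDGES,
) -> pd.Series:
    """Per-cell group labels, splitting one group by focal-gene level.

    ``base_groups`` maps each cell to a named group (e.g. from a
    cluster -> group table).  Cells of ``split_group`` are reassigned to
    ``<group>_low`` / ``<group>_med`` / ``<group>_hi`` by their
    normalized focal expression, using left-open/right-closed bins at
    ``bin_edges``.
    """
    groups = pd.Series(base_groups).astype(str)
    if focal_values is None:
        return groups
    v = np.asarray(focal_values, dtype=float)
    if len(v) != len(groups):
        raise ValueError("focal_values length must match cells")
    c1, c2 = bin_edges
    sub = np.where(v <= c1, "_low", np.where(v <= c2, "_med", "_hi"))
    out = groups.copy()
    mask = groups == split_group
    out[mask] = groups[mask] + pd.Series(sub, index=groups.index)[mask]
    return out


def group_mean_expression(expr: pd.DataFrame, groups) -> pd.DataFrame:
    """Arithmetic mean of non-negative expression per group (genes x groups)."""
    groups = pd.Series(groups, index=expr.index) if not isinstance(groups, pd.Series) else groups
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression must be non-negative (use expm1 of log-normalized values)")
    return expr.groupby(groups, observed=True).mean().T


def interaction_probability(L, R, Kh: float = 0.5, n: float = 1.0):
    """Hill-function interaction probability of ligand/receptor means."""
    L = np.asarray(L, dtype=float)
    R = np.asarray(R, dtype=float)
    if (L < 0).any() or (R < 0).any():
        raise ValueError("ligand/receptor means must be non-negative")
    x = (L * R) ** n
    return x / (Kh**n + x)


def _side_mean(means: pd.DataFrame, subunits: list[str]) -> np.ndarray:
    """Collapse a multi-subunit side by the geometric mean of subunit means."""
    missing = [s for s in subunits if s not in means.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    vals = means.loc[subunits].to_numpy()  # subunits x groups
    return np.exp(np.mean(np.log(vals + 1e-300), axis=0)) * (vals > 0).all(axis=0)


@dataclass
class CommTensor:
    """sender x receiver x pair interaction probabilities and p-values."""

    probability: np.ndarray  # (groups, groups, pairs)
    p_value: np.ndarray
    groups: list[str]
    pairs: pd.DataFrame  # pair, ligand_subunits, receptor_subunits, pathway

    def prob_frame(self, pair: str) -> pd.DataFrame:
        k = list(self.pairs["pair"]).index(pair)
        return pd.DataFrame(self.probability[:, :, k], index=self.groups, columns=self.groups)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for k, pr in enumerate(self.pairs.itertuples()):
            for i, s in enumerate(self.groups):
                for j, r in enumerate(self.groups):
                    rows.append(
                        {
                            "sender": s,
                            "receiver": r,
                            "pair": pr.pair,
                            "pathway": pr.pathway,
                            "probability": self.probability[i, j, k],
                            "p_value": self.p_value[i, j, k],
                        }
                    )
        return pd.DataFrame(rows)


def _parse_side(s: str) -> list[str]:
    return [x for x in str(s).split(";") if x]


def _prob_tensor(means: pd.DataFrame, db: pd.DataFrame, Kh: float, n: float) -> np.ndarray:
    G = means.shape[1]
    P = np.zeros((G, G, len(db)))
    for k, row in enumerate(db.itertuples()):
        L = _side_mean(means, _parse_side(row.ligand_subunits))
        R = _side_mean(means, _parse_side(row.receptor_subunits))
        P[:, :, k] = interaction_probability(np.outer(L, R), 1.0, Kh=Kh, n=n)
    return P


def communication_probability(
    expr: pd.DataFrame, groups, db: pd.DataFrame, Kh: float = 0.5, n: float = 1.0
) -> CommTensor:
    """Observed interaction probabilities without significance."""
    groups = pd.Series(groups, index=expr.index) if not isinstance(groups, pd.Series) else groups
    means = group_mean_expression(expr, groups)
    names = list(means.columns)
    P = _prob_tensor(means, db, Kh, n)
    return CommTensor(probability=P, p_value=np.ones_like(P), groups=names, pairs=db.reset_index(drop=True))


def permutation_pvalues(
    expr: pd.DataFrame,
    groups,
    db: pd.DataFrame,
    n_perm: int = 100,
    Kh: float = 0.5,
    n: float = 1.0,
    seed: int = 0,
) -> CommTensor:
    """Interaction probabilities with label-permutation p-values.

    The null permutes group labels over cells; ``p = (1 + #{null P >=
    observed P}) / (n_perm + 1)``, so p is never exactly 0.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    groups = pd.Series(groups, index=expr.index) if not isinstance(groups, pd.Series) else groups
    # restrict to genes in the database: permutations only need those means
    used = sorted(
        {g for s in db["ligand_subunits"] for g in _parse_side(s)}
        | {g for s in db["receptor_subunits"] for g in _parse_side(s)}
    )
    missing = [g for g in used if g not in expr.columns]
    if missing:
        raise KeyError(f"database genes absent from expression matrix: {missing}")
    sub = expr[used]
    means = group_mean_expression(sub, groups)
    names = list(means.columns)
    obs = _prob_tensor(means, db, Kh, n)

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    garr = groups.to_numpy()
    for _ in range(n_perm):
        perm = pd.Series(rng.permutation(garr), index=sub.index)
        null_means = group_mean_expression(sub, perm)[names]
        null = _prob_tensor(null_means, db, Kh, n)
        exceed += null >= obs
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    return CommTensor(probability=obs, p_value=pvals, groups=names, pairs=db.reset_index(drop=True))


def pattern_contributions(
    tensor: CommTensor, direction: str = "outgoing", p_max: float | None = None,
    normalize: bool = True,
) -> pd.DataFrame:
    """Pathway x group contribution scores.

    Outgoing sums probabilities over receivers and pairs-in-pathway with
    the group as sender (incoming is symmetric); with ``normalize`` each
    pathway row is divided by its maximum over groups, giving scores in
    [0, 1] (rows of zeros stay zero).  Optionally pairs with
    ``p_value > p_max`` are dropped first; dropping pairs can never
    increase an unnormalized total.
    """
    if direction not in ("outgoing", "incoming"):
        raise ValueError("direction must be 'outgoing' or 'incoming'")
    P = tensor.probability.copy()
    if p_max is not None:
        P = np.where(tensor.p_value <= p_max, P, 0.0)
    pathways = list(dict.fromkeys(tensor.pairs["pathway"]))
    out = np.zeros((len(pathways), len(tensor.groups)))
    for pi, path in enumerate(pathways):
        ks = np.flatnonzero((tensor.pairs["pathway"] == path).to_numpy())
        block = P[:, :, ks]
        totals = block.sum(axis=(1, 2)) if direction == "outgoing" else block.sum(axis=(0, 2))
        if normalize:
            m = totals.max()
            out[pi] = totals / m if m > 0 else 0.0
        else:
            out[pi] = totals
    return pd.DataFrame(out, index=pathways, columns=tensor.groups)
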