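"""Keyword characterization of gene groups via TF-IDF.

Each gene is a text document (its functional description); documents are
weighted with TF-IDF (raw term frequency times ``ln(N/df)``), rows are
L2-normalized, documents are clustered by average-linkage agglomeration
on cosine distance, and every group of genes is characterized by the
terms whose within-group mean TF-IDF most exceeds the best competing
group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .synthdata import GeneDocCorpus

# a compact English stopword list; configurable via build_tfidf(stopwords=...)
STOPWORDS = frozenset(
    """a about above after again all also among an and any are as at be because
    been being below between both but by can did do does doing down during each
    few for from further had has have having here how however into is it its
    itself more most not now of off on once only or other our out over own same
    she some such than that the their theirs them then there these they this
    those through under until upon very was were what when where which while who
    whom why will with within would""".split()
)


def tokenize(text: str, stopwords=STOPWORDS, min_len: int = 3) -> list[str]:
    """Lowercase, split on non-alphanumerics, drop short tokens and stopwords."""
    out = []
    for raw in "".join(c if c.isalnum() else " " for c in text.lower()).split():
        if len(raw) >= min_len and raw not in stopwords:
            out.append(raw)
    return out


def corpus_from_text(texts: dict[str, str], stopwords=STOPWORDS) -> GeneDocCorpus:
    """Tokenize free-text gene descriptions into a bag-of-words corpus."""
    from collections import Counter

    docs = {g: Counter(tokenize(t, stopwords)) for g, t in texts.items()}
    vocab = sorted(set().union(*docs.values())) if docs else []
    return GeneDocCorpus(docs=docs, vocabulary=vocab)


@dataclass
class TfidfMatrix:
    matrix: sp.csr_matrix  # documents x terms, L2-normalized rows
    docs: list[str]
    terms: list[str]
    idf: np.ndarray
    normalized: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix.toarray(), index=self.docs, columns=self.terms)


def build_tfidf(
    corpus: GeneDocCorpus, min_df: int = 2, stopwords=frozenset(),
    l2_normalize: bool = True,
) -> TfidfMatrix:
    """TF-IDF weights: raw tf times ``ln(N/df)``, L2 row normalization.

    Terms present in fewer than ``min_df`` documents or listed in
    ``stopwords`` are dropped.  A term occurring in every document gets
    idf 0 and hence weight 0 everywhere.  ``l2_normalize=False`` returns
    the raw ``tf * idf`` weights.
    """
    if not corpus.docs:
        raise ValueError("empty corpus")
    docs = list(corpus.docs)
    df_count: dict[str, int] = {}
    for bag in corpus.docs.values():
        for term in bag:
            df_count[term] = df_count.get(term, 0) + 1
    terms = sorted(t for t, c in df_count.items() if c >= min_df and t not in stopwords)
    if not terms:
        raise ValueError("vocabulary empty after min_df/stopword filtering")
    tindex = {t: j for j, t in enumerate(terms)}
    N = len(docs)
    idf = np.array([np.log(N / df_count[t]) for t in terms])

    rows, cols, vals = [], [], []
    for i, doc in enumerate(docs):
        for term, tf in corpus.docs[doc].items():
            j = tindex.get(term)
            if j is not None:
                rows.append(i)
                cols.append(j)
                vals.append(tf * idf[j])
    M = sp.csr_matrix((vals, (rows, cols)), shape=(N, len(terms)))
    if l2_normalize:
        norms = np.sqrt(np.asarray(M.multiply(M).sum(axis=1)).ravel())
        inv = np.where(norms > 0, 1.0 / np.where(norms > 0, norms, 1.0), 0.0)
        M = sp.diags(inv) @ M
    return TfidfMatrix(
        matrix=M.tocsr(), docs=docs, terms=terms, idf=idf, normalized=l2_normalize
    )


def cosine_distances(tfidf: TfidfMatrix) -> np.ndarray:
    """Pairwise ``1 - cosine`` distances; all-zero documents sit at distance 1."""
    M = tfidf.matrix
    norms = np.sqrt(np.asarray(M.multiply(M).sum(axis=1)).ravel())
    zero = norms == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero documents assigned distance 1")
    sim = np.asarray((M @ M.T).todense())
    dist = np.clip(1.0 - sim, 0.0, 1.0)
    dist[zero, :] = 1.0
    dist[:, zero] = 1.0
    np.fill_diagonal(dist, 0.0)
    return dist


def cluster_documents(
    tfidf: TfidfMatrix, n_clusters: int | None = None, cut_height: float | None = None,
    linkage: str = "average",
) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering of documents on cosine distance.

    Cut either to ``n_clusters`` groups or at dendrogram ``cut_height``.
    Returns 0-based labels and the scipy linkage matrix.
    """
    if (n_clusters is None) == (cut_height is None):
        raise ValueError("specify exactly one of n_clusters or cut_height")
    n = len(tfidf.docs)
    if n_clusters is not None and n < n_clusters:
        raise ValueError(f"{n} documents < n_clusters={n_clusters}")
    dist = cosine_distances(tfidf)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    if n_clusters is not None:
        raw = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    _, labels = np.unique(raw, return_inverse=True)
    return labels, Z


def unique_keywords(
    tfidf: TfidfMatrix, labels, top_k: int = 10
) -> pd.DataFrame:
    """Terms that characterize each document group uniquely.

    ``score(t, c) = mean TF-IDF of t in c - max over other groups of the
    mean TF-IDF``; only positive scores qualify.  Returns a table with
    columns (cluster, rank, term, score).
    """
    labels = np.asarray(labels)
    if len(labels) != len(tfidf.docs):
        raise ValueError("labels must match number of documents")
    groups = np.unique(labels)
    M = tfidf.matrix
    means = np.vstack(
        [np.asarray(M[labels == g].mean(axis=0)).ravel() for g in groups]
    )  # groups x terms
    rows = []
    for gi, g in enumerate(groups):
        if (labels == g).sum() == 0:  # pragma: no cover - unique() precludes it
            warnings.warn(f"cluster {g} empty; skipped")
            continue
        others = np.delete(means, gi, axis=0)
        competitor = others.max(axis=0) if len(others) else np.zeros(means.shape[1])
        score = means[gi] - competitor
        order = np.argsort(-score, kind="stable")
        taken = 0
        for j in order:
            if score[j] <= 0 or taken >= top_k:
                break
            rows.append(
                {"cluster": int(g), "rank": taken + 1, "term": tfidf.terms[j],
                 "score": float(score[j])}
            )
            taken += 1
    return pd.DataFrame(rows, columns=["cluster", "rank", "term", "score"])


def keywords_for_gene_sets(
    tfidf: TfidfMatrix, gene_sets: dict, top_k: int = 10
) -> pd.DataFrame:
    """Unique keywords for named, possibly partial, groups of genes.

    Convenience wrapper for characterizing expression clusters by their
    marker-gene sets: documents not in any set are ignored, and the
    returned ``cluster`` column carries the set names.
    """
    name_by_doc = {}
    for name, genes in gene_sets.items():
        for g in genes:
            name_by_doc[g] = name
    keep = [i for i, d in enumerate(tfidf.docs) if d in name_by_doc]
    if not keep:
        raise ValueError("no corpus documents overlap the gene sets")
    sub = TfidfMatrix(
        matrix=tfidf.matrix[keep],
        docs=[tfidf.docs[i] for i in keep],
        terms=tfidf.terms,
        idf=tfidf.idf,
    )
    names = sorted(gene_sets)
    labels = np.array([names.index(name_by_doc[d]) for d in sub.docs])
    table = unique_keywords(sub, labels, top_k=top_k)
    table["cluster"] = [names[c] for c in table["cluster"]]
    return table
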