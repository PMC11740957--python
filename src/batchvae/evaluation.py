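"""Alignment evaluation: PCA + k-nearest-neighbor tumor-type assignment,
batch-mixing entropy, and before/after differential expression.

The classification procedure mirrors how aligned preclinical models are
assigned a disease type: embed reference tumors with PCA (fitted on the
reference only, centered, unscaled), place each query in that space, take
its k nearest reference samples by Euclidean distance, and call the
majority tumor type among them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

__all__ = [
    "pca_embed",
    "nn_classify",
    "agreement_rate",
    "differential_expression",
    "batch_mixing_entropy",
    "NeighborTypeClassifier",
    "NeighborClassification",
]


def _matrix(X) -> np.ndarray:
    if hasattr(X, "X"):
        X = X.X
    return np.atleast_2d(np.asarray(X, dtype=float))


def pca_embed(reference, queries, n_components: int = 70):
    """Fit PCA on the reference matrix (mean-centered, no per-gene scaling)
    and transform both sets with the reference's mean and loadings."""
    R = _matrix(reference)
    Q = _matrix(queries)
    if R.shape[1] != Q.shape[1]:
        raise ValueError("reference and queries must share the gene space")
    max_comp = min(R.shape)
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds min(reference shape)={max_comp}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    ref_coords = pca.fit_transform(R)
    return ref_coords, pca.transform(Q)


@dataclass
class NeighborClassification:
    """Per-query nearest-neighbor vote results."""

    assigned: np.ndarray  # winning label per query
    neighbor_labels: np.ndarray  # (n_queries, k) labels of the k neighbors
    vote_counts: np.ndarray  # votes received by the winning label
    neighbor_indices: np.ndarray  # (n_queries, k) reference row indices


def _majority_vote(labels_k: np.ndarray, dists_k: np.ndarray):
    """Majority label among one query's neighbors. Ties are broken by the
    smaller summed distance to the tied label's neighbors, then by
    lexicographic label order."""
    uniq, counts = np.unique(labels_k, return_counts=True)
    top = counts.max()
    tied = uniq[counts == top]
    if len(tied) == 1:
        return tied[0], int(top)
    sums = {lab: dists_k[labels_k == lab].sum() for lab in tied}
    best = sorted(tied, key=lambda lab: (sums[lab], lab))[0]
    return best, int(top)


def nn_classify(query_coords, reference_coords, reference_labels,
                k: int = 25) -> NeighborClassification:
    """Assign each query the majority label of its k nearest reference
    points (Euclidean distance)."""
    R = _matrix(reference_coords)
    Q = _matrix(query_coords)
    labels = np.asarray(reference_labels)
    if R.shape[0] == 0:
        raise ValueError("reference set is empty")
    if len(labels) != R.shape[0]:
        raise ValueError("reference labels must align with reference rows")
    if k > R.shape[0]:
        raise ValueError(f"k={k} exceeds reference size {R.shape[0]}")
    nn = NearestNeighbors(n_neighbors=k, algorithm="brute").fit(R)
    dists, idx = nn.kneighbors(Q)
    neigh_labels = labels[idx]
    assigned, votes = [], []
    for i in range(Q.shape[0]):
        lab, v = _majority_vote(neigh_labels[i], dists[i])
        assigned.append(lab)
        votes.append(v)
    return NeighborClassification(
        assigned=np.asarray(assigned),
        neighbor_labels=neigh_labels,
        vote_counts=np.asarray(votes),
        neighbor_indices=idx,
    )


def agreement_rate(classification: NeighborClassification, annotations):
    """Fraction of annotated queries whose assigned label matches the
    annotation. Returns ``(rate, n_scored, n_excluded)``; rate is ``None``
    when no query carries an annotation."""
    ann = pd.Series(np.asarray(annotations, dtype=object))
    missing = ann.isna() | (ann.astype(str) == "")
    n_excluded = int(missing.sum())
    scored = ~missing.to_numpy()
    n_scored = int(scored.sum())
    if n_scored == 0:
        return None, 0, n_excluded
    agree = classification.assigned[scored] == ann.to_numpy()[scored]
    return float(np.mean(agree)), n_scored, n_excluded


class NeighborTypeClassifier(BaseEstimator, ClassifierMixin):
    """PCA + majority-vote kNN disease-type assignment as an estimator.

    ``fit`` takes the reference expression matrix and its type labels and
    fits the (centered, unscaled) PCA on the reference only; ``predict``
    embeds queries with the reference loadings and votes among the
    ``n_neighbors`` nearest reference samples.
    """

    def __init__(self, n_neighbors: int = 25, n_components: int = 70):
        self.n_neighbors = n_neighbors
        self.n_components = n_components

    def fit(self, X, y):
        R = _matrix(X)
        y = np.asarray(y)
        n_comp = min(self.n_components, *R.shape)
        self.pca_ = PCA(n_components=n_comp, svd_solver="full")
        self.reference_coords_ = self.pca_.fit_transform(R)
        self.reference_labels_ = y
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        check_is_fitted(self, "pca_")
        coords = self.pca_.transform(_matrix(X))
        res = nn_classify(
            coords, self.reference_coords_, self.reference_labels_, k=self.n_neighbors
        )
        return res.assigned

    def classify(self, X) -> NeighborClassification:
        """Like predict but returning the full vote detail."""
        check_is_fitted(self, "pca_")
        coords = self.pca_.transform(_matrix(X))
        return nn_classify(
            coords, self.reference_coords_, self.reference_labels_, k=self.n_neighbors
        )


def differential_expression(group_a, group_b, alpha: float = 0.01,
                            top_n: int = 100, equal_var: bool = False) -> pd.DataFrame:
    """Gene-wise two-sample t-test between two normalized matrices.

    Values are log-space, so the mean difference is a log2 fold change.
    P-values are Benjamini-Hochberg adjusted; the result table is the full
    gene list with a ``passes`` flag (adjusted p < alpha) and ``rank``
    giving the |lfc| order among passing genes, truncated to ``top_n`` —
    non-passing or below-rank genes have rank NaN.
    """
    A = _matrix(group_a)
    B = _matrix(group_b)
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the gene space")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least 2 samples per group")
    genes = (
        list(map(str, group_a.var_names))
        if hasattr(group_a, "var_names")
        else [f"gene_{g}" for g in range(A.shape[1])]
    )
    lfc = A.mean(axis=0) - B.mean(axis=0)
    import warnings

    with warnings.catch_warnings():
        # genes constant in both groups produce an expected precision
        # warning; they are flagged and assigned p = 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(A, B, axis=0, equal_var=equal_var)
    degenerate = (A.var(axis=0) == 0) & (B.var(axis=0) == 0)
    p = np.where(degenerate, 1.0, p)
    t = np.where(degenerate, 0.0, t)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame(
        {
            "gene": genes,
            "lfc": lfc,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "degenerate": degenerate,
        }
    )
    table["passes"] = table["p_adj"] < alpha
    table = table.sort_values("lfc", key=np.abs, ascending=False, kind="mergesort")
    ranks = np.full(len(table), np.nan)
    ranks[: min(top_n, int(table["passes"].sum()))] = np.arange(
        1, min(top_n, int(table["passes"].sum())) + 1
    )
    # ranks only apply to passing genes, in |lfc| order
    passing_pos = np.flatnonzero(table["passes"].to_numpy())
    table["rank"] = np.nan
    table.iloc[
        passing_pos[:top_n], table.columns.get_loc("rank")
    ] = np.arange(1, len(passing_pos[:top_n]) + 1)
    return table.reset_index(drop=True)


def batch_mixing_entropy(coords, source_labels, k: int = 25):
    """Shannon entropy (normalized by ln K) of the source composition in
    each sample's k-nearest-neighborhood; well-mixed data scores near 1,
    fully separated sources score 0. Returns ``(per_sample, mean)``."""
    X = _matrix(coords)
    labels = np.asarray(source_labels)
    sources = np.unique(labels)
    if len(sources) < 2:
        raise ValueError("batch mixing entropy needs at least 2 sources")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= X.shape[0]:
        raise ValueError("k must be smaller than the number of samples")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute").fit(X)
    _, idx = nn.kneighbors(X)
    neigh = labels[idx[:, 1:]]  # drop self
    ent = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        _, counts = np.unique(neigh[i], return_counts=True)
        p = counts / counts.sum()
        ent[i] = -(p * np.log(p)).sum() / np.log(len(sources))
    return ent, float(ent.mean())
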