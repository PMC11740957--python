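"""Count-matrix preprocessing: gene harmonisation across datasets,
small-indication filtering, TMM scaling factors, and log2-CPM transform.

Matrices are carried as :class:`anndata.AnnData` with samples as ``obs``
rows and genes as ``var`` columns; ``obs`` holds the per-sample ``source``
and optional ``indication`` labels. Plain arrays are accepted wherever noted
and are always oriented samples x genes.

TMM (trimmed mean of M-values) computes one scaling factor per sample from
gene-wise log-ratios against a reference sample, double-trimmed by log-ratio
(M) and average log-abundance (A) quantiles and combined by inverse-variance
weights; factors are rescaled to geometric mean 1. The effective library
size ``libsize * factor`` then feeds counts-per-million.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "intersect_genes",
    "filter_small_indications",
    "tmm_factors",
    "log_cpm",
    "TMMNormalizer",
    "preprocess",
]


def _counts(X) -> np.ndarray:
    arr = X.X if hasattr(X, "X") else X
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D samples x genes matrix")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr


def intersect_genes(matrices: list):
    """Subset every AnnData to the genes present in all of them, in
    lexicographically sorted order. Sample content is unchanged.

    Raises ``ValueError`` naming the first pair of inputs with no genes in
    common when the intersection is empty.
    """
    if len(matrices) == 0:
        raise ValueError("at least one matrix is required")
    gene_sets = [set(map(str, m.var_names)) for m in matrices]
    for gs, m in zip(gene_sets, matrices):
        if len(gs) == 0:
            raise ValueError("a matrix with no genes cannot be intersected")
    common = set.intersection(*gene_sets)
    if not common:
        for i in range(len(matrices)):
            for j in range(i + 1, len(matrices)):
                if not gene_sets[i] & gene_sets[j]:
                    raise ValueError(
                        f"matrices {i} and {j} share no genes; check identifier conventions"
                    )
        raise ValueError("no gene is present in all matrices")
    order = sorted(common)
    return [m[:, order].copy() for m in matrices]


def filter_small_indications(adata, min_samples: int = 5):
    """Drop samples whose indication has fewer than ``min_samples`` samples.

    Samples with a missing indication label are retained. Raises if the
    filter would remove every sample.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if "indication" not in adata.obs:
        raise ValueError("obs['indication'] is required for indication filtering")
    ind = adata.obs["indication"]
    missing = ind.isna() | (ind.astype(str) == "")
    counts = ind[~missing].value_counts()
    keep_labels = set(counts[counts >= min_samples].index)
    keep = missing | ind.isin(keep_labels)
    if not keep.any():
        raise ValueError(
            f"no samples survive the indication filter (min_samples={min_samples})"
        )
    return adata[keep.to_numpy()].copy()


def _choose_reference(counts: np.ndarray) -> int:
    """Sample whose 75th percentile of count/libsize is closest to the mean."""
    libsize = counts.sum(axis=1)
    f75 = np.quantile(counts / libsize[:, None], 0.75, axis=1)
    return int(np.argmin(np.abs(f75 - f75.mean())))


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """log2 TMM factor of one sample against the reference."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        return 0.0
    y_o, y_r = obs[pos], ref[pos]
    p_o, p_r = y_o / n_obs, y_r / n_ref
    M = np.log2(p_o / p_r)
    A = 0.5 * np.log2(p_o * p_r)
    # delta-method variance of M; precision weights are its inverse
    v = (n_obs - y_o) / (n_obs * y_o) + (n_ref - y_r) / (n_ref * y_r)
    if np.max(np.abs(M)) < 1e-6:
        return 0.0
    n = len(M)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(M).rank().to_numpy()
    rank_a = pd.Series(A).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    f = float(np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep]))
    return 0.0 if not np.isfinite(f) else f


def tmm_factors(X, trim_m: float = 0.3, trim_a: float = 0.05,
                reference: int | str = "auto") -> np.ndarray:
    """Per-sample TMM scaling factors, geometric-mean-normalized to 1.

    ``X`` is an AnnData or samples x genes array of raw counts. ``reference``
    is a sample index, or "auto" for the sample whose upper-quartile
    count fraction is closest to the mean upper-quartile.
    """
    counts = _counts(X)
    if counts.shape[0] < 2:
        raise ValueError("TMM needs at least 2 samples")
    libsize = counts.sum(axis=1)
    if (libsize <= 0).any():
        bad = int(np.argmax(libsize <= 0))
        raise ValueError(f"sample {bad} has zero library size")
    ref_idx = _choose_reference(counts) if reference == "auto" else int(reference)
    ref = counts[ref_idx]
    n_ref = libsize[ref_idx]
    log_f = np.array(
        [
            _tmm_pair(counts[i], ref, libsize[i], n_ref, trim_m, trim_a)
            for i in range(counts.shape[0])
        ]
    )
    factors = 2.0**log_f
    return factors / np.exp(np.mean(np.log(factors)))


def log_cpm(X, factors: np.ndarray | None = None, pseudocount: float = 1.0):
    """log2 counts-per-million with a pseudocount, on TMM-effective library
    sizes: ``log2(count / (libsize * factor) * 1e6 + pseudocount)``.

    Returns an array for array input; for AnnData input returns a new
    AnnData with the transformed ``X``, ``obs['tmm_factor']`` and raw counts
    kept in ``layers['counts']``.
    """
    counts = _counts(X)
    n = counts.shape[0]
    if factors is None:
        factors = np.ones(n)
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (n,):
        raise ValueError("factors must align with samples (one per sample)")
    if (factors <= 0).any():
        raise ValueError("TMM factors must be strictly positive")
    libsize = counts.sum(axis=1)
    if (libsize <= 0).any():
        raise ValueError("every sample needs a positive library size")
    eff = libsize * factors
    values = np.log2(counts / eff[:, None] * 1e6 + pseudocount)
    if hasattr(X, "X"):
        out = X.copy()
        out.layers["counts"] = counts
        out.X = values
        out.obs["tmm_factor"] = factors
        return out
    return values


class TMMNormalizer(BaseEstimator, TransformerMixin):
    """TMM + log2-CPM as an sklearn transformer.

    ``fit`` selects (and stores) the reference sample from the training
    counts; ``transform`` computes each sample's TMM factor against that
    stored reference and returns log2(CPM + pseudocount), so new samples are
    normalized consistently with the training batch.
    """

    def __init__(self, trim_m: float = 0.3, trim_a: float = 0.05,
                 pseudocount: float = 1.0):
        self.trim_m = trim_m
        self.trim_a = trim_a
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        counts = _counts(X)
        if counts.shape[0] < 2:
            raise ValueError("TMM needs at least 2 samples")
        ref_idx = _choose_reference(counts)
        self.reference_counts_ = counts[ref_idx].copy()
        self.reference_index_ = ref_idx
        self.n_genes_ = counts.shape[1]
        self.factors_ = self._factors(counts)
        return self

    def _factors(self, counts: np.ndarray) -> np.ndarray:
        libsize = counts.sum(axis=1)
        if (libsize <= 0).any():
            raise ValueError("every sample needs a positive library size")
        n_ref = self.reference_counts_.sum()
        log_f = np.array(
            [
                _tmm_pair(c, self.reference_counts_, ls, n_ref, self.trim_m, self.trim_a)
                for c, ls in zip(counts, libsize)
            ]
        )
        factors = 2.0**log_f
        return factors / np.exp(np.mean(np.log(factors)))

    def transform(self, X):
        check_is_fitted(self, "reference_counts_")
        counts = _counts(X)
        if counts.shape[1] != self.n_genes_:
            raise ValueError(
                f"input has {counts.shape[1]} genes, normalizer expects {self.n_genes_}"
            )
        factors = self._factors(counts)
        return log_cpm(X, factors, pseudocount=self.pseudocount)


def preprocess(matrices: list, min_indication_samples: int = 5,
               joint_tmm: bool = True, pseudocount: float = 1.0):
    """Full preprocessing pipeline over one or more raw-count AnnDatas:
    gene intersection (sorted), concatenation, small-indication filtering,
    TMM scaling (jointly by default, else per input dataset), log2-CPM.

    Returns a single normalized AnnData (samples x genes) with
    ``obs['tmm_factor']`` and counts preserved in ``layers['counts']``.
    """
    import anndata as ad

    matrices = intersect_genes(matrices)
    merged = (
        matrices[0]
        if len(matrices) == 1
        else ad.concat(matrices, join="inner", merge="same", index_unique=None)
    )
    merged = merged.copy()
    if "indication" in merged.obs and min_indication_samples > 1:
        merged = filter_small_indications(merged, min_indication_samples)
    if joint_tmm or "dataset_of_origin" not in merged.obs:
        factors = tmm_factors(merged)
    else:
        factors = np.empty(merged.n_obs)
        for grp in merged.obs["dataset_of_origin"].unique():
            mask = (merged.obs["dataset_of_origin"] == grp).to_numpy()
            factors[mask] = tmm_factors(merged[mask])
    return log_cpm(merged, factors, pseudocount=pseudocount)
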