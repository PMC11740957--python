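"""Independent reference implementations used only to cross-check the
package: a from-definition TMM computation, a brute-force all-pairs kNN
majority-vote classifier, and a hand-coded Benjamini-Hochberg step-up.

These are deliberately written with different primitives (scipy rankdata,
explicit loops, Counter) than the library code they verify.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from scipy import stats


def tmm_oracle(counts: np.ndarray, trim_m: float = 0.3, trim_a: float = 0.05) -> np.ndarray:
    """Trimmed mean of M-values, straight from the published definition.

    ``counts`` is samples x genes. Reference = sample whose 75th percentile
    of count/libsize is closest to the mean of those percentiles. For each
    sample vs the reference, gene-wise log-ratios M and mean log-abundances
    A over doubly positive genes are double-trimmed by rank (30% on M, 5%
    on A) and combined by inverse-variance (delta-method) weights. Factors
    are rescaled to geometric mean 1.
    """
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=1)
    f75 = np.array([np.quantile(c / l, 0.75) for c, l in zip(counts, lib)])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    log_factors = []
    for i in range(counts.shape[0]):
        o, r = counts[i], counts[ref]
        both = (o > 0) & (r > 0)
        po, pr = o[both] / lib[i], r[both] / lib[ref]
        M = np.log2(po / pr)
        A = 0.5 * np.log2(po * pr)
        # asymptotic variance of each M; weight by its reciprocal (precision)
        var = (lib[i] - o[both]) / (lib[i] * o[both]) + (lib[ref] - r[both]) / (
            lib[ref] * r[both]
        )
        if M.size == 0 or np.max(np.abs(M)) < 1e-6:
            log_factors.append(0.0)
            continue
        n = M.size
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = stats.rankdata(M)
        ra = stats.rankdata(A)
        sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not sel.any():
            log_factors.append(0.0)
        else:
            precision = 1.0 / var[sel]
            log_factors.append(float(np.sum(M[sel] * precision) / np.sum(precision)))
    f = 2.0 ** np.array(log_factors)
    return f / np.exp(np.mean(np.log(f)))


def knn_vote_oracle(queries: np.ndarray, reference: np.ndarray,
                    labels: np.ndarray, k: int) -> list:
    """Exhaustive all-pairs-distance kNN majority vote with the documented
    tie-breaks (smaller summed distance, then lexicographic label)."""
    assigned = []
    for q in np.atleast_2d(queries):
        d = np.sqrt(((reference - q) ** 2).sum(axis=1))
        order = np.argsort(d, kind="stable")[:k]
        votes = Counter(labels[order])
        top = max(votes.values())
        tied = [lab for lab, v in votes.items() if v == top]
        if len(tied) == 1:
            assigned.append(tied[0])
        else:
            sums = {
                lab: d[order][labels[order] == lab].sum() for lab in tied
            }
            assigned.append(sorted(tied, key=lambda lab: (sums[lab], lab))[0])
    return assigned


def bh_stepup_oracle(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the textbook step-up rule."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj
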