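"""Independent oracles used by the test suite.

Each function here is a deliberately naive second implementation —
brute-force pairwise counting, a memoized counting recurrence, direct
textbook formulas — kept free of any code path it is used to check.
"""

from __future__ import annotations

import functools

import numpy as np
from scipy.stats import binom

CANONICAL_WOBBLE = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)


def pairwise_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC = [#(pos > neg) + 0.5 · #(pos = neg)] / (n_pos · n_neg)."""
    pos = np.asarray(scores)[np.asarray(labels, bool)]
    neg = np.asarray(scores)[~np.asarray(labels, bool)]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


def count_structures_recurrence(
    seq: str, min_loop: int = 3, allowed=CANONICAL_WOBBLE
) -> int:
    """Nussinov-style counting recurrence over region [i, j]:

    N(i, j) = N(i+1, j) + Σ_{k pairable with i, k−i−1 ≥ min_loop}
              N(i+1, k−1) · N(k+1, j),   N(empty) = 1.
    """

    @functools.lru_cache(maxsize=None)
    def count(i: int, j: int) -> int:
        if i > j:
            return 1
        total = count(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in allowed:
                total += count(i + 1, k - 1) * count(k + 1, j)
        return total

    return count(0, len(seq) - 1)


def binomial_mixture_auc(
    levels_pos: dict[float, float], levels_neg: dict[float, float], n: int
) -> float:
    """AUC between two mixtures of Binomial(n, ·)/n count distributions.

    Exhaustive summation over the count support:
    AUC = Σ_x P(X_pos = x)[P(X_neg < x) + 0.5 · P(X_neg = x)].
    """
    x = np.arange(n + 1)

    def mixture_pmf(levels: dict[float, float]) -> np.ndarray:
        pmf = np.zeros(n + 1)
        for level, weight in levels.items():
            pmf += weight * binom.pmf(x, n, level)
        return pmf

    pmf_pos = mixture_pmf(levels_pos)
    pmf_neg = mixture_pmf(levels_neg)
    cdf_below = np.concatenate([[0.0], np.cumsum(pmf_neg)[:-1]])
    return float(np.sum(pmf_pos * (cdf_below + 0.5 * pmf_neg)))


def pearson_by_hand(x, y) -> float:
    """Textbook covariance formula, no library call."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))
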