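"""Shared statistical primitives: Wilcoxon rank-sum and BH-FDR.

The rank-sum wrapper switches to an exhaustive permutation distribution for
small samples, so p-values agree with exact enumeration (ties included);
larger samples use the tie-corrected normal approximation.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy import stats

EXACT_MAX_N = 12  # exhaustive enumeration up to n1+n2 of this size


def rank_sum_test(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) test.

    Returns (U statistic of ``x``, p-value). ``alternative`` follows scipy
    semantics: "less" means ``x`` stochastically smaller than ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        return np.nan, np.nan
    if min(len(x), len(y)) < 2 and alternative == "two-sided" and len(x) + len(y) < 4:
        # Too few observations for any meaningful p
        return np.nan, np.nan
    n = len(x) + len(y)
    if n <= EXACT_MAX_N:
        method = stats.PermutationMethod(n_resamples=comb(n, len(x)) + 1)
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum() == 0:
        return q
    pv = p[ok]
    m = len(pv)
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    q[ok] = adj
    return q
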