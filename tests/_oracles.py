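"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (all-pairs scans, closed forms,
subset enumeration) and shares no code with the package internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


def brute_overlaps(a_start, a_end, b_start, b_end) -> bool:
    """Half-open interval intersection test."""
    return a_start < b_end and b_start < a_end


def brute_pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def brute_pearson_p(x, y) -> float:
    """Two-sided p from the t transform of r with n-2 df."""
    n = len(x)
    r = brute_pearson(x, y)
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), n - 2))


def brute_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def brute_welch(x, y) -> tuple[float, float]:
    """Welch's t and two-sided p with Welch-Satterthwaite df, closed form."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    v1 = x.var(ddof=1) / n1
    v2 = y.var(ddof=1) / n2
    t = (x.mean() - y.mean()) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(t), float(2 * stats.t.sf(abs(t), df))


def tree_conditional_expectation(arrays, x, subset) -> float:
    """Cover-weighted expectation of a tree with features in ``subset`` fixed."""
    left, right, feat, thr, cover, value, _ = arrays

    def rec(j):
        if left[j] < 0:
            return value[j]
        if feat[j] in subset:
            return rec(left[j]) if x[feat[j]] <= thr[j] else rec(right[j])
        return (cover[left[j]] * rec(left[j]) + cover[right[j]] * rec(right[j])) / cover[j]

    return rec(0)


def brute_tree_shapley(arrays, x, n_features) -> np.ndarray:
    """Exact Shapley values by enumerating all feature subsets."""
    phi = np.zeros(n_features)
    feats = list(range(n_features))
    for i in feats:
        others = [f for f in feats if f != i]
        for k in range(len(others) + 1):
            for sub in itertools.combinations(others, k):
                w = math.factorial(k) * math.factorial(n_features - k - 1) / math.factorial(
                    n_features
                )
                with_i = tree_conditional_expectation(arrays, x, set(sub) | {i})
                without = tree_conditional_expectation(arrays, x, set(sub))
                phi[i] += w * (with_i - without)
    return phi
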