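"""Exact Shapley attributions for sklearn tree ensembles.

Implements the polynomial-time, path-dependent tree-Shapley recursion
(cover-weighted conditional expectations over the training distribution
recorded in each node).  For a random-forest classifier the attributed
output is the positive-class probability, so per-row attributions satisfy
local accuracy: sum(phi) + expected_value == predict_proba(x)[1], averaged
over trees.

The per-tree kernel is an iterative reformulation of the recursive
EXTEND/UNWIND algorithm, jit-compiled with numba when available.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _unwound_sum(pz, po, pw, length, i):
    """Sum of path weights after notionally unwinding element ``i``."""
    total = 0.0
    nxt = pw[length - 1]
    if po[i] != 0.0:
        for j in range(length - 2, -1, -1):
            tmp = nxt * length / ((j + 1) * po[i])
            total += tmp
            nxt = pw[j] - tmp * pz[i] * (length - 1 - j) / length
    else:
        for j in range(length - 2, -1, -1):
            total += pw[j] * length / (pz[i] * (length - 1 - j))
    return total


@njit(cache=True)
def _tree_shap_one(children_left, children_right, feature, threshold, cover, value, x, phi, max_depth):
    """Accumulate one tree's Shapley values for sample ``x`` into ``phi``."""
    size = max_depth + 4
    # DFS stack; each frame holds a node, its pre-extension path snapshot
    # and the (pz, po, pi) extension to apply on entry.
    st_node = np.empty(size, np.int64)
    st_len = np.empty(size, np.int64)
    st_pz = np.empty(size, np.float64)
    st_po = np.empty(size, np.float64)
    st_pi = np.empty(size, np.int64)
    fd = np.empty((size, size), np.int64)
    fz = np.empty((size, size), np.float64)
    fo = np.empty((size, size), np.float64)
    fw = np.empty((size, size), np.float64)
    # working path for the frame being processed
    pd_ = np.empty(size, np.int64)
    pz = np.empty(size, np.float64)
    po = np.empty(size, np.float64)
    pw = np.empty(size, np.float64)

    st_node[0] = 0
    st_len[0] = 0
    st_pz[0] = 1.0
    st_po[0] = 1.0
    st_pi[0] = -1
    top = 1
    while top > 0:
        top -= 1
        node = st_node[top]
        length = st_len[top]
        for i in range(length):
            pd_[i] = fd[top, i]
            pz[i] = fz[top, i]
            po[i] = fo[top, i]
            pw[i] = fw[top, i]
        # EXTEND with this frame's (pz, po, pi)
        epz = st_pz[top]
        epo = st_po[top]
        epi = st_pi[top]
        pd_[length] = epi
        pz[length] = epz
        po[length] = epo
        pw[length] = 1.0 if length == 0 else 0.0
        for i in range(length - 1, -1, -1):
            pw[i + 1] += epo * pw[i] * (i + 1) / (length + 1)
            pw[i] = epz * pw[i] * (length - i) / (length + 1)
        length += 1

        if children_left[node] < 0:  # leaf
            leaf = value[node]
            for i in range(1, length):
                w = _unwound_sum(pz, po, pw, length, i)
                phi[pd_[i]] += w * (po[i] - pz[i]) * leaf
            continue

        split = feature[node]
        if x[split] <= threshold[node]:
            hot, cold = children_left[node], children_right[node]
        else:
            hot, cold = children_right[node], children_left[node]
        iz = 1.0
        io = 1.0
        k = -1
        for i in range(1, length):
            if pd_[i] == split:
                k = i
                break
        if k >= 0:
            iz = pz[k]
            io = po[k]
            # UNWIND element k in place
            nxt = pw[length - 1]
            for j in range(length - 2, -1, -1):
                if io != 0.0:
                    tmp = pw[j]
                    pw[j] = nxt * length / ((j + 1) * io)
                    nxt = tmp - pw[j] * iz * (length - 1 - j) / length
                else:
                    pw[j] = pw[j] * length / (iz * (length - 1 - j))
            for j in range(k, length - 1):
                pd_[j] = pd_[j + 1]
                pz[j] = pz[j + 1]
                po[j] = po[j + 1]
            length -= 1

        r_node = cover[node]
        # push cold then hot (hot processed first; order is immaterial)
        for child, cpz, cpo in (
            (cold, iz * cover[cold] / r_node, 0.0),
            (hot, iz * cover[hot] / r_node, io),
        ):
            st_node[top] = child
            st_len[top] = length
            st_pz[top] = cpz
            st_po[top] = cpo
            st_pi[top] = split
            for i in range(length):
                fd[top, i] = pd_[i]
                fz[top, i] = pz[i]
                fo[top, i] = po[i]
                fw[top, i] = pw[i]
            top += 1


def tree_arrays(tree, class_index: int = 1):
    """Flatten an sklearn tree into the arrays the kernel consumes.

    For classifiers, node values become the ``class_index`` probability
    (cover-weighted class proportions); for regressors the raw node mean.
    """
    t = tree.tree_
    raw = t.value[:, 0, :]
    if raw.shape[1] > 1:
        totals = raw.sum(axis=1)
        value = raw[:, class_index] / np.where(totals == 0, 1.0, totals)
    else:
        value = raw[:, 0].astype(float)
    return (
        t.children_left.astype(np.int64),
        t.children_right.astype(np.int64),
        t.feature.astype(np.int64),
        t.threshold.astype(np.float64),
        t.weighted_n_node_samples.astype(np.float64),
        np.ascontiguousarray(value, dtype=np.float64),
        int(t.max_depth),
    )


def tree_expected_value(arrays) -> float:
    """Cover-weighted mean leaf value (the tree's base prediction)."""
    left, right, _, _, cover, value, _ = arrays
    leaves = left < 0
    return float((cover[leaves] * value[leaves]).sum() / cover[0])


def tree_shap_values(arrays, X: np.ndarray) -> np.ndarray:
    """Shapley values of one tree for each row of ``X`` (n_samples, n_feat)."""
    left, right, feature, threshold, cover, value, max_depth = arrays
    X = np.ascontiguousarray(X, dtype=np.float64)
    phi = np.zeros_like(X)
    for i in range(X.shape[0]):
        _tree_shap_one(left, right, feature, threshold, cover, value, X[i], phi[i], max_depth)
    return phi


def forest_shap_values(forest, X: np.ndarray, class_index: int = 1):
    """Mean per-tree Shapley values and base value for a fitted forest.

    Returns ``(phi, expected)`` with ``phi.shape == X.shape``;
    ``phi.sum(1) + expected`` reproduces ``predict_proba(X)[:, class_index]``.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    phi = np.zeros_like(X)
    expected = 0.0
    estimators = forest.estimators_
    for est in estimators:
        arrays = tree_arrays(est, class_index)
        phi += tree_shap_values(arrays, X)
        expected += tree_expected_value(arrays)
    n = len(estimators)
    return phi / n, expected / n
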