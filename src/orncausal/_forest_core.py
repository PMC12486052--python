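"""Numba kernels for regression and honest causal forests.

These kernels are deliberately free of Python objects: trees are stored in
flat preallocated arrays (`feature`, `threshold`, `left`, `right`, `value`)
so that thousands of small forests can be fitted inside threshold scans and
bootstrap loops.  All randomness is injected from the caller (subsample
index arrays and per-tree seeds), so results are bit-reproducible.

Conventions
-----------
* A split sends ``x <= threshold`` to the left child.
* Candidate cut points lie between consecutive distinct sorted values of
  the structure (split-selection) sample; the cut is the midpoint, demoted
  to the lower value if floating-point rounding would swallow the gap.
* ``feature[node] == -1`` marks a leaf; ``value[node]`` is its estimate.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LEAF = -1


# ---------------------------------------------------------------------------
# regression trees (used for OOB local centering of Y and T)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _grow_reg_tree(X, y, idx, n_idx, min_leaf, mtry, feature, threshold, left, right, value):
    """Grow one CART regression tree in place; returns the node count."""
    n_features = X.shape[1]
    feat_pool = np.arange(n_features)
    # stack of (start, end, node_id)
    max_nodes = feature.shape[0]
    stack_lo = np.empty(max_nodes, np.int64)
    stack_hi = np.empty(max_nodes, np.int64)
    stack_id = np.empty(max_nodes, np.int64)
    stack_lo[0] = 0
    stack_hi[0] = n_idx
    stack_id[0] = 0
    top = 1
    n_nodes = 1
    sv = np.empty(n_idx, np.float64)
    sy = np.empty(n_idx, np.float64)
    while top > 0:
        top -= 1
        lo = stack_lo[top]
        hi = stack_hi[top]
        node = stack_id[top]
        m = hi - lo
        tot = 0.0
        for k in range(lo, hi):
            tot += y[idx[k]]
        value[node] = tot / m
        feature[node] = LEAF
        if m < 2 * min_leaf or n_nodes + 2 > max_nodes:
            continue
        # choose features to try at this node
        if mtry < n_features:
            for k in range(mtry):
                j = k + np.random.randint(n_features - k)
                tmp = feat_pool[k]
                feat_pool[k] = feat_pool[j]
                feat_pool[j] = tmp
        best_score = -1.0
        best_feat = -1
        best_cut = 0.0
        n_try = mtry if mtry < n_features else n_features
        for fi in range(n_try):
            j = feat_pool[fi] if mtry < n_features else fi
            for k in range(m):
                sv[k] = X[idx[lo + k], j]
            order = np.argsort(sv[:m])
            # reorder values and targets
            prev = 0.0
            for k in range(m):
                sy[k] = y[idx[lo + order[k]]]
            # walk cuts
            s_left = 0.0
            for k in range(1, m):
                s_left += sy[k - 1]
                a = sv[order[k - 1]]
                b = sv[order[k]]
                if a >= b:
                    continue
                if k < min_leaf or m - k < min_leaf:
                    continue
                s_right = tot - s_left
                score = s_left * s_left / k + s_right * s_right / (m - k)
                if score > best_score + 1e-12 * abs(best_score):
                    cut = 0.5 * (a + b)
                    if not (a <= cut and cut < b):
                        cut = a
                    best_score = score
                    best_feat = j
                    best_cut = cut
        if best_feat < 0:
            continue
        # partition idx[lo:hi] around the cut
        i = lo
        k = hi - 1
        while i <= k:
            if X[idx[i], best_feat] <= best_cut:
                i += 1
            else:
                tmp = idx[i]
                idx[i] = idx[k]
                idx[k] = tmp
                k -= 1
        mid = i
        if mid == lo or mid == hi:
            continue
        feature[node] = best_feat
        threshold[node] = best_cut
        left[node] = n_nodes
        right[node] = n_nodes + 1
        stack_lo[top] = lo
        stack_hi[top] = mid
        stack_id[top] = n_nodes
        top += 1
        stack_lo[top] = mid
        stack_hi[top] = hi
        stack_id[top] = n_nodes + 1
        top += 1
        n_nodes += 2
    return n_nodes


@njit(cache=True)
def _tree_leaf_value(X, row, feature, threshold, left, right, value):
    node = 0
    while feature[node] != LEAF:
        if X[row, feature[node]] <= threshold[node]:
            node = left[node]
        else:
            node = right[node]
    return value[node]


@njit(cache=True)
def regression_forest_oob(X, y, sub_idx, min_leaf, mtry, tree_seeds):
    """Fit a subsampled regression forest, returning OOB prediction sums.

    sub_idx : (n_trees, s) int64 row indices sampled without replacement.
    Returns (oob_sum, oob_cnt) over the n training rows.
    """
    n = X.shape[0]
    n_trees, s = sub_idx.shape
    oob_sum = np.zeros(n, np.float64)
    oob_cnt = np.zeros(n, np.float64)
    max_nodes = 2 * s + 1
    feature = np.empty(max_nodes, np.int64)
    threshold = np.empty(max_nodes, np.float64)
    left = np.empty(max_nodes, np.int64)
    right = np.empty(max_nodes, np.int64)
    value = np.empty(max_nodes, np.float64)
    idx = np.empty(s, np.int64)
    inbag = np.zeros(n, np.uint8)
    for t in range(n_trees):
        np.random.seed(tree_seeds[t])
        for k in range(s):
            idx[k] = sub_idx[t, k]
            inbag[idx[k]] = 1
        _grow_reg_tree(X, y, idx, s, min_leaf, mtry, feature, threshold, left, right, value)
        for row in range(n):
            if inbag[row] == 0:
                oob_sum[row] += _tree_leaf_value(X, row, feature, threshold, left, right, value)
                oob_cnt[row] += 1.0
        for k in range(s):
            inbag[sub_idx[t, k]] = 0
    return oob_sum, oob_cnt


# ---------------------------------------------------------------------------
# honest causal trees
# ---------------------------------------------------------------------------


@njit(cache=True)
def _node_effect(yr, tr, tb, idx, lo, hi, use_rr):
    """Treatment-effect estimate on idx[lo:hi].

    use_rr: residual-on-residual ratio sum(yr*tr)/sum(tr^2) (local-centering
    mode); otherwise the difference in mean yr between arms of the binary
    treatment tb.
    """
    if use_rr:
        a = 0.0
        b = 0.0
        for k in range(lo, hi):
            i = idx[k]
            a += yr[i] * tr[i]
            b += tr[i] * tr[i]
        if b <= 0.0:
            return 0.0
        return a / b
    s1 = 0.0
    s0 = 0.0
    n1 = 0
    n0 = 0
    for k in range(lo, hi):
        i = idx[k]
        if tb[i] == 1:
            s1 += yr[i]
            n1 += 1
        else:
            s0 += yr[i]
            n0 += 1
    if n1 == 0 or n0 == 0:
        return 0.0
    return s1 / n1 - s0 / n0


@njit(cache=True)
def grow_causal_tree(X, yr, tr, tb, sidx, n_s, eidx, n_e, min_leaf, mtry, use_rr,
                     feature, threshold, left, right, value):
    """Grow one honest causal tree in place; returns the node count.

    Splits are chosen on the structure sample ``sidx`` by maximizing the
    size-weighted sum of squared child effects; a split is admissible only
    if every child keeps >= min_leaf treated and >= min_leaf control samples
    in BOTH the structure and the estimation sample.  Leaf values are
    computed from the estimation sample only (honesty).
    """
    n_features = X.shape[1]
    feat_pool = np.arange(n_features)
    max_nodes = feature.shape[0]
    st_slo = np.empty(max_nodes, np.int64)
    st_shi = np.empty(max_nodes, np.int64)
    st_elo = np.empty(max_nodes, np.int64)
    st_ehi = np.empty(max_nodes, np.int64)
    st_id = np.empty(max_nodes, np.int64)
    st_slo[0] = 0
    st_shi[0] = n_s
    st_elo[0] = 0
    st_ehi[0] = n_e
    st_id[0] = 0
    top = 1
    n_nodes = 1
    sv = np.empty(n_s, np.float64)
    sa = np.empty(n_s, np.float64)  # yr*tr   (rr mode) | yr if treated else 0
    sb = np.empty(n_s, np.float64)  # tr*tr   (rr mode) | yr if control else 0
    stt = np.empty(n_s, np.int64)   # treated flags, sorted
    ev = np.empty(n_e, np.float64)
    ett = np.empty(n_e, np.int64)
    while top > 0:
        top -= 1
        slo = st_slo[top]
        shi = st_shi[top]
        elo = st_elo[top]
        ehi = st_ehi[top]
        node = st_id[top]
        value[node] = _node_effect(yr, tr, tb, eidx, elo, ehi, use_rr)
        feature[node] = LEAF
        m = shi - slo
        me = ehi - elo
        if m < 2 * min_leaf or me < 2 * min_leaf or n_nodes + 2 > max_nodes:
            continue
        if mtry < n_features:
            for k in range(mtry):
                j = k + np.random.randint(n_features - k)
                tmp = feat_pool[k]
                feat_pool[k] = feat_pool[j]
                feat_pool[j] = tmp
        # totals on the structure segment
        tot_a = 0.0
        tot_b = 0.0
        tot_t = 0
        for k in range(slo, shi):
            i = sidx[k]
            if use_rr:
                tot_a += yr[i] * tr[i]
                tot_b += tr[i] * tr[i]
            else:
                if tb[i] == 1:
                    tot_a += yr[i]
                else:
                    tot_b += yr[i]
            tot_t += tb[i]
        # totals on the estimation segment
        etot_t = 0
        for k in range(elo, ehi):
            etot_t += tb[eidx[k]]
        best_score = -1.0
        best_feat = -1
        best_cut = 0.0
        n_try = mtry if mtry < n_features else n_features
        for fi in range(n_try):
            j = feat_pool[fi] if mtry < n_features else fi
            for k in range(m):
                i = sidx[slo + k]
                sv[k] = X[i, j]
            order = np.argsort(sv[:m])
            for k in range(m):
                i = sidx[slo + order[k]]
                if use_rr:
                    sa[k] = yr[i] * tr[i]
                    sb[k] = tr[i] * tr[i]
                else:
                    sa[k] = yr[i] if tb[i] == 1 else 0.0
                    sb[k] = yr[i] if tb[i] == 0 else 0.0
                stt[k] = tb[i]
            svs = sv[:m][order]
            for k in range(me):
                i = eidx[elo + k]
                ev[k] = X[i, j]
                ett[k] = tb[i]
            eorder = np.argsort(ev[:me])
            evs = ev[:me][eorder]
            etts = ett[:me][eorder]
            # walk candidate cuts in ascending order
            cl_a = 0.0
            cl_b = 0.0
            cl_t = 0
            q = 0
            el_t = 0
            for k in range(1, m):
                cl_a += sa[k - 1]
                cl_b += sb[k - 1]
                cl_t += stt[k - 1]
                a = svs[k - 1]
                b = svs[k]
                if a >= b:
                    continue
                cut = 0.5 * (a + b)
                if not (a <= cut and cut < b):
                    cut = a
                # structure-side arm counts
                nl = k
                nr = m - k
                nl_t = cl_t
                nl_c = nl - cl_t
                nr_t = tot_t - cl_t
                nr_c = (m - tot_t) - nl_c
                if nl_t < min_leaf or nl_c < min_leaf or nr_t < min_leaf or nr_c < min_leaf:
                    continue
                # estimation-side arm counts via pointer walk
                while q < me and evs[q] <= cut:
                    el_t += etts[q]
                    q += 1
                el = q
                er = me - q
                el_c = el - el_t
                er_t = etot_t - el_t
                er_c = er - er_t
                if el_t < min_leaf or el_c < min_leaf or er_t < min_leaf or er_c < min_leaf:
                    continue
                if use_rr:
                    if cl_b <= 0.0 or (tot_b - cl_b) <= 0.0:
                        continue
                    tau_l = cl_a / cl_b
                    tau_r = (tot_a - cl_a) / (tot_b - cl_b)
                else:
                    tau_l = cl_a / nl_t - cl_b / nl_c
                    tau_r = (tot_a - cl_a) / nr_t - (tot_b - cl_b) / nr_c
                score = nl * tau_l * tau_l + nr * tau_r * tau_r
                if score > best_score + 1e-12 * abs(best_score):
                    best_score = score
                    best_feat = j
                    best_cut = cut
        if best_feat < 0:
            continue
        # partition both halves around the chosen cut
        i = slo
        k = shi - 1
        while i <= k:
            if X[sidx[i], best_feat] <= best_cut:
                i += 1
            else:
                tmp = sidx[i]
                sidx[i] = sidx[k]
                sidx[k] = tmp
                k -= 1
        smid = i
        i = elo
        k = ehi - 1
        while i <= k:
            if X[eidx[i], best_feat] <= best_cut:
                i += 1
            else:
                tmp = eidx[i]
                eidx[i] = eidx[k]
                eidx[k] = tmp
                k -= 1
        emid = i
        feature[node] = best_feat
        threshold[node] = best_cut
        left[node] = n_nodes
        right[node] = n_nodes + 1
        st_slo[top] = slo
        st_shi[top] = smid
        st_elo[top] = elo
        st_ehi[top] = emid
        st_id[top] = n_nodes
        top += 1
        st_slo[top] = smid
        st_shi[top] = shi
        st_elo[top] = emid
        st_ehi[top] = ehi
        st_id[top] = n_nodes + 1
        top += 1
        n_nodes += 2
    return n_nodes


@njit(cache=True)
def fit_causal_forest(X, yr, tr, tb, sub_idx, n_structure, min_leaf, mtry, use_rr,
                      tree_seeds, feature, threshold, left, right, value):
    """Fit all trees of an honest causal forest.

    sub_idx : (n_trees, s) subsample row indices; the first ``n_structure``
    entries of each row form the structure half, the rest the estimation
    half.  Tree t is written to row t of the flat node arrays; returns the
    per-tree node counts.
    """
    n_trees, s = sub_idx.shape
    n_nodes = np.empty(n_trees, np.int64)
    sidx = np.empty(n_structure, np.int64)
    eidx = np.empty(s - n_structure, np.int64)
    for t in range(n_trees):
        np.random.seed(tree_seeds[t])
        for k in range(n_structure):
            sidx[k] = sub_idx[t, k]
        for k in range(s - n_structure):
            eidx[k] = sub_idx[t, n_structure + k]
        n_nodes[t] = grow_causal_tree(
            X, yr, tr, tb, sidx, n_structure, eidx, s - n_structure, min_leaf,
            mtry, use_rr, feature[t], threshold[t], left[t], right[t], value[t])
    return n_nodes


@njit(cache=True)
def forest_oob_cate(X, sub_idx, feature, threshold, left, right, value):
    """Per-sample OOB CATE sums: average leaf value over trees whose
    subsample excluded the sample.  Returns (oob_sum, oob_cnt)."""
    n = X.shape[0]
    n_trees, s = sub_idx.shape
    oob_sum = np.zeros(n, np.float64)
    oob_cnt = np.zeros(n, np.float64)
    inbag = np.zeros(n, np.uint8)
    for t in range(n_trees):
        for k in range(s):
            inbag[sub_idx[t, k]] = 1
        for row in range(n):
            if inbag[row] == 0:
                oob_sum[row] += _tree_leaf_value(X, row, feature[t], threshold[t],
                                                 left[t], right[t], value[t])
                oob_cnt[row] += 1.0
        for k in range(s):
            inbag[sub_idx[t, k]] = 0
    return oob_sum, oob_cnt


@njit(cache=True)
def forest_predict(X, feature, threshold, left, right, value):
    """Mean leaf value over all trees, for arbitrary query rows."""
    n = X.shape[0]
    n_trees = feature.shape[0]
    out = np.zeros(n, np.float64)
    for t in range(n_trees):
        for row in range(n):
            out[row] += _tree_leaf_value(X, row, feature[t], threshold[t],
                                         left[t], right[t], value[t])
    return out / n_trees
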