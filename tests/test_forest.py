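import numpy as np
import pytest

from orncausal import _forest_core as core
from orncausal.forest import CausalForest, ForestConfig, NoOOBTreeError


def _fit(X, T, Y, **kw):
    defaults = dict(n_trees=100, centering_trees=50, seed=0)
    defaults.update(kw)
    return CausalForest(ForestConfig(**defaults)).fit(X, T, Y)


# ---------------------------------------------------------------------------
# split mechanics against brute-force oracles
# ---------------------------------------------------------------------------


def _brute_force_root_split(X, y, tb, sidx, eidx, min_leaf):
    """Best (feature, cut) by exhaustive enumeration of the honest
    heterogeneity criterion in difference-in-means mode."""
    def effect(idx):
        t1 = [i for i in idx if tb[i] == 1]
        t0 = [i for i in idx if tb[i] == 0]
        return y[t1].mean() - y[t0].mean()

    best = (-1.0, None, None)
    for j in range(X.shape[1]):
        vals = sorted(set(X[sidx, j]))
        for a, b in zip(vals, vals[1:]):
            cut = (a + b) / 2
            if not (a <= cut < b):
                cut = a
            sl = [i for i in sidx if X[i, j] <= cut]
            sr = [i for i in sidx if X[i, j] > cut]
            el = [i for i in eidx if X[i, j] <= cut]
            er = [i for i in eidx if X[i, j] > cut]
            counts = [sum(tb[i] for i in part) for part in (sl, sr, el, er)]
            counts += [len(part) - c for part, c in zip((sl, sr, el, er), counts)]
            if min(counts) < min_leaf:
                continue
            score = len(sl) * effect(sl) ** 2 + len(sr) * effect(sr) ** 2
            if score > best[0] + 1e-12:
                best = (score, j, cut)
    return best


def _grow_one_tree(X, yr, tr, tb, sidx, eidx, min_leaf, use_rr=False):
    max_nodes = 2 * len(eidx) + 3
    feature = np.full(max_nodes, core.LEAF, np.int64)
    threshold = np.zeros(max_nodes)
    left = np.zeros(max_nodes, np.int64)
    right = np.zeros(max_nodes, np.int64)
    value = np.zeros(max_nodes)
    n = core.grow_causal_tree(X, yr, tr, tb, sidx.copy(), len(sidx),
                              eidx.copy(), len(eidx), min_leaf, X.shape[1],
                              use_rr, feature, threshold, left, right, value)
    return feature[:n], threshold[:n], left[:n], right[:n], value[:n]


class TestTreeGrowth:
    def test_root_split_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(2)
        for rep in range(5):
            n = 60
            X = rng.standard_normal((n, 3)).round(2)
            tb = rng.integers(0, 2, n).astype(np.int64)
            y = (rng.random(n) < 0.3 + 0.4 * tb * (X[:, 1] > 0)).astype(float)
            sidx = np.arange(0, n, 2)
            eidx = np.arange(1, n, 2)
            tr = (tb - tb.mean()).astype(float)
            f, thr, *_ = _grow_one_tree(X, y, tr, tb, sidx, eidx, min_leaf=3)
            score, j, cut = _brute_force_root_split(X, y, tb, sidx, eidx, 3)
            if j is None:
                assert f[0] == core.LEAF
            else:
                assert f[0] == j
                assert thr[0] == pytest.approx(cut)

    def test_eight_sample_fixture_split(self):
        # X < 0 has no effect, X > 0 has effect 1: the only sensible cut is 0
        X = np.array([[-2.0], [-1.5], [-1.0], [-0.5], [0.5], [1.0], [1.5], [2.0]])
        X = np.vstack([X, X])
        tb = np.array([0, 1] * 8, dtype=np.int64)
        y = np.where((X[:, 0] > 0) & (tb == 1), 1.0, 0.0)
        sidx = np.arange(8)
        eidx = np.arange(8, 16)
        f, thr, l, r, v = _grow_one_tree(X, y, (tb - 0.5).astype(float), tb,
                                         sidx, eidx, min_leaf=1)
        assert f[0] == 0
        score, j, cut = _brute_force_root_split(X, y, tb, sidx, eidx, 1)
        assert thr[0] == pytest.approx(cut)

    def test_honesty_estimation_outcomes_move_leaves_not_structure(self):
        rng = np.random.default_rng(5)
        n = 120
        X = rng.standard_normal((n, 4))
        tb = rng.integers(0, 2, n).astype(np.int64)
        y = (rng.random(n) < 0.3 + 0.3 * tb * (X[:, 0] > 0)).astype(float)
        sidx, eidx = np.arange(0, n, 2), np.arange(1, n, 2)
        tr = (tb - tb.mean()).astype(float)
        f1, t1, l1, r1, v1 = _grow_one_tree(X, y, tr, tb, sidx, eidx, 3)
        y2 = y.copy()
        y2[eidx] = rng.permutation(y[eidx])  # permute estimation outcomes only
        f2, t2, l2, r2, v2 = _grow_one_tree(X, y2, tr, tb, sidx, eidx, 3)
        assert np.array_equal(f1, f2) and np.array_equal(t1, t2)
        assert not np.allclose(v1, v2)

    def test_no_valid_split_yields_single_leaf(self):
        X = np.zeros((20, 2))
        tb = np.array([0, 1] * 10, dtype=np.int64)
        y = tb.astype(float)
        f, thr, l, r, v = _grow_one_tree(X, y, (tb - 0.5).astype(float), tb,
                                         np.arange(10), np.arange(10, 20), 2)
        assert len(f) == 1 and f[0] == core.LEAF
        assert v[0] == pytest.approx(1.0)  # honest diff-in-means on est half


# ---------------------------------------------------------------------------
# forest-level behaviour
# ---------------------------------------------------------------------------


class TestForest:
    def test_seed_determinism_to_the_last_bit(self, rct_arrays):
        X, T, Y = rct_arrays
        a = _fit(X, T, Y, n_trees=60).estimate_ate()
        b = _fit(X, T, Y, n_trees=60).estimate_ate()
        assert a.ate == b.ate and a.se == b.se

    def test_oob_tree_counts_follow_subsampling_rate(self, rct_arrays):
        X, T, Y = rct_arrays
        cf = _fit(X, T, Y, n_trees=200)
        counts = cf.oob_tree_counts()
        # each sample is OOB for Binomial(200, 0.5) trees
        assert counts.mean() == pytest.approx(100, abs=5)
        assert counts.min() >= 60

    def test_single_leaf_forest_oob_equals_manual_average(self, rct_arrays):
        X, T, Y = rct_arrays
        cf = _fit(X[:300], T[:300], Y[:300], n_trees=40, min_leaf=200)
        tree_vals = np.array([cf.tree_structure(t)[4][0] for t in range(40)])
        assert all(cf.tree_structure(t)[0][0] == core.LEAF for t in range(40))
        inbag = np.zeros((40, 300), bool)
        for t in range(40):
            inbag[t, cf._sub_idx[t]] = True
        for i in (0, 17, 299):
            expected = tree_vals[~inbag[:, i]].mean()
            assert cf.oob_cate(i) == pytest.approx(expected, rel=1e-12)

    def test_rct_recovers_tau_and_agrees_with_naive(self, rct_arrays):
        X, T, Y = rct_arrays
        est = _fit(X, T, Y, n_trees=200).estimate_ate()
        naive = Y[T == 1].mean() - Y[T == 0].mean()
        assert abs(est.ate - 0.25) < 2 * est.se
        assert abs(est.ate - naive) < 2 * est.se
        assert abs(est.ate) <= 1.0
        assert est.ci95[0] < est.ate < est.ci95[1]

    def test_null_treatment_is_covered(self):
        inside = 0
        for s in range(20):
            rng = np.random.default_rng(900 + s)
            n = 1000
            X = rng.standard_normal((n, 6))
            T = rng.integers(0, 2, n)
            Y = (rng.random(n) < 0.25 + 0.1 * (X[:, 0] > 0)).astype(float)
            est = _fit(X, T, Y, n_trees=50, centering_trees=40, seed=s).estimate_ate()
            inside += abs(est.ate) < 2 * est.se
        assert inside >= 16

    def test_mean_cate_estimator_close_to_aipw_in_rct(self, rct_arrays):
        X, T, Y = rct_arrays
        aipw = _fit(X, T, Y).estimate_ate()
        mc = CausalForest(ForestConfig(n_trees=100, centering_trees=50, seed=0,
                                       estimator="mean_cate")).fit(X, T, Y).estimate_ate()
        assert abs(aipw.ate - mc.ate) < 3 * aipw.se

    def test_empty_arm_rejected(self, rct_arrays):
        X, _, Y = rct_arrays
        with pytest.raises(ValueError):
            _fit(X, np.zeros(len(Y), int), Y)

    def test_no_oob_tree_raises_at_full_subsampling(self):
        rng = np.random.default_rng(1)
        n = 60
        X = rng.standard_normal((n, 2))
        T = rng.integers(0, 2, n)
        Y = rng.random(n).round()
        cf = CausalForest(ForestConfig(n_trees=5, subsample_fraction=1.0,
                                       centering_trees=20, seed=0)).fit(X, T, Y)
        with pytest.raises(NoOOBTreeError):
            cf.oob_cate(0)
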