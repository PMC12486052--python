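"""Honest causal forest for binary treatments and (binary) outcomes.

The estimand is the average treatment effect (ATE)

    ATE = E[Y(T=1) - Y(T=0)],

a risk difference when the outcome Y is a 0/1 event indicator.  The forest
follows the generalized-random-forest recipe in simplified form:

* each tree is grown on a subsample drawn *without* replacement;
* each subsample is split into a structure half (used to choose splits) and
  an estimation half (used to estimate leaf effects) — "honesty";
* splits maximize the size-weighted sum of squared child treatment-effect
  estimates, i.e. heterogeneity of the effect across children;
* Y and T are locally centered before tree growth by subtracting
  out-of-bag regression-forest estimates of m(x)=E[Y|X=x] and the
  propensity e(x)=E[T|X=x] (disable with ``center=False`` for ablation);
* per-sample CATEs are estimated out-of-bag (only trees whose subsample
  excluded the sample vote), and the ATE is the mean of doubly-robust AIPW
  scores built from the OOB CATE, e(x) and m(x), with an influence-function
  standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _forest_core as core

__all__ = ["ForestConfig", "ATEEstimate", "CausalForest", "NoOOBTreeError"]


class NoOOBTreeError(RuntimeError):
    """A sample appears in every tree's subsample, so it has no OOB vote."""


@dataclass(frozen=True)
class ForestConfig:
    """Hyperparameters of the honest causal forest.

    Defaults follow common GRF practice: 2000 trees, half-sampling without
    replacement, an even honesty split, and at least ``min_leaf`` treated
    and control estimation samples per leaf.
    """

    n_trees: int = 2000
    subsample_fraction: float = 0.5
    honesty_fraction: float = 0.5
    min_leaf: int = 5
    mtry: Optional[int] = None  # None -> all features at every split
    seed: int = 0
    center: bool = True
    centering_trees: int = 200
    estimator: str = "aipw"  # or "mean_cate"
    propensity_clip: float = 0.01

    def __post_init__(self):
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must be in (0, 1]")
        if not (0 < self.honesty_fraction < 1):
            raise ValueError("honesty_fraction must be in (0, 1)")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.estimator not in ("aipw", "mean_cate"):
            raise ValueError("estimator must be 'aipw' or 'mean_cate'")


@dataclass(frozen=True)
class ATEEstimate:
    """ATE (risk difference for a 0/1 outcome) with influence-function SE."""

    ate: float
    se: float
    ci95: tuple
    n_treated: int
    n_control: int
    positivity_warning: bool = False
    clipped_fraction: float = 0.0

    def __post_init__(self):
        lo, hi = self.ci95
        if not (lo <= self.ate <= hi):
            raise ValueError("ci95 must bracket the point estimate")


def _sub_seeds(seed: int, n: int) -> np.ndarray:
    """Counter-based per-tree seeds (< 2**31) from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n) % np.uint32(2**31)


class CausalForest:
    """Fit with :meth:`fit`; then :meth:`oob_cate` / :meth:`estimate_ate`."""

    def __init__(self, config: ForestConfig = ForestConfig()):
        self.config = config

    # -- fitting ----------------------------------------------------------

    def fit(self, X: np.ndarray, T: np.ndarray, Y: np.ndarray,
            m_hat: Optional[np.ndarray] = None,
            e_hat: Optional[np.ndarray] = None,
            feature_names: Optional[Sequence[str]] = None) -> "CausalForest":
        cfg = self.config
        X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
        T = np.asarray(T)
        Y = np.asarray(Y, dtype=np.float64)
        n, p = X.shape
        if T.shape != (n,) or Y.shape != (n,):
            raise ValueError("X, T, Y must have matching first dimension")
        tb = np.ascontiguousarray(T.astype(np.int8))
        if not np.isin(tb, (0, 1)).all():
            raise ValueError("treatment must be binary 0/1")
        if tb.sum() == 0 or tb.sum() == n:
            raise ValueError("treatment has an empty arm")
        self.feature_names_ = list(feature_names) if feature_names is not None else \
            [f"x{j}" for j in range(p)]

        ss = np.random.SeedSequence(cfg.seed)
        rng = np.random.default_rng(ss.spawn(1)[0])
        s = max(4, int(round(cfg.subsample_fraction * n)))
        s = min(s, n)
        h = int(round(cfg.honesty_fraction * s))
        h = min(max(h, 2), s - 2)
        sub_idx = np.empty((cfg.n_trees, s), np.int64)
        for t in range(cfg.n_trees):
            sub_idx[t] = rng.permutation(n)[:s]

        # local centering via OOB regression forests
        if m_hat is None:
            m_hat = (self._regression_oob(X, Y, cfg, cfg.seed + 101)
                     if cfg.center or cfg.estimator == "aipw" else np.zeros(n))
        if e_hat is None:
            e_hat = self._regression_oob(X, tb.astype(np.float64), cfg, cfg.seed + 202)
        m_hat = np.asarray(m_hat, dtype=np.float64)
        e_hat = np.asarray(e_hat, dtype=np.float64)
        eps = cfg.propensity_clip
        clipped = (e_hat < eps) | (e_hat > 1 - eps)
        self.clipped_fraction_ = float(clipped.mean())
        e_hat = np.clip(e_hat, eps, 1 - eps)

        if cfg.center:
            yr = Y - m_hat
            tr = tb - e_hat
            use_rr = True
        else:
            yr = Y.copy()
            tr = tb - tb.mean()
            use_rr = False

        mtry = cfg.mtry if cfg.mtry is not None else p
        mtry = min(mtry, p)
        leaves_cap = max(1, (s - h) // (2 * cfg.min_leaf)) + 1
        max_nodes = 2 * leaves_cap + 1
        self._feature = np.full((cfg.n_trees, max_nodes), core.LEAF, np.int64)
        self._threshold = np.zeros((cfg.n_trees, max_nodes), np.float64)
        self._left = np.zeros((cfg.n_trees, max_nodes), np.int64)
        self._right = np.zeros((cfg.n_trees, max_nodes), np.int64)
        self._value = np.zeros((cfg.n_trees, max_nodes), np.float64)
        tree_seeds = _sub_seeds(cfg.seed + 303, cfg.n_trees).astype(np.int64)
        self.n_nodes_ = core.fit_causal_forest(
            X, yr, tr, tb.astype(np.int64), sub_idx, h, cfg.min_leaf, mtry,
            use_rr, tree_seeds, self._feature, self._threshold, self._left,
            self._right, self._value)
        self._sub_idx = sub_idx
        self.X_ = X
        self.T_ = tb
        self.Y_ = Y
        self.m_hat_ = m_hat
        self.e_hat_ = e_hat
        self._oob = None
        return self

    @staticmethod
    def _regression_oob(X, y, cfg: ForestConfig, seed: int) -> np.ndarray:
        """OOB regression-forest prediction of E[y|X] on the training rows."""
        n = X.shape[0]
        n_trees = cfg.centering_trees
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        s = max(4, int(round(0.5 * n)))
        sub_idx = np.empty((n_trees, s), np.int64)
        for t in range(n_trees):
            sub_idx[t] = rng.permutation(n)[:s]
        mtry = max(1, int(np.ceil(np.sqrt(X.shape[1]))))
        tree_seeds = _sub_seeds(seed, n_trees).astype(np.int64)
        oob_sum, oob_cnt = core.regression_forest_oob(
            X, np.asarray(y, np.float64), sub_idx, 5, mtry, tree_seeds)
        out = np.where(oob_cnt > 0, oob_sum / np.maximum(oob_cnt, 1), y.mean())
        return out

    # -- inference --------------------------------------------------------

    def _oob_arrays(self):
        if self._oob is None:
            self._oob = core.forest_oob_cate(
                self.X_, self._sub_idx, self._feature, self._threshold,
                self._left, self._right, self._value)
        return self._oob

    def oob_cate(self, index: Optional[int] = None) -> np.ndarray:
        """OOB CATE for one training sample, or the full vector."""
        oob_sum, oob_cnt = self._oob_arrays()
        if index is not None:
            if oob_cnt[index] == 0:
                raise NoOOBTreeError(f"sample {index} is in every subsample")
            return oob_sum[index] / oob_cnt[index]
        if (oob_cnt == 0).any():
            bad = int(np.flatnonzero(oob_cnt == 0)[0])
            raise NoOOBTreeError(f"sample {bad} is in every subsample")
        return oob_sum / oob_cnt

    def oob_tree_counts(self) -> np.ndarray:
        return self._oob_arrays()[1].copy()

    def _cate_vector(self) -> np.ndarray:
        """OOB CATE, falling back to the all-trees prediction for the rare
        sample that landed in every subsample (possible at small tree
        counts); the strict no-fallback contract lives in oob_cate()."""
        oob_sum, oob_cnt = self._oob_arrays()
        if (oob_cnt == 0).any():
            out = np.where(oob_cnt > 0, oob_sum / np.maximum(oob_cnt, 1), 0.0)
            miss = oob_cnt == 0
            out[miss] = self.predict_cate(self.X_[miss])
            return out
        return oob_sum / oob_cnt

    def estimate_ate(self) -> ATEEstimate:
        cfg = self.config
        tau = self._cate_vector()
        n = tau.shape[0]
        t = self.T_.astype(np.float64)
        if cfg.estimator == "mean_cate":
            psi = tau
        else:
            e = self.e_hat_
            m = self.m_hat_
            resid = self.Y_ - m - (t - e) * tau
            psi = tau + (t - e) / (e * (1 - e)) * resid
        ate = float(psi.mean())
        se = float(psi.std(ddof=1) / np.sqrt(n))
        pos_warn = self.clipped_fraction_ > 0.05
        if pos_warn:
            warnings.warn(
                f"positivity: {self.clipped_fraction_:.1%} of propensity estimates "
                f"clipped to [{cfg.propensity_clip}, {1 - cfg.propensity_clip}]",
                RuntimeWarning, stacklevel=2)
        return ATEEstimate(
            ate=ate, se=se, ci95=(ate - 1.96 * se, ate + 1.96 * se),
            n_treated=int(self.T_.sum()), n_control=int(n - self.T_.sum()),
            positivity_warning=pos_warn, clipped_fraction=self.clipped_fraction_)

    def predict_cate(self, X: np.ndarray) -> np.ndarray:
        """CATE at new covariate rows (all trees vote)."""
        X = np.ascontiguousarray(np.asarray(X, np.float64))
        return core.forest_predict(X, self._feature, self._threshold,
                                   self._left, self._right, self._value)

    # -- diagnostics ------------------------------------------------------

    def tree_structure(self, t: int):
        """(feature, threshold, left, right, value) arrays of tree t."""
        k = self.n_nodes_[t]
        return (self._feature[t, :k].copy(), self._threshold[t, :k].copy(),
                self._left[t, :k].copy(), self._right[t, :k].copy(),
                self._value[t, :k].copy())

    def average_depth(self) -> float:
        depths = []
        for t in range(self.config.n_trees):
            f, _, l, r, _ = self.tree_structure(t)
            stack = [(0, 0)]
            leaf_depths = []
            while stack:
                node, d = stack.pop()
                if f[node] == core.LEAF:
                    leaf_depths.append(d)
                else:
                    stack.append((l[node], d + 1))
                    stack.append((r[node], d + 1))
            depths.append(np.mean(leaf_depths))
        return float(np.mean(depths))
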