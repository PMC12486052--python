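"""Critical dose-volume-constraint derivation by ATE-maximizing threshold
scans, with bootstrap confidence intervals and a randomized-dosimetry
robustness check.

For one dosimetric factor within one modality cohort, every candidate
threshold on a percentile grid (default 1st-99th percentile in 1-percentile
steps) binarizes the factor into a treatment, an honest causal forest with
the clinical covariates as features estimates the ATE on ORN, and the
most significant threshold (max z = ATE/SE by default, max raw ATE
optionally) is the critical constraint.  The percentile grid interpretation of "1% increments"
keeps both arms populated even for heavily skewed volumes; a raw-range grid
is available via ``grid_kind="range"``.

The bootstrap refits the *entire* scan on each patient resample so the CI
reflects threshold-selection variability, not just ATE noise at a fixed
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import CohortTable, DegenerateArmError, design_matrix
from .forest import CausalForest, ForestConfig

__all__ = ["DVCResult", "ScanError", "BootstrapError", "scan_thresholds",
           "derive_dvc", "bootstrap_dvc", "robustness_check"]


class ScanError(RuntimeError):
    """Fewer than two usable grid points in a threshold scan."""


class BootstrapError(RuntimeError):
    """Too many bootstrap replicates failed."""


@dataclass
class DVCResult:
    """Critical constraint for one dosimetric factor."""

    factor: str
    critical_value: float
    ate: float
    se: float
    ate_curve: pd.DataFrame
    ci95: Optional[Tuple[float, float]] = None
    n_boot: int = 0
    boot_values: Optional[np.ndarray] = None


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % np.uint32(2**31)


def _scan_arrays(X: np.ndarray, values: np.ndarray, Y: np.ndarray,
                 forest_config: ForestConfig, grid_step: float = 1.0,
                 grid_kind: str = "percentile", min_arm: int = 10,
                 m_hat: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Threshold scan on raw arrays (hot path for bootstrap replicates)."""
    values = np.asarray(values, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if values.min() == values.max():
        raise ScanError("factor is constant; cannot scan thresholds")
    pcts = np.arange(grid_step, 100.0, grid_step)
    if grid_kind == "percentile":
        thresholds = np.percentile(values, pcts)
    elif grid_kind == "range":
        thresholds = values.min() + (values.max() - values.min()) * pcts / 100.0
    else:
        raise ValueError("grid_kind must be 'percentile' or 'range'")
    # deduplicate grid points produced by tied values
    keep = np.concatenate([[True], np.diff(thresholds) > 0])
    thresholds, pcts = thresholds[keep], pcts[keep]
    seeds = _child_seeds(forest_config.seed, len(thresholds) + 1)
    if m_hat is None and (forest_config.center or forest_config.estimator == "aipw"):
        m_hat = CausalForest._regression_oob(
            np.ascontiguousarray(X, dtype=np.float64), Y, forest_config,
            int(seeds[-1]))
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for k, thr in enumerate(thresholds):
            T = (values > thr).astype(np.int8)
            n1 = int(T.sum())
            if n1 < min_arm or len(T) - n1 < min_arm:
                continue
            cf = CausalForest(replace(forest_config, seed=int(seeds[k])))
            cf.fit(X, T, Y, m_hat=m_hat)
            est = cf.estimate_ate()
            rows.append((float(thr), float(pcts[k]), est.ate, est.se,
                         est.n_treated, est.n_control))
    if len(rows) < 2:
        raise ScanError("fewer than 2 usable (non-degenerate) grid points")
    return pd.DataFrame(rows, columns=["threshold", "percentile", "ate", "se",
                                       "n_treated", "n_control"])


def scan_thresholds(table: CohortTable, factor: str,
                    forest_config: ForestConfig = ForestConfig(),
                    grid_step: float = 1.0, grid_kind: str = "percentile",
                    min_arm: int = 10) -> pd.DataFrame:
    """ATE(threshold) curve for one dosimetric factor of a cohort.

    Clinical covariates (one-hot, MISSING as its own level) are the forest
    features; thresholds leaving an arm below ``min_arm`` patients are
    skipped.  Returns a DataFrame (threshold, percentile, ate, se, ...)
    with strictly increasing thresholds.
    """
    X, _ = design_matrix(table)
    return _scan_arrays(X, table.factor_values(factor), table.outcome.astype(float),
                        forest_config, grid_step, grid_kind, min_arm)


def derive_dvc(ate_curve: pd.DataFrame, factor: str = "",
               rule: str = "max_z") -> DVCResult:
    """Critical value = the most significant grid threshold, maximizing
    z = ATE/SE (default) or the raw ATE point estimate (``rule="max_ate"``);
    ties break to the smallest threshold.  The z rule is the default because
    the raw argmax is drawn to high-variance near-edge thresholds where one
    arm is small."""
    if len(ate_curve) == 0:
        raise ScanError("empty ATE curve")
    curve = ate_curve.sort_values("threshold").reset_index(drop=True)
    if rule == "max_ate":
        objective = curve["ate"].to_numpy()
    elif rule == "max_z":
        objective = (curve["ate"] / curve["se"].replace(0, np.nan)).fillna(-np.inf).to_numpy()
    else:
        raise ValueError("rule must be 'max_ate' or 'max_z'")
    k = int(np.argmax(objective))  # first (= smallest threshold) on ties
    return DVCResult(factor=factor,
                     critical_value=float(curve.loc[k, "threshold"]),
                     ate=float(curve.loc[k, "ate"]), se=float(curve.loc[k, "se"]),
                     ate_curve=curve)


def bootstrap_dvc(table: CohortTable, factor: str, n_boot: int = 1000,
                  forest_config: ForestConfig = ForestConfig(),
                  grid_step: float = 1.0, grid_kind: str = "percentile",
                  min_arm: int = 10, rule: str = "max_z",
                  seed: Optional[int] = None,
                  max_failure_fraction: float = 0.1) -> DVCResult:
    """Critical value with a percentile-bootstrap 95% CI.

    Patients are resampled with replacement within the cohort and the whole
    scan+argmax is rerun per replicate; per-replicate seeds derive from the
    master seed, so a fixed master seed gives an identical CI.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    X, _ = design_matrix(table)
    values = table.factor_values(factor)
    Y = table.outcome.astype(float)
    point = derive_dvc(
        _scan_arrays(X, values, Y, forest_config, grid_step, grid_kind, min_arm),
        factor=factor, rule=rule)
    master = seed if seed is not None else forest_config.seed
    rep_seeds = _child_seeds(master + 7919, n_boot)
    rng = np.random.default_rng(np.random.SeedSequence(master + 104729))
    n = len(Y)
    crit = []
    failures = []
    for r in range(n_boot):
        rows = rng.integers(0, n, n)
        try:
            cfg_r = replace(forest_config, seed=int(rep_seeds[r]))
            curve = _scan_arrays(X[rows], values[rows], Y[rows], cfg_r,
                                 grid_step, grid_kind, min_arm)
            crit.append(derive_dvc(curve, factor=factor, rule=rule).critical_value)
        except (ScanError, ValueError) as exc:
            failures.append((r, str(exc)))
    if len(failures) > max_failure_fraction * n_boot:
        raise BootstrapError(
            f"{len(failures)}/{n_boot} bootstrap replicates failed: "
            f"{failures[:3]}...")
    boot = np.asarray(crit, dtype=float)
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    point.ci95 = ci
    point.n_boot = n_boot
    point.boot_values = boot
    return point


def robustness_check(table: CohortTable,
                     forest_config: ForestConfig = ForestConfig(),
                     n_boot: int = 0, seed: Optional[int] = None,
                     factors: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Null calibration: replace each dosimetric factor by iid Uniform(0,1)
    draws, binarize at the sample median, refit the forest, report the ATE.

    Since the synthetic "dose" is independent of everything, a trustworthy
    estimator must return ATEs near zero.  Returns a DataFrame (factor,
    ate, se, ci_lo, ci_hi, abs_ate); with ``n_boot`` > 0 the CI is a
    patient-resampling percentile bootstrap, otherwise a normal interval.
    """
    X, _ = design_matrix(table)
    Y = table.outcome.astype(float)
    n = len(Y)
    factors = list(factors if factors is not None else table.schema.dosimetric)
    master = seed if seed is not None else forest_config.seed
    fseeds = _child_seeds(master + 31337, 2 * len(factors) + 1)
    rng = np.random.default_rng(np.random.SeedSequence(master + 65537))
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for k, factor in enumerate(factors):
            u = rng.uniform(0.0, 1.0, n)
            T = (u > np.median(u)).astype(np.int8)
            if T.sum() in (0, n):
                raise DegenerateArmError(
                    f"median binarization of factor {factor!r} left one arm empty")
            cf = CausalForest(replace(forest_config, seed=int(fseeds[k])))
            cf.fit(X, T, Y)
            est = cf.estimate_ate()
            if n_boot > 0:
                bseeds = _child_seeds(int(fseeds[len(factors) + k]), n_boot)
                brng = np.random.default_rng(np.random.SeedSequence(int(fseeds[-1]) + k))
                boot = []
                for r in range(n_boot):
                    sel = brng.integers(0, n, n)
                    ub = u[sel]
                    Tb = (ub > np.median(ub)).astype(np.int8)
                    if Tb.sum() in (0, n):
                        continue
                    cfb = CausalForest(replace(forest_config, seed=int(bseeds[r])))
                    cfb.fit(X[sel], Tb, Y[sel])
                    boot.append(cfb.estimate_ate().ate)
                ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
            else:
                ci = est.ci95
            rows.append((factor, est.ate, est.se, ci[0], ci[1], abs(est.ate)))
    return pd.DataFrame(rows, columns=["factor", "ate", "se", "ci_lo", "ci_hi",
                                       "abs_ate"])
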