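"""Propensity-score estimation and 1:1 optimal matching of VMAT to PBSPT.

The propensity model is a plain maximum-likelihood logistic regression of
P(modality = PBSPT | clinical covariates) on the one-hot design matrix
(MISSING kept as its own level).  Matching is globally optimal 1:1
assignment minimizing the total pairwise distance on the logit propensity
scale, solved as a rectangular min-cost assignment problem — not greedy
nearest-neighbour.  Between-group balance is reported with chi-square tests
for categorical factors and a two-sided Welch t-test for age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import linear_sum_assignment
from scipy.special import logit
from scipy.stats import chi2_contingency, ttest_ind

from .cohort import CohortTable

__all__ = ["SeparationError", "MatchedCohort", "estimate_propensity",
           "optimal_match", "balance_tests", "match_cohort"]


class SeparationError(RuntimeError):
    """A covariate (combination) perfectly predicts the modality."""


@dataclass
class MatchedCohort:
    """1:1 matched VMAT/PBSPT pairs with scores and balance diagnostics."""

    pairs: List[Tuple[str, str]]          # (VMAT patient_id, PBSPT patient_id)
    propensity: pd.Series                 # indexed by patient_id
    balance_before: Optional[pd.DataFrame] = None
    balance_after: Optional[pd.DataFrame] = None

    @property
    def matched_ids(self) -> List[str]:
        return [pid for pair in self.pairs for pid in pair]

    def pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["vmat_id", "pbspt_id"])


def _propensity_design(table: CohortTable):
    from .cohort import design_matrix
    # drop_first avoids the dummy trap in the unpenalized ML fit
    X, names = design_matrix(table, drop_first=True)
    return X, names


def estimate_propensity(table: CohortTable, ridge: float = 1e-6) -> pd.Series:
    """Per-patient P(modality = PBSPT | covariates), in (0, 1).

    Unpenalized ML logistic fit; if the fit fails to converge or produces
    non-finite/diverging coefficients (near-separation), a small-ridge
    refit (lambda = ``ridge``) is used instead.  A single covariate level
    that perfectly predicts modality raises :class:`SeparationError`
    naming the covariate.
    """
    y = (table.modality == "PBSPT").to_numpy(float)
    if y.min() == y.max():
        raise ValueError("cohort contains a single modality")
    # explicit separation diagnostic, per covariate level
    s = table.schema
    for cov in s.categorical_covariates:
        col = table.df[cov].astype(str)
        if col.nunique() < 2:
            continue
        constant_within_level = all(
            np.ptp(y[(col == level).to_numpy()]) == 0 for level in col.unique())
        if constant_within_level:
            raise SeparationError(
                f"covariate {cov!r} perfectly predicts modality")
    X, names = _propensity_design(table)
    Xc = sm.add_constant(X, has_constant="add")
    scores = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            params = res.params
            if np.isfinite(params).all() and np.abs(params).max() < 30:
                scores = res.predict(Xc)
        except Exception:
            scores = None
    if scores is None:
        # ridge fallback for (near-)separation
        beta = _ridge_logistic(Xc, y, ridge)
        scores = 1.0 / (1.0 + np.exp(-(Xc @ beta)))
    eps = 1e-12
    scores = np.clip(scores, eps, 1 - eps)
    return pd.Series(scores, index=table.df[s.patient_id].to_numpy(), name="propensity")


def _ridge_logistic(X, y, lam, n_iter=100):
    """Newton iterations for an L2-penalized logistic fit (intercept included)."""
    beta = np.zeros(X.shape[1])
    pen = lam * np.eye(X.shape[1])
    pen[0, 0] = 0.0
    for _ in range(n_iter):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        W = p * (1 - p)
        g = X.T @ (y - p) - pen @ beta
        H = (X.T * W) @ X + pen + 1e-10 * np.eye(X.shape[1])
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    return beta


def optimal_match(scores: pd.Series, groups: pd.Series,
                  distance: str = "logit") -> MatchedCohort:
    """Globally optimal 1:1 match of VMAT to PBSPT on the propensity score.

    Minimizes the total absolute score difference over all one-to-one
    assignments (rectangular min-cost assignment); ``distance`` is
    ``"logit"`` (default, common PSM practice) or ``"raw"``.  Each patient
    is matched at most once; pair count = min(group sizes).
    """
    groups = groups.reindex(scores.index) if groups.index.equals(scores.index) \
        else pd.Series(np.asarray(groups), index=scores.index)
    vmat_ids = scores.index[(groups == "VMAT").to_numpy()]
    pbspt_ids = scores.index[(groups == "PBSPT").to_numpy()]
    if len(vmat_ids) == 0 or len(pbspt_ids) == 0:
        raise ValueError("both modality groups must be non-empty")
    sv = scores.loc[vmat_ids].to_numpy(float)
    sp = scores.loc[pbspt_ids].to_numpy(float)
    if distance == "logit":
        sv, sp = logit(sv), logit(sp)
    elif distance != "raw":
        raise ValueError("distance must be 'logit' or 'raw'")
    cost = np.abs(sv[:, None] - sp[None, :])
    row, col = linear_sum_assignment(cost)
    order = np.argsort(row)
    pairs = [(str(vmat_ids[i]), str(pbspt_ids[j]))
             for i, j in zip(row[order], col[order])]
    return MatchedCohort(pairs=pairs, propensity=scores)


def balance_tests(table: CohortTable, subset_ids: Optional[List[str]] = None) -> pd.DataFrame:
    """Per-covariate between-modality tests (chi-square / Welch t for age).

    Returns a DataFrame with columns covariate, test, statistic, p_value.
    A covariate with a single observed level gets p = 1 with a warning.
    """
    s = table.schema
    df = table.df
    if subset_ids is not None:
        df = df[df[s.patient_id].isin(set(subset_ids))]
    g = df[s.modality]
    if g.nunique() < 2:
        raise ValueError("subset must contain both modality groups")
    rows = []
    for cov in s.continuous_covariates:
        a = df.loc[g == "VMAT", cov].to_numpy(float)
        b = df.loc[g == "PBSPT", cov].to_numpy(float)
        if np.std(a) == 0 and np.std(b) == 0 and np.mean(a) == np.mean(b):
            stat, p = 0.0, 1.0
        else:
            stat, p = ttest_ind(a, b, equal_var=False)
        rows.append((cov, "t", float(stat), float(p)))
    for cov in s.categorical_covariates:
        ct = pd.crosstab(df[cov].astype(str), g)
        if ct.shape[0] < 2:
            warnings.warn(f"covariate {cov!r} has a single level; p set to 1",
                          stacklevel=2)
            rows.append((cov, "chi2", 0.0, 1.0))
            continue
        stat, p, _, _ = chi2_contingency(ct.to_numpy(), correction=False)
        rows.append((cov, "chi2", float(stat), float(p)))
    return pd.DataFrame(rows, columns=["covariate", "test", "statistic", "p_value"])


def match_cohort(table: CohortTable, distance: str = "logit",
                 ridge: float = 1e-6) -> MatchedCohort:
    """Full matching stage: propensity fit, optimal 1:1 match, balance
    tests before and after (mirroring a before/after p-value table)."""
    scores = estimate_propensity(table, ridge=ridge)
    matched = optimal_match(scores, table.modality.set_axis(scores.index))
    matched.balance_before = balance_tests(table)
    matched.balance_after = balance_tests(table, subset_ids=matched.matched_ids)
    return matched
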