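"""Within-group confounding diagnostic: worst-case standardized mean
differences (SMD) of clinical factors across dose-quartile strata.

For one clinical factor and one dosimetric factor, the (single-modality)
cohort is stratified into four subgroups by sample quartiles of the
dosimetric factor (low, mid-low, mid-high, high).  The SMD between strata
i and j is

    SMD_ij = |mu_i - mu_j| / sqrt((s_i^2 + s_j^2) / 2)

and the reported statistic is the worst case, SMD_max = max_{i!=j} SMD_ij.
Interpretation thresholds: < 0.2 well-balanced, [0.2, 0.8) moderately
biased, >= 0.8 highly biased.  Categorical factors are expanded into
per-level indicators and the cell value is the maximum over levels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = ["pairwise_smd", "quartile_strata", "smd_max", "smd_report",
           "SMDMatrix", "StratificationError", "classify_smd"]

BALANCED, MODERATE, HIGH, DEGENERATE = "balanced", "moderate", "high", "degenerate"


class StratificationError(ValueError):
    """The dosimetric factor cannot be split into quartile strata."""


def pairwise_smd(values_i: np.ndarray, values_j: np.ndarray) -> float:
    """|mean difference| / pooled SD between two samples.

    Returns 0 when both samples are constant and equal, and +inf when the
    pooled SD is zero but the means differ (degenerate cell).
    """
    a = np.asarray(values_i, dtype=float)
    b = np.asarray(values_j, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    va = a.var(ddof=1) if a.size > 1 else 0.0
    vb = b.var(ddof=1) if b.size > 1 else 0.0
    pooled = math.sqrt((va + vb) / 2.0)
    diff = abs(float(a.mean() - b.mean()))
    if pooled == 0.0:
        return 0.0 if diff == 0.0 else math.inf
    return diff / pooled


def quartile_strata(values: np.ndarray) -> np.ndarray:
    """Stratum labels 0..3 by sample quartiles, ties going to the lower
    stratum (deterministic under heavily tied values, e.g. many zero V70)."""
    v = np.asarray(values, dtype=float)
    if v.size < 8:
        raise StratificationError("need >= 8 records for quartile strata")
    if v.min() == v.max():
        raise StratificationError("dosimetric factor is constant")
    qs = np.quantile(v, [0.25, 0.5, 0.75])
    return np.searchsorted(qs, v, side="left").astype(np.int8)


def _factor_columns(df: pd.DataFrame, clinical: str) -> List[np.ndarray]:
    col = df[clinical]
    if pd.api.types.is_numeric_dtype(col):
        return [col.to_numpy(float)]
    levels = sorted(col.astype(str).unique())
    return [(col.astype(str) == lev).to_numpy(float) for lev in levels]


def smd_max(table: CohortTable, clinical: str, dosimetric: str) -> float:
    """Worst-case SMD of ``clinical`` across quartile strata of ``dosimetric``.

    Maximum over all 6 stratum pairs (and over levels for categorical
    factors); +inf marks a degenerate zero-variance/unequal-mean cell.
    Strata left empty by heavy ties are skipped.
    """
    strata = quartile_strata(table.factor_values(dosimetric))
    columns = _factor_columns(table.df, clinical)
    worst = 0.0
    present = [k for k in range(4) if (strata == k).sum() > 0]
    for x in columns:
        for i, j in itertools.combinations(present, 2):
            worst = max(worst, pairwise_smd(x[strata == i], x[strata == j]))
    return worst


@dataclass
class SMDMatrix:
    """SMD_max per clinical (rows) x dosimetric (cols) cell, with flags."""

    values: pd.DataFrame
    flags: pd.DataFrame

    def to_csv(self, path) -> None:
        self.values.to_csv(path)


def classify_smd(v: float) -> str:
    if math.isinf(v) or math.isnan(v):
        return DEGENERATE
    if v < 0.2:
        return BALANCED
    if v < 0.8:
        return MODERATE
    return HIGH


def smd_report(table: CohortTable, group: Optional[str] = None,
               clinical: Optional[Sequence[str]] = None,
               dosimetric: Optional[Sequence[str]] = None) -> SMDMatrix:
    """Full SMD_max matrix over clinical x dosimetric factors for one
    modality group (or the whole table when ``group`` is None)."""
    t = table.modality_subset(group) if group is not None else table
    if len(t) == 0:
        raise ValueError("group is empty")
    clinical = list(clinical if clinical is not None else t.schema.covariates)
    dosimetric = list(dosimetric if dosimetric is not None else t.schema.dosimetric)
    values = pd.DataFrame(index=clinical, columns=dosimetric, dtype=float)
    flags = pd.DataFrame(index=clinical, columns=dosimetric, dtype=object)
    for c in clinical:
        for d in dosimetric:
            v = smd_max(t, c, d)
            values.loc[c, d] = v
            flags.loc[c, d] = classify_smd(v)
    return SMDMatrix(values=values, flags=flags)


def plot_smd_heatmap(matrix: SMDMatrix, ax=None, title: str = ""):
    """Three-band heatmap (balanced / moderate / high) of the SMD matrix."""
    import matplotlib
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    vals = matrix.values.to_numpy(float)
    capped = np.where(np.isfinite(vals), vals, 2.0)
    cmap = ListedColormap(["#c6dbef", "#ffe08a", "#fdae6b"])
    norm = BoundaryNorm([0.0, 0.2, 0.8, max(2.0, np.nanmax(capped) + 0.1)], cmap.N)
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * vals.shape[1] + 2, 0.5 * vals.shape[0] + 2))
    im = ax.imshow(capped, cmap=cmap, norm=norm, aspect="auto")
    ax.set_xticks(range(vals.shape[1]), matrix.values.columns, rotation=45, ha="right")
    ax.set_yticks(range(vals.shape[0]), matrix.values.index)
    for i in range(vals.shape[0]):
        for j in range(vals.shape[1]):
            label = "inf" if not np.isfinite(vals[i, j]) else f"{vals[i, j]:.2f}"
            ax.text(j, i, label, ha="center", va="center", fontsize=8)
    if title:
        ax.set_title(title)
    return ax
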