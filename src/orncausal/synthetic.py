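"""Seeded synthetic head-and-neck cohorts with known causal structure.

Real mandible-ORN registries are not public, so every downstream stage is
exercised on generated cohorts that reproduce the statistical structure the
analysis assumes:

* clinical covariate marginals matching a typical H&N chemoradiotherapy
  cohort (median age ~62, ~74% male, stage IV most common, ORN prevalence
  a few percent), with an explicit MISSING category;
* confounded treatment-modality assignment (covariates tilt the odds of
  proton vs photon therapy);
* modality-dependent mandible dosimetry driven by a latent per-patient
  "dose burden" that is itself covariate-confounded, with VxGy monotone in
  the dose level by construction;
* an ORN outcome with a configurable true threshold v* on one dosimetric
  factor and a known effect size, so the estimand the causal forest targets
  is available exactly (or to Monte-Carlo precision) via
  :func:`ground_truth_ate`.

Coefficient dictionaries are keyed ``"covariate:level"`` (e.g.
``"diabetes:yes"``) or ``"age"`` (per standard deviation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit
from scipy.stats import norm

from .cohort import MISSING, CohortSchema, CohortTable

__all__ = ["SimConfig", "generate", "ground_truth_ate"]


DEFAULT_MARGINALS: Dict[str, Dict[str, float]] = {
    "tumor_stage": {"I": 0.103, "II": 0.119, "III": 0.144, "IV": 0.528, "X": 0.106},
    "gender": {"male": 0.742, "female": 0.258},
    "chemo": {"yes": 0.580, "no": 0.420},
    "smoking_history": {"yes": 0.521, "no": 0.479},
    "current_smoker": {"yes": 0.107, "no": 0.893},
    "hypertension": {"yes": 0.502, "no": 0.498},
    "diabetes": {"yes": 0.143, "no": 0.857},
    "dental_extraction": {"yes": 0.163, "no": 0.837},
}

# modality tilt (positive -> more likely proton), mirroring the pre-matching
# imbalances a proton-referral pattern produces
DEFAULT_MODALITY_COEF = {
    "tumor_stage:X": 0.9, "smoking_history:yes": -0.7, "current_smoker:yes": -0.8,
    "hypertension:yes": -0.5, "chemo:yes": -0.4, "diabetes:yes": -0.2,
    "dental_extraction:yes": 0.3,
}
# covariate -> latent dose-burden shift (units of burden SD)
DEFAULT_DOSE_COEF = {
    "tumor_stage:IV": 0.6, "chemo:yes": 0.4, "dental_extraction:yes": 0.3,
    "diabetes:yes": 0.3, "smoking_history:yes": 0.2,
}
# covariate -> ORN log-odds
DEFAULT_OUTCOME_COEF = {
    "smoking_history:yes": 0.5, "current_smoker:yes": 0.4, "diabetes:yes": 0.4,
    "dental_extraction:yes": 0.6, "chemo:yes": 0.3, "age": 0.2,
}

# per-modality dosimetric means/SDs: VxGy in cc, Dmax/Dmean in cGy, loosely
# centred so that derived critical values land in a clinically plausible
# range (photon volumes larger than proton at every dose level)
DEFAULT_DOSE_MODEL = {
    "VMAT": {"V40Gy": (85.0, 25.0), "V50Gy": (70.0, 22.0), "V60Gy": (50.0, 18.0),
             "V70Gy": (12.0, 8.0), "Dmax": (7200.0, 500.0), "Dmean": (6000.0, 700.0)},
    "PBSPT": {"V40Gy": (40.0, 18.0), "V50Gy": (32.0, 15.0), "V60Gy": (16.0, 10.0),
              "V70Gy": (5.0, 4.0), "Dmax": (6800.0, 700.0), "Dmean": (3500.0, 900.0)},
}


class ConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults emulate the matched study cohort
    (335 patients per modality, ORN prevalence ~3%)."""

    n_per_modality: int = 335
    n_vmat: Optional[int] = None          # override arm sizes, e.g. the
    n_pbspt: Optional[int] = None         # 931/335 pre-matching imbalance
    seed: int = 0
    covariate_marginals: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINALS.items()})
    age_mean: float = 62.0
    age_sd: float = 13.0
    missing_rate: float = 0.03
    confounding_strength: float = 1.0     # scales covariate -> modality tilt
    dose_confounding: float = 1.0         # scales covariate -> dose burden
    modality_coef: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MODALITY_COEF))
    dose_coef: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DOSE_COEF))
    dose_model: Dict[str, Dict[str, Tuple[float, float]]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_DOSE_MODEL.items()})
    dose_correlation: float = 0.6         # factor loading on the latent burden
    outcome_kind: str = "logistic"        # or "linear" (risk-difference scale)
    base_rate: float = 0.0066             # intercept risk; marginal ORN ~3%
    outcome_coef: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_COEF))
    threshold_factor: str = "V50Gy"
    v_star: float = 50.0
    effect: float = 1.2                   # log-odds (logistic) or risk diff (linear)

    def __post_init__(self):
        for cov, probs in self.covariate_marginals.items():
            p = np.array(list(probs.values()), dtype=float)
            if (p < 0).any() or (p > 1).any() or not math.isclose(p.sum(), 1.0, abs_tol=1e-6):
                raise ConfigError(f"marginals of {cov!r} must be in [0,1] and sum to 1")
        for mod, factors in self.dose_model.items():
            for f, (mu, sd) in factors.items():
                if sd <= 0:
                    raise ConfigError(f"dose_model[{mod}][{f}] has non-positive SD")
        if not (0 <= self.dose_correlation < 1):
            raise ConfigError("dose_correlation must be in [0, 1)")
        if self.outcome_kind not in ("logistic", "linear"):
            raise ConfigError("outcome_kind must be 'logistic' or 'linear'")
        if not (0 < self.base_rate < 1):
            raise ConfigError("base_rate must be in (0, 1)")
        if self.outcome_kind == "linear" and abs(self.effect) > 1:
            raise ConfigError("linear-model effect is a risk difference in [-1, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**cfg)


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _coef_score(df: pd.DataFrame, coef: Dict[str, float], age_mean: float,
                age_sd: float) -> np.ndarray:
    score = np.zeros(len(df))
    for key, beta in coef.items():
        if key == "age":
            score += beta * (df["age"].to_numpy(float) - age_mean) / age_sd
        else:
            cov, level = key.split(":", 1)
            score += beta * (df[cov].astype(str) == level).to_numpy(float)
    return score


def _draw_covariates(cfg: SimConfig, rng: np.random.Generator, n: int) -> pd.DataFrame:
    data = {"age": np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 18, 95).round(1)}
    for cov, probs in cfg.covariate_marginals.items():
        levels = list(probs.keys())
        p = np.array([probs[l] for l in levels], dtype=float)
        p = p / p.sum()
        data[cov] = rng.choice(levels, size=n, p=p)
    df = pd.DataFrame(data)
    if cfg.missing_rate > 0:
        for cov in cfg.covariate_marginals:
            mask = rng.random(n) < cfg.missing_rate
            df.loc[mask, cov] = MISSING
    return df


def _event_probability(cfg: SimConfig, cov_score: np.ndarray,
                       above: np.ndarray) -> np.ndarray:
    """P(ORN=1) given the covariate outcome score and the v* indicator."""
    if cfg.outcome_kind == "logistic":
        eta = logit(cfg.base_rate) + cov_score + cfg.effect * above
        return expit(eta)
    return np.clip(cfg.base_rate + cov_score + cfg.effect * above, 0.0, 1.0)


def generate(config: SimConfig) -> CohortTable:
    """Generate a cohort with ``n_per_modality`` patients per modality.

    Identical seed -> byte-identical table.  Covariates are drawn first,
    modality is assigned by a confounded logistic model (rejection-filled
    until both arms reach their quota), dosimetry follows a latent-burden
    factor model with VxGy sorted to enforce monotonicity, and the ORN
    outcome follows the configured threshold model.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    quota = {"VMAT": cfg.n_vmat if cfg.n_vmat is not None else cfg.n_per_modality,
             "PBSPT": cfg.n_pbspt if cfg.n_pbspt is not None else cfg.n_per_modality}
    frames = {"VMAT": [], "PBSPT": []}
    got = {"VMAT": 0, "PBSPT": 0}
    guard = 0
    while got["VMAT"] < quota["VMAT"] or got["PBSPT"] < quota["PBSPT"]:
        guard += 1
        if guard > 200:
            raise ConfigError("modality assignment failed to fill both arms")
        pool = _draw_covariates(cfg, rng, max(4 * max(quota.values()), 64))
        score = cfg.confounding_strength * _coef_score(
            pool, cfg.modality_coef, cfg.age_mean, cfg.age_sd)
        p_proton = expit(score - score.mean())
        is_proton = rng.random(len(pool)) < p_proton
        for mod, mask in (("PBSPT", is_proton), ("VMAT", ~is_proton)):
            need = quota[mod] - got[mod]
            if need > 0:
                take = pool[mask].head(need)
                frames[mod].append(take)
                got[mod] += len(take)
    df = pd.concat(
        [pd.concat(frames["VMAT"]), pd.concat(frames["PBSPT"])],
        ignore_index=True)
    modality = np.array(["VMAT"] * quota["VMAT"] + ["PBSPT"] * quota["PBSPT"])
    df.insert(0, "modality", modality)
    df.insert(0, "patient_id", [f"P{i:05d}" for i in range(len(df))])

    # dosimetry: latent burden + factor-specific noise, sorted for monotonicity
    dose_score = cfg.dose_confounding * _coef_score(
        df, cfg.dose_coef, cfg.age_mean, cfg.age_sd)
    burden = dose_score + rng.standard_normal(len(df))
    sd_b = burden.std()
    burden = (burden - burden.mean()) / (sd_b if sd_b > 0 else 1.0)
    rho = cfg.dose_correlation
    factors = list(cfg.dose_model["VMAT"].keys())
    vals = {}
    for f in factors:
        noise = rng.standard_normal(len(df))
        z = rho * burden + math.sqrt(1 - rho * rho) * noise
        mu = np.where(modality == "PBSPT",
                      cfg.dose_model["PBSPT"][f][0], cfg.dose_model["VMAT"][f][0])
        sd = np.where(modality == "PBSPT",
                      cfg.dose_model["PBSPT"][f][1], cfg.dose_model["VMAT"][f][1])
        vals[f] = np.maximum(mu + sd * z, 0.0)
    vcols = [f for f in factors if f.startswith("V")]
    if vcols:
        vmat = np.sort(np.column_stack([vals[f] for f in vcols]), axis=1)[:, ::-1]
        for k, f in enumerate(vcols):
            vals[f] = vmat[:, k]
    if "Dmax" in vals and "Dmean" in vals:
        dpair = np.sort(np.column_stack([vals["Dmax"], vals["Dmean"]]), axis=1)
        vals["Dmax"], vals["Dmean"] = dpair[:, 1], dpair[:, 0]
    for f in factors:
        df[f] = np.round(vals[f], 4)

    cov_score = _coef_score(df, cfg.outcome_coef, cfg.age_mean, cfg.age_sd)
    above = (df[cfg.threshold_factor].to_numpy(float) > cfg.v_star).astype(float)
    p = _event_probability(cfg, cov_score, above)
    df["orn"] = (rng.random(len(df)) < p).astype(np.int8)

    schema = CohortSchema(covariates=["age"] + list(cfg.covariate_marginals),
                          dosimetric=factors)
    return CohortTable(df, schema)


def ground_truth_ate(config: SimConfig, factor: str, threshold: float,
                     n_mc: int = 200_000, seed: int = 12345):
    """True population ATE of binarizing ``factor`` at ``threshold``.

    The intervention "T=1" forces the factor above the threshold (drawing it
    from its patient-specific conditional distribution given exceedance),
    "T=0" forces it below; the outcome depends on the factor only through
    the true-threshold indicator 1[factor > v*], whose conditional
    probability under each arm is available in closed form for the normal
    factor model (zero-clipping of volumes is ignored here, which is exact
    whenever v* and the threshold are positive).

    Returns (ate, mc_standard_error).
    """
    cfg = config
    if factor not in cfg.dose_model["VMAT"]:
        raise KeyError(f"unknown factor {factor!r}")
    rng = np.random.default_rng(seed)
    df = _draw_covariates(cfg, rng, n_mc)
    modality = np.where(rng.random(n_mc) < 0.5, "PBSPT", "VMAT")
    dose_score = cfg.dose_confounding * _coef_score(
        df, cfg.dose_coef, cfg.age_mean, cfg.age_sd)
    burden = dose_score + rng.standard_normal(n_mc)
    sd_b = burden.std()
    burden = (burden - burden.mean()) / (sd_b if sd_b > 0 else 1.0)
    rho = cfg.dose_correlation
    cov_score = _coef_score(df, cfg.outcome_coef, cfg.age_mean, cfg.age_sd)

    if factor != cfg.threshold_factor:
        # the outcome does not depend on this factor: ATE is exactly 0
        return 0.0, 0.0

    mu = np.where(modality == "PBSPT",
                  cfg.dose_model["PBSPT"][factor][0], cfg.dose_model["VMAT"][factor][0])
    sd = np.where(modality == "PBSPT",
                  cfg.dose_model["PBSPT"][factor][1], cfg.dose_model["VMAT"][factor][1])
    cmu = mu + sd * rho * burden
    csd = sd * math.sqrt(1 - rho * rho)
    # P(factor > v* | factor > t) and P(factor > v* | factor <= t), per patient
    tail = lambda x: norm.sf((x - cmu) / csd)
    t_hi = max(threshold, cfg.v_star)
    p_above = tail(threshold)
    p_below = 1.0 - p_above
    with np.errstate(divide="ignore", invalid="ignore"):
        p_star_arm1 = np.where(p_above > 0, tail(t_hi) / np.maximum(p_above, 1e-300), 1.0)
        if cfg.v_star <= threshold:
            p_star_arm0 = np.where(
                p_below > 0,
                (norm.sf((cfg.v_star - cmu) / csd) - p_above) / np.maximum(p_below, 1e-300),
                0.0)
        else:
            p_star_arm0 = np.zeros(n_mc)
    p_star_arm1 = np.clip(p_star_arm1, 0.0, 1.0)
    p_star_arm0 = np.clip(p_star_arm0, 0.0, 1.0)
    p_event_star = _event_probability(cfg, cov_score, np.ones(n_mc))
    p_event_base = _event_probability(cfg, cov_score, np.zeros(n_mc))
    y1 = p_star_arm1 * p_event_star + (1 - p_star_arm1) * p_event_base
    y0 = p_star_arm0 * p_event_star + (1 - p_star_arm0) * p_event_base
    diff = y1 - y0
    return float(diff.mean()), float(diff.std(ddof=1) / math.sqrt(n_mc))
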