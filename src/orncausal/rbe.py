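"""Volume-tolerance curves and empirical proton RBE by equivalent
constraint dose.

A tolerance curve for one modality lists the derived critical volume (cc)
at each dose level (Gy on that modality's reported scale).  The photon
(VMAT) curve is linearly interpolated to find the *equivalent constraint
dose*: the photon dose at which the photon critical volume equals a given
proton critical volume.  The empirical RBE at a nominal proton dose
d Gy[RBE=1.1] is then

    RBE = equivalent photon dose / proton physical dose,
    proton physical dose = d / 1.1,

since proton prescriptions already carry the generic 1.1 factor while
photon doses are physical.  Bootstrap replicates of both modality curves
propagate threshold-selection uncertainty into a percentile CI on the RBE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dvc import DVCResult

__all__ = ["ToleranceCurve", "ExtrapolationError", "build_curve", "volume_at",
           "equivalent_dose", "empirical_rbe", "rbe_with_ci", "GENERIC_RBE"]

GENERIC_RBE = 1.1


class ExtrapolationError(ValueError):
    """Target volume lies outside the photon curve's volume range."""


@dataclass(frozen=True)
class ToleranceCurve:
    """(dose level, critical volume) knots for one modality."""

    modality: str
    dose_levels: np.ndarray      # Gy, strictly increasing
    volumes: np.ndarray          # cc
    ci95: Optional[np.ndarray] = None   # (k, 2) bootstrap bounds, optional
    dose_scale: str = "photon_physical"  # or "proton_rbe11"

    def __post_init__(self):
        d = np.asarray(self.dose_levels, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "dose_levels", d)
        object.__setattr__(self, "volumes", v)
        if d.size < 2:
            raise ValueError("a tolerance curve needs >= 2 dose levels")
        if d.size != v.size:
            raise ValueError("dose_levels and volumes must align")
        if np.unique(d).size != d.size:
            raise ValueError("duplicate dose level in tolerance curve")
        if not (np.diff(d) > 0).all():
            raise ValueError("dose levels must be strictly increasing")
        if (np.diff(v) > 0).any():
            warnings.warn(
                f"{self.modality} tolerance curve is not monotone non-increasing",
                RuntimeWarning, stacklevel=3)


def build_curve(dvcs: Dict[float, "DVCResult | float"], modality: str = "VMAT",
                dose_scale: str = "photon_physical") -> ToleranceCurve:
    """Assemble a tolerance curve from {dose level (Gy): DVCResult | volume}.

    Input order is irrelevant (knots are sorted by dose); duplicate dose
    levels raise, non-monotone volumes only warn.
    """
    levels = []
    vols = []
    cis = []
    for d, r in dvcs.items():
        levels.append(float(d))
        if isinstance(r, DVCResult):
            vols.append(r.critical_value)
            cis.append(r.ci95 if r.ci95 is not None else (np.nan, np.nan))
        else:
            vols.append(float(r))
            cis.append((np.nan, np.nan))
    order = np.argsort(levels)
    ci = np.asarray(cis, dtype=float)[order]
    return ToleranceCurve(modality=modality,
                          dose_levels=np.asarray(levels)[order],
                          volumes=np.asarray(vols)[order],
                          ci95=ci if np.isfinite(ci).any() else None,
                          dose_scale=dose_scale)


def volume_at(curve: ToleranceCurve, dose: float) -> float:
    """Critical volume at ``dose`` by linear interpolation (no extrapolation)."""
    d, v = curve.dose_levels, curve.volumes
    if dose < d[0] or dose > d[-1]:
        raise ExtrapolationError(f"dose {dose} outside curve range [{d[0]}, {d[-1]}]")
    return float(np.interp(dose, d, v))


def equivalent_dose(photon_curve: ToleranceCurve, target_volume: float) -> float:
    """Photon dose whose interpolated critical volume equals ``target_volume``.

    Piecewise-linear inverse of the (generally decreasing) curve.  On a
    non-monotone curve the volume may be attained on several segments; the
    lowest such dose is returned with a multiplicity warning.
    """
    d, v = photon_curve.dose_levels, photon_curve.volumes
    if not (min(v) <= target_volume <= max(v)):
        raise ExtrapolationError(
            f"target volume {target_volume} outside curve volume range "
            f"[{min(v)}, {max(v)}]")
    hits: List[float] = []
    for k in range(len(d) - 1):
        v0, v1 = v[k], v[k + 1]
        lo, hi = (v0, v1) if v0 <= v1 else (v1, v0)
        if lo <= target_volume <= hi:
            if v1 == v0:
                hits.append(float(d[k]))
            else:
                frac = (target_volume - v0) / (v1 - v0)
                hits.append(float(d[k] + frac * (d[k + 1] - d[k])))
    distinct = sorted({round(h, 12) for h in hits})
    if len(distinct) > 1:
        warnings.warn(
            f"target volume {target_volume} attained at multiple doses "
            f"{distinct}; returning the lowest", RuntimeWarning, stacklevel=2)
    return distinct[0]


def empirical_rbe(equiv_dose: float, nominal_proton_dose: float) -> float:
    """RBE = equivalent photon dose / proton physical dose (= nominal / 1.1)."""
    if equiv_dose <= 0 or nominal_proton_dose <= 0:
        raise ValueError("doses must be positive")
    return equiv_dose / (nominal_proton_dose / GENERIC_RBE)


def rbe_with_ci(photon_curve: ToleranceCurve,
                proton_volumes: Dict[float, float],
                photon_boot_curves: Optional[Sequence[ToleranceCurve]] = None,
                proton_boot_volumes: Optional[Dict[float, np.ndarray]] = None,
                max_drop_fraction: float = 0.2,
                on_extrapolation: str = "raise") -> pd.DataFrame:
    """Empirical RBE table with percentile bootstrap CIs.

    ``proton_volumes`` maps nominal proton dose (Gy[RBE=1.1]) to the proton
    critical volume at that level.  Paired bootstrap replicates of the
    photon curve and of each proton volume, when given, are recomputed into
    replicate RBEs; replicates where the proton volume falls outside the
    photon curve are dropped and counted, and the CI is flagged unreliable
    if more than ``max_drop_fraction`` were dropped.
    """
    if on_extrapolation not in ("raise", "skip"):
        raise ValueError("on_extrapolation must be 'raise' or 'skip'")
    rows = []
    for nominal, target in sorted(proton_volumes.items()):
        physical = nominal / GENERIC_RBE
        try:
            equiv = equivalent_dose(photon_curve, target)
            rbe = empirical_rbe(equiv, nominal)
        except ExtrapolationError:
            if on_extrapolation == "raise":
                raise
            warnings.warn(
                f"proton volume {target:.2f} cc at {nominal} Gy outside the "
                "photon curve; RBE row reported as NaN", RuntimeWarning,
                stacklevel=2)
            rows.append((nominal, physical, np.nan, np.nan, np.nan, np.nan,
                         0, True))
            continue
        ci_lo = ci_hi = np.nan
        dropped = 0
        unreliable = False
        if photon_boot_curves is not None and proton_boot_volumes is not None:
            reps = []
            boot_targets = proton_boot_volumes[nominal]
            n_rep = min(len(photon_boot_curves), len(boot_targets))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                for r in range(n_rep):
                    try:
                        e_r = equivalent_dose(photon_boot_curves[r],
                                              float(boot_targets[r]))
                        reps.append(empirical_rbe(e_r, nominal))
                    except (ExtrapolationError, ValueError):
                        dropped += 1
            if reps:
                ci_lo = float(np.percentile(reps, 2.5))
                ci_hi = float(np.percentile(reps, 97.5))
            unreliable = dropped > max_drop_fraction * n_rep
        rows.append((nominal, physical, equiv, rbe, ci_lo, ci_hi, dropped,
                     unreliable))
    return pd.DataFrame(rows, columns=[
        "nominal_proton_gy_rbe11", "proton_physical_gy", "equivalent_photon_gy",
        "rbe", "ci_lo", "ci_hi", "dropped_replicates", "ci_unreliable"])
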