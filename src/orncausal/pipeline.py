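"""End-to-end configuration-driven pipeline.

Stages: cohort load/simulate -> propensity matching + balance tests ->
within-group SMD matrices -> per-modality threshold scans with bootstrap
CIs for every VxGy factor -> tolerance curves -> empirical RBE table ->
randomized-dosimetry robustness check.  All artifacts are CSV/JSON under
``out_dir``; a manifest records the configuration and seeds so an
identical config reproduces an identical bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import __version__
from .balance import smd_report
from .cohort import CohortSchema, CohortTable, read_cohort, write_cohort
from .dvc import bootstrap_dvc, robustness_check
from .forest import ForestConfig
from .matching import match_cohort
from .rbe import ToleranceCurve, build_curve, rbe_with_ci
from .synthetic import SimConfig, generate

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Exactly one of ``input_path`` / ``sim`` provides the cohort."""

    input_path: Optional[str] = None
    schema_path: Optional[str] = None
    sim: Optional[SimConfig] = None
    forest: ForestConfig = ForestConfig(n_trees=500)
    grid_step: float = 1.0
    min_arm: int = 10
    n_boot: int = 1000
    rule: str = "max_z"
    v_factors: tuple = ("V40Gy", "V50Gy", "V60Gy", "V70Gy")
    rbe_nominal_doses: tuple = (40.0, 50.0, 60.0)
    out_dir: str = "results/pipeline"
    seed: int = 0

    def __post_init__(self):
        if (self.input_path is None) == (self.sim is None):
            raise ValueError("exactly one of input_path / sim must be set")
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimConfig(**raw["sim"])
        if "forest" in raw and raw["forest"] is not None:
            raw["forest"] = ForestConfig(**raw["forest"])
        for key in ("v_factors", "rbe_nominal_doses"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _dose_level_of(factor: str) -> float:
    m = re.match(r"V(\d+(?:\.\d+)?)Gy", factor)
    if not m:
        raise ValueError(f"cannot parse dose level from factor name {factor!r}")
    return float(m.group(1))


def _config_digest(cfg: PipelineConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)
    payload = json.dumps(dataclasses.asdict(cfg), default=enc, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute every stage; returns a dict of in-memory results and writes
    the artifact bundle under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: Dict[str, object] = {}

    # --- stage 1: cohort -------------------------------------------------
    if config.sim is not None:
        sim = replace(config.sim, seed=config.sim.seed + config.seed)
        table = generate(sim)
        write_cohort(table, out / "cohort.csv")
    else:
        schema = (CohortSchema.from_yaml(config.schema_path)
                  if config.schema_path else None)
        table = read_cohort(config.input_path, schema=schema)
    results["cohort"] = table

    # --- stage 2: matching ----------------------------------------------
    matched = match_cohort(table)
    matched.pairs_frame().to_csv(out / "matched_pairs.csv", index=False)
    balance = matched.balance_before.merge(
        matched.balance_after, on=["covariate", "test"],
        suffixes=("_before", "_after"))
    balance.to_csv(out / "balance.csv", index=False)
    results["matched"] = matched
    mtable = table.subset(table.df[table.schema.patient_id]
                          .isin(set(matched.matched_ids)).to_numpy())
    results["matched_table"] = mtable

    # --- stage 3: within-group SMD ---------------------------------------
    smd = {}
    for mod in ("VMAT", "PBSPT"):
        rep = smd_report(mtable, group=mod)
        rep.values.to_csv(out / f"smd_{mod}.csv")
        rep.flags.to_csv(out / f"smd_{mod}_flags.csv")
        smd[mod] = rep
    results["smd"] = smd

    # --- stage 4: per-modality DVC scans ---------------------------------
    dvcs: Dict[str, Dict[str, object]] = {"VMAT": {}, "PBSPT": {}}
    dvc_rows = []
    for mod in ("VMAT", "PBSPT"):
        sub = mtable.modality_subset(mod)
        for factor in config.v_factors:
            res = bootstrap_dvc(
                sub, factor, n_boot=config.n_boot, forest_config=config.forest,
                grid_step=config.grid_step, min_arm=config.min_arm,
                rule=config.rule,
                seed=config.seed + zlib.crc32(f"{mod}:{factor}".encode()) % 10000)
            res.ate_curve.to_csv(out / f"ate_curve_{mod}_{factor}.csv", index=False)
            dvcs[mod][factor] = res
            dvc_rows.append((mod, factor, res.critical_value,
                             res.ci95[0], res.ci95[1], res.ate, res.se))
    dvc_table = pd.DataFrame(dvc_rows, columns=[
        "modality", "factor", "critical_volume_cc", "ci_lo", "ci_hi", "ate", "se"])
    dvc_table.to_csv(out / "dvc_table.csv", index=False)
    results["dvc_table"] = dvc_table
    results["dvcs"] = dvcs

    # --- stage 5: tolerance curves + empirical RBE -----------------------
    photon_curve = build_curve(
        {_dose_level_of(f): r for f, r in dvcs["VMAT"].items()},
        modality="VMAT", dose_scale="photon_physical")
    proton_curve = build_curve(
        {_dose_level_of(f): r for f, r in dvcs["PBSPT"].items()},
        modality="PBSPT", dose_scale="proton_rbe11")
    n_boot = config.n_boot
    photon_boot_curves: List[ToleranceCurve] = []
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        for r in range(n_boot):
            try:
                photon_boot_curves.append(build_curve(
                    {_dose_level_of(f): float(res.boot_values[r])
                     for f, res in dvcs["VMAT"].items()}, modality="VMAT"))
            except ValueError:
                continue
    proton_volumes = {}
    proton_boot = {}
    for d in config.rbe_nominal_doses:
        factor = f"V{int(d)}Gy"
        if factor not in dvcs["PBSPT"]:
            continue
        proton_volumes[d] = dvcs["PBSPT"][factor].critical_value
        proton_boot[d] = dvcs["PBSPT"][factor].boot_values
    rbe_table = rbe_with_ci(photon_curve, proton_volumes,
                            photon_boot_curves=photon_boot_curves,
                            proton_boot_volumes=proton_boot,
                            on_extrapolation="skip")
    rbe_table.to_csv(out / "rbe_table.csv", index=False)
    results["photon_curve"] = photon_curve
    results["proton_curve"] = proton_curve
    results["rbe_table"] = rbe_table

    # --- stage 6: robustness check ---------------------------------------
    robust = robustness_check(mtable, forest_config=config.forest,
                              seed=config.seed)
    robust.to_csv(out / "robustness.csv", index=False)
    results["robustness"] = robust

    manifest = {
        "package_version": __version__,
        "config_digest": _config_digest(config),
        "seed": config.seed,
        "n_patients": len(table),
        "n_matched": len(mtable),
        "max_abs_robustness_ate": float(robust["abs_ate"].max()),
        "artifacts": sorted({p.name for p in out.iterdir()} | {"manifest.json"}),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
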