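"""Cohort data model, delimited-file I/O, DVH index extraction.

A cohort is a per-patient table with a treatment-modality column (VMAT or
PBSPT), a binary osteoradionecrosis outcome, clinical covariates (age plus
categorical factors, where an empty cell is kept as the explicit category
``MISSING`` rather than imputed), and mandible dosimetric factors: absolute
volumes VxGy in cc and Dmax/Dmean in cGy.  Doses are stored internally in
cGy; file readers accept Gy with a unit flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MISSING", "MODALITIES", "CohortSchema", "CohortTable", "DVHCurve",
    "SchemaError", "ValidationError", "DegenerateArmError",
    "read_cohort", "write_cohort", "extract_index", "binarize",
    "design_matrix",
]

MISSING = "MISSING"
MODALITIES = ("VMAT", "PBSPT")

DEFAULT_COVARIATES = [
    "age", "tumor_stage", "gender", "chemo", "smoking_history",
    "current_smoker", "hypertension", "diabetes", "dental_extraction",
]
DEFAULT_DOSIMETRIC = ["V40Gy", "V50Gy", "V60Gy", "V70Gy", "Dmax", "Dmean"]
CONTINUOUS_COVARIATES = ("age",)


class SchemaError(ValueError):
    """A mandatory column is absent or mis-declared."""


class ValidationError(ValueError):
    """Cell values violate the cohort invariants."""


class DegenerateArmError(ValueError):
    """A binarization threshold left one treatment arm empty/too small."""


@dataclass(frozen=True)
class CohortSchema:
    """Column-role assignment for a cohort file."""

    modality: str = "modality"
    outcome: str = "orn"
    patient_id: str = "patient_id"
    covariates: Sequence[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    dosimetric: Sequence[str] = field(default_factory=lambda: list(DEFAULT_DOSIMETRIC))

    @property
    def categorical_covariates(self) -> List[str]:
        return [c for c in self.covariates if c not in CONTINUOUS_COVARIATES]

    @property
    def continuous_covariates(self) -> List[str]:
        return [c for c in self.covariates if c in CONTINUOUS_COVARIATES]

    @classmethod
    def from_yaml(cls, path) -> "CohortSchema":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**cfg)


class CohortTable:
    """An ordered patient cohort with column-role metadata.

    Thin wrapper around a pandas DataFrame; validation enforces the domain
    invariants (binary outcome, non-negative doses, VxGy monotone in dose,
    Dmax >= Dmean, unique patient ids).
    """

    def __init__(self, df: pd.DataFrame, schema: Optional[CohortSchema] = None,
                 validate: bool = True):
        self.schema = schema or CohortSchema()
        self.df = df.reset_index(drop=True)
        if validate:
            self.validate()

    # -- basic protocol ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, CohortTable) and self.df.equals(other.df)

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        s, df = self.schema, self.df
        required = ([s.patient_id, s.modality, s.outcome]
                    + list(s.covariates) + list(s.dosimetric))
        missing_cols = [c for c in required if c not in df.columns]
        if missing_cols:
            raise SchemaError(f"missing mandatory columns: {missing_cols}")
        if df[s.patient_id].duplicated().any():
            dup = df[s.patient_id][df[s.patient_id].duplicated()].iloc[0]
            raise ValidationError(f"duplicate patient_id: {dup!r}")
        bad_mod = set(df[s.modality].unique()) - set(MODALITIES)
        if bad_mod:
            raise ValidationError(f"unknown modality values: {sorted(bad_mod)}")
        y = df[s.outcome]
        if not y.isin([0, 1]).all():
            raise ValidationError("outcome column must be binary 0/1")
        dose = df[list(s.dosimetric)].to_numpy(dtype=float)
        if np.isnan(dose).any():
            raise ValidationError("dosimetric factors must not be missing")
        if (dose < 0).any():
            raise ValidationError("negative dose/volume value")
        vcols = [c for c in s.dosimetric if c.startswith("V")]
        if len(vcols) >= 2:
            v = df[vcols].to_numpy(dtype=float)
            if (np.diff(v, axis=1) > 1e-9).any():
                raise ValidationError("VxGy volumes must be non-increasing in dose level")
        if "Dmax" in s.dosimetric and "Dmean" in s.dosimetric:
            if (df["Dmax"].to_numpy(float) + 1e-9 < df["Dmean"].to_numpy(float)).any():
                raise ValidationError("Dmax must be >= Dmean")

    # -- accessors --------------------------------------------------------

    @property
    def outcome(self) -> np.ndarray:
        return self.df[self.schema.outcome].to_numpy(dtype=np.int8)

    @property
    def modality(self) -> pd.Series:
        return self.df[self.schema.modality]

    def subset(self, mask) -> "CohortTable":
        return CohortTable(self.df[mask].reset_index(drop=True), self.schema,
                           validate=False)

    def modality_subset(self, modality: str) -> "CohortTable":
        if modality not in MODALITIES:
            raise ValueError(f"unknown modality {modality!r}")
        return self.subset((self.modality == modality).to_numpy())

    def factor_values(self, factor: str) -> np.ndarray:
        if factor not in self.df.columns:
            raise KeyError(f"unknown factor {factor!r}")
        return self.df[factor].to_numpy(dtype=float)


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume histogram: volume (cc) receiving >= dose (cGy)."""

    dose_grid: np.ndarray
    volume: np.ndarray

    def __post_init__(self):
        dose = np.asarray(self.dose_grid, dtype=float)
        vol = np.asarray(self.volume, dtype=float)
        object.__setattr__(self, "dose_grid", dose)
        object.__setattr__(self, "volume", vol)
        if dose.size == 0:
            raise ValidationError("empty DVH curve")
        if dose.size != vol.size:
            raise ValidationError("dose_grid and volume must have equal length")
        if not (np.diff(dose) > 0).all():
            raise ValidationError("dose_grid must be strictly ascending")
        if (np.diff(vol) > 1e-9).any():
            raise ValidationError("cumulative volume must be non-increasing")
        if (vol < 0).any():
            raise ValidationError("volumes must be non-negative")

    @classmethod
    def from_csv(cls, path) -> "DVHCurve":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


def extract_index(curve: DVHCurve, dose_level: float) -> float:
    """Cumulative volume (cc) at ``dose_level`` (cGy), linearly interpolated.

    Beyond the last grid dose the structure receives nothing, so 0 is
    returned; below the first grid dose the total structure volume applies.
    """
    if dose_level < 0:
        raise ValueError("dose_level must be >= 0")
    return float(np.interp(dose_level, curve.dose_grid, curve.volume,
                           left=curve.volume[0], right=0.0))


def binarize(table_or_values: Union[CohortTable, np.ndarray], factor: Optional[str] = None,
             threshold: float = 0.0, min_arm: int = 0) -> np.ndarray:
    """Binary treatment vector: 1 where the factor value exceeds ``threshold``.

    Ties go to the control arm (value <= threshold -> T=0).  With
    ``min_arm`` > 0, a threshold leaving either arm smaller than that raises
    :class:`DegenerateArmError` so threshold scans can skip the grid point.
    """
    if isinstance(table_or_values, CohortTable):
        if factor is None:
            raise ValueError("factor name required with a CohortTable")
        values = table_or_values.factor_values(factor)
    else:
        values = np.asarray(table_or_values, dtype=float)
    t = (values > threshold).astype(np.int8)
    if min_arm > 0:
        n1 = int(t.sum())
        if n1 < min_arm or len(t) - n1 < min_arm:
            raise DegenerateArmError(
                f"threshold {threshold} leaves arms of size {len(t) - n1}/{n1}")
    return t


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_cohort(path, schema: Optional[CohortSchema] = None, sep: str = ",",
                dose_unit: str = "cGy") -> CohortTable:
    """Read a delimited cohort file.

    Empty cells in categorical covariates become the explicit category
    ``MISSING`` (never imputed).  ``dose_unit='Gy'`` converts Dmax/Dmean
    columns to the internal cGy scale on read.
    """
    schema = schema or CohortSchema()
    df = pd.read_csv(path, sep=sep, dtype={schema.patient_id: str})
    for c in schema.categorical_covariates:
        if c in df.columns:
            df[c] = df[c].astype("object")
            df[c] = df[c].where(df[c].notna() & (df[c].astype(str).str.strip() != ""),
                                MISSING)
            df[c] = df[c].astype(str)
    if dose_unit == "Gy":
        for c in ("Dmax", "Dmean"):
            if c in df.columns:
                df[c] = df[c] * 100.0
    elif dose_unit != "cGy":
        raise ValueError("dose_unit must be 'cGy' or 'Gy'")
    return CohortTable(df, schema)


def write_cohort(table: CohortTable, path, sep: str = ",") -> None:
    """Write a cohort as delimited text (round-trips with read_cohort)."""
    table.df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# model matrix
# ---------------------------------------------------------------------------


def design_matrix(table: CohortTable, drop_first: bool = False):
    """One-hot clinical covariate matrix for models.

    Age stays continuous; each categorical level (including MISSING) gets
    its own indicator column.  Returns (X (n,p) float64, feature names).
    """
    s = table.schema
    cols = []
    names: List[str] = []
    for c in s.continuous_covariates:
        cols.append(table.df[c].to_numpy(dtype=float))
        names.append(c)
    for c in s.categorical_covariates:
        dummies = pd.get_dummies(table.df[c].astype(str), prefix=c,
                                 drop_first=drop_first)
        dummies = dummies[sorted(dummies.columns)]
        for name in dummies.columns:
            cols.append(dummies[name].to_numpy(dtype=float))
            names.append(name)
    X = np.column_stack(cols) if cols else np.empty((len(table), 0))
    return np.ascontiguousarray(X), names
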