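"""Cohort table loading, validation and model-matrix preparation.

The cohort is an ordinary :class:`pandas.DataFrame`, one row per ICU
admission, with the column vocabulary declared in :data:`COHORT_SCHEMA`.
This module turns it into the objects the inferential stages need: tertile
group labels for the descriptive layer, and fully numeric design matrices
(indicator-coded categoricals, hinge terms, missing-value dummy columns)
for the logistic fits.  Design matrices never contain missing values:
missingness is resolved explicitly (indicator + mean fill) before any model
sees the data, so fits never silently drop rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "COHORT_SCHEMA",
    "TertileAssignment",
    "DesignMatrix",
    "FormulaSpec",
    "assign_tertiles",
    "add_missing_dummies",
    "build_design",
    "hinge",
    "read_cohort_csv",
    "write_cohort_csv",
    "drop_missing_exposure",
]

#: Declared column vocabulary: name -> (kind, units/levels).
COHORT_SCHEMA: dict[str, dict] = {
    "id": {"kind": "id", "units": ""},
    "death28": {"kind": "binary", "units": "1 = died within 28 days of ICU admission"},
    "death14": {"kind": "binary", "units": "1 = died within 14 days of ICU admission"},
    "ratio": {"kind": "continuous", "units": "non-HDLc/HDLc ratio (unitless)"},
    "age": {"kind": "continuous", "units": "years"},
    "sex": {"kind": "categorical", "levels": ["male", "female"]},
    "weight": {"kind": "continuous", "units": "kg"},
    "heart_rate": {"kind": "continuous", "units": "beats/min"},
    "lactate": {"kind": "continuous", "units": "mmol/L"},
    "apache_iv": {"kind": "continuous", "units": "APACHE IV score"},
    "sofa": {"kind": "continuous", "units": "SOFA score"},
    "septic_shock": {"kind": "binary", "units": "1 = septic shock"},
    "infection_site": {
        "kind": "categorical",
        "levels": ["pulmonary", "renal/UTI", "GI", "unknown", "cutaneous/soft tissue", "other"],
    },
}

#: Columns that may never be made missing or dummy-coded away.
PROTECTED_COLUMNS = ("id", "death28", "death14", "ratio")


@dataclass
class TertileAssignment:
    """Exposure tertile labels with realized cut values and group sizes."""

    boundaries: tuple[float, float]
    labels: pd.Series  # values in {1, 2, 3}
    counts: tuple[int, int, int]

    def mask(self, tertile: int) -> pd.Series:
        return self.labels == tertile


def assign_tertiles(values) -> TertileAssignment:
    """Split a continuous vector into three near-equal ordered groups.

    Cut ranks are ``n//3`` and ``2n//3`` of the sorted values (nearest-rank
    quantiles with the remainder going to the top group, so n=724 splits
    241/241/242).  Observations tied with a cut value go to the lower group,
    which makes the assignment deterministic and permutation-equivariant.
    """
    v = pd.Series(values).astype(float).reset_index(drop=True)
    n = len(v)
    if n < 3:
        raise ValueError(f"need at least 3 observations for tertiles, got {n}")
    if v.isna().any():
        raise ValueError("tertile assignment requires non-missing values")
    if v.nunique() == 1:
        raise ValueError("constant vector: tertiles undefined")
    s = np.sort(v.to_numpy())
    c1, c2 = s[n // 3 - 1], s[2 * n // 3 - 1]
    labels = pd.Series(np.where(v <= c1, 1, np.where(v <= c2, 2, 3)), index=v.index)
    counts = tuple(int((labels == k).sum()) for k in (1, 2, 3))
    return TertileAssignment(boundaries=(float(c1), float(c2)), labels=labels, counts=counts)


def add_missing_dummies(
    table: pd.DataFrame,
    covariates: list[str] | None = None,
    threshold_fraction: float = 0.01,
) -> pd.DataFrame:
    """Missing-indicator handling for continuous covariates.

    For each covariate with a missing fraction strictly greater than
    ``threshold_fraction``, adds a ``<name>_missing`` indicator (1 = value was
    missing) and replaces the missing entries with the observed mean.
    Covariates at or below the threshold are mean-filled without an
    indicator.  Outcome and exposure columns are never touched.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    out = table.copy()
    if covariates is None:
        covariates = [
            c for c in table.columns
            if c not in PROTECTED_COLUMNS and pd.api.types.is_numeric_dtype(table[c])
        ]
    for name in covariates:
        if name in PROTECTED_COLUMNS:
            raise ValueError(f"{name!r} is an outcome/exposure column and may not be dummy-coded")
        col = out[name]
        miss = col.isna()
        if miss.all():
            raise ValueError(f"covariate {name!r} is 100% missing; cannot mean-fill")
        frac = miss.mean()
        if frac > threshold_fraction:
            out[f"{name}_missing"] = miss.astype(int)
        if miss.any():
            out[name] = col.fillna(col.mean())
    return out


def hinge(values, knot: float) -> np.ndarray:
    """Hinge transform max(x - knot, 0); with a linear term it gives a
    continuous piecewise-linear predictor with a slope change at ``knot``."""
    return np.maximum(np.asarray(values, dtype=float) - knot, 0.0)


@dataclass
class FormulaSpec:
    """Declarative recipe for a design matrix.

    ``categorical`` maps each factor to its reference level (the level that
    gets no indicator column); ``hinge_terms`` maps a continuous column to a
    knot, producing both the linear column and ``<name>_hinge``.
    """

    continuous: list[str] = dc_field(default_factory=list)
    categorical: dict[str, str] = dc_field(default_factory=dict)
    hinge_terms: dict[str, float] = dc_field(default_factory=dict)
    missing_indicators: str = "auto"  # auto | off
    intercept: bool = True


@dataclass
class DesignMatrix:
    """Numeric model inputs: response vector, predictor frame, reference levels."""

    y: pd.Series
    X: pd.DataFrame
    reference_levels: dict[str, str]

    def __post_init__(self):
        if self.X.isna().any().any():
            bad = list(self.X.columns[self.X.isna().any()])
            raise ValueError(f"design matrix has missing values in {bad}")
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate design matrix columns")


# reference levels matching the published adjusted models
DEFAULT_REFERENCES = {"sex": "male", "infection_site": "pulmonary"}


def build_design(table: pd.DataFrame, spec: FormulaSpec, outcome: str = "death28") -> DesignMatrix:
    """Expand a cohort table into a numeric design matrix.

    Categoricals are coded as k-1 indicator columns against the declared
    reference level; hinge terms produce the linear column plus
    ``max(x - knot, 0)``; continuous covariates pass through.  With
    ``missing_indicators='auto'`` the missing-dummy rule is applied to the
    continuous covariates first.
    """
    if outcome not in table.columns:
        raise KeyError(f"outcome column {outcome!r} not in table")
    work = table
    if spec.missing_indicators == "auto":
        cont = [c for c in spec.continuous if c in table.columns]
        work = add_missing_dummies(table, covariates=cont)
    cols: dict[str, np.ndarray] = {}
    n = len(work)
    if spec.intercept:
        cols["intercept"] = np.ones(n)
    for name, knot in spec.hinge_terms.items():
        if name not in work.columns:
            raise KeyError(f"hinge column {name!r} not in table")
        x = work[name].to_numpy(dtype=float)
        cols[name] = x
        cols[f"{name}_hinge"] = hinge(x, knot)
    for name in spec.continuous:
        if name not in work.columns:
            raise KeyError(f"continuous column {name!r} not in table")
        cols[name] = work[name].to_numpy(dtype=float)
        ind = f"{name}_missing"
        if ind in work.columns and ind not in cols:
            cols[ind] = work[ind].to_numpy(dtype=float)
    refs = {}
    for name, ref in spec.categorical.items():
        if name not in work.columns:
            raise KeyError(f"categorical column {name!r} not in table")
        series = work[name].astype(str)
        levels = COHORT_SCHEMA.get(name, {}).get("levels")
        if levels is None:
            levels = sorted(series.unique())
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not a level of {name!r} (levels: {levels})")
        unknown = set(series.unique()) - set(levels)
        if unknown:
            raise ValueError(f"unknown level(s) {sorted(unknown)} in column {name!r}")
        refs[name] = ref
        for lev in levels:
            if lev == ref:
                continue
            cols[f"{name}[{lev}]"] = (series == lev).astype(float).to_numpy()
    y = work[outcome].astype(int)
    y.name = outcome
    return DesignMatrix(y=y, X=pd.DataFrame(cols, index=work.index), reference_levels=refs)


def drop_missing_exposure(table: pd.DataFrame, exposure: str = "ratio") -> tuple[pd.DataFrame, int]:
    """Exclude rows with a missing exposure (mirrors the cohort's exclusion
    of admissions without a post-admission cholesterol measurement).
    Returns the filtered table and the number of rows dropped."""
    keep = table[exposure].notna()
    return table.loc[keep].reset_index(drop=True), int((~keep).sum())


# ---------------------------------------------------------------------------
# CSV round-trip with a schema sidecar

def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write the cohort as CSV (missing values as empty fields) plus a
    ``<path>.schema.json`` sidecar describing columns, types and levels."""
    path = Path(path)
    table.to_csv(path, index=False, na_rep="")
    sidecar = {
        "columns": [
            {"name": c, **COHORT_SCHEMA.get(c, {"kind": "unknown"})} for c in table.columns
        ]
    }
    Path(str(path) + ".schema.json").write_text(json.dumps(sidecar, indent=2))


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV, coercing dtypes per the schema sidecar when present."""
    path = Path(path)
    df = pd.read_csv(path)
    for c in df.columns:
        kind = COHORT_SCHEMA.get(c, {}).get("kind")
        if kind in ("continuous",):
            df[c] = df[c].astype(float)
        elif kind == "binary":
            df[c] = df[c].astype(int)
        elif kind == "categorical":
            df[c] = df[c].astype(str)
    validate_cohort(df)
    return df


def validate_cohort(table: pd.DataFrame) -> None:
    """Check cohort invariants; raises ``ValueError`` naming the violation."""
    if "ratio" in table.columns and table["ratio"].isna().any():
        raise ValueError("exposure column 'ratio' contains missing values")
    if {"death14", "death28"} <= set(table.columns):
        bad = (table["death14"] == 1) & (table["death28"] == 0)
        if bad.any():
            raise ValueError("death14=1 rows must have death28=1")
    for c in table.columns:
        meta = COHORT_SCHEMA.get(c)
        if not meta:
            continue
        if meta["kind"] == "binary":
            vals = set(table[c].dropna().unique())
            if not vals <= {0, 1}:
                raise ValueError(f"binary column {c!r} has values outside {{0,1}}: {sorted(vals)}")
        elif meta["kind"] == "categorical":
            extra = set(table[c].dropna().astype(str)) - set(meta["levels"])
            if extra:
                raise ValueError(f"column {c!r} has undeclared levels {sorted(extra)}")
        elif meta["kind"] == "continuous":
            finite = np.isfinite(table[c].dropna().to_numpy(dtype=float))
            if not finite.all():
                raise ValueError(f"column {c!r} has non-finite values")
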