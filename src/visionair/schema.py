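"""Cohort data model: schema, ocular derivations, validation, CSV I/O, encoding.

The cohort is a pandas DataFrame with one row per student, validated against
the machine-readable schema shipped in ``data/schema.yaml``. Columns cover
demographic, habit, and environmental predictors plus the ocular outcomes:
uncorrected visual acuity (UCVA, Chinese 5-point logarithmic chart,
3.0-5.3), sphere and cylinder (diopters).

Derived labels follow the screening definitions: spherical equivalent
SE = sphere + cylinder/2; myopia when SE <= -0.50 D and UCVA < 5.0; high
myopia when additionally SE <= -6.00 D; school level groups middle and high
school together as "senior".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CohortSchema",
    "FeatureMatrix",
    "ValidationReport",
    "load_schema",
    "compute_spherical_equivalent",
    "classify_myopia",
    "derive_labels",
    "combine_eyes",
    "validate_cohort",
    "read_cohort",
    "write_cohort",
    "encode_features",
]

MYOPIA_SE_THRESHOLD = -0.50
HIGH_MYOPIA_SE_THRESHOLD = -6.00
UCVA_MYOPIA_CUTOFF = 5.0
UCVA_RANGE = (3.0, 5.3)

MISSING_LEVEL = "missing"


class SchemaError(ValueError):
    """A table does not conform to the cohort schema."""


class CohortSchema:
    """Column schema: names, types, units, level sets, feature groups."""

    def __init__(self, spec: dict):
        self.schema_version: str = str(spec.get("schema_version", "1.0"))
        self.id_column: str = spec.get("id_column", "id")
        self.columns: dict[str, dict] = dict(spec["columns"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSchema":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(yaml.safe_load(fh))

    @property
    def column_names(self) -> list[str]:
        return list(self.columns)

    @property
    def predictors(self) -> list[str]:
        return [c for c, s in self.columns.items() if s.get("role") == "predictor"]

    @property
    def outcomes(self) -> list[str]:
        return [c for c, s in self.columns.items() if s.get("role") == "outcome"]

    @property
    def categorical(self) -> list[str]:
        return [c for c, s in self.columns.items() if s.get("type") == "categorical"]

    @property
    def numeric(self) -> list[str]:
        return [c for c, s in self.columns.items() if s.get("type") == "numeric"]

    def levels(self, column: str) -> list[str]:
        return list(self.columns[column]["levels"])

    def group(self, column: str) -> str | None:
        return self.columns[column].get("group")

    @property
    def group_map(self) -> dict[str, str]:
        """feature -> {demog, habit, environ} for every predictor."""
        return {c: self.columns[c]["group"] for c in self.predictors}

    def numeric_range(self, column: str) -> tuple[float, float]:
        s = self.columns[column]
        return (s.get("min", -np.inf), s.get("max", np.inf))


def load_schema() -> CohortSchema:
    """Load the packaged default schema."""
    with resources.files("visionair.data").joinpath("schema.yaml").open(
        "r", encoding="utf-8"
    ) as fh:
        return CohortSchema(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Ocular derivations


def compute_spherical_equivalent(sphere, cylinder):
    """Spherical equivalent SE = sphere + cylinder / 2, in diopters.

    Accepts scalars or arrays; raises on non-finite scalar input.
    """
    sphere_arr = np.asarray(sphere, dtype=float)
    cylinder_arr = np.asarray(cylinder, dtype=float)
    if sphere_arr.ndim == 0 and not np.isfinite(sphere_arr):
        raise ValueError("sphere must be finite")
    if cylinder_arr.ndim == 0 and not np.isfinite(cylinder_arr):
        raise ValueError("cylinder must be finite")
    out = sphere_arr + cylinder_arr / 2.0
    return float(out) if out.ndim == 0 else out


def classify_myopia(se, ucva):
    """Screening myopia class from spherical equivalent and UCVA.

    none if SE > -0.50 D or UCVA >= 5.0; high if myopic and SE <= -6.00 D;
    school otherwise. Vectorized; scalar in, scalar out.
    """
    se_arr = np.asarray(se, dtype=float)
    ucva_arr = np.asarray(ucva, dtype=float)
    lo, hi = UCVA_RANGE
    finite = np.isfinite(ucva_arr)
    if np.any(finite & ((ucva_arr < lo) | (ucva_arr > hi))):
        raise ValueError(f"ucva out of range [{lo}, {hi}]")
    myopic = (se_arr <= MYOPIA_SE_THRESHOLD) & (ucva_arr < UCVA_MYOPIA_CUTOFF)
    out = np.where(
        myopic,
        np.where(se_arr <= HIGH_MYOPIA_SE_THRESHOLD, "high", "school"),
        "none",
    )
    if se_arr.ndim == 0 and ucva_arr.ndim == 0:
        return str(out)
    return out


def combine_eyes(right: pd.DataFrame, left: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-eye ocular measurements to the worse (lower-UCVA) eye.

    Both frames need columns ucva, sphere, cylinder aligned on index; rows
    where one eye is missing take the measured eye.
    """
    take_left = left["ucva"] < right["ucva"]
    take_left = take_left.fillna(right["ucva"].isna())
    out = right[["ucva", "sphere", "cylinder"]].copy()
    out[take_left] = left[["ucva", "sphere", "cylinder"]][take_left]
    return out


def derive_labels(table: pd.DataFrame) -> pd.DataFrame:
    """Derived labels per row: se, myopia_class, school_level.

    Rows missing any of sphere, cylinder, ucva get myopia_class/se of NA
    (flagged out of labeled subsets). school_level is 'senior' iff
    school_type is middle or high.
    """
    ocular_ok = (
        table["sphere"].notna() & table["cylinder"].notna() & table["ucva"].notna()
    )
    se = pd.Series(np.nan, index=table.index, name="se")
    se[ocular_ok] = compute_spherical_equivalent(
        table.loc[ocular_ok, "sphere"].to_numpy(),
        table.loc[ocular_ok, "cylinder"].to_numpy(),
    )
    myopia_class = pd.Series(pd.NA, index=table.index, dtype="object", name="myopia_class")
    if ocular_ok.any():
        myopia_class[ocular_ok] = classify_myopia(
            se[ocular_ok].to_numpy(), table.loc[ocular_ok, "ucva"].to_numpy()
        )
    school_level = table["school_type"].map(
        {"primary": "primary", "middle": "senior", "high": "senior"}
    )
    return pd.DataFrame(
        {
            "se": se,
            "myopia_class": myopia_class,
            "school_level": school_level,
            "labeled": ocular_ok,
        },
        index=table.index,
    )


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationReport:
    """Report-only summary of schema conformance for a cohort table."""

    n_rows: int
    missing: dict[str, int] = field(default_factory=dict)
    out_of_range: dict[str, int] = field(default_factory=dict)
    unknown_levels: dict[str, list[str]] = field(default_factory=dict)
    duplicate_ids: int = 0

    @property
    def n_issues(self) -> int:
        return (
            sum(self.out_of_range.values())
            + sum(len(v) for v in self.unknown_levels.values())
            + self.duplicate_ids
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for col, n in self.missing.items():
            rows.append({"column": col, "issue": "missing", "count": n, "detail": ""})
        for col, n in self.out_of_range.items():
            rows.append({"column": col, "issue": "out_of_range", "count": n, "detail": ""})
        for col, levels in self.unknown_levels.items():
            rows.append(
                {
                    "column": col,
                    "issue": "unknown_level",
                    "count": len(levels),
                    "detail": "|".join(map(str, levels)),
                }
            )
        if self.duplicate_ids:
            rows.append(
                {
                    "column": "id",
                    "issue": "duplicate_id",
                    "count": self.duplicate_ids,
                    "detail": "",
                }
            )
        return pd.DataFrame(rows, columns=["column", "issue", "count", "detail"])


def validate_cohort(table: pd.DataFrame, schema: CohortSchema | None = None) -> ValidationReport:
    """Check a cohort table against the schema; the table is unchanged."""
    schema = schema or load_schema()
    report = ValidationReport(n_rows=len(table))
    if len(table) == 0:
        return report
    for col in schema.column_names:
        if col not in table.columns:
            continue
        s = table[col]
        n_missing = int(s.isna().sum())
        if n_missing:
            report.missing[col] = n_missing
        spec = schema.columns[col]
        if spec.get("type") == "numeric":
            lo, hi = schema.numeric_range(col)
            vals = pd.to_numeric(s, errors="coerce")
            bad = int(((vals < lo) | (vals > hi)).sum())
            if bad:
                report.out_of_range[col] = bad
        elif spec.get("type") == "categorical":
            unknown = sorted(set(s.dropna().astype(str)) - set(schema.levels(col)))
            if unknown:
                report.unknown_levels[col] = unknown
    if schema.id_column in table.columns:
        report.duplicate_ids = int(table[schema.id_column].duplicated().sum())
    return report


# ---------------------------------------------------------------------------
# CSV I/O


def write_cohort(table: pd.DataFrame, path: str | Path, schema: CohortSchema | None = None) -> None:
    """Write a cohort CSV (UTF-8, empty cell = missing) in schema column order."""
    schema = schema or load_schema()
    cols = [c for c in schema.column_names if c in table.columns]
    extra = [c for c in table.columns if c not in schema.column_names]
    table[cols + extra].to_csv(path, index=False, encoding="utf-8")


def read_cohort(
    path: str | Path,
    schema: CohortSchema | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Read a cohort CSV and validate its header against the schema.

    Missing required columns raise :class:`SchemaError` naming them. Unknown
    extra columns raise when ``strict`` else warn and drop. write o read is
    the identity on values and column order.
    """
    schema = schema or load_schema()
    frame = pd.read_csv(path, dtype={schema.id_column: str})
    missing_cols = [c for c in schema.column_names if c not in frame.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {', '.join(missing_cols)}")
    extra = [c for c in frame.columns if c not in schema.column_names]
    if extra:
        if strict:
            raise SchemaError(f"unknown column(s): {', '.join(extra)}")
        warnings.warn(f"dropping unknown column(s): {', '.join(extra)}", stacklevel=2)
        frame = frame.drop(columns=extra)
    for col in schema.categorical:
        frame[col] = frame[col].astype("object")
        frame.loc[frame[col].isna(), col] = np.nan
    return frame[schema.column_names]


# ---------------------------------------------------------------------------
# Feature encoding


@dataclass
class FeatureMatrix:
    """Encoded model matrix: factor codes + unscaled numerics.

    Categoricals are integer level codes carrying their level maps
    (order-free semantics downstream: tree models split on level subsets).
    Numerics pass through unscaled; missing numerics are median-imputed with
    a paired ``<col>__missing`` indicator; missing categoricals get an
    explicit level.
    """

    X: pd.DataFrame
    categorical: list[str]
    levels: dict[str, list[str]]
    medians: dict[str, float]
    groups: dict[str, str]

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def categorical_mask(self) -> np.ndarray:
        return np.array([c in self.categorical for c in self.X.columns])


def encode_features(
    table: pd.DataFrame,
    feature_list: list[str] | None = None,
    schema: CohortSchema | None = None,
) -> FeatureMatrix:
    """Encode predictors for model fitting; deterministic given table+schema.

    No normalization is applied; categoricals become unordered factor codes.
    """
    schema = schema or load_schema()
    features = feature_list if feature_list is not None else schema.predictors
    bad = [f for f in features if f not in schema.predictors]
    if bad:
        raise SchemaError(f"feature(s) not in schema predictors: {', '.join(bad)}")

    cols: dict[str, np.ndarray] = {}
    categorical: list[str] = []
    levels: dict[str, list[str]] = {}
    medians: dict[str, float] = {}
    groups: dict[str, str] = {}

    for f in features:
        group = schema.group(f) or "other"
        s = table[f]
        if schema.columns[f]["type"] == "categorical":
            lv = schema.levels(f)
            n_missing = int(s.isna().sum())
            if n_missing == len(s) and len(s) > 0:
                warnings.warn(f"column {f!r} is entirely missing", stacklevel=2)
                lv_used = [MISSING_LEVEL]
                codes = np.zeros(len(s), dtype=np.int64)
            else:
                lv_used = lv + ([MISSING_LEVEL] if n_missing else [])
                cat = pd.Categorical(s.astype("object"), categories=lv)
                codes = cat.codes.astype(np.int64).copy()
                codes[codes < 0] = len(lv)  # missing level code
            cols[f] = codes.astype(np.float64)
            categorical.append(f)
            levels[f] = lv_used
            groups[f] = group
        else:
            vals = pd.to_numeric(s, errors="coerce").to_numpy(dtype=np.float64)
            n_missing = int(np.isnan(vals).sum())
            if n_missing == len(vals) and len(vals) > 0:
                warnings.warn(f"column {f!r} is entirely missing", stacklevel=2)
                med = 0.0
            else:
                med = float(np.nanmedian(vals)) if len(vals) else np.nan
            if n_missing:
                ind = np.isnan(vals).astype(np.float64)
                vals = np.where(np.isnan(vals), med, vals)
                cols[f] = vals
                cols[f + "__missing"] = ind
                groups[f + "__missing"] = group
            else:
                cols[f] = vals
            medians[f] = med
            groups[f] = group

    X = pd.DataFrame(cols, index=table.index)
    return FeatureMatrix(X=X, categorical=categorical, levels=levels, medians=medians, groups=groups)
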