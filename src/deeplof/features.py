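"""Feature preprocessing: log transform, standardization, mean imputation.

Raw gene-level features come in two kinds.  Continuous features may be
right-skewed and nonnegative, in which case they are log-transformed as
x' = log(x + delta) with delta the minimum observed positive value of the
column; every continuous feature is then z-scored (sample standard
deviation), and missing entries are finally imputed with the column mean —
which, after standardization, is ~0.  Binary features pass through untouched
and must take values in {0, 1}.

The fitted transform state (delta, mean, sd, fill value per column) is
retained so the identical transform can be applied to new genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSpec",
    "FeatureMatrix",
    "log_transform_column",
    "standardize_column",
    "impute_missing_column",
    "build_feature_matrix",
    "apply_transform_state",
]


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    kind: str  # "continuous" | "binary"
    log_transform: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"{self.name}: kind must be 'continuous' or 'binary'")
        if self.kind == "binary" and self.log_transform:
            raise ValueError(f"{self.name}: binary features are never log-transformed")


@dataclass
class FeatureMatrix:
    """Standardized, fully imputed G x F feature matrix plus transform state."""

    gene_ids: list[str]
    values: np.ndarray
    specs: list[FeatureSpec]
    transform_state: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        return [s.name for s in self.specs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.feature_names)


def log_transform_column(values, column: str = "<unnamed>") -> tuple[np.ndarray, float]:
    """log(x + delta) with delta = minimum observed positive value.

    Missing entries (NaN) stay missing; they are imputed after
    standardization.
    """
    x = np.asarray(values, dtype=float)
    observed = x[~np.isnan(x)]
    positive = observed[observed > 0]
    if positive.size == 0:
        raise ValueError(
            f"column {column!r} has no positive observed value; cannot log-transform"
        )
    delta = float(positive.min())
    out = np.where(np.isnan(x), np.nan, np.log(x + delta))
    return out, delta


def standardize_column(values, column: str = "<unnamed>") -> tuple[np.ndarray, float, float]:
    """Z-score over non-missing entries with the sample (G-1) standard deviation.

    A constant column maps to all zeros with a warning rather than erroring.
    """
    x = np.asarray(values, dtype=float)
    observed = x[~np.isnan(x)]
    if observed.size < 2:
        raise ValueError(f"column {column!r} needs at least 2 non-missing values")
    mean = float(observed.mean())
    sd = float(observed.std(ddof=1))
    if sd == 0.0:
        warnings.warn(f"column {column!r} is constant; standardized to zeros", stacklevel=2)
        return np.where(np.isnan(x), np.nan, 0.0), mean, 0.0
    return (x - mean) / sd, mean, sd


def impute_missing_column(values, column: str = "<unnamed>") -> tuple[np.ndarray, float]:
    """Replace missing entries with the mean of the non-missing entries."""
    x = np.asarray(values, dtype=float)
    observed = x[~np.isnan(x)]
    if observed.size == 0:
        raise ValueError(f"column {column!r} is entirely missing")
    fill = float(observed.mean())
    return np.where(np.isnan(x), fill, x), fill


def _coerce_binary(values, column: str) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise ValueError(f"binary column {column!r} contains missing values")
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError(f"binary column {column!r} contains values outside {{0, 1}}")
    return x


def build_feature_matrix(raw_table: pd.DataFrame, specs: list[FeatureSpec]) -> FeatureMatrix:
    """Fit the preprocessing pipeline on a raw gene table and return the matrix.

    Per continuous column: optional log transform, then standardization, then
    mean imputation (fill value ~0 by construction).  Binary columns are
    validated and passed through.  Deterministic.
    """
    if len(raw_table) == 0:
        raise ValueError("cannot build a feature matrix from an empty gene table")
    missing = [s.name for s in specs if s.name not in raw_table.columns]
    if missing:
        raise KeyError(f"feature columns absent from table: {missing}")
    columns: list[np.ndarray] = []
    state: dict[str, dict[str, float]] = {}
    for spec in specs:
        raw = raw_table[spec.name].to_numpy(dtype=float)
        if spec.kind == "binary":
            columns.append(_coerce_binary(raw, spec.name))
            state[spec.name] = {}
            continue
        st: dict[str, float] = {}
        x = raw
        if spec.log_transform:
            x, st["delta"] = log_transform_column(x, spec.name)
        x, st["mean"], st["sd"] = standardize_column(x, spec.name)
        x, st["fill"] = impute_missing_column(x, spec.name)
        columns.append(x)
        state[spec.name] = st
    if "gene_id" in raw_table.columns:
        gene_ids = [str(g) for g in raw_table["gene_id"]]
    else:
        gene_ids = [str(g) for g in raw_table.index]
    return FeatureMatrix(
        gene_ids=gene_ids,
        values=np.column_stack(columns),
        specs=list(specs),
        transform_state=state,
    )


def apply_transform_state(
    raw_table: pd.DataFrame, specs: list[FeatureSpec], state: dict[str, dict[str, float]]
) -> np.ndarray:
    """Apply a previously fitted transform to new genes (frozen delta/mean/sd)."""
    columns = []
    for spec in specs:
        raw = raw_table[spec.name].to_numpy(dtype=float)
        if spec.kind == "binary":
            columns.append(_coerce_binary(raw, spec.name))
            continue
        st = state[spec.name]
        x = raw
        if spec.log_transform:
            x = np.where(np.isnan(x), np.nan, np.log(x + st["delta"]))
        if st["sd"] == 0.0:
            x = np.where(np.isnan(x), np.nan, 0.0)
        else:
            x = (x - st["mean"]) / st["sd"]
        x = np.where(np.isnan(x), st["fill"], x)
        columns.append(x)
    return np.column_stack(columns)
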