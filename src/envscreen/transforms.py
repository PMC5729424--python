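"""Variable transformations.

Indicators are transformed to approximate normality before correlation,
PCA, and regression analysis: log10, cube root, square root, or arcsine
square root depending on the variable.  The hospitalization-rate disease
burden uses a modulus transformation sign(sqrt(DB)) * ln(|sqrt(DB)| + 1),
which on nonnegative rates reduces to ln(sqrt(DB) + 1).  Predictors are
standardized (centered, unit sample SD) so fitted coefficients are
comparable across variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import TRANSFORM_KINDS, IndicatorSchema


@dataclass(frozen=True)
class TransformSpec:
    kind: str = "none"
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in TRANSFORM_KINDS + ("modulus",):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.offset < 0:
            raise ValueError("offset must be nonnegative")
        if self.offset != 0.0 and self.kind not in ("log10", "sqrt"):
            raise ValueError("offset only valid for log10/sqrt")


def apply(x, spec: TransformSpec, name: str = "<column>"):
    """Apply ``spec`` elementwise; missing values stay missing.

    Raises ValueError naming the variable on a domain violation
    (nonpositive log10 argument, negative sqrt argument, arcsine input
    outside [0, 1]).
    """
    arr = np.asarray(x, dtype=float)
    out = np.full_like(arr, np.nan)
    ok = ~np.isnan(arr)
    v = arr[ok]
    kind = spec.kind
    if kind == "none":
        out[ok] = v
    elif kind == "log10":
        shifted = v + spec.offset
        if np.any(shifted <= 0):
            bad = v[shifted <= 0][0]
            raise ValueError(f"log10 domain violation in {name}: value {bad!r}")
        out[ok] = np.log10(shifted)
    elif kind == "sqrt":
        shifted = v + spec.offset
        if np.any(shifted < 0):
            bad = v[shifted < 0][0]
            raise ValueError(f"sqrt domain violation in {name}: value {bad!r}")
        out[ok] = np.sqrt(shifted)
    elif kind == "cube_root":
        out[ok] = np.cbrt(v)
    elif kind == "arcsine_sqrt":
        if np.any((v < 0) | (v > 1)):
            bad = v[(v < 0) | (v > 1)][0]
            raise ValueError(
                f"arcsine_sqrt domain violation in {name}: value {bad!r} not in [0,1]"
            )
        out[ok] = np.arcsin(np.sqrt(v))
    elif kind == "modulus":
        out[ok] = modulus_transform(v)
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index, name=x.name)
    if np.isscalar(x):
        return float(out)
    return out


def apply_schema(table: pd.DataFrame, schema: IndicatorSchema) -> pd.DataFrame:
    """Transform every schema column present in ``table``; others pass through."""
    out = table.copy()
    for var in schema:
        if var.name in out.columns:
            spec = TransformSpec(var.transform, var.offset)
            out[var.name] = apply(out[var.name], spec, name=var.name)
    return out


def modulus_transform(db):
    """Modulus transform of a nonnegative rate: sign(sqrt(db))*ln(|sqrt(db)|+1).

    On the nonnegative domain the sign/abs wrappers are inert and the
    transform is ln(sqrt(db)+1): strictly increasing, 0 at 0.
    """
    arr = np.asarray(db, dtype=float)
    ok = ~np.isnan(arr)
    if np.any(arr[ok] < 0):
        raise ValueError("modulus_transform: rates must be nonnegative")
    root = np.sqrt(arr)
    out = np.sign(root) * np.log(np.abs(root) + 1.0)
    if np.isscalar(db):
        return float(out)
    if isinstance(db, pd.Series):
        return pd.Series(out, index=db.index, name=db.name)
    return out


def inverse_modulus(y):
    """Inverse of :func:`modulus_transform` on its range [0, inf)."""
    arr = np.asarray(y, dtype=float)
    ok = ~np.isnan(arr)
    if np.any(arr[ok] < 0):
        raise ValueError("inverse_modulus: argument must be nonnegative")
    out = np.square(np.expm1(arr))
    if np.isscalar(y):
        return float(out)
    return out


def standardize(column):
    """Center and scale to unit sample SD (ddof=1); missing preserved.

    Raises on a constant column or fewer than two distinct observed values.
    """
    arr = np.asarray(column, dtype=float)
    ok = ~np.isnan(arr)
    vals = arr[ok]
    if np.unique(vals).size < 2:
        raise ValueError("standardize: column is constant or has <2 observed values")
    sd = vals.std(ddof=1)
    out = np.full_like(arr, np.nan)
    out[ok] = (vals - vals.mean()) / sd
    if isinstance(column, pd.Series):
        return pd.Series(out, index=column.index, name=column.name)
    return out


def standardize_frame(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    out = table.copy()
    for c in columns if columns is not None else table.columns:
        out[c] = standardize(out[c])
    return out
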