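"""Per-ZCTA disease-burden measure from hospitalization records.

Each hospitalization record carries a zip id and flags for 14 diagnostic
categories (pneumonia, COPD, asthma, MI, CVA, diarrhea, pancreatic
cancer, lung cancer, breast cancer, lymphoma, leukemia, depression,
schizophrenia, low birth weight).  A hospitalization spanning several
categories is counted as a single event; the burden is the deduplicated
event count divided by ZCTA population, modulus-transformed for
analysis.  ZCTAs with population below a threshold (default 100) are
excluded from analysis to avoid unstable small-denominator rates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .transforms import modulus_transform

log = logging.getLogger(__name__)

CATEGORIES = (
    "pneumonia",
    "copd",
    "asthma",
    "mi",
    "cva",
    "diarrhea",
    "pancreatic_cancer",
    "lung_cancer",
    "breast_cancer",
    "lymphoma",
    "leukemia",
    "depression",
    "schizophrenia",
    "low_birth_weight",
)


def apply_category_lookup(
    records: pd.DataFrame,
    lookup: pd.DataFrame,
    code_col: str = "icd9",
    prefix_col: str = "code_prefix",
    category_col: str = "category",
) -> pd.DataFrame:
    """Flag records from raw diagnosis codes via a prefix->category lookup.

    The lookup is an input table (the category definitions name diseases,
    not code lists); a record is flagged for a category when any of its
    codes starts with one of the category's prefixes.
    """
    out = records.copy()
    for cat in CATEGORIES:
        prefixes = tuple(lookup.loc[lookup[category_col] == cat, prefix_col].astype(str))
        if prefixes:
            out[cat] = records[code_col].astype(str).str.startswith(prefixes).astype(int)
        else:
            out[cat] = 0
    return out


def count_events(records: pd.DataFrame, zip_col: str = "zip_id",
                 id_col: str = "record_id") -> pd.Series:
    """Deduplicated per-zip event counts.

    A record with one or more category flags contributes exactly one
    event; zero-flag records contribute nothing.  Duplicate record ids
    are a hard error (double-counting guard).
    """
    if records[id_col].duplicated().any():
        raise ValueError("duplicate record_id in hospitalization records")
    flag_cols = [c for c in CATEGORIES if c in records.columns]
    if not flag_cols:
        raise ValueError("no diagnostic category columns found")
    flagged = records[flag_cols].to_numpy(dtype=float).sum(axis=1) >= 1
    counts = records.loc[flagged].groupby(records.loc[flagged, zip_col]).size()
    counts.name = "event_count"
    counts.index = counts.index.astype(str)
    return counts


def build_burden(
    counts: pd.Series,
    populations: pd.Series,
    over65: pd.Series | None = None,
    threshold: int = 100,
) -> pd.DataFrame:
    """Assemble the per-zip burden table.

    rate = event_count / population; ``included`` is False below the
    population threshold and the modulus-transformed rate is only
    reported for included zips.  Zips with events but no population row
    are dropped with a warning.
    """
    pop = pd.Series(populations).astype(float)
    pop.index = pop.index.astype(str)
    counts = pd.Series(counts).astype(float)
    counts.index = counts.index.astype(str)

    orphan = counts.index.difference(pop.index)
    if len(orphan):
        log.warning("dropping %d zips with events but no population row", len(orphan))
        counts = counts.drop(orphan)

    out = pd.DataFrame(index=pop.index.copy())
    out.index.name = "zip_id"
    out["event_count"] = counts.reindex(pop.index).fillna(0.0)
    out["population"] = pop
    if (out["event_count"] < 0).any() or (out["population"] < 0).any():
        raise ValueError("negative count or population")
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(pop.to_numpy() > 0,
                        out["event_count"].to_numpy() / pop.to_numpy(), np.nan)
    out["rate"] = rate
    out["included"] = (out["population"] >= threshold) & ~np.isnan(rate)
    transformed = np.full(len(out), np.nan)
    inc = out["included"].to_numpy()
    transformed[inc] = modulus_transform(out.loc[inc, "rate"].to_numpy())
    out["transformed"] = transformed
    if over65 is not None:
        o = pd.Series(over65).astype(float)
        o.index = o.index.astype(str)
        out["over65"] = o.reindex(out.index)
    out.attrs["n_excluded_population"] = int((~out["included"]).sum())
    out.attrs["n_orphan_zips"] = int(len(orphan))
    return out
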