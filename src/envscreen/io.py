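"""Reading indicator tables and aligning census tracts to zip-scale units.

Indicator tables are plain :class:`pandas.DataFrame` objects indexed by
geographic unit id, with a ``population`` column plus one column per
schema variable; the unit level ("tract" or "zip") is kept in
``df.attrs["unit_level"]``.  Tract-scale indicators are aligned to the
zip scale by averaging tract values within each zip (the zip link is an
input table, not re-derived from GIS overlays).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import IndicatorSchema

log = logging.getLogger(__name__)

AGG_MODES = ("unweighted_mean", "population_weighted_mean")


def read_indicator_table(
    path,
    schema: IndicatorSchema,
    unit_col: str = "tract_id",
    pop_col: str = "population",
    unit_level: str = "tract",
) -> pd.DataFrame:
    """Read a delimited-text or spreadsheet indicator table.

    Columns are matched to schema names through ``schema.aliases``;
    unknown extra columns are ignored with a warning, unparseable cells
    become missing with a logged count.  Percentage-type variables
    flagged ``is_percentage`` are divided by 100.

    Raises on a missing unit/population column or duplicated unit ids.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        raw = pd.read_csv(path, sep=sep)

    unit_name = None
    pop_name = None
    for c in raw.columns:
        if c == unit_col or schema.aliases.get(c) == unit_col:
            unit_name = c
        if c == pop_col or schema.aliases.get(c) == pop_col:
            pop_name = c
    if unit_name is None:
        raise ValueError(f"mandatory column {unit_col!r} not found in {path}")
    if pop_name is None:
        raise ValueError(f"mandatory column {pop_col!r} not found in {path}")

    if raw[unit_name].duplicated().any():
        dupes = raw.loc[raw[unit_name].duplicated(), unit_name].tolist()
        raise ValueError(f"duplicated unit_id values in {path}: {dupes[:5]}")

    out = pd.DataFrame(index=pd.Index(raw[unit_name].astype(str), name=unit_col))
    pop = pd.to_numeric(raw[pop_name], errors="coerce").to_numpy()
    if np.any(pop[~np.isnan(pop)] < 0):
        raise ValueError("negative population values")
    out["population"] = pop

    n_bad = 0
    unknown = []
    for c in raw.columns:
        if c in (unit_name, pop_name):
            continue
        target = schema.resolve(c)
        if target is None:
            unknown.append(c)
            continue
        col = pd.to_numeric(raw[c], errors="coerce")
        n_bad += int(col.isna().sum() - raw[c].isna().sum())
        if schema[target].is_percentage:
            col = col / 100.0
        out[target] = col.to_numpy()
    if unknown:
        log.warning("ignored %d unknown columns: %s", len(unknown), unknown)
    if n_bad:
        log.info("coerced %d unparseable cells to missing", n_bad)

    out.attrs["unit_level"] = unit_level
    out.attrs["n_unparseable"] = n_bad
    return out


def read_zip_link(path, tract_col: str = "tract_id", zip_col: str = "zip_id") -> pd.Series:
    """Read a two-column tract->zip link table; returns tract-indexed Series."""
    raw = pd.read_csv(path, dtype=str)
    if raw[tract_col].duplicated().any():
        raise ValueError("tract appears more than once in link table")
    return pd.Series(raw[zip_col].values, index=raw[tract_col].values, name="zip_id")


def aggregate_to_zip(
    table: pd.DataFrame,
    link: pd.Series,
    mode: str = "unweighted_mean",
) -> pd.DataFrame:
    """Average a tract-level table to the zip scale.

    Each indicator is the (optionally population-weighted) mean over
    non-missing tract values in the zip; population is summed.  Tracts
    absent from the link are dropped with a logged count; a zip whose
    tracts are all missing a variable carries missing for it.
    """
    if mode not in AGG_MODES:
        raise ValueError(f"mode must be one of {AGG_MODES}")
    link = pd.Series(link)
    in_link = table.index.isin(link.index)
    n_dropped = int((~in_link).sum())
    if n_dropped:
        log.warning("dropping %d tracts absent from zip link", n_dropped)
    sub = table.loc[in_link]
    zips = link.reindex(sub.index)

    value_cols = [c for c in sub.columns if c != "population"]
    grouped = sub.groupby(zips.values)

    pop_sum = grouped["population"].sum(min_count=1)
    if mode == "unweighted_mean":
        agg = grouped[value_cols].mean()
    else:
        def wmean(frame: pd.DataFrame) -> pd.Series:
            res = {}
            wloc = frame["population"].to_numpy(dtype=float)
            for c in value_cols:
                v = frame[c].to_numpy(dtype=float)
                ok = ~np.isnan(v) & ~np.isnan(wloc) & (wloc > 0)
                res[c] = np.average(v[ok], weights=wloc[ok]) if ok.any() else np.nan
            return pd.Series(res)

        agg = grouped[value_cols + ["population"]].apply(wmean)

    out = agg.copy()
    out.insert(0, "population", pop_sum)
    out.index = out.index.astype(str)
    out.index.name = "zip_id"
    out.attrs["unit_level"] = "zip"
    out.attrs["n_dropped_tracts"] = n_dropped
    return out
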