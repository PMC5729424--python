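"""Percentile-rank composite impact score.

The screening score is built in three steps: (1) each indicator is
converted to a percentile rank across units, (2) a weighted average of
percentiles is taken within the environmental block (12 variables) and
within the population block (5 socioeconomic + 3 health variables),
(3) each block average is linearly rescaled to [0, 10] by its maximum and
the two rescaled components are multiplied, giving a score in [0, 100].

Being rank-based, the score is invariant to strictly monotone transforms
of any raw variable, and the multiplicative combination sends a unit with
a zero population component to score zero regardless of its environmental
burden.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .schema import IndicatorSchema, default_schema

TIE_RULES = ("average", "max")


def percentile_rank(column, tie_rule: str = "average"):
    """Percentile = 100 * rank / n over non-missing values; in (0, 100]."""
    if tie_rule not in TIE_RULES:
        raise ValueError(f"tie_rule must be one of {TIE_RULES}")
    arr = np.asarray(column, dtype=float)
    ok = ~np.isnan(arr)
    if not ok.any():
        raise ValueError("percentile_rank: empty column")
    ranks = rankdata(arr[ok], method=tie_rule)
    out = np.full_like(arr, np.nan)
    out[ok] = 100.0 * ranks / ok.sum()
    if isinstance(column, pd.Series):
        return pd.Series(out, index=column.index, name=column.name)
    return out


def group_average(
    percentiles: pd.DataFrame,
    schema: IndicatorSchema,
    group_set,
    min_present: int = 4,
) -> pd.Series:
    """Weighted average of percentile columns, renormalized over present values.

    Units with fewer than ``min_present`` non-missing variables in the
    group get a missing average.
    """
    cols = [c for c in group_set if c in percentiles.columns]
    if not cols:
        raise ValueError("no group variables present in percentile table")
    w = np.array([schema[c].weight for c in cols], dtype=float)
    p = percentiles[cols].to_numpy(dtype=float)
    present = ~np.isnan(p)
    wmat = np.where(present, w, 0.0)
    wsum = wmat.sum(axis=1)
    if np.any((wsum == 0) & (present.sum(axis=1) > 0)):
        raise ValueError("all weights zero over the present variable set")
    num = np.nansum(p * wmat, axis=1)
    avg = np.where(wsum > 0, num / np.where(wsum > 0, wsum, 1.0), np.nan)
    avg = np.where(present.sum(axis=1) >= min_present, avg, np.nan)
    return pd.Series(avg, index=percentiles.index)


def combine(env_avg: pd.Series, pop_avg: pd.Series) -> pd.DataFrame:
    """Rescale each block average to [0, 10] by its max and multiply."""
    frame = pd.DataFrame({"env_avg": env_avg, "pop_avg": pop_avg})
    for name, col in (("env", "env_avg"), ("pop", "pop_avg")):
        mx = frame[col].max(skipna=True)
        if not np.isfinite(mx) or mx == 0:
            raise ValueError(f"cannot rescale {col}: max is 0 or undefined")
        frame[f"{name}_component"] = 10.0 * frame[col] / mx
    frame["score"] = frame["env_component"] * frame["pop_component"]
    return frame


class CumulativeScorer(TransformerMixin, BaseEstimator):
    """Composite impact score as a scikit-learn style transformer.

    ``fit`` stores the per-variable reference distributions (for the
    percentile ECDF) and the block-average maxima; ``transform`` scores a
    table of raw indicator values against that reference.  Calling
    ``fit_transform`` on a full table reproduces the in-sample score.

    Parameters
    ----------
    schema : indicator schema (default: the 20-variable default schema).
    tie_rule : "average" or "max" rank assignment for ties.
    min_present : minimum non-missing variables required per block average.
    """

    def __init__(self, schema: IndicatorSchema | None = None,
                 tie_rule: str = "average", min_present: int = 4):
        self.schema = schema
        self.tie_rule = tie_rule
        self.min_present = min_present

    def _schema(self) -> IndicatorSchema:
        return self.schema if self.schema is not None else default_schema()

    def fit(self, X: pd.DataFrame, y=None) -> "CumulativeScorer":
        schema = self._schema()
        if self.tie_rule not in TIE_RULES:
            raise ValueError(f"tie_rule must be one of {TIE_RULES}")
        self.variables_ = [v.name for v in schema if v.name in X.columns]
        if not self.variables_:
            raise ValueError("no schema variables found in input table")
        self.reference_ = {}
        for name in self.variables_:
            vals = X[name].to_numpy(dtype=float) * schema[name].direction
            vals = np.sort(vals[~np.isnan(vals)])
            if vals.size == 0:
                raise ValueError(f"variable {name} has no observed values")
            self.reference_[name] = vals
        ranks = self._percentiles(X)
        env = group_average(ranks, schema, schema.environmental, self.min_present)
        pop = group_average(ranks, schema, schema.population_chars, self.min_present)
        self.env_max_ = float(env.max(skipna=True))
        self.pop_max_ = float(pop.max(skipna=True))
        if self.env_max_ == 0 or self.pop_max_ == 0:
            raise ValueError("degenerate reference: a block average maximum is 0")
        return self

    def _percentiles(self, X: pd.DataFrame) -> pd.DataFrame:
        schema = self._schema()
        out = {}
        for name in self.variables_:
            ref = self.reference_[name]
            n = ref.size
            x = X[name].to_numpy(dtype=float) * schema[name].direction
            below = np.searchsorted(ref, x, side="left")
            upto = np.searchsorted(ref, x, side="right")
            if self.tie_rule == "average":
                # average rank of x within the reference: mean of the tied span
                rank = np.where(upto > below, (below + 1 + upto) / 2.0, upto)
            else:
                rank = upto.astype(float)
            rank = np.where(np.isnan(x), np.nan, np.maximum(rank, 1e-12))
            out[name] = 100.0 * rank / n
        return pd.DataFrame(out, index=X.index)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Return a table with percentiles, block averages, components, score."""
        if not hasattr(self, "reference_"):
            raise ValueError("CumulativeScorer is not fitted")
        schema = self._schema()
        ranks = self._percentiles(X)
        env = group_average(ranks, schema, schema.environmental, self.min_present)
        pop = group_average(ranks, schema, schema.population_chars, self.min_present)
        out = ranks.add_prefix("pct_")
        out["env_avg"] = env
        out["pop_avg"] = pop
        out["env_component"] = 10.0 * env / self.env_max_
        out["pop_component"] = 10.0 * pop / self.pop_max_
        out["score"] = out["env_component"] * out["pop_component"]
        env_cols = [c for c in schema.environmental if c in self.variables_]
        pop_cols = [c for c in schema.population_chars if c in self.variables_]
        out["n_missing_env"] = ranks[env_cols].isna().sum(axis=1)
        out["n_missing_pop"] = ranks[pop_cols].isna().sum(axis=1)
        return out


def score_table(
    table: pd.DataFrame,
    schema: IndicatorSchema | None = None,
    tie_rule: str = "average",
    min_present: int = 4,
) -> pd.DataFrame:
    """One-shot in-sample scoring of an indicator table."""
    scorer = CumulativeScorer(schema=schema, tie_rule=tie_rule, min_present=min_present)
    return scorer.fit(table).transform(table)
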