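"""Synthetic study inputs: indicators, geography, and hospitalizations.

The generator emulates the structure of the real study inputs so every
downstream stage is testable without external downloads:

* tract-level indicators are Gaussian-copula draws matching a target
  pairwise correlation matrix (default: the published 20-variable
  correlation matrix of the transformed indicator data), back-transformed
  through each variable's inverse schema transform to plausible raw
  scales, with MCAR missingness;
* tracts sit on a regular grid and nest into spatially contiguous zip
  blocks (strips of consecutive tracts within a grid row);
* a per-zip disease-burden surface is generated under the SAR error
  model y = X beta + u, u = (I - lambda W)^-1 eps, on the
  modulus-transformed rate scale, with predictors built from the latent
  factor structure (PC1 of the 17 env+soc latent variables) and a
  per-zip elderly fraction (Over65) negatively correlated with it;
* the rate is inverted to an expected count and integer hospitalization
  events are drawn from a Poisson law, each carrying one or more of the
  14 diagnostic-category flags.

The ``truth`` record keeps the generating parameters and latent scores so
parameter recovery can be scored without re-deriving anything.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .burden import CATEGORIES
from .pca import CorrelationPCA
from .schema import IndicatorSchema, default_schema
from .transforms import inverse_modulus, standardize
from .spatial import SpatialWeights

# Pairwise correlations of the transformed indicator data (lower triangle),
# variable order matching the default schema's print order.
_CORR_ORDER = [
    "ozone", "pm25", "diesel_pm", "traffic", "drinking_water", "pesticides",
    "toxic_release", "cleanup_sites", "groundwater_threats", "haz_waste",
    "impaired_water", "solid_waste", "education", "linguistic_isolation",
    "poverty", "unemployment", "housing_burden", "asthma", "low_birth_weight",
    "cardiovascular",
]

_CORR_LOWER = [
    [0.41],
    [-0.16, 0.41],
    [-0.09, 0.23, 0.56],
    [0.56, 0.35, -0.10, -0.02],
    [0.08, -0.05, -0.30, -0.30, 0.21],
    [0.06, 0.56, 0.54, 0.43, 0.09, -0.24],
    [-0.12, 0.10, 0.20, 0.14, -0.01, -0.01, 0.13],
    [-0.33, -0.05, 0.10, 0.10, -0.12, 0.08, 0.00, 0.44],
    [-0.13, 0.09, 0.28, 0.23, -0.03, -0.02, 0.20, 0.49, 0.39],
    [-0.30, -0.23, -0.09, -0.03, -0.17, 0.14, -0.13, 0.12, 0.22, 0.13],
    [0.03, -0.02, -0.17, -0.04, 0.13, 0.18, -0.02, 0.33, 0.29, 0.31, 0.17],
    [0.06, -0.10, -0.18, -0.08, 0.06, 0.09, -0.12, -0.08, -0.03, -0.13,
     -0.12, 0.19],
    [-0.02, 0.30, 0.43, 0.28, 0.10, -0.07, 0.31, 0.22, 0.13, 0.18, -0.09,
     0.06, 0.70],
    [0.23, 0.22, 0.16, 0.05, 0.18, 0.04, 0.04, 0.19, 0.13, 0.12, -0.11,
     0.17, 0.82, 0.58],
    [0.30, 0.16, 0.00, -0.05, 0.19, 0.04, -0.01, 0.05, 0.02, 0.02, -0.08,
     0.10, 0.51, 0.24, 0.60],
    [0.04, 0.15, 0.29, 0.26, 0.06, -0.16, 0.17, 0.15, 0.10, 0.14, -0.08,
     0.08, 0.57, 0.50, 0.72, 0.40],
    [0.08, 0.12, 0.20, 0.00, -0.04, -0.01, 0.05, 0.13, 0.11, 0.10, -0.05,
     0.08, 0.51, 0.25, 0.53, 0.45, 0.50],
    [0.10, 0.18, 0.19, 0.11, 0.06, -0.09, 0.14, 0.08, 0.00, 0.09, -0.09,
     0.03, 0.33, 0.25, 0.32, 0.27, 0.72, 0.28],
    [0.39, 0.16, 0.02, -0.08, 0.18, 0.08, 0.03, 0.03, -0.05, 0.01, -0.14,
     0.08, 0.46, 0.17, 0.43, 0.44, 0.21, 0.71, 0.24],
]


def default_target_corr() -> pd.DataFrame:
    """The default 20x20 target correlation matrix (symmetric, unit diag)."""
    p = len(_CORR_ORDER)
    mat = np.eye(p)
    for i, row in enumerate(_CORR_LOWER, start=1):
        if len(row) != i:
            raise RuntimeError("malformed correlation template")
        mat[i, :i] = row
        mat[:i, i] = row
    return pd.DataFrame(mat, index=_CORR_ORDER, columns=_CORR_ORDER)


def one_factor_corr(loading: float = 0.8, names=None) -> pd.DataFrame:
    """Single-factor correlation matrix R = ll' + (1 - l^2) I."""
    names = list(names) if names is not None else _CORR_ORDER
    p = len(names)
    lvec = np.full(p, float(loading))
    mat = np.outer(lvec, lvec)
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=names, columns=names)


def nearest_positive_definite(corr: np.ndarray, min_eig: float = 1e-8):
    """Eigenvalue clipping followed by rescaling to unit diagonal.

    Returns (repaired, max_abs_change).  Matrices assembled from
    pairwise-complete correlations can be indefinite; clipping preserves
    the overall structure.
    """
    sym = 0.5 * (corr + corr.T)
    vals, vecs = np.linalg.eigh(sym)
    clipped = np.maximum(vals, min_eig)
    rep = vecs @ np.diag(clipped) @ vecs.T
    d = np.sqrt(np.diag(rep))
    rep = rep / np.outer(d, d)
    np.fill_diagonal(rep, 1.0)
    return rep, float(np.max(np.abs(rep - sym)))


@dataclass
class SyntheticConfig:
    """Generator configuration; defaults are the study conditions.

    The default grid (90 x 90 tracts, 5 tracts per zip) matches the scale
    of the real analysis (~8000 tracts, ~1600 zip units); ``beta_true``
    defaults to the fitted disease-burden model (standardized-predictor
    coefficients 0.47 on the first combined factor and 0.59 on Over65)
    around a baseline modulus-rate level of 0.37 (~0.2 hospitalizations
    per person over a four-year window); ``burden_scale`` maps one
    standardized-response unit onto the modulus-rate scale (default 0.1,
    keeping zip rates within a realistic 0.01-0.6 band).
    """

    n_rows: int = 90
    n_cols: int = 90
    tracts_per_zip: int = 5
    target_corr: pd.DataFrame | None = None
    lambda_true: float = 0.6
    beta_true: dict = field(default_factory=lambda: {"PC1all": 0.47, "Over65": 0.59})
    baseline: float = 0.37
    burden_scale: float = 0.1
    sigma_eps: float = 0.45
    missing_rate: float = 0.02
    pop_range: tuple = (300, 3000)
    multi_category_rate: float = 0.1
    over65_corr: float = -0.45
    over65_mean: float = 0.14
    over65_sd: float = 0.04
    max_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.tracts_per_zip < 1:
            raise ValueError("tracts_per_zip must be positive")
        if not -1 < self.lambda_true < 1:
            raise ValueError("lambda_true must lie in (-1, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.pop_range[0] < 1 or self.pop_range[1] < self.pop_range[0]:
            raise ValueError("pop_range must satisfy 1 <= min <= max")
        if not 0 <= self.multi_category_rate <= 1:
            raise ValueError("multi_category_rate must lie in [0, 1]")

    def corr(self) -> pd.DataFrame:
        c = self.target_corr if self.target_corr is not None else default_target_corr()
        if not isinstance(c, pd.DataFrame):
            raise ValueError("target_corr must be a named DataFrame")
        arr = c.to_numpy(dtype=float)
        if arr.shape[0] != arr.shape[1]:
            raise ValueError("target_corr must be square")
        if not np.allclose(arr, arr.T, atol=1e-10):
            raise ValueError("target_corr must be symmetric")
        if not np.allclose(np.diag(arr), 1.0, atol=1e-10):
            raise ValueError("target_corr must have unit diagonal")
        return c

    @classmethod
    def from_json(cls, source) -> "SyntheticConfig":
        if hasattr(source, "read"):
            payload = json.load(source)
        elif str(source).lstrip().startswith("{"):
            payload = json.loads(str(source))
        else:
            with open(source) as fh:
                payload = json.load(fh)
        corr = payload.pop("target_corr", None)
        cfg = cls(**payload)
        if corr is not None:
            cfg.target_corr = pd.DataFrame(
                corr["values"], index=corr["names"], columns=corr["names"]
            )
        if isinstance(cfg.pop_range, list):
            cfg.pop_range = tuple(cfg.pop_range)
        return cfg

    def to_json(self) -> str:
        payload = asdict(self)
        if self.target_corr is not None:
            payload["target_corr"] = {
                "names": list(self.target_corr.columns),
                "values": self.target_corr.to_numpy().tolist(),
            }
        payload["pop_range"] = list(self.pop_range)
        return json.dumps(payload, indent=2)


@dataclass
class SyntheticLandscape:
    """Generated study inputs plus the generating truth."""

    indicator_table: pd.DataFrame
    zip_assignment: pd.Series  # tract_id -> zip_id
    tract_grid: tuple  # (n_rows, n_cols)
    truth: dict

    def tract_weights(self, scheme: str = "queen") -> SpatialWeights:
        nr, nc = self.tract_grid
        return SpatialWeights.grid(nr, nc, scheme=scheme,
                                   ids=list(self.indicator_table.index))

    def zip_weights(self, scheme: str = "queen") -> SpatialWeights:
        """Zip contiguity projected from tract contiguity."""
        tw = self.tract_weights(scheme=scheme)
        za = self.zip_assignment
        zips = list(dict.fromkeys(za.values))
        nb = {z: set() for z in zips}
        for tract, js in tw.neighbors.items():
            zi = za[tract]
            for j in js:
                zj = za[j]
                if zj != zi:
                    nb[zi].add(zj)
                    nb[zj].add(zi)
        return SpatialWeights(zips, {z: sorted(v) for z, v in nb.items()})

    def tract_geometry(self, cell: float = 1.0) -> dict:
        """GeoJSON FeatureCollection of unit-square tract polygons."""
        nr, nc = self.tract_grid
        feats = []
        for k, tid in enumerate(self.indicator_table.index):
            r, c = divmod(k, nc)
            x0, y0 = c * cell, (nr - 1 - r) * cell
            ring = [[x0, y0], [x0 + cell, y0], [x0 + cell, y0 + cell],
                    [x0, y0 + cell], [x0, y0]]
            feats.append({
                "type": "Feature",
                "properties": {"tract_id": tid, "zip_id": self.zip_assignment[tid]},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            })
        return {"type": "FeatureCollection", "features": feats}


def _zip_blocks(n_rows: int, n_cols: int, tracts_per_zip: int) -> list[str]:
    """Zip label per tract (row-major): strips of consecutive tracts within
    a row; a short final strip in each row is absorbed into the previous zip."""
    labels = []
    for r in range(n_rows):
        n_full = max(n_cols // tracts_per_zip, 1)
        for c in range(n_cols):
            b = min(c // tracts_per_zip, n_full - 1)
            labels.append(f"z{r}_{b}")
    return labels


def _inverse_marginal(z: np.ndarray, var) -> np.ndarray:
    """Map standard-normal latents to a plausible raw scale whose schema
    transform approximately restores normality (marginals are package
    assumptions; the copula controls the dependence structure)."""
    kind = var.transform
    if kind == "log10":
        return np.power(10.0, 1.0 + 0.5 * z) - var.offset
    if kind == "cube_root":
        return np.clip(2.5 + 0.5 * z, 0.0, None) ** 3
    if kind == "sqrt":
        return np.clip(5.0 + 1.0 * z, 0.0, None) ** 2 - var.offset
    if kind == "arcsine_sqrt":
        return np.sin(np.clip(0.7 + 0.18 * z, 0.0, np.pi / 2)) ** 2
    return 10.0 + 2.0 * z  # untransformed variables


def generate_indicators(
    config: SyntheticConfig,
    schema: IndicatorSchema | None = None,
) -> SyntheticLandscape:
    """Draw the tract-level indicator table and grid/zip structure."""
    schema = schema if schema is not None else default_schema()
    rng = np.random.default_rng(config.seed)
    corr = config.corr()
    names = list(corr.columns)
    for name in names:
        if name not in schema:
            raise ValueError(f"target_corr variable {name!r} not in schema")

    repaired, delta = nearest_positive_definite(corr.to_numpy(dtype=float))
    repair_warning = delta > 0.1
    chol = np.linalg.cholesky(repaired)

    n = config.n_rows * config.n_cols
    latent = rng.standard_normal((n, len(names))) @ chol.T
    latent_df = pd.DataFrame(latent, columns=names)

    tract_ids = [f"t{k:05d}" for k in range(n)]
    table = pd.DataFrame(index=pd.Index(tract_ids, name="tract_id"))
    table["population"] = rng.integers(config.pop_range[0],
                                       config.pop_range[1] + 1, size=n)
    for j, name in enumerate(names):
        table[name] = _inverse_marginal(latent[:, j], schema[name])

    if config.missing_rate > 0:
        mask = rng.random((n, len(names))) < config.missing_rate
        vals = table[names].to_numpy()
        vals[mask] = np.nan
        table[names] = vals

    # latent factors (PCs of the latent normal columns): the generating-truth
    # counterparts of the principal components the analysis will estimate
    def _factor_scores(cols, k=2):
        if len(cols) >= 2:
            pca = CorrelationPCA(n_components=k).fit(latent_df[cols])
            f = pca.transform(latent_df[cols])
            return [standardize(f[f"PC{i + 1}"].to_numpy()) for i in range(k)]
        base = standardize(latent[:, 0])
        return [base] + [np.zeros(n)] * (k - 1)

    subset17 = [v for v in schema.environmental + schema.socioeconomic
                if v in names]
    f1, f2 = _factor_scores(subset17)
    f1soc, f2soc = _factor_scores([v for v in schema.socioeconomic if v in names])
    f1env, f2env = _factor_scores([v for v in schema.environmental if v in names])

    zip_labels = _zip_blocks(config.n_rows, config.n_cols, config.tracts_per_zip)
    assignment = pd.Series(zip_labels, index=table.index, name="zip_id")

    truth = {
        "config": config,
        "target_corr": corr,
        "repaired_corr": pd.DataFrame(repaired, index=names, columns=names),
        "repair_max_change": delta,
        "repair_warning": repair_warning,
        "factor_scores": pd.DataFrame(
            {"f1": f1, "f2": f2, "f1soc": f1soc, "f2soc": f2soc,
             "f1env": f1env, "f2env": f2env},
            index=table.index),
        "latent": latent_df.set_index(table.index),
    }
    return SyntheticLandscape(indicator_table=table, zip_assignment=assignment,
                              tract_grid=(config.n_rows, config.n_cols),
                              truth=truth)


def generate_disease(
    landscape: SyntheticLandscape, config: SyntheticConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw hospitalization records and the per-zip population table.

    Returns ``(records, zip_table)``: records with one row per
    hospitalization (record_id, zip_id, year, 14 binary category flags),
    and a zip table with population and the Over65 fraction.  Updates
    ``landscape.truth`` with the generating surface (lambda, beta, the
    transformed-burden vector, clip counts).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    za = landscape.zip_assignment
    zips = list(dict.fromkeys(za.values))
    pop = landscape.indicator_table["population"].groupby(za).sum().reindex(zips)

    fs = landscape.truth["factor_scores"]
    zip_factors = {c: standardize(fs[c].groupby(za).mean().reindex(zips).to_numpy())
                   for c in fs.columns}
    pc1 = zip_factors["f1"]

    eta = rng.standard_normal(len(zips))
    r = config.over65_corr
    o_latent = r * pc1 + np.sqrt(1.0 - r * r) * eta
    over65 = np.clip(config.over65_mean + config.over65_sd * o_latent, 0.02, 0.45)
    over65_pred = standardize(np.sqrt(over65))

    predictors = {"PC1all": pc1, "PC2all": zip_factors["f2"],
                  "PC1soc": zip_factors["f1soc"], "PC2soc": zip_factors["f2soc"],
                  "PC1env": zip_factors["f1env"], "PC2env": zip_factors["f2env"],
                  "Over65": over65_pred, "intercept": np.ones(len(zips))}
    x_cols = []
    beta = []
    for name, b in config.beta_true.items():
        if name not in predictors:
            raise ValueError(f"beta_true names unknown predictor {name!r}")
        x_cols.append(predictors[name])
        beta.append(float(b))
    xb = (np.column_stack(x_cols) @ np.array(beta)) if x_cols else np.zeros(len(zips))

    w = landscape.zip_weights().dense()
    eps = config.sigma_eps * rng.standard_normal(len(zips))
    u = np.linalg.solve(np.eye(len(zips)) - config.lambda_true * w, eps)
    # beta_true is on the standardized-response scale (as fitted models
    # report it); burden_scale maps that model onto the modulus-rate scale
    # around the baseline level.
    y = config.baseline + config.burden_scale * (xb + u)

    n_clip_low = int((y < 0).sum())
    rate = inverse_modulus(np.clip(y, 0.0, None))
    n_clip_high = int((rate > config.max_rate).sum())
    rate = np.clip(rate, 0.0, config.max_rate)

    expected = rate * pop.to_numpy()
    counts = rng.poisson(expected)

    total = int(counts.sum())
    zip_rep = np.repeat(np.array(zips, dtype=object), counts)
    years = rng.integers(2008, 2012, size=total)
    primary = rng.integers(0, len(CATEGORIES), size=total)
    flags = np.zeros((total, len(CATEGORIES)), dtype=np.int8)
    flags[np.arange(total), primary] = 1
    multi = rng.random(total) < config.multi_category_rate
    extra = rng.integers(1, len(CATEGORIES), size=total)
    second = (primary + extra) % len(CATEGORIES)
    flags[np.where(multi)[0], second[multi]] = 1

    records = pd.DataFrame({
        "record_id": [f"h{k:08d}" for k in range(total)],
        "zip_id": zip_rep,
        "year": years,
    })
    for c, cat in enumerate(CATEGORIES):
        records[cat] = flags[:, c]

    zip_table = pd.DataFrame({"population": pop.to_numpy(),
                              "over65": over65},
                             index=pd.Index(zips, name="zip_id"))

    landscape.truth.update({
        "lambda": config.lambda_true,
        "beta": dict(config.beta_true),
        "sigma_eps": config.sigma_eps,
        "transformed_burden": pd.Series(y, index=zips),
        "rate": pd.Series(rate, index=zips),
        "zip_pc1": pd.Series(pc1, index=zips),
        "zip_over65_pred": pd.Series(over65_pred, index=zips),
        "n_clip_low": n_clip_low,
        "n_clip_high": n_clip_high,
    })
    return records, zip_table


def write_landscape(landscape: SyntheticLandscape, records: pd.DataFrame,
                    zip_table: pd.DataFrame, out_dir, schema=None) -> None:
    """Write generated inputs as delimited text + JSON sidecars."""
    from pathlib import Path

    schema = schema if schema is not None else default_schema()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    landscape.indicator_table.to_csv(out / "indicators.csv")
    landscape.zip_assignment.rename("zip_id").to_csv(out / "zip_link.csv")
    records.to_csv(out / "hospitalizations.csv", index=False)
    zip_table.to_csv(out / "zip_population.csv")
    schema.to_json(out / "schema.json")
    with open(out / "geometry.geojson", "w") as fh:
        json.dump(landscape.tract_geometry(), fh)
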