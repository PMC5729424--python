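"""End-to-end orchestration: simulate/ingest -> transform -> score ->
impute + PCA -> burden -> align -> spatial regression -> report.

A run is driven by a single :class:`RunConfig` (real input paths XOR a
synthetic configuration).  The report carries every table needed to
reproduce the headline outputs: the correlation matrix of transformed
indicators, PCA variance-explained tables, the Spearman table of the
composite score against each principal component, and the two SAR model
families (combined-factor predictors vs separate environmental /
socioeconomic factors) with selection traces and pseudo-R^2 ablations.
"""

from __future__ import annotations

import json
import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import burden as burden_mod
from . import io as io_mod
from .pca import CorrelationPCA, PCAImputer, spearman
from .schema import IndicatorSchema, default_schema
from .scoring import score_table
from .simulate import SyntheticConfig, generate_disease, generate_indicators
from .spatial import SpatialWeights, morans_i, select_model
from .transforms import apply_schema, standardize

log = logging.getLogger(__name__)

PCA_SUBSETS = ("env", "soc", "all17", "all20")


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Exactly one of ``synthetic`` or ``paths`` must be provided.  ``paths``
    is a mapping with keys indicators, zip_link, records, zip_population,
    and optionally weights (GAL file).
    """

    synthetic: SyntheticConfig | None = None
    paths: dict | None = None
    schema: IndicatorSchema | None = None
    aggregation_mode: str = "unweighted_mean"
    pca_subsets: tuple = PCA_SUBSETS
    population_threshold: int = 100
    min_present: int = 4
    ncp: int = 2
    seed: int = 0
    moran_permutations: int = 499

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.paths is None):
            raise ValueError("exactly one of synthetic config or input paths required")

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            payload = json.load(source)
        elif str(source).lstrip().startswith("{"):
            payload = json.loads(str(source))
        else:
            with open(source) as fh:
                payload = json.load(fh)
        synth = payload.pop("synthetic", None)
        schema = payload.pop("schema", None)
        cfg = cls(
            synthetic=SyntheticConfig(**synth) if synth is not None else None,
            schema=IndicatorSchema.from_json(json.dumps(schema)) if schema else None,
            **payload,
        )
        return cfg


@dataclass
class RunReport:
    """Serializable record of a pipeline run."""

    stages: dict = field(default_factory=dict)
    correlation: pd.DataFrame | None = None
    variance_tables: dict = field(default_factory=dict)
    spearman_table: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, pd.DataFrame):
                return {"columns": list(map(str, obj.columns)),
                        "index": list(map(str, obj.index)),
                        "values": np.round(obj.to_numpy(dtype=float), 10).tolist()}
            if isinstance(obj, (np.floating, float)):
                return round(float(obj), 10)
            if isinstance(obj, (np.integer, int)):
                return int(obj)
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in obj.items()}
            return obj

        return clean({
            "stages": self.stages,
            "correlation": self.correlation,
            "variance_tables": self.variance_tables,
            "spearman": self.spearman_table,
            "models": self.models,
            "manifest": self.manifest,
        })

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _model_record(sel) -> dict:
    fit = sel.model
    return {
        "terms": sel.terms,
        "coef": {n: float(c) for n, c in zip(fit.names_, fit.coef_)},
        "se": {n: float(s) for n, s in zip(fit.names_, fit.stderr_)},
        "p": {n: float(p) for n, p in zip(fit.names_, fit.pvalues_)},
        "lambda": fit.lambda_,
        "lambda_se": fit.lambda_se_,
        "sigma2": fit.sigma2_,
        "loglik": fit.loglik_,
        "bic": fit.bic_,
        "n": fit.n_,
        "k": fit.k_,
        "lr_lambda_p": fit.lr_lambda_p_,
        "nagelkerke_r2": fit.nagelkerke_r2_,
        "r2_ablation": sel.r2_ablation,
        "n_selection_steps": len(sel.trace),
    }


def run(config: RunConfig) -> RunReport:
    """Execute the full analysis; identical config + seed give identical reports."""
    schema = config.schema if config.schema is not None else default_schema()
    report = RunReport()

    # ---- stage 1: inputs ---------------------------------------------------
    if config.synthetic is not None:
        landscape = generate_indicators(config.synthetic, schema)
        records, zip_table = generate_disease(landscape, config.synthetic)
        tracts = landscape.indicator_table
        link = landscape.zip_assignment
        weights = landscape.zip_weights()
    else:
        p = config.paths
        tracts = io_mod.read_indicator_table(p["indicators"], schema)
        link = io_mod.read_zip_link(p["zip_link"])
        records = pd.read_csv(p["records"])
        zip_table = pd.read_csv(p["zip_population"], index_col=0)
        zip_table.index = zip_table.index.astype(str)
        weights = SpatialWeights.read_gal(p["weights"])
        landscape = None
    indicator_cols = [v.name for v in schema if v.name in tracts.columns]
    report.stages["inputs"] = {
        "n_tracts": int(len(tracts)),
        "n_zip_units": int(len(zip_table)),
        "n_records": int(len(records)),
        "n_missing_cells": int(tracts[indicator_cols].isna().sum().sum()),
    }

    # ---- stage 2: transform + correlation matrix ---------------------------
    transformed = apply_schema(tracts, schema)
    corr = transformed[indicator_cols].corr(method="pearson", min_periods=2)
    report.correlation = corr.round(4)

    # ---- stage 3: composite score (raw tract table; rank-based) ------------
    scores = score_table(tracts, schema, min_present=config.min_present)
    n_unscored = int(scores["score"].isna().sum())
    report.stages["score"] = {
        "n_scored": int(scores["score"].notna().sum()),
        "n_unscored_missing_block": n_unscored,
    }

    # ---- stage 4: impute + PCA per subset ----------------------------------
    imputer = PCAImputer(ncp=config.ncp)
    completed = imputer.fit_transform(transformed[indicator_cols])
    report.stages["imputation"] = {
        "n_filled": int(imputer.filled_mask_.sum()),
        "n_iter": imputer.n_iter_,
        "converged": bool(imputer.converged_),
    }
    pca_scores: dict[str, pd.DataFrame] = {}
    for subset in config.pca_subsets:
        cols = [c for c in schema.subset(subset) if c in completed.columns]
        model = CorrelationPCA().fit(completed[cols])
        pca_scores[subset] = model.transform(completed[cols])
        report.variance_tables[subset] = {
            "eigenvalues": [float(e) for e in model.eigenvalues_[:5]],
            "var_explained": [float(v) for v in model.var_explained_[:5]],
        }

    # ---- stage 5: score vs PC concordance ----------------------------------
    sc = scores["score"]
    table = {}
    for subset, comp in (("all20", "PC1"), ("all20", "PC2"), ("all20", "PC3"),
                         ("env", "PC1"), ("env", "PC2"),
                         ("soc", "PC1"), ("soc", "PC2")):
        if subset in pca_scores and comp in pca_scores[subset]:
            rho = spearman(sc.to_numpy(),
                           pca_scores[subset][comp].to_numpy())
            table[f"{comp}{subset}"] = round(float(rho), 4)
    report.spearman_table = table

    # ---- stage 6: disease burden -------------------------------------------
    counts = burden_mod.count_events(records)
    db = burden_mod.build_burden(counts, zip_table["population"],
                                 over65=zip_table.get("over65"),
                                 threshold=config.population_threshold)
    report.stages["burden"] = {
        "n_zips": int(len(db)),
        "n_included": int(db["included"].sum()),
        "n_excluded_population": db.attrs["n_excluded_population"],
        "n_orphan_zips": db.attrs["n_orphan_zips"],
        "total_events": int(db["event_count"].sum()),
    }

    # ---- stage 7: align PC scores to zip scale ------------------------------
    zip_preds = {}
    for subset in ("all17", "env", "soc"):
        if subset not in pca_scores:
            continue
        sub = pca_scores[subset].copy()
        sub["population"] = tracts["population"]
        agg = io_mod.aggregate_to_zip(sub, link, mode=config.aggregation_mode)
        zip_preds[subset] = agg.drop(columns="population")

    analysis = db.loc[db["included"]].copy()
    keep = [z for z in analysis.index if z in weights._pos]
    analysis = analysis.loc[keep]
    w_fit = weights.subset(analysis.index)
    if w_fit.islands:
        analysis = analysis.drop(index=w_fit.islands)
        w_fit = w_fit.subset(analysis.index)
        report.stages.setdefault("burden", {})["n_island_excluded"] = len(
            set(db.index) - set(analysis.index))

    y = standardize(analysis["transformed"].to_numpy())

    def prepared(subset, rename):
        frame = zip_preds[subset].reindex(analysis.index)
        frame = frame.rename(columns=rename)
        return frame

    fam1 = prepared("all17", {"PC1": "PC1all", "PC2": "PC2all", "PC3": "PC3all"})
    fam1 = fam1[["PC1all", "PC2all", "PC3all"]]
    fam2 = pd.concat(
        [prepared("env", {"PC1": "PC1env", "PC2": "PC2env"})[["PC1env", "PC2env"]],
         prepared("soc", {"PC1": "PC1soc", "PC2": "PC2soc"})[["PC1soc", "PC2soc"]]],
        axis=1,
    )
    over65_col = analysis.get("over65")
    for fam in (fam1, fam2):
        if over65_col is not None:
            fam["Over65"] = np.sqrt(over65_col.to_numpy(dtype=float))
        for c in fam.columns:
            fam[c] = standardize(fam[c].to_numpy())

    # ---- stage 8: Moran diagnostics + SAR selection -------------------------
    mor = morans_i(y, w_fit, n_perm=config.moran_permutations, seed=config.seed)
    report.stages["moran_burden"] = {"I": round(mor.I, 6), "p": mor.p_value}

    for name, fam in (("combined_factors", fam1), ("separate_factors", fam2)):
        sel = select_model(y, fam, w_fit)
        rec = _model_record(sel)
        resid_m = sel.model.residual_moran(n_perm=config.moran_permutations,
                                           seed=config.seed + 1)
        rec["moran_resid_I"] = round(resid_m.I, 6)
        rec["moran_resid_p"] = resid_m.p_value
        report.models[name] = rec

    # ---- conservation accounting -------------------------------------------
    report.stages["conservation"] = {
        "zips_in": int(len(db)),
        "zips_analyzed": int(len(analysis)),
        "excluded_population": db.attrs["n_excluded_population"],
        "excluded_other": int(len(db) - len(analysis)
                              - db.attrs["n_excluded_population"]),
    }
    return report


def export_choropleth(values: pd.Series, geometry: dict, path,
                      key: str = "zip_id", n_classes: int = 5,
                      image_path=None) -> dict:
    """Write a GeoJSON layer carrying ``value`` and a quantile class.

    ``geometry`` is a GeoJSON FeatureCollection whose features carry the
    unit id in ``properties[key]``.  An id mismatch above 5% is an error;
    a smaller mismatch is a logged warning.
    """
    values = pd.Series(values)
    values.index = values.index.astype(str)
    feats = geometry.get("features", [])
    ids = [str(f["properties"].get(key)) for f in feats]
    missing = [i for i in ids if i not in values.index]
    if feats and len(missing) > 0.05 * len(feats):
        raise ValueError(f"{len(missing)}/{len(feats)} geometry ids lack values")
    if missing:
        log.warning("%d geometry ids lack values: %s", len(missing), missing[:10])

    vals = values.reindex([i for i in ids if i in values.index]).to_numpy(dtype=float)
    finite = vals[~np.isnan(vals)]
    if finite.size and np.unique(finite).size > 1:
        qs = np.quantile(finite, np.linspace(0, 1, n_classes + 1))
        qs = np.unique(qs)
    else:
        qs = np.array([finite.min(), finite.max()]) if finite.size else np.array([0, 1])

    out = {"type": "FeatureCollection", "features": []}
    for f in feats:
        uid = str(f["properties"].get(key))
        val = float(values.get(uid, np.nan))
        cls = int(np.clip(np.searchsorted(qs, val, side="right") - 1,
                          0, max(len(qs) - 2, 0))) if not np.isnan(val) else None
        g = {"type": "Feature", "geometry": f["geometry"],
             "properties": {**f["properties"], "value": None if np.isnan(val) else val,
                            "class": cls}}
        out["features"].append(g)
    with open(path, "w") as fh:
        json.dump(out, fh)

    if image_path is not None:
        _render_choropleth(out, image_path, n_classes=max(len(qs) - 1, 1))
    return out


def _render_choropleth(collection: dict, image_path, n_classes: int = 5) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection

    polys, classes = [], []
    for f in collection["features"]:
        geom = f["geometry"]
        if geom["type"] != "Polygon" or f["properties"].get("class") is None:
            continue
        polys.append(np.asarray(geom["coordinates"][0]))
        classes.append(f["properties"]["class"])
    fig, ax = plt.subplots(figsize=(6, 6))
    if polys:
        pc = PolyCollection(polys, array=np.asarray(classes, dtype=float),
                            cmap="viridis", edgecolor="none")
        ax.add_collection(pc)
        ax.autoscale()
        fig.colorbar(pc, ax=ax, label="quantile class")
    ax.set_aspect("equal")
    fig.savefig(image_path, dpi=100)
    plt.close(fig)


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
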