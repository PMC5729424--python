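# envscreen

Cumulative environmental-health screening analysis for small-area
indicator data — built for environmental epidemiologists and
environmental-justice analysts who work with screening tools like
California's CalEnviroScreen and want to validate composite scores
against multivariate structure and health outcomes.

The package covers the full analysis chain:

1. **Composite impact score.** Each of 20 tract-level indicators
   (12 environmental, 5 socioeconomic, 3 health outcomes) is percentile
   ranked; weighted block averages are rescaled to [0, 10] and
   multiplied:

   `score = 10 · P̄_env / max(P̄_env) × 10 · P̄_pop / max(P̄_pop) ∈ [0, 100]`

2. **PCA alternate scoring.** Regularized iterative PCA imputation of
   missing cells, then PCA on the correlation matrix for the standard
   variable subsets (all 20, the 17 non-health variables, 12
   environmental, 5 socioeconomic), with Spearman rank correlation of
   the composite score against each component.

3. **Disease burden.** Per-zip deduplicated hospitalization events over
   14 diagnostic categories, divided by population (zips under 100
   persons excluded), normalized by the modulus transform
   `sign(√DB)·ln(|√DB|+1)`.

4. **Spatial regression.** Maximum-likelihood SAR spatial-error models
   `y = Xβ + u, u = λWu + ε` on queen-contiguity row-standardized
   weights, with Moran permutation diagnostics, likelihood-ratio test of
   λ, BIC + p-value term selection (ΔBIC ≥ 2, α = 0.05), and Nagelkerke
   pseudo-R² with per-term ablations.

A first-class synthetic-data generator reproduces the study design —
Gaussian-copula indicators matching the published 20-variable
correlation matrix, contiguous tract→zip nesting, a SAR burden surface,
and Poisson hospitalization events — so the whole chain is testable
without external downloads. See `docs/methods.md` for models,
assumptions, and defaults.

Core classes follow scikit-learn conventions (`fit`/`transform`/
`predict`, trailing-underscore fitted attributes): `CumulativeScorer`,
`PCAImputer`, `CorrelationPCA`, `SpatialErrorModel`.

## Worked example

```python
import envscreen as es

cfg = es.SyntheticConfig(n_rows=30, n_cols=30, tracts_per_zip=5, seed=7)
report = es.run(es.RunConfig(synthetic=cfg, seed=7, moran_permutations=199))

ve = report.variance_tables
print("PC1 variance explained (all 20 vars): "
      f"{ve['all20']['var_explained'][0]:.1%}")
print("first two socioeconomic PCs:         "
      f"{sum(ve['soc']['var_explained'][:2]):.1%}")
print("Spearman rho, score vs PC1(all):      "
      f"{report.spearman_table['PC1all20']:.2f}")

m = report.models["combined_factors"]
terms = " + ".join(f"({m['coef'][t]:.2f} ± {m['se'][t]:.3f}) {t}" for t in m["terms"])
print(f"selected SAR model: burden = {terms}")
print(f"lambda = {m['lambda']:.2f}, Nagelkerke R2 = {m['nagelkerke_r2']:.2f}")
print(f"R2 without Over65: {m['r2_ablation'].get('Over65'):.2f}, "
      f"without PC1all: {m['r2_ablation'].get('PC1all'):.2f}")
```

prints

```
PC1 variance explained (all 20 vars): 23.9%
first two socioeconomic PCs:         80.8%
Spearman rho, score vs PC1(all):      0.97
selected SAR model: burden = (0.73 ± 0.045) Over65 + (0.57 ± 0.045) PC1all
lambda = 0.52, Nagelkerke R2 = 0.70
R2 without Over65: 0.17, without PC1all: 0.37
```

Reading the output: the first principal component of the full indicator
set carries about a quarter of the variance and the composite score
tracks it almost perfectly in rank (ρ = 0.97) — the multiplicative
score captures the dominant joint gradient of hazard and vulnerability.
Two of nine candidate terms survive BIC/p selection: the combined
first factor and the elderly-population share, with coefficients on
standardized variables directly comparable in magnitude. The fitted
spatial dependence λ = 0.52 reflects the autocorrelated error surface
the generator planted (λ_true = 0.6 at this modest 180-zip size), and
ablating Over65 costs far more explained variation than ablating the
factor — age structure must be accounted for before reading the
environmental/socioeconomic signal.

The same stages are scriptable from a shell:

```sh
envscreen simulate --out data/ --seed 1
envscreen score   --table data/indicators.csv --out scores.csv
envscreen burden  --records data/hospitalizations.csv --pop data/zip_population.csv --out burden.csv
envscreen run     --config run.json --out report.json
```

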