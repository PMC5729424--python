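# Methods

`envscreen` implements a cumulative environmental-health screening
analysis over small-area indicator data: a multiplicative percentile-rank
impact score, a PCA-based alternate scoring of the same indicators, a
hospitalization-based disease-burden measure, and spatial-error
regression relating the dominant environmental and socioeconomic
gradients to that burden. This note records the models, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter.

## The composite impact score

Each of 20 indicators (12 environmental — 7 exposures, 5 environmental
effects; 5 socioeconomic; 3 health outcomes) is converted to a percentile
rank `100 * rank / n` over the units with observed values (average-rank
ties by default; a max-rank variant is available — the exact convention
used upstream by the screening tool's authors is not published, so both
are exposed). A weighted average of percentiles is formed within the
environmental block and within the population block (socioeconomic +
health), weights renormalized over the non-missing variables; a unit
needs at least `min_present = 4` observed variables per block (the
published tool leaves a small number of tracts unscored without stating
its exact rule, so the threshold is package policy). Each block average
is rescaled to [0, 10] by its maximum over units, and the two components
are multiplied, giving a score in [0, 100]. Default weights follow the
screening tool's documented convention: exposures and population
variables weight 1.0, environmental-effect variables weight 0.5; all
weights are configurable in the schema.

Because the score is rank-based it is invariant to strictly monotone
transformations of any raw variable, and a zero in either block forces a
zero score — both properties are tested.

The `CumulativeScorer` estimator separates `fit` (store per-variable
reference distributions and block maxima) from `transform` (score any
table against that reference), so new or hypothetical units can be scored
against a fixed baseline; `fit_transform` reproduces in-sample scoring.

## Variable transforms and standardization

Indicators are transformed toward normality before correlation, PCA and
regression: log10 (count-like variables, with a configurable offset of 1
for columns containing zeros), cube root, square root, arcsine square
root (drinking-water contamination, as a proportion), with PM2.5 and low
birth weight untransformed. The published transform counts (7 log10, 6
cube root, 5 square root, 1 arcsine) include the Over65 regression
covariate; the per-variable assignment beyond the explicitly named ones
is not published, so the default schema chooses a plausible assignment
honoring those counts and leaves it fully editable.

The disease-burden rate DB uses the modulus transformation
`sign(sqrt(DB)) * ln(|sqrt(DB)| + 1)`, which on nonnegative rates equals
`ln(sqrt(DB) + 1)` (the equivalence is asserted in tests, as is the
round-trip with the inverse used by the generator). Predictors (and the
response) are standardized to zero mean and unit sample SD before
regression so coefficients are comparable across variables.

## Missing-value imputation and PCA

Missing indicator cells are filled by regularized iterative PCA:
initialize with column means, then iterate standardize → rank-`ncp` SVD
reconstruction (each retained direction shrunk by
`(eigenvalue − residual variance) / eigenvalue`) → refill only the
missing cells, until the largest change in a filled cell is below `tol`.
Defaults: `ncp = 2`, `tol = 1e-6`, `max_iter = 1000`; the dimension used
in the original analysis is unstated, and results on real data may move
in the third decimal with it. Plain hard truncation is available
(`regularized=False`). Observed cells are never altered; the procedure
is deterministic; non-convergence returns a flagged result with a
warning rather than raising.

PCA is performed on the correlation matrix: columns standardized with
sample SD, eigendecomposition via SVD of the standardized data.
Eigenvalues therefore sum to the number of variables and
variance-explained is `eigenvalue / p`. Component signs are fixed by
forcing an anchor variable's loading positive — poverty when present,
else diesel PM, else the largest-magnitude loading — so "higher = more
burdened" reads consistently and results are invariant to row order.
Four standard subsets are wired through the pipeline: all 20 variables,
the 17 environmental + socioeconomic variables (the regression input,
excluding the health outcomes), the 12 environmental, and the 5
socioeconomic variables.

## Disease burden

Hospitalization records carry flags for 14 diagnostic categories
(pneumonia, COPD, asthma, MI, CVA, diarrhea, pancreatic/lung/breast
cancer, lymphoma, leukemia, depression, schizophrenia, low birth
weight). A record with several qualifying categories counts as a single
event; duplicate record ids are a hard error. The per-zip burden is the
deduplicated event count over total population, pooled across years;
zips below 100 persons are excluded (small denominators produce unstable
rates). Rates are not age-standardized; the fraction of population over
65 enters the regression as a covariate instead. Mapping raw ICD-9 codes
to categories is an input lookup table (code prefix → category), not
hardcoded: the category definitions name diseases, not code lists.

## Spatial weights, Moran's I, and the SAR error model

Weights default to queen contiguity, row-standardized (the conventional
default of the standard spatial-econometrics software); rook, k-nearest
(symmetrized by union), polygon-derived contiguity, and GAL text
round-trips are provided. Islands are retained and flagged; diagnostics
and fits require them to be subset out (a fully empty adjacency is
allowed as the ordinary-regression limit).

Global Moran's I is `(n/S0) z'Wz / z'z` with a two-sided permutation
test, `p = (extreme + 1)/(n_perm + 1)`, seeded and deterministic.

The SAR error model `y = Xβ + u, u = λWu + ε` is fit by maximum
likelihood via the concentrated log-likelihood in λ: GLS on the filtered
variables `(I − λW)y, (I − λW)X`, log-determinant from the (real)
eigenvalues of W computed through the similar symmetric matrix
`D^{-1/2} B D^{-1/2}`, bounded golden-section/Brent search on
`(1/ω_min, 1/ω_max)` with tolerance 1e-8. The concentrated form is
verified against the dense multivariate-normal log-density on small
grids (1e-6). β standard errors come from `σ²(X'A'AX)^{-1}` — exact
asymptotically because the information matrix is block-diagonal between
β and (λ, σ²); the λ standard error is a profile-curvature estimate.
BIC counts λ and σ² as free parameters (`k = p + 2`). Model adequacy is
assessed by the likelihood-ratio test of λ (χ², 1 df) and a permutation
Moran test on the filtered residuals `(I − λ̂W)(y − Xβ̂)`.

Nagelkerke pseudo-R² is Cox–Snell `1 − exp((2/n)(LL0 − LL1))` rescaled by
`1 − exp((2/n)LL0)`, with LL0 the intercept-only non-spatial Gaussian
model. For a fitted model that does not nest that null (no intercept)
the value is floored at 0. If the response is scaled so the null density
exceeds 1 per observation the rescaling is undefined and the Cox–Snell
value is reported with a warning.

Term selection is greedy forward/backward: a term enters only if its
coefficient has p < 0.05 and it improves BIC by at least 2; after each
addition every included term must still satisfy both conditions
(dropping it would raise BIC by ≥ 2 and its p stays below 0.05) or it is
removed. The intercept is an ordinary candidate, removable by the same
rule. The trace records every candidate's ΔBIC and p at every step, and
the final report includes the pseudo-R² of the selected model with each
retained term ablated.

## The synthetic-data generator

The generator is first-class, tested code that emulates the full study
design:

* **Indicators.** Gaussian copula: latent standard normals with a target
  correlation matrix, back-transformed through each variable's inverse
  schema transform to plausible raw scales. The default target is the
  published 20-variable correlation matrix of the transformed data;
  assembled from pairwise-complete correlations it is slightly
  indefinite (smallest eigenvalue ≈ −0.085), so it is repaired by
  eigenvalue clipping at 1e-8 and rescaling to unit diagonal (maximum
  entry change ≈ 0.043; changes above 0.1 are flagged in the truth
  record). Correlation fidelity holds on the transformed scale; the raw
  marginals themselves are package assumptions, since no marginal
  distributions are published.
* **Geography.** Tracts on an `n_rows × n_cols` grid; zips are
  contiguous strips of `tracts_per_zip` consecutive tracts within a grid
  row (a short final strip is absorbed by its neighbor); zip contiguity
  is projected from tract queen contiguity.
* **Burden.** On the modulus-rate scale,
  `y = baseline + burden_scale · (Xβ_true + u)` with
  `u = (I − λW)^{-1}ε`. β_true (default `{PC1all: 0.47, Over65: 0.59}`,
  the coefficients of the fitted model this package re-derives) is
  expressed on the standardized-response scale; `burden_scale = 0.1`
  maps one standardized unit onto the rate scale, keeping 4-year zip
  rates in a realistic 0.01–0.6 band around the baseline level 0.37
  (≈ 0.2 hospitalizations/person over a 4-year window). Predictors named
  in β_true resolve to the generating latent factors (PC1/PC2 of the
  combined, environmental, or socioeconomic latent blocks, aggregated to
  zip and standardized) and to Over65, itself drawn with correlation
  −0.45 to the combined first factor via the same copula. Negative y or
  rates above 1/person are clipped with counts recorded in the truth.
* **Events.** Expected count = rate × zip population; integer counts are
  Poisson; each event receives one uniform primary category and, with
  probability `multi_category_rate` (default 0.1), a second distinct
  category — so deduplicated event counts equal record counts by
  construction while flag totals exceed them.

Defaults are the study conditions: a 90×90 grid (8100 tracts, matching
the ~8035-tract scale of the real table) with 5 tracts per zip (1620 zip
units vs ~1606 analyzed), λ = 0.6, σ_ε = 0.45, 2% MCAR missingness
(matching the pairwise-complete sample-size range of the published
correlation table), tract populations uniform on [300, 3000]. Tests and
the acceptance experiments use smaller grids (down to 8×8) and reduced
populations where the quantity under test does not need the full scale;
the Monte-Carlo recovery experiments use a 20×20 field of analysis
units, where maximum-likelihood λ̂ is nearly unbiased (at ~100 units its
small-sample downward bias is visible).

What the generator does **not** emulate: real California geography,
informative missingness, ICD-9 code streams (category flags only),
within-zip population structure, readmissions, or any marginal
distribution of the raw indicators. Passing tests therefore demonstrate
correctness of the algorithms and internal consistency of the analysis
chain under the published correlation and dependence structure — not
fidelity of any particular raw-scale feature of the real data.

## Degenerate inputs and tie-breaks

Constant columns are hard errors in standardization and PCA; constant
vectors return NaN with a warning from the Spearman helper and raise in
Moran's I. Ranks use average ties by default. Duplicated unit or record
ids are hard errors. Aggregation drops tracts absent from the zip link
with a logged count and conserves total population; zips whose tracts
are all missing a variable carry missing. λ estimates at the search
boundary produce a warning; a negative likelihood-ratio statistic beyond
1e-6 raises (an optimization-failure signal).

## Known limitations

* The λ standard error is a profile-curvature estimate, not the full
  information matrix entry; the likelihood-ratio test is the supported
  inference for λ.
* Dense log-determinants limit fits to a few thousand units; no sparse
  approximations are provided.
* The tract→zip link is an input; no GIS overlay or areal interpolation
  is performed, and whether the original tract→zip averaging was
  population-weighted is unstated — both modes are provided
  (`unweighted_mean` is the default, matching the stated "average").
* Spatial-lag (autoregressive-response) and conditional autoregressive
  models are out of scope.
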