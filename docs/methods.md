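# Methods

## The model

richstack implements stacked species-distribution modelling (S-SDM) for
richness-change analysis. Per taxon, a presence-background maximum-entropy
model is fitted: the predicted distribution is the Gibbs density over a
background sample of landscape cells,

    q(x) = exp( Σ_j λ_j f_j(x) ) / Z(λ),

with weights chosen to maximize the L1-penalized log-likelihood

    Σ_j λ_j f̄_j − log Z(λ) − Σ_j β_j |λ_j|,

where f̄_j is the mean of feature j over presence sites. Equivalently, q is
the maximum-entropy distribution subject to the relaxed moment constraints
|E_q[f_j] − f̄_j| ≤ β_j. Features are linear and quadratic terms of
covariates min–max scaled to [0, 1] over the background (pairwise products
are available but off by default; hinge/threshold features are not
implemented). The objective is concave; it is solved by L-BFGS-B after the
exact split λ = λ⁺ − λ⁻ with λ⁺, λ⁻ ≥ 0, which turns the L1 term into a
linear one. Fits are deterministic: cold start at λ = 0, fixed data order.

Two monotone-equivalent output scales are produced: *raw* (q itself,
summing to one over the training background) and *logistic*,
c·q/(1 + c·q) with c = exp(H_q), H_q the entropy of the fitted raw
distribution — the conventional (0, 1) suitability index for this model
family. Projection onto new (e.g. future) conditions clamps scaled
covariates to the [0, 1] training range by default, so feature responses
are never extrapolated.

Key assumptions: presences are an unbiased (if sparse) sample of the
taxon's distribution; the background sample represents the available
environment; there are no true absences, so the background serves as the
negative class for evaluation and thresholding; no dispersal limitation —
a cell predicted suitable in the future counts regardless of reachability.

## Regularization

The per-feature penalty is β_j = beta0 · s_j / √n, with s_j the presence
standard deviation of feature j (floored at 1e-3) and n the number of
presences — the standard error-bound form for this model family. The
default multiplier is **beta0 = 0.25**, the tuned scale conventional for
linear+quadratic feature sets at a hundred or more presences. A multiplier
of 1 on s/√n demonstrably over-smooths sharply unimodal responses: on the
synthetic benchmark it drove recovery AUC for the sharpest niches down to
~0.77 while a near-zero penalty reached 0.94–0.98; at 0.25 every
default-configuration taxon is recovered above 0.92 and the moment
constraints remain comfortably slack. `beta0` (and a direct per-feature
`betas` override) are exposed.

## Evaluation and thresholds

Metrics treat background as the negative class: AUC (Mann–Whitney, ties
half), point-biserial COR (Pearson correlation of scores with 0/1 labels),
and Cohen's Kappa of the thresholded prediction. Cross-validation
partitions only the presences into k = 5 folds; the background is shared
across folds. Thresholds are estimated from the full-data model's scores
at presence and background sites (final maps are what get thresholded);
per-fold Kappa applies that final threshold to held-out scores.

Three threshold rules operate on the sorted unique pooled scores:
sensitivity = specificity (T1), Youden's J maximum (T2), and predicted
prevalence = observed prevalence (T3). All three criteria are rational
numbers with fixed denominators, so they are compared in exact integer
arithmetic (e.g. |sens − spec|·n_p·n_b); this makes the documented
tie-break — toward the lower, more inclusive candidate — immune to
floating-point rounding of expressions like 3/5 + 7/15 vs 2/5 + 10/15.
A score equal to the threshold predicts presence.

A property worth knowing: with a large background sample the observed
prevalence n_pres/(n_pres + n_bg) is far below a taxon's true prevalence,
so T3 yields very high thresholds and very small predicted ranges. On the
synthetic benchmark T3 change maps correlate weakly (often negatively)
with true richness change. This is a property of prevalence matching in
presence-background designs, not an implementation defect; the recovery
acceptance check therefore uses the combined scenario with the Youden
rule, the discrimination-optimal member of the trio.

## Land-cover change

Baseline herbaceous cover is H = 100 − (T + B) (tree + bare from
fractional-cover products of different epochs; inconsistent pixels clamp
to [0, 100] with a warning). Deforestation is projected pixel-wise at a
constant annual rate r (default 0.0028/yr) accumulated *linearly on the
baseline*: loss = min(T, T·r·years). Over 2001–2080 that removes
0.0028 × 79 = 22.12 % of baseline tree cover; compounding would give
19.9 % and is not used. Herb cover gains exactly the tree loss; bare
ground is static; pixels are independent (uniform degradation, no
deforestation frontiers).

## Scenarios and the factorial

Three scenarios: climate only (nine climate covariates), land cover only
(tree and herb percent), combined (all eleven). Bare soil never enters a
model. Models are trained on the scenario's *own* layer subset under
recent conditions and projected to recent and future; a scenario's future
stack differs from its recent stack only in the scenario's own layers.
Crossing scenarios × three rules × two taxonomic levels × two epochs gives
36 richness maps and 18 change maps. Within each scenario × level, the
run with mean richness change closest to zero is flagged as the
conservative run (ties resolve T1, T2, T3). One background sample is
shared by all taxa in a scenario (less between-taxon variance); its size
is capped at the number of land cells.

## Occurrence filtering

In order: per-taxon deduplication at the grid-cell level (first record in
input order kept) → land-mask membership → collection year ≥ 1981 → DEM
elevation at the record's cell strictly below 2876 m → taxa with fewer
than 11 surviving records dropped. The record's own elevation field is
never used for filtering (grid elevation is authoritative at ~1 km); it is
retained for reporting. Genus tables are built by truncating binomials to
the generic epithet, pooling congeners and re-deduplicating per cell;
non-binomial names pass through unchanged with a warning.

## Zonal analysis

Elevation bands: *equal interval* uses a step of (max − min)/n_bands —
for a 0–2744 m DEM and 7 bands, 392 m; a published round figure (e.g.
390 m) can be forced via `interval=`. The top band is closed at the
maximum. *Equal area* ranks valid pixels by elevation (ties by row-major
position, stable sort) and splits them into contiguous rank groups whose
counts differ by at most one, remainders to the lowest bands. Ecoregion
zonings wrap a label raster; labels can be excluded from reporting while
remaining on the map (the mangrove convention). Zone statistics use the
sample (n−1) standard deviation, matching common zonal-statistics tools;
the area-normalized mean is zone total change / zone area. Cell areas
default to a constant per cell, with a cos(latitude) option for
geographic grids.

## The synthetic generator

`synthetic` builds everything the pipeline consumes, deterministically
from seeds:

* **Covariates** — white noise convolved with a Gaussian kernel
  (σ = 6 cells by default; lag-1 autocorrelation well above 0.5) plus
  directional gradients, mapped into field-realistic units (temperatures
  °C, precipitation and water balance mm, wet months 1–12, cover
  percent). Hydrological covariates are derived from one another the way
  real ones are (water balance = precipitation − evapotranspiration +
  noise), so the stack carries realistic collinearity.
* **DEM** — a smooth [0, 1] field cubed and scaled to 2600 m: right-skewed
  hypsometry (most land low, few high cells), below the 2876 m filter
  ceiling so that filter is non-binding unless a test raises it.
* **Land cover** — tree percent from a logistic transform, bare a small
  fraction of the remainder, herb the complement; T + H + B = 100 exactly.
* **Ecoregions** — six labels from quantile bins of a smooth composite of
  noise, elevation and latitude.
* **Virtual taxa** — logistic suitability in linear+quadratic terms of
  scaled covariates. Each taxon responds unimodally to three covariates
  drawn from distinct correlated families (temperatures; precipitation/
  water balance; evapotranspiration; cover) so its ground truth is
  identifiable. Because spatial correlation makes the *realized* niche
  contrast of a raw coefficient draw unpredictable, coefficients are
  rescaled jointly so the realized logit span over the landscape hits a
  drawn target of 8–12 logits — suitability traverses essentially the
  whole (0, 1) interval, a well-defined niche. The intercept targets a
  true-range prevalence uniform in [0.1, 0.5]; taxa outside [0.02, 0.8]
  are redrawn. Occurrences are sampled without replacement with
  probability proportional to suitability, with uniform collection years.
* **Futures** — climate: +2.7 °C mean warming with a ±0.8 °C north–south
  gradient, a ±10 % east–west precipitation shift, evapotranspiration
  rising 3 %/°C, water balance and wet months adjusted consistently;
  land cover: the deforestation projector. Scenario stacks replace only
  the scenario's own layers.

What the generator does **not** emulate: sampling bias (roads, herbaria),
taxonomic error and synonymy, dispersal limitation, interactions between
taxa, observation error in covariates, and real geography. Passing tests
therefore demonstrate correct machinery and recoverability under clean
sampling, not performance on biased real-world occurrence data.

## Numerical choices and degenerate inputs

* Grids are float64 with NaN as the internal invalid value; nodata
  sentinels exist only on disk (ESRI ASCII). Cells are half-open,
  row 0 northernmost; points map to the containing cell.
* Constant covariates are dropped from feature sets (warning); an
  all-constant background is an error. Fewer presences than folds, empty
  score lists, oversized background requests and constant DEMs raise
  typed errors (`InputError`, `CapacityError`, ...).
* Optimizer termination: relative objective change below `tol`
  (default 1e-6) or `max_iter` (500); hitting `max_iter` warns and returns
  the best iterate.
* The factorial records per-cell failures in `result.errors` and
  continues; the manifest reflects what completed.

## Problem sizes

Unit tests run on 40×40 landscapes with ≤ 600 background cells. The
end-to-end benchmark — in tests and examples — uses the default study
configuration: a 100×100 landscape, 30 taxa, 200 presences each, a shared
background of up to 10,000 cells, the full 36-map factorial. That
configuration completes in a few seconds on one CPU; solver-oracle
comparisons use ≤ 100-cell backgrounds where a plain proximal-gradient
reference is exact.

## Known limitations

* No hinge/threshold/category features and no cumulative output scale, so
  fitted responses are smooth; sharply thresholded truths are recovered
  only approximately (a deliberate mis-specification mode for robustness
  testing is available by constructing taxa outside the quadratic family).
* No spatially structured cross-validation; with strong spatial
  autocorrelation, random folds overestimate transferability.
* Raster I/O is deliberately minimal: single-sentinel ESRI ASCII grids,
  pre-aligned; no reprojection or resampling.
* The equal-interval/equal-area band machinery assumes a single-valued
  DEM; bathymetry or negative elevations work but are untested territory.
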