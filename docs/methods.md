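# Methods

This note documents the models and numerical choices behind `lfmckit`: a
pipeline that predicts species-specific live fuel moisture content (LFMC)
on a gridded, semi-monthly (1st/15th) calendar from lagged meteorological
predictors and a satellite greenness composite, with per-fuel random
forests, ensemble-spread prediction intervals, and observation-anchored
quantile-mapping bias correction.

## The prediction problem

LFMC is the mass of water in live vegetation divided by its dry mass,
expressed as a percent (~30% is effectively dead fuel; wet tissue can
exceed 300%). Fire agencies sample it at scattered sites roughly twice a
month. The pipeline learns the mapping from antecedent weather and current
vegetation state to LFMC at those samples, then applies it everywhere on a
~1-km grid, per fuel type (chamise-type shrubs, old growth, sage,
ceanothus), producing a continuous historical record where only sparse
point measurements exist.

## Predictors

Nine predictors per point and date:

| name  | definition                        | units |
|-------|-----------------------------------|-------|
| P90   | 90-day total precipitation        | mm    |
| T90   | 90-day mean temperature           | °C    |
| SW150 | 150-day mean shortwave radiation  | W m⁻² |
| NIRv  | semi-monthly greenness composite  | –     |
| DL    | astronomical day length           | h     |
| SM7   | 7-day mean soil moisture          | m³ m⁻³|
| W30   | 30-day mean wind speed            | m s⁻¹ |
| VPD30 | 30-day mean vapor pressure deficit| kPa   |
| P30   | 30-day total precipitation        | mm    |

Trailing windows are inclusive of the target day (`[t − w + 1, t]`), so a
window resolves first on day `w − 1` of the forcing record; the pipeline
conservatively starts its prediction calendar 150 days after forcing
start. The predictor set is configurable; longer-lag variants (150-day
mean temperature/RH, 90-day ETo and climatic water deficit, 3/7-day
precipitation) are implemented as optional extras.

Reference evapotranspiration uses the FAO-56 daily Penman–Monteith
formulation with zero soil heat flux and a logarithmic wind-profile
adjustment from the measurement height (default 10 m) to 2 m. Climatic
water deficit is ETo − AET with no clamping (negative values record wet
surplus). Day length comes from the standard sunrise equation and is
restricted to |lat| < 66.5°.

Gridded predictors are sampled to observation points bilinearly in space
and linearly in time (daily fields between days, the NIRv cube between
its semi-monthly steps). Predictors are z-scored with statistics computed
on training rows only and carried with the fitted model.

## NIRv compositing

NIRv = NDVI × NIR suppresses the non-vegetated fraction of mixed pixels.
The compositor converts an irregular stack of cloud-screened scenes into
the semi-monthly calendar:

1. cloud-flagged cells are dropped and NIRv computed per scene;
2. a one-pass shadow filter compares each point with a Theil–Sen robust
   line through its 6 nearest temporal neighbors and removes it when it
   falls below the line by more than 2 robust (MAD) standard deviations
   plus an absolute floor of 0.01 NIRv. The robust line matters: at
   realistic contamination rates (roughly a fifth of valid points
   shadowed), shadowed neighbors drag an ordinary least-squares fit down
   and inflate the residual spread enough to mask most true shadows. Only
   downward outliers are removed, since shadows can only depress the
   index. The floor encodes that deviations under ~2% of the index's
   dynamic range are never "substantial";
3. values ≤ 0 (water) or > 0.5 (outliers; exactly 0.5 is kept) are
   screened;
4. each 1st/15th step is estimated from the points in a centered, closed
   120-day window: quadratic least squares with ≥ 6 points, linear with
   3–5, the median with 1–2, missing with none;
5. interior gaps are filled by linear interpolation in time when the day
   span between the bounding valid steps is under 90 days; longer gaps
   and gaps touching the series boundary stay missing.

With noiseless scenes on a quadratic greenness signal and ≥ 6 scenes per
window, step 4 is exact to rounding; the property suite verifies recovery
to 1e-8. Fine-resolution rasters are aggregated to the model grid by a
missing-aware mean over contributing cells.

## Random forest and uncertainty

One `RandomForestRegressor` per fuel type. Tuned defaults follow a
randomized search (100 draws from a grid over tree count, depth, split
and leaf sizes, features per split, and bootstrap use) scored by mean
5-fold test R²; the shipped per-fuel defaults are 800 trees / leaf 2 /
depth 50 / 3 features / no bootstrap for chamise and 1000 trees /
bootstrap on for the other fuels. `max_features` counts predictors tried
per split.

Two cross-validation modes: pooled shuffled 5-fold, and site-wise
(each observation site withheld in turn), which probes spatial
transferability. Normalization statistics are recomputed inside each
training fold, so the held-out fold never leaks into the scaling.

Prediction uncertainty follows the quantile-regression-forest view of the
ensemble: per prediction, σ is the standard deviation of individual tree
predictions and the 95% prediction interval is mean ± 1.96σ. This is an
epistemic spread — it collapses to zero where all trees agree, so with a
single tree (or far inside dense training data) the interval can be
degenerate; coverage of noisy observations is reported, not assumed.
Because a forest averages trees, predictions are bounded by the training
predictand range and regress toward the mean: the predicted-vs-observed
OLS slope sits below 1 (over-prediction at low LFMC, under-prediction at
high LFMC), which is reproduced and asserted on the synthetic data.

Grid prediction evaluates every land cell with a complete predictor
vector at every step; cells missing NIRv (persistent cloud) are filled
afterwards by triangulated linear interpolation over land cells, per
step. Gaps outside the convex hull of valid cells remain missing and are
logged. Sea cells are never filled.

## Quantile-mapping bias correction

Sites with dense records exhibit systematic model-observation offsets,
strongest in the tails of the seasonal cycle. For the densely sampled
fuel (chamise role), per-site additive corrections are derived on the
shared semi-monthly calendar:

- observations are assigned to their nearest step (same-step duplicates
  averaged); interior runs of at most two missing steps are filled by
  quadratic interpolation, longer runs left missing; sites with fewer
  than 8 records are skipped;
- at each site, empirical quantiles at Q equally spaced levels are
  computed for the aligned observations and the colocated model series;
  the per-level correction is obs_q − model_q. A constant model series
  degenerates to a single overall-offset bin;
- a modeled value is assigned to its nearest model-quantile node
  (clamping outside the observed model range) and that node's correction
  is added. The correction is purely additive: within-bin variance is
  never rescaled, and the σ/PI layers pass through unchanged;
- Q is chosen by scanning {10, 20, …, 100} for the smallest mean |MBE|
  across sites after correction, ties breaking toward the smaller Q
  (within 1e-9 numerical tolerance).

Site corrections at each time step are spread across the grid with a
thin-plate-spline RBF over (lat, lon, elevation), z-scored so degrees and
meters are commensurable, with least-squares smoothing 0.01 because
nearby sites can disagree. Fewer than three usable sites fall back to a
constant mean-correction field. Each step is interpolated independently;
a site's correction varies in time only through which quantile bin the
modeled value falls in.

## Lag exploration

An advisory analysis cross-correlates each site's semi-monthly LFMC with
lagged candidate predictors (precipitation, ETo and climatic water
deficit summed per period, state variables averaged), picks the lag of
largest |Pearson r| per site (ties to the smaller lag), and averages best
lags across sites, reported in periods and days (14.9 days per period,
the conversion implied by "3.9 periods ≈ 58 days"). The production
windows stay fixed at the configured 90/150-day values regardless — fixed
windows generalized better than discovered lags — so the report never
feeds back into the model. Note an identifiability limit: when the
predictand is a flat moving sum of the driver, every in-window lag has
identical expected correlation, so only the distribution of recovered
lags (centered on the kernel centroid) is meaningful, not a single run.

## Synthetic data: what it emulates, and what it does not

All tests and the demo run on generated data with known truth:

- **Domain**: a coastal-mountain grid (default 12×12 at ~1-km spacing)
  with a smooth random elevation field rising inland and a masked coastal
  sea strip.
- **Forcing** (default 10 years): winter-concentrated storms (seasonal
  Bernoulli occurrence, Gamma amounts, smooth orographic modulation),
  sinusoidal annual temperature with a 6.5 °C km⁻¹ lapse and an AR(1)
  regional anomaly, humidity anti-correlated with temperature and boosted
  on storm days, shortwave with an annual cycle and storm-day reduction,
  and soil water from a leaky bucket (150 mm capacity, 2%/day drainage,
  AET = 0.9·ETo·(W/capacity)^0.7 capped by storage). Saturation/actual
  vapor pressures follow Tetens from temperature and humidity, so
  ea ≤ es holds by construction.
- **Scenes**: a smooth seasonal greenness truth observed through 12-day
  revisits with jitter and occasional missed acquisitions, 30% random
  cloud (bright cells, flagged), and cloud-shadow contamination in ~70%
  of cloud-adjacent cells (NIR depressed ×0.45, truth-flagged but not
  cloud-flagged).
- **Observations**: 12 chamise-role sites (plus a sparser second fuel)
  visited near each semi-monthly step with 15% dropout and a few days of
  date jitter. True LFMC is a smooth monotone blend
  g = 40 + 120·P90/(P90+150) + 150·SM7 + 100·NIRv − 15·VPD30 + 2·DL,
  clipped to [30, 300] — saturating in precipitation, increasing in soil
  moisture and greenness, decreasing in vapor deficit; nonlinear enough
  that the forest must learn it. Observations add per-site biases
  (constant offsets ~ U(−15, 15) plus quantile-dependent tail-heavy
  components, emulating systematic error at the wet and dry peaks) and
  Gaussian noise (σ = 10 LFMC points), with occasional same-day duplicate
  records to exercise deduplication.

The generator reproduces the statistical structure the pipeline needs —
seasonality, lags, contamination, site bias — not meteorological realism:
there is no orographic precipitation model, no wind events, no
cross-sensor calibration differences, and the planted g() is far smoother
than real plant physiology. Passing tests therefore demonstrate that the
machinery recovers known structure under realistic noise, not that the
trained models transfer to any particular real landscape.

## Numerical choices and degeneracies

- QC thresholds are strict: sites need ≥ 25 records, fuels > 500
  (both configurable); manual site exclusions are configuration, never
  automated.
- `best_lag` requires ≥ 20 overlapping periods and skips zero-variance
  series; ties in |r| break toward the smaller lag.
- Windowed features are missing whenever any day of the window is
  missing; no partial-window estimates.
- ETo is clamped at zero; supersaturated input (ea > es) and
  non-positive surface pressure raise immediately.
- The spatial gap filler needs ≥ 3 valid land cells; boundary gaps
  outside the triangulation hull are left missing and logged.
- All randomness flows from integer seeds through `numpy` generators and
  `random_state` of the forest; two runs of the same configuration are
  bitwise identical, which the suite asserts on the full demo.

## Problem sizes

The default demo is desk-scale by design: a 12×12 grid over 10 years
(~230 semi-monthly steps), ~2,300 chamise-role training rows, forests of
800–1,000 trees, and quantile mapping over 12 sites. The demo skips
hyperparameter tuning (the randomized search is exercised separately on
its own test problems) and completes in roughly two minutes on one CPU;
all tolerance-critical properties are checked at these sizes.

## Known limitations

- The piecewise-constant quantile correction is discontinuous at bin
  boundaries; a piecewise-linear mode would be smoother but is not the
  default behavior.
- Site-wise CV with few sites (the sparser fuels) has high variance;
  its per-site metrics are reported, not aggregated away.
- Interval coverage from tree spread is not calibrated: it under-covers
  where the forest is confidently wrong and over-covers in dense regions.
- The NetCDF writer uses the NetCDF-3 (classic) format; files are
  readable by any NetCDF tool but do not carry NetCDF-4 compression.
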