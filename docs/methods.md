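# Methods

This note documents the models, the synthetic study system, the numerical
choices, and the known limitations of the `winterhab` pipeline.

## The hurdle habitat model

The response is the number of right whales sighted per *sampling unit* (one
composite-grid cell × one semimonthly period). Sightings of this species are
rare and counts are zero-inflated, so the model is a hurdle:

- **Occurrence**: P(whales > 0) is a quasibinomial GAM with logit link over
  all surveyed units. The quasi family keeps the binomial mean–variance
  relation but estimates the dispersion φ from Pearson residuals.
- **Positive abundance**: E[N | N > 0] is a gamma GAM with log link over the
  occupied units only. The gamma family is applied to the integer counts
  (≥ 1) directly, without continuity correction.
- **Relative abundance** is the product p · E[N | presence]. Because
  availability and perception bias are not corrected, the product is a
  relative index, not a density.

Candidate predictors are survey effort (searched km², as a smoothed
covariate — not an offset, since the observed effort response saturates),
SST, distance to shore, depth, signed distance to the 22 °C isotherm, survey
year (an unpenalized factor for interannual totals), and a semimonth ×
northing tensor smooth that absorbs within-season migration.

### Spline engine

Smooths are natural cubic regression splines parameterized by their values
at k = 3 quantile knots, with the integrated-squared-second-derivative
penalty and a sum-to-zero constraint (so each univariate smooth contributes
2 coefficients and at most 2 effective df — deliberately restrictive, to
keep responses ecologically interpretable). *Shrinkage* smooths replace the
penalty's null-space eigenvalue with a small positive fraction (1e-2 of the
largest eigenvalue), so λ → ∞ removes the whole term (edf → 0); smoothing
selection can therefore effectively drop uninformative terms. The
interaction is a tensor product of two marginal k = 3 bases with one penalty
per margin (both shrinkage-modified), constrained to sum to zero.

Fitting is penalized IRLS (convergence when the relative deviance change
falls below 1e-8, 200-iteration cap, separation reported distinctly). The
smoothing vector minimizes GCV = n·D/(n − edf)² with edf = tr[(XᵀWX +
Σλⱼ Sⱼ)⁻¹ XᵀWX], searched by Nelder–Mead over log λ (clipped to [−20, 30])
from up to three starts (0, +3, −3), with warm-started IRLS inside the
search. Coefficient covariance is the Bayesian form (XᵀWX + S)⁻¹φ, which
gives the ±2 SE bands used for partial effects and predictions.

### Stepwise selection

Forward selection starts from the null model; at each step every remaining
candidate is added singly and the addition with the lowest GCV advances. It
is accepted only if (i) the analysis-of-deviance F-test against the previous
step — F = (ΔD/Δedf)/φ_new on (Δedf, n − edf_new) df — is significant at
α = 0.05, (ii) the GCV is lower than the previous step's, and (iii) the
fitted partial effect's ±2 SE band is not zero everywhere. GCV ties break by
fewer edf, then candidate order. Mean ASPE is computed per accepted step
from five independent 80/20 train/validation splits (random splits, not a
partitioned 5-fold — matching how the validation is described); the presence
component is scored as (p̂ − y)² against the 0/1 response, the abundance
component as squared count error, which reconciles the two components'
order-of-magnitude difference in ASPE. Validation rows with factor levels
unseen in training are dropped and counted; a training split that loses a
factor level entirely degrades that term to the intercept rather than
failing.

### Prediction maps

Hindcasts override effort with a constant reference value so that variable
effort does not confound the spatial pattern. The published analysis uses
250 km², the plateau of its effort smooth; the synthetic surveys fly fewer
passes per semimonth, so the analysis drivers use the 90th percentile of
training effort instead — `predict_map` enforces that the reference lies
inside the presence model's training range either way. No extrapolation:
rows with any covariate outside its training range, an unseen year, invalid
depth (above sea level or > 70 m), or missing SST/isotherm are masked with a
recorded reason. The product's standard error uses the delta method under
component independence, Var ≈ p²·Var(E) + E²·Var(p) — an approximation,
since both components are fit to overlapping data.

## Detection functions and effort

Perpendicular distances are fitted per platform with the covariate
half-normal conditional likelihood Π g(xᵢ; σ(zᵢ))/μ(zᵢ), σ(z) = exp(β₀ +
β₁·z) on Beaufort sea state, truncated at W (default: 95th percentile of the
observed distances — the standard distance-sampling choice, since no
truncation distance is prescribed for this survey program). Optimization is
Nelder–Mead from three starts (log of the RMS distance, ± 0.5); ESWs use
adaptive quadrature (equal to the erf closed form). The Skymaster's 0.186-km
per-side blind spot is subtracted from the swath *after* ESW estimation, as
an area correction, not via a left-truncated likelihood. Segment swath areas
are apportioned to grid cells proportionally to in-cell track length; this
equals the buffered-polygon overlay for straight segments away from swath
ends and is exact for the cell-aligned synthetic segments (conservation is
verified to 1e-6 km²).

## The synthetic study system

The generator emulates the survey context on a flat projected plane
(km east/north; at this spatial scale projection error is irrelevant, so no
geodesy):

- **Geometry**: a north–south coastline at x ≈ 0 with a 4-km meander; a
  southern zone of 27 east–west transects spaced 5.56 km (9 cells each) and
  a northern zone of 11 northwest–southeast transects spaced 7.52 km
  (7 cells each, each row staggered one cell west so the block follows the
  coast). Two seasons × 8 semimonths × 320 cells ≈ 5100 sampling units.
- **Bathymetry**: depth increases monotonically offshore to a 75-m shelf
  maximum, with the shelf width modulated alongshore by two sinusoidal
  harmonics (amplitude 0.5). This keeps depth, distance to shore and SST
  correlated but identifiable (max VIF ≈ 5, the collinearity regime the
  analysis is designed for); a shelf whose depth is a pure function of
  offshore distance would make the smooths unidentifiable.
- **SST**: daily fields = seasonal base (16 °C dipping to 11 °C
  mid-winter) + per-season anomaly (−1.5 °C "cold" season, +1.5 °C "warm"
  season) + north–south gradient (4 °C across the domain) + a Gulf Stream
  proxy band that blends toward a 24.5 °C advected core (> 22 °C year-round,
  meandering ±12 km) + spatially smooth AR(1) noise (0.9 °C, 9-km
  correlation). Cloud masks are thresholded smooth random fields (spatially
  coherent, 30 % cover).
- **Whales**: the latent occurrence logit sums a Gaussian SST response
  peaking at 14 °C, exponential shore affinity (25-km scale), a mild depth
  optimum at 17 m, a tanh isotherm-distance response (avoiding the warm
  side), a migration term whose preferred northing starts high in December,
  dips mid-season and returns in March, and per-season intercepts. Positive
  counts are 1 + Poisson(m − 1) with m = 3 (the gamma family downstream is a
  modelling choice, not the generator's truth), split into groups placed
  uniformly in their cell; cow-calf flags are more likely in shallow cells.
- **Surveys**: 8 flights per zone per semimonth on random days, platform and
  sea state drawn per flight; groups within the truncation distance of a
  flown transect are detected with probability exp(−d²/2σ²). ESWs span
  ≈ 1.2–1.9 km across strata, matching the program's published 1.3–2.2 km
  range. Fixed proportions of flights violate the altitude/visibility rules
  and fixed proportions of sightings are duplicated or flagged as
  verification records, so filter accounting is exactly predictable.

What the generator does **not** emulate: availability/perception bias,
observer heterogeneity, aircraft dynamics, photo-identification, real Gulf
Stream physics, temporally persistent cloud systems, or whale movement
between semimonths (units are redrawn independently each period). Passing
recovery tests therefore demonstrates that the pipeline estimates what it
claims under a faithful rare-species survey geometry — not that it would be
unbiased under every violation real data can offer.

## Numerical choices and conventions

- Semimonth halves are inclusive day ranges: A = days 1–15, B = 16–end;
  December belongs to the season labelled "year/year+1".
- A point exactly on a shared cell edge is assigned to the lower cell id;
  zone membership is decided by northing at the zones' shared boundary,
  which coincides with the southern block's upper cell edge.
- Exactly-22 °C cells get a non-negative isotherm distance (negatives are
  reserved for strictly warmer water). Isotherm contours come from marching
  squares with linear interpolation; slope uses the Horn 3×3 operator —
  both chosen to match common GIS implementations so independent oracles
  agree.
- Excluded sampling units are retained with reason codes
  (`effort_outlier`, `depth>70`, `above_sea_level`, `missing_SST`,
  `missing_isotherm`) rather than dropped, so row accounting is auditable.
- Mann–Whitney uses midranks, tie-corrected variance and continuity
  correction by default, with exact enumeration when n₁ + n₂ ≤ 12. Full
  enumeration at n₁ = n₂ = 6 puts the worst exact-vs-normal discrepancy at
  0.0155 (at U = 12); without continuity correction it is 0.069, which is
  why the correction defaults on. "Sequential Bonferroni" is Holm's
  step-down over the tested family.
- The composite hurdle deviance residual is a documented choice (no
  standard definition exists for the two-part prediction): gamma-form
  deviance against the relative-abundance prediction for positive counts,
  the presence component's −2·log(1 − p̂) contribution for zeros, signed by
  (observed − predicted).
- Moran's I uses unstandardized inverse-distance weights over all cell pairs
  (row-standardized available as an option; the unstandardized statistic can
  slightly exceed [−1, 1]). Its z-score uses the normality-assumption
  variance.
- VIF screening is a report, not an automatic excluder; which collinear
  predictors to drop (easting, slope in the original program) is a
  configuration decision.

## Problem sizes

Default study conditions throughout: ≈ 5100 sampling units (two seasons),
≈ 600–750 occupied units, ≈ 5–7 k sightings. Recovery checks use 20
replicate datasets where replication is required (selection consistency,
cold/warm centroid contrast); detection recovery uses n = 2000 distances.
These sizes were chosen so that every stochastic check is comfortably
powered while the whole suite remains quick to run.

## Known limitations

- Quantile knots at k = 3 give each smooth at most 2 df; strongly bimodal
  responses cannot be represented (intentional, but a limitation).
- GCV smoothing selection at small positive-unit counts can be
  under-smoothing-prone; REML is out of scope.
- The delta-method SE for relative abundance ignores the covariance between
  hurdle components.
- The gamma component treats repeat sightings of the same whale within a
  semimonth as independent contributions, exactly as the survey counts do.
- Stepwise selection inherits the usual caveats of sequential testing; the
  ASPE column is advisory, not an automatic decision rule.
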