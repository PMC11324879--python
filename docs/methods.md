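# Methods

## Scope and model

`cloudshift` decomposes the 2003→2022 change of near-surface temperature
variables (Tmax, Tmin, Tmean, Tdew) and of cloud base height (CBH) at each
deforested montane pixel into a background climate component and a
deforestation component, using nearby stable forest as the climate
reference.  The additive model is

    ΔT = ΔT_fcc + ΔT_cc            ΔCBH = ΔCBH_fcc + ΔCBH_cc

where the `cc` component is estimated from stable references and the `fcc`
component is the residual; both identities therefore hold exactly wherever
the climate component is defined.

### Montane mask

A pixel is montane forest when elevation ∈ [1200, 3500] m a.s.l.
(inclusive), local elevation range (LER) > 300 m (strict), and tree cover
≥ 30% (inclusive).  LER is max − min elevation over all pixels whose
centres lie within a 5-km Euclidean radius (a circular, not square,
neighbourhood); nodata pixels inside the window are ignored rather than
poisoning it, because real DEMs have voids.  When a fine mask must be
aggregated, a coarse pixel is montane if ≥ 50% of its fine pixels are
(`coarsen_mask`); the aggregation fraction is a package choice — no
authoritative rule exists — and is exposed as a parameter.

### Change detection

NDFI is computed from fully constrained (non-negative, sum-to-one)
spectral-mixture fractions of green vegetation, non-photosynthetic
vegetation, soil and shade:

    NDFI = (GV/(1−Shade) − (NPV + Soil)) / (GV/(1−Shade) + NPV + Soil)

The endmember spectra are a configurable input with documented Landsat-like
defaults.  The sum-to-one constraint is enforced by a heavily weighted
appended row in a non-negative least-squares system; tests verify the
fractions against an independent SLSQP constrained solver.

Annual NDFI series (2003–2022, ≥ 10 non-missing years) are tested with the
Theil–Sen slope and a two-sided tie-corrected Mann–Kendall test at
α = 0.05.  The *direction* of a significant trend is taken from the sign of
the Mann–Kendall S statistic rather than the Theil–Sen slope: for an abrupt
persistent loss the series is a step function whose median pairwise slope
is exactly zero while the monotone association is strongly significant.
A pixel counts as deforested when its recorded loss year falls in
2004–2022, it lies inside the montane mask, and the NDFI trend class is
`loss`; gain or stable trends (recovered pixels) are discarded.  Stable
reference pixels are montane pixels with no recorded loss and a stable
NDFI trend.

### Temperature models

Monthly Tmax, Tmin and Tdew are estimated by a stacked ensemble: one
random-forest base learner per sensor view ("Terra-like" 10:30, "Aqua-like"
13:30) on the schema features (Tmax: LST_day, NDVI, albedo, lat, lon;
Tmin: LST_night analogues; Tdew: e_s(Tmin), LST_night, lat, lon), combined
by a random-forest meta learner.  The meta learner is trained on
out-of-fold base predictions (5-fold) so it never sees in-sample base
predictions — the leakage control is our choice, as no training protocol is
prescribed for the meta stage.  Defaults: 300 trees, fixed seed,
`min_samples_leaf=5` for the meta forest only.  The meta leaf size matters:
with single-observation leaves the meta stage chases out-of-fold noise and
can degrade the stack by ~20% RMSE; at leaf 5 the stack is never more than
a few percent worse than the best base learner, which the tests assert.

Saturation vapour pressure uses the Magnus-type form
e_s(T) = 0.6108·exp(17.27 T/(T+237.3)) kPa (T in °C, pole at −237.3 °C
rejected).  Tmean is exactly (Tmax + Tmin)/2.  Station rows are split
70/30 by station for training/diagnostics.  Forward feature selection under
spatially blocked CV adds a candidate only if the blocked-CV RMSE improves
by at least 1% (relative); a strict-zero threshold admits pure-noise
features through chance CV fluctuations.  Exactly duplicated candidate
columns are deduplicated before selection.

At desk scale the stacked models are fitted on pooled monthly station rows
(the synthetic feature-to-temperature mapping is month-invariant) and
predictions are made per month; annual values are the mean of the 12
monthly predictions.

### Attribution

For each loss pixel, admissible references are stable pixels whose centres
lie within the 5-km search radius and whose elevation falls inside the loss
pixel's elevation envelope — the fine-scale minimum/maximum elevation
within the (coarser) loss pixel.  ΔT_cc is the power-1 inverse-distance-
weighted mean of the references' ΔT (power 1, not the more common power 2);
it is a convex combination, so it always lies within the reference extrema,
which is asserted in tests.  A reference at exactly zero distance is used
directly (the infinite-weight limit).  Pixels with fewer than `n_min = 3`
references are excluded and logged; the choice of 3 is ours — the
empty-neighbourhood case has no prescribed behaviour.

### Cloud base height

CBH = 125 m/°C × (T_air − T_dew) (the Espy approximation).  Because the
relation is linear in the dew-point depression, ΔCBH_cc =
125·(ΔT_air,cc − ΔT_dew,cc) and the decomposition identity is exact.  Which
air temperature enters the equation is configurable (`tmean` default,
`tmax` optional): the choice is genuinely underdetermined — headline mean
changes of Tmax and Tdew would imply a larger CBH shift than is obtained
with Tmean — so the package exposes it rather than hard-coding one.

An independent check, `parcel_lcl`, computes the lifting condensation level
by iterative adiabatic parcel ascent: constant mixing ratio (vapour
pressure diluting as e0·p/p0), dry adiabat T = T0(p/p0)^(Rd/cp), bisection
for the saturation pressure, height = cp(T0 − T_lcl)/g.  Both the adiabat
and the dilution depend only on p/p0, so the result is independent of the
assumed surface pressure — the reason this form was chosen over a
virtual-temperature variant, which would introduce a pressure-dependent
correction of similar size to the effect being checked.

**Measured validity.**  Over T ∈ [0, 30] °C × RH ∈ (50%, 100%) the maximum
relative deviation of the Espy value from the parcel LCL is ≈ 2.5%, reached
very close to saturation at warm temperatures (T = 30 °C, RH ≈ 0.99, where
the LCL is only ~22 m and the true height-per-degree is ≈ 128 m/°C); about
97% of the grid is within 2%.  The often-quoted 2% validity bound for this
approximation is therefore slightly optimistic near saturation, and the
acceptance test asserting the 2% bound fails honestly at that corner.  For
the montane dew-point depressions this package works with (several K), the
approximation is comfortably within 2%.

The climate-only CBH change uses a ≥ 30-year coarse reanalysis cube with a
static vegetation state: CBH per year from annual means, OLS trend against
year, change = slope × record span (a trend is more robust than endpoint
differencing over a 31-year noisy record), nearest-neighbour resampling to
the fine grid, nodata below 10 valid years.

### Assessment

Random-holdout and spatial-block cross-validation share the estimator and
metrics (RMSE, MAE, R²; MAE ≤ RMSE is asserted structurally); blocks are
squares of side 5× the noise correlation length by default.  With spatially
autocorrelated residuals the spatial scheme is the pessimistic (honest)
one, which a seeded simulation verifies in ≥ 80% of repeats.

Accuracy and error-adjusted area follow the stratified good-practice
estimators: cell proportions per stratum combined with area weights;
overall accuracy and area come with normal-approximation 95% intervals
(z = 1.96).  With a single stratum everything reduces algebraically to the
plain confusion-matrix quantities, which is tested exactly.

GAM summaries fit a penalized cubic B-spline (statsmodels GLMGam) with the
penalty weight selected by an explicit GCV grid search,
GCV(λ) = n·RSS/(n − tr(H))² (the installed statsmodels' built-in penalty
selection is unusable; see the repository notes).  Reported:
deviance explained = 1 − RSS/TSS and an R² adjusted by the hat-matrix
trace, mirroring the convention of mainstream GAM software, plus a
pointwise 95% band.

## Synthetic scenes: what they emulate, and what they do not

The generator builds, from a single seed: smooth terrain (Gaussian-filtered
white noise rescaled to the elevation range, generated at 5× subdivision so
per-pixel elevation envelopes exist), tree cover densest at mid elevations,
contiguous loss patches grown by random walk with fractional loss uniform
in [5, 90]% and loss years in 2004–2020 (a quarter of events partially
recover: 90% of the lost cover returns over 8 years), monthly observables
for 2003 and 2022, an annual NDFI series, and a 31-year coarse reanalysis
(10× block mean, no deforestation signal).

Injected structure: lapse rate 6.5 K/km; sea-level Tmax/Tmin 30/18 °C with
seasonal half-amplitudes 3.0/1.8 K; dew point = Tmin − 2 K, drying by
`dewpoint_drying_K` per unit fractional loss and warming at half the
climate trend; deforestation warming `deforestation_warming_K` per unit
fractional loss applied equally to Tmax and Tmin; spatially correlated
Gaussian noise (correlation length 5 km, sd 0.3 K by default); ~1% missing
LST observations per month.  Surface-temperature observables are the air
fields plus constant offsets (+2 K day, −1 K night), NDVI increases
linearly with tree cover, albedo decreases.  Defaults (100×100 pixels at
1 km, 15 loss events, warming 2 K per unit loss, trend 0.2 K/decade) are
the package's one-time choices of realistic desk-scale conditions.

Not emulated: radiative transfer, cloud-cover and orographic-precipitation
processes, differing day/night deforestation responses (warming is applied
equally to Tmax and Tmin, so all temperature variables share one truth
grid), non-local moisture feedbacks, and real sensor QC structure (a random
nodata mask stands in for quality flags).  Passing recovery tests therefore
demonstrate the statistical machinery — masking, trend filtering, stacked
regression, reference decomposition — under known signals, not the physical
fidelity of any real satellite archive.

## Numerical and design notes

* All randomness flows from a single seed; reruns are bit-identical
  (checksummed in the pipeline manifest).
* IDW at d = 0 uses the coincident reference directly; excluded pixels
  (n < 3 references) carry NaN everywhere downstream.
* The NDFI trend over a grid is vectorised for the tie-free case and falls
  back per pixel to the tie-corrected scalar test when exact ties occur
  (zero-noise scenes).
* Binned summaries use half-open bins [lo, hi) with the final bin closed, so
  no pixel is double-counted; per-bin counts sum to the number of valid
  pixels.  At desk scale, latitude summaries use 0.01° intervals (the scene
  spans < 1°) in place of the 1° intervals a continental map would use.
* Stage dependencies are explicit; toggling a required stage off fails with
  the missing stage named.  Only synthetic mode is wired end-to-end; real
  rasters enter through the same `Grid`/cube containers.
* Problem sizes in the test-suite simulations (scenes from 30×30 to
  200×200, 10–20 seeds per property) are the package's choices for a
  single-workstation run of the full suite.
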