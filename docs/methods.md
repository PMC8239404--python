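# Methods

`nfixnet` studies how environment shapes symbiotic nitrogen fixation in
soybean. The response of primary interest is the relative abundance of
ureides (RAU, %), a stem-tissue proxy for the fraction of plant N derived
from fixation; seed yield (Mg ha⁻¹) and seed protein (g kg⁻¹) are modeled
with the same machinery to gauge how strongly they co-vary with RAU. This
note records the models, the assumptions behind them, and the choices made
where the design was genuinely open.

## The statistical model

For observation *i* in site *s(i)*:

```
y_i = β₀ + x_iᵀβ + u_{s(i)} + ε_i,   u_s ~ N(0, σ²_site),  ε_i ~ N(0, σ²_res)
```

with `x_i` the standardized covariable vector. The fixed effects carry an
elastic-net penalty on the mean-squared-error scale,

```
(1/2n) Σ (y_i − β₀ − x_iᵀβ − u_{s(i)})² + λ [ α‖β‖₁ + (1−α)/2 ‖β‖₂² ],
```

with the intercept and the site intercepts unpenalized. This is the exact
parameterization of standard elastic-net software, so a single-group fit is
directly comparable coefficient-by-coefficient with a generic solver — the
test suite holds this to 1e-5. The mixing parameter is fixed at α = 0.5;
the overall penalty λ is chosen by cross-validation (below). Only a random
site intercept is modeled: years, blocks, and random slopes are out of
scope.

### Fitting algorithm

For fixed variance components the penalized mixed model is the Henderson
joint minimization over (β₀, β, u) with a ridge weight κ = σ²_res/σ²_site
on the site intercepts. The solver alternates three exact descent steps —
per-group shrunken means for `u` (`u_s = n_s r̄_s/(n_s + κ)`), the residual
mean for β₀, and one cyclic coordinate-descent sweep with soft-thresholding
for β (`β_j ← S(z_j, λα)/(d_j + λ(1−α))`) — so every iteration decreases
the joint objective. Variance components are re-estimated by EM-type
moment updates interleaved with these sweeps; once they stabilize
(relative change < 1e-9), κ is frozen and the fit polishes to the
coefficient tolerance. The reported `objective_trace` covers this final
phase and is non-increasing by construction. Zeros produced by the soft
threshold are literal `0.0`. Coordinates cycle in table column order, so
runs are bit-reproducible.

Defaults: `tol = 1e-6` on the maximum coefficient change, `max_iter = 500`
per phase. With λ = 0 the same iteration is an exact EM for the Gaussian
mixed model and converges to the maximum-likelihood fit (validated against
a generic ML mixed-model solver to ~1e-4 relative). σ²_site estimates may
hit the boundary at exactly 0 — this is expected, and is in fact the
signature behavior when site-level covariables absorb the site means.
The inner kernels are numba-compiled; the first call in a fresh
environment pays a one-time compilation cost.

## Covariable engineering

* **RAU** `= 100·4u/(4u + n)` from stem ureide (u) and nitrate (n)
  concentrations in μmol g⁻¹; the factor 4 counts N atoms per molecule.
* **VPD** uses the FAO-56 saturation curve
  `es(T) = 0.6108·exp(17.27T/(T+237.3))` kPa with
  `vpd = mean(es(tmin), es(tmax))·(1 − rh/100)`. The humidity covariable
  (`Hum`) is the actual vapor pressure `es·rh/100` in kPa.
* **SDI** is Shannon evenness of daily rain within a window,
  `−Σ pᵢ ln pᵢ / ln n`, oriented so 1 = perfectly even and 0 = all rain on
  one day. (The opposite orientation is sometimes quoted; the standard
  evenness convention is used here and stated explicitly.)
* **Windows.** Daily weather is aggregated over three phenology windows —
  vegetative `v = [VE, R1)`, pre-seed-filling `r = [R1, R5)`, seed filling
  `s = [R5, R7]` — cumulative for water/energy fluxes (Prec, Rad, ET0,
  drought), means for state variables (Tmean, T.Amp, VPD, Hum). Days
  between R4 and R5 belong to `r`; intervals are half-open on the right so
  the three windows partition the season with no double counting.
* **Drought stress** is the cumulative reduction in crop transpiration
  (mm) from a single-bucket soil-water balance: demand is `kc·ET0`; stress
  triggers when relative plant-available water falls below a
  demand-dependent threshold (0.80 of capacity on low-demand days, 0.95
  when demand exceeds 4 mm d⁻¹ — high atmospheric demand makes stress set
  in wetter, mirroring the dual-tension trigger of full soil-water
  models). Below threshold, transpiration ramps down linearly with
  relative content but never below 70% of demand (a subsoil-supply floor),
  so daily reduction ≤ 30% of demand. Bucket capacity comes from texture
  via a pedotransfer rule of thumb at 1.2 m root depth. This is a
  deliberately simple stand-in for a Richards-equation soil-water model:
  it preserves the trigger logic and the covariable's units, not the
  soil physics.
* **Correlation pre-filter.** Pairs of continuous covariables with
  |r| > 0.75 and a two-sided Pearson test p < 0.05 are resolved by
  dropping the member ranked lower in a keep-preference list (defaults
  encode field conventions: sand over silt/clay, SOM over its
  mineralization index, temperature over humidity, VPD over reference ET).
  Every drop is logged with (r, p). Covariables varying in fewer than 20%
  of rows (e.g. early-season drought in a network that saw none) are
  screened out first — they carry no usable signal and go constant inside
  resampling folds.
* **Standardization** centers and scales by the population SD computed on
  the fitting rows only; binary treatment indicators (N fertilization,
  reinoculation) are centered but never variance-scaled, so their
  coefficients keep the "effect of presence" reading. Scaling pairs are
  stored for back-transformation.

## Model selection and evaluation

Nested cross-validation: 20 outer folds estimate out-of-bag performance;
within each outer-training set, 10 inner folds select λ by the median
out-of-fold RMSE over 90 log-spaced values from λ_max (the smallest
penalty that zeroes every coefficient, computed from the null-model
residuals) down to λ_max·10⁻³. Ties go to the heavier penalty. Each outer
fold re-standardizes on its own training rows; held-out rows never touch
scaling, λ selection, or fitting (instrumented tests corrupt a held-out
row and verify the fold's fit is bit-identical). Held-out predictions are
marginal plus the BLUP of sites seen in training (zero for unseen sites).
Metrics per fold: RMSE, MAE, RRMSE (= 100·RMSE/mean(obs)), and R² as the
squared Pearson correlation of observed and predicted; fold medians and
SDs are reported. Folds are simple random partitions by default; a
`grouped_folds` option makes outer folds respect sites, which removes the
BLUP advantage from evaluation — a documented trade-off, off by default.
R² is undefined on single-row folds and recorded as missing with a notice.

Penalty-path fits inside the inner loop run at a coarser coefficient
tolerance (1e-4) than final fits (1e-6); on the default study this changes
no selected λ and cuts runtime roughly in half.

## Interpretation

Per covariable, the median coefficient across the 20 outer folds is the
importance summary; a covariable is *shrunk to zero* if its coefficient is
exactly 0.0 in at least half the folds. One-dimensional k-means (k = 4, 50
restarts, fixed seed) groups the absolute medians into high, medium-high,
medium-low, and low magnitude clusters, labeled by descending centroid;
the test suite checks the clustering against an exact dynamic-programming
1-D k-means oracle. The *reduced model* refits the high ∪ medium-high
covariables (zero-flagged members excluded with a warning) without
penalty, under the same outer-fold protocol. The subset is frozen before
refitting — no re-selection inside folds — mirroring the two-stage
procedure; the selection bias this can introduce in the reduced model's
apparent precision is acknowledged, not corrected.

Partial dependence here is the observed-value profile used in this
literature rather than the classic grid marginalization: model predictions
for the observed rows are averaged within seven equal-width intervals of
one covariable's observed range, with empty intervals flagged rather than
interpolated. Interval means of an additive linear fit therefore lie on
the model line at the interval-mean covariable values when the other
covariables are uncorrelated.

## The synthetic trial generator

No field data ship with the package; every study runs on a generator that
emulates the structure of a US soybean research network — 11 sites × 2
years, ~45 environments (site-year-sowing-cultivar combinations), 95
environment × treatment observations, with control and N-fertilization
rows everywhere and reinoculation in every fifth environment.

* **Soil** is drawn uniformly inside observed envelopes (CEC 3–27
  cmol_c dm⁻³, sulfate-S 0.9–21.3 mg dm⁻³, …); texture closes to exactly
  100% with clay concentrated mid-range, so the closure plays out as a
  strong sand-silt trade-off; the organic-matter mineralization index
  tracks SOM (r ≈ 0.98). These induced collinearities are what the
  correlation filter is for.
* **Weather** is a two-stage generator: a daily pattern (first-order
  wet/dry rain chain conditioned on its wet-day count, gamma amounts;
  sinusoid-plus-AR(1) temperature with centered multi-day "spell" noise;
  humidity set so each season's mean VPD hits a drawn target) rescaled to
  season totals drawn from envelope-truncated normals whose means scale
  with season length. Consequence: every season aggregate (cumulative
  rain, radiation, ET0, mean temperature, VPD, vapor pressure, SDI,
  drought) falls inside its observed [min, max] envelope in ≥ 99% of 1000
  replicate seasons — a property the test suite checks directly. The
  spell-scale noise decorrelates the three phenology windows within a
  season; without it, window aggregates of the same variable are nearly
  collinear and the filter collapses the weather block.
* **Phenology** is a fixed-fraction stand-in: R1/R4/R5 at 0.40/0.60/0.65
  of the VE→R7 season, season length a linear map of maturity group onto
  75–112 days. Only window boundaries matter downstream.
* **Responses** are built as `y = μ + X_std β_true + u_site + ε` on the
  standardized engineered features. RAU is clipped to [0, 100] with every
  clip logged; stem ureide and nitrate assay values are back-calculated
  from the generated RAU. The default RAU truth places five active
  effects of a common scale (≈ 1 residual SD each) on distinct design
  strata: N fertilization −4 points, pre-seed-filling VPD −3.2 and rain
  −2.8, soil CEC +3.2, sowing day +2.8; σ²_site = 4, σ²_res = 9 (so RAU
  spans roughly 60–98%). Only one active is site-level on purpose: with
  11 sites, several correlated soil actives are not separately estimable
  and a recovery study against them would measure the design, not the
  method. Yield and protein have analogous sparse truths.

**What passing tests do and do not show.** The generator reproduces the
marginal envelopes, the site-intercept structure, and the collinearity
families of real trial networks, but its effects are exactly linear and
additive, its noise Gaussian, and its covariables stationary within
windows. Recovery and ordering results therefore validate the machinery —
not the claim that a real network would yield the same covariable ranking.

## Replicate studies and problem sizes

The package's own validation (`nfixnet.studies`, also run by
`scripts/acceptance.py`) uses 100 independently seeded trials, each taken
end-to-end through filtering, nested CV (20×10 folds, 90 λ values), null
model, clustering, and the reduced refit. Scoring conventions: the
*estimated important set* is the high ∪ medium-high cluster union; sign
recovery is the fraction of true actives in it with the correct median
sign; the false-positive rate is the fraction of truly-inactive retained
covariables in it. An active removed by the correlation filter counts as
a miss. These sizes keep a full study within a few minutes on one core
while leaving the per-replicate protocol identical to the single-dataset
pipeline.

## Known limitations

* The drought stand-in has no soil layering, runoff, or root growth; its
  parameters were chosen to reproduce observed drought envelopes, not
  measured soil hydraulics.
* λ values are parameterization-specific and not comparable across
  software; coefficients, not penalties, are the portable output.
* With 11 sites, site-level (soil) effects are estimated from effectively
  11 observations; their recovery is intrinsically noisier than that of
  environment-level weather effects, and occasional collapses of a true
  soil effect into the low-importance clusters are expected.
* The reduced model's covariable list is selected on the same data it is
  then cross-validated on (two-stage selection bias).
* The k-means magnitude clustering imposes exactly four bands; covariables
  near band boundaries can swap clusters under resampling.
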