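# Methods

`edattrib` implements an exposure-attribution analysis for weekly
emergency-department (ED) admission counts: environmental exposures
(rainfall, temperature, wind speed, PM10, SO2, CO) enter a lagged additive
count regression per admission category, and the fitted model is then
interrogated counterfactually to produce incidence-rate-ratio (IRR)
exposure-response curves and population-attributable-fraction (PAF)
series.  Because the admissions data such analyses run on is typically
restricted, the package ships a calibrated synthetic-data generator with
closed-form oracles, so every stage can be validated against known truth.

## The count model

For category-specific weekly counts Y_t the model is a generalized
additive model with log link:

    log E[Y_t] = b0 + sum_{n=1..l} f_n(Y_{t-n})
               + sum_{i} sum_{n=n0..l} f_{i,n}(X_{i,t-n})
               + s_week(Week_t) + s_year(Year_t)

with l the maximum lag (1-3 weeks; n0 = 0 when "immediate" same-week
effects are included, else 1), X_{i,t} the six national weekly exposures,
f and s penalized low-rank spline smooths, and the family Poisson,
quasi-Poisson, or negative binomial.  Autoregressive terms enter as
smooths of the raw lagged counts (a log1p transform was considered and
rejected to keep the autoregressive smooth on the model's natural count
scale; the raw form is what the fitted formula states).  The maximum lag
of 3 is supported diagnostically by the partial autocorrelation function
(`features.pacf`, Durbin-Levinson recursion with a +-1.96/sqrt(n) band).

### Spline bases

* Exposure, autoregressive and year smooths use the 1-D thin-plate
  smoother basis (equivalently the cubic-smoothing-spline reproducing
  kernel) with knots at covariate quantiles.  The penalty is the kernel
  Gram matrix: positive semi-definite, null space = the linear trend, so
  an infinitely penalized smooth degenerates to a straight line rather
  than to zero.  Defaults: k = 8 per exposure/AR smooth, k = 4 for year
  (only 5 distinct years; the basis dimension auto-reduces with a warning
  when a covariate has fewer distinct values than k).  These keep the
  total effective degrees of freedom well below the 258 usable rows of a
  261-week, 3-lag design.
* The epi-week seasonal smooth is cyclic.  A harmonic (sine/cosine)
  basis with period 52 and the j^4 roughness penalty is used rather than
  a cyclic cubic regression spline: periodicity in value and all
  derivatives at the week-1/week-53 boundary is exact by construction,
  the penalty is diagonal, and at k = 10 (four harmonics) the two
  constructions are practically indistinguishable for a smooth annual
  cycle.  Week 53, which exists only in 53-week epi-years, shares the
  phase of week 1.
* Every smooth absorbs the sum-to-zero identifiability constraint by
  centering its basis columns over the training rows, so the intercept is
  the log baseline rate.
* Evaluation outside the training range extends each basis function
  linearly from the boundary (continuous value and first derivative) and
  warns.  This matters only for the literal "set-zero" PAF mode
  (below), where exposure value 0 lies far outside every observed range.

### Fitting

The inner loop is penalized iteratively reweighted least squares,
converged when the relative change in penalized deviance falls below
1e-8 (cap 200 iterations; non-convergence raises).  Smoothing parameters
are chosen by restricted maximum likelihood via Fellner-Schall updates:
at each outer step the fixed point condition

    beta' S_j beta  =  rank(S_j) / lambda_j  -  tr[(X'WX + S_lambda)^-1 S_j]

drives the multiplicative update of each lambda_j, clipped to
[1e-7, 1e9], until the largest log10 change falls below 2e-3 (cap 60
outer iterations).  On single-smooth Poisson test problems the resulting
fits agree with mgcv's thin-plate REML fits to |delta eta| < 0.005 and
EDF within 0.05 (the residual difference reflects the different low-rank
basis parameterisations); the agreement is asserted (more loosely) in the
test suite.

Families: quasi-Poisson reuses the Poisson point estimates and scales the
coefficient covariance by the Pearson dispersion (its AIC is undefined
and never reported).  The negative-binomial size theta is profiled: the
REML fit at fixed theta alternates with a bounded 1-D likelihood
maximisation of theta given the fitted means.  AIC = -2 loglik + 2 EDF,
with one extra degree of freedom for an estimated theta.  The coefficient
covariance is the Bayesian posterior covariance (X'WX + S_lambda)^-1
(times the dispersion under quasi-Poisson), which is what the IRR
intervals use.

### Model selection

The default candidate grid is {Poisson, negative binomial} x {max lag 1,
2, 3}, lagged-only; immediate-effect variants and quasi-Poisson join via
configuration as sensitivity analyses.  Selection is by AIC among the
likelihood-based families, with differences below 1e-6 treated as ties
and resolved toward the smaller design; quasi-Poisson candidates appear
only in the RMSE/MAPE report.  MAPE excludes (and counts) zero-count
weeks, where a percentage error is undefined.  A "consistency" mode
forces one lag specification across all categories, reproducing the
common choice of uniformity over marginal per-category gains.

## IRR curves

IRR_i(x) is the ratio of predicted admissions with exposure-lag term i
set to x versus set to its training mean, all other covariates — the
other exposures, the autoregressive terms and the seasonal terms — held
at their training means.  Under the log link the common terms cancel, so
the ratio equals exp(f_i(x) - f_i(x_mean)); the implementation computes
the log-ratio from the difference of basis rows, which makes IRR = 1
*exactly* (not to rounding) at the reference and keeps the
ratio-of-predictions route and the smooth-difference route equal to
< 1e-10, a consistency that is tested.  The grid is 100 quantile-spaced
points of the observed exposure with the reference inserted.  Intervals
are pointwise 95% Wald intervals on the log scale from the variance of
the linear-predictor difference; no simultaneous-band or multiplicity
adjustment is applied (a known limitation), and the interval degenerates
to {1} at the reference.  Points whose interval excludes 1 are flagged
significant (risk or protective).

## PAF series

For one exposure-lag term: remove the exposure, predict the expected
counts under removal with the fitted model, and per week compute
PAF_t = (observed_t - expected_t) / observed_t x 100.  Observed counts
are the actual (or synthetic) counts, not fitted values.  The default
removal mode is **drop-term**: subtract the fitted smooth's contribution
from the linear predictor, i.e. delete f_i from the model.  The literal
alternative — setting the exposure column to zero — is retained as mode
"set-zero" because removing the smooth is exactly what that step is
intended to achieve, while an actual zero (e.g. temperature 0 degC
against a 25-30 degC range) forces long-range extrapolation of the
spline; when chosen it triggers the extrapolation warnings.  PAF can be
negative (protective exposure) and is always < 100% because expected
counts are strictly positive under the log link.  Weeks with zero
observed counts are excluded and counted.

The weekly PAF points are summarised against the lagged exposure value by
local-linear regression with tricube weights (span 0.75, 100-point grid).
The pointwise band comes from the equivalent kernel and a residual
variance estimated at the data points; it is a smoother band, not a full
propagation of model uncertainty (lambda estimation uncertainty is not
propagated), and is labelled as such.  Per-category curves are computed
and then overlaid by physiological-system group (cardiorespiratory /
metabolic-digestive / others) for display.

## Upstream data preparation

**Station weather to national weekly exposures.**  Daily station
observations are interpolated to a raster by inverse distance weighting;
predictions are convex combinations of station values with weights
d^-p, stations within 1e-9 km take over exactly, and the power p is
selected from a candidate grid (0.5 to 5.0 in steps of 0.25 by default)
by leave-one-out RMSE, ties toward the smallest power.  Distances are
planar Euclidean km — at city-state scale the geodesic correction is
negligible, and the synthetic geometry is planar by construction.  The
default raster is 1 km cells over the 10%-padded station bounding box.
The national weekly value is the unweighted mean over the epi-week of the
daily rasters' spatial means (a population-weighting hook is reserved);
weekly rainfall is likewise the mean of daily totals, which is what the
emulated summary statistics are consistent with.  Incomplete epi-weeks
are an error naming the missing dates, never silently imputed.

**Zone AQI to national concentrations.**  Zone-level AQI values are
averaged per day (recording how many zones contributed), then converted
to concentration units by inverting the US-EPA breakpoint table (PM10
ug/m3, SO2 ppb, CO ppm), shipped as a checksummed CSV asset.  The EPA
bands are contiguous in integer AQI, so real-valued zone means fall into
gaps such as (50, 51); short bridge segments map those AQI gaps linearly
onto the matching concentration gaps, making the conversion strictly
increasing, exact at every printed edge, and exactly invertible.
Average-then-convert follows the stated protocol order; convert-then-
average is available as a sensitivity flag (the two differ only when
zones straddle a band edge).  Sub-daily aggregation and NowCast rules are
out of scope; daily AQI values are taken as given.

## Synthetic data generator

The generator emulates the study conditions: 261 epi-weeks (2014-2018,
MMWR convention, 2014 having 53 weeks), 12 admission categories with the
published weekly-count baselines, and exposure marginals matching the
published summary statistics (mean, sd, range, units).  Each exposure is
a truncated AR(1) Gaussian with autocorrelation 0.5; the latent mean and
sd are moment-matched so the *truncated* marginal hits the target
moments (a naive truncation would bias rainfall's mean upward by ~13%).
PM10 additionally carries a haze-spike process (probability 0.02/week,
multiplier uniform on 2-4, clipped to the observed maximum), emulating
transboundary haze years; the base process variance is deflated so the
spiked marginal still matches the target sd.  Exposure cross-correlation
is available as a shared-innovation knob but defaults to zero — no
target values exist for it.

Admission counts are drawn sequentially from the same model family the
engine fits: intercept = log of the category baseline, a library of truth
smooths (linear, hockey-stick, inverted-U — the qualitative curve types
the analysis is meant to detect) centered to be zero at the exposure
mean, linear autoregressive feedback on the relative deviation of lagged
counts from baseline, a sinusoidal weekly seasonal term and a linear
year trend.  The first max-lag weeks are seeded at the stationary
baseline.  Because the truth smooths are centered, the oracles are closed
form: oracle IRR(x) = exp(f(x)), and the oracle per-week PAF from
removing a smooth with contribution c_t is (1 - exp(-c_t)) x 100.

What the generator does **not** emulate: real station geometry or
spatial covariance structure, inter-exposure correlations (unreported),
reporting artefacts, holidays, epidemics, or policy breaks.  Passing
recovery tests therefore demonstrates that the pipeline recovers effects
of the assumed functional form under realistic marginals and dependence —
not that the original point estimates are reproducible, which would
require the restricted admissions data.

## Validation suites and problem sizes

The simulation suites (shared by the tests and `scripts/acceptance.py`)
use: 50 seeds of 261-week single-effect Poisson series for IRR-curve and
PAF recovery; 100 seeds each for dispersion calibration (Poisson truth
vs negative-binomial theta = 2 truth); 50 seeds of 3-lag truths for AIC
selection consistency (fitting the full 1/2/3-lag candidate models); 100
randomized small fits for the exact IRR reference identity and the
< 1e-10 route consistency; 20 random IDW surfaces for leave-one-out power
selection.  The full 12-category study at default settings completes in
well under a minute on one CPU.

One calibration caveat: pointwise Wald bands on a hockey-stick truth
undercover in a minority of replicates — over the flat region the true
IRR is exactly 1 while the spline, which cannot represent the kink,
carries a small smoothed-through bias that narrow bands (large counts)
expose.  mgcv's bands behave identically on the same data (checked
seed-for-seed), so this reflects the statistics of pointwise intervals,
not the implementation; across-the-function coverage remains high.

## Known limitations

* No distributed-lag (crossbasis) interaction structure: per-lag smooths
  are additive, as in the fitted formula.
* No simultaneous confidence bands; no multiplicity adjustment across
  grid points, lags, exposures or categories.
* PAF bands quantify smoother uncertainty only.
* Quasi-Poisson enters selection only through RMSE/MAPE, never AIC.
* The breakpoint inversion assumes daily AQI values are index values of
  the shipped table's pollutants; NowCast-type temporal reweighting is
  out of scope.
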