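# edattrib

Quantifying how weather and ambient air pollution drive weekly
emergency-department (ED) admissions — and how much of each cause-specific
admission load is attributable to each exposure.

The package is for epidemiologists and health-system analysts working
with weekly count time series of admissions (or similar health events)
alongside environmental exposures.  It implements the full analysis
chain:

1. **Exposure preparation** — inverse-distance-weighted (IDW)
   interpolation of daily station weather to rasters, with the distance
   power chosen by leave-one-out cross-validation, aggregated to national
   epi-week means; zone-level air-quality-index (AQI) values averaged and
   converted to concentration units by inverting the US-EPA breakpoint
   table.
2. **Lagged additive count regression** — for each admission category,
   counts Y_t are modelled as

   log E[Y_t] = β₀ + Σₙ f(Y_{t−n}) + Σᵢ Σₙ f_{i,n}(X_{i,t−n}) + s(Week_t) + s(Year_t)

   with penalized low-rank spline smooths of every lagged exposure
   X_{i,t−n} (rainfall mm, temperature °C, wind km/hr, PM₁₀ μg/m³, SO₂
   ppb, CO ppm; lags n = 1..3 weeks), autoregressive smooths of the
   lagged counts, and cyclic weekly plus annual seasonal smooths.
   Families: Poisson, quasi-Poisson, negative binomial.  Smoothing
   parameters are selected by REML; candidate formulas (family × max lag
   × immediate effects) are compared by AIC (RMSE/MAPE for
   quasi-Poisson).
3. **Incidence rate ratios (IRR)** — counterfactual exposure-response
   curves IRR_i(x) = E[Ŷ | X_i = x, rest at means] / E[Ŷ | X_i = x̄, rest
   at means], with pointwise 95% intervals and significance flags.
4. **Population attributable fractions (PAF)** — per week,
   PAF_t = (observed_t − expected_t under removal of the exposure) /
   observed_t × 100, with loess-smoothed PAF-versus-exposure trend curves
   by physiological-system group.

Because admissions data of this kind is typically restricted, a
first-class synthetic-data generator reproduces the study conditions
(261 epi-weeks, 12 admission categories, published exposure marginals,
autocorrelation, haze spikes) from a generative model of exactly the
fitted form — with closed-form IRR/PAF oracles, so recovery of known
truth is testable end to end.

## Worked example

```python
import numpy as np
import edattrib as ea
from edattrib.features import build_lag_design
from edattrib.gam import fit_gam, score

exposures = ea.generate_exposures(n_weeks=261, seed=1)
truth = ea.default_truth("Respiratory infection")
admissions = ea.generate_admissions(exposures, truth, seed=2)

design = build_lag_design(admissions, exposures, max_lag=3)
model = fit_gam(design, family="poisson")
s = score(model, design)
print(f"AIC {s.aic:.1f}  RMSE {s.rmse:.1f}  MAPE {s.mape:.2f}%  "
      f"dispersion {model.dispersion_:.2f}")

curve = ea.irr_curve(model, design, "co_ppm", lag=1)
i = np.argmax(curve.grid)
print(f"IRR at {curve.grid[i]:.2f} ppm CO (lag 1): "
      f"{curve.irr[i]:.2f} (95% CI {curve.lo[i]:.2f}-{curve.hi[i]:.2f})")

ps = ea.paf_series(model, design, "co_ppm", lag=1)
x = design.frame["co_ppm_lag1"]
hi = (x >= x.quantile(0.9)).to_numpy()
print(f"mean PAF over the top-decile CO weeks: "
      f"{ps.frame.loc[hi, 'paf_pct'].mean():.1f}%")
oracle = ea.oracle_paf(truth, exposures, "co_ppm", 1)
print(f"truth-model oracle for the same weeks:  "
      f"{oracle.loc[ps.frame['week_index'][hi]].mean():.1f}%")
```

Output:

```
AIC 2794.4  RMSE 44.2  MAPE 1.53%  dispersion 1.05
IRR at 0.75 ppm CO (lag 1): 1.21 (95% CI 1.18-1.24)
mean PAF over the top-decile CO weeks: 4.3%
truth-model oracle for the same weeks:  3.8%
```

Reading this: the model fits the 258 usable weeks with a Pearson
dispersion near 1 (no residual overdispersion).  At the highest observed
lag-1 CO concentration, admissions are predicted 21% above the
at-mean-CO counterfactual, and the interval excludes 1.  Over the
windiest-in-CO tenth of weeks, about 4% of observed admissions are
attributed to CO one week prior — close to the generator's closed-form
oracle (3.8%), which is the kind of recovery the test suite checks
systematically.

A command-line interface wraps the same pipeline:

```bash
edattrib simulate --seed 1 --out data/          # synthetic study bundle
edattrib fit --data data/ --out results/        # candidate grid + selection
edattrib effects --data data/ --out results/    # irr_curves.csv
edattrib attribute --data data/ --out results/  # paf_series.csv, paf_curves.csv
edattrib run --seed 1 --out results/            # everything incl. figures
```

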