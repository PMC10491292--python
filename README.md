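# heatlimits

Detection and projection of **noncompensable heat stress** — outdoor
conditions under which a healthy human can no longer hold a stable core
temperature without external cooling — from daily weather-station-style
records and climate-model-style ensembles.

The package is for climate and health-impact researchers who want to ask:
*given an empirical physiological limit in temperature–humidity space, how
often is it crossed today, and how often will it be crossed at 1.0–3.5 °C
of global warming?*

## What it computes

1. **Threshold.** A quadratic critical-humidity curve q(T) is fit by least
   squares to laboratory calibration points.  Any hourly state (T, RH) maps
   to a signed exceedance scalar s = RH − q(T) (positive = noncompensable)
   and a binary flag (s > 0).
2. **Diurnal reconstruction.** Daily max/min/mean of T and RH are expanded
   to hourly series as fixed-frequency sinusoids (offset = mean, amplitude
   = half-range, T and RH 180° out of phase).  The annual block maximum is
   the largest 6-hour rolling mean of s — six hours because core
   temperature rises ≈1 °C/hour under noncompensable conditions and the
   37 → 43 °C lethal margin is six degrees.
3. **Station QC.** Staged filters (land, |lat| ≤ 60°, ≤ 50 % missing,
   no early-era record maximum, inhomogeneity ≤ 1 °C) and two-tier gap
   filling (seasonal-harmonic regression for runs < 5 days; regression on
   the three nearest complete neighbors within 100 km otherwise).
4. **Extremes.** Stationary and nonstationary GEV fits to the annual maxima
   by Nelder-Mead maximum likelihood,

   F(x; μ, σ, ξ) = exp{ −[1 + ξ(x−μ)/σ]^(−1/ξ) },  μ(Tₜ) = a₁ + a₂·Tₜ,

   with Tₜ the annual GMST anomaly; KS adequacy screen, χ²(1)
   likelihood-ratio model selection at α = 0.05, and return periods
   1 / (1 − F(0)) at warming levels 1.0–3.5 °C (censored at 10⁴ years).
5. **Ensembles.** Warming-level sampling (earliest 30-year window whose
   mean GMST reaches each level per member) and pooled empirical return
   periods N/k over 17 × 30 = 510 member-years.
6. **Synthetic data.** Generators for calibration points, GMST series,
   spatially clustered station networks and ensembles whose annual block
   maxima are exactly GEV(a₁ + a₂·GMST, σ, ξ) *through* the diurnal and
   windowing machinery, so every stage has a recoverable ground truth.

Fit-shaped components follow scikit-learn conventions
(`CompensabilityThreshold`, `StationaryGEV`, `NonstationaryGEV` expose
`fit` / `predict` / `decision_function` and trailing-underscore fitted
attributes); module-level functions wrap them.

## Worked example

```python
from heatlimits import (
    SyntheticConfig, generate_station_network, generate_calibration_points,
    fit_threshold, run_station_pipeline,
)

threshold = fit_threshold(generate_calibration_points(seed=0))

# a marginal climate: noncompensable heat is rare today, emerges with warming
config = SyntheticConfig(seed=42, n_stations=8, n_clusters=2, gev_a1=-10.0)
stations, metadata, gmst, truth = generate_station_network(config)
result = run_station_pipeline(stations, threshold, gmst)
```

Output (abridged):

```
threshold q(T) = +0.099 T^2 -11.95 T +369.4   (R^2 = 0.999)
stations kept: 7/8
trend model selected: 7 stations
station SYN0000: mu(T) = -9.97 + 3.09 T, sigma = 1.36, xi = -0.14  (true: -10 + 3 T)
 warming_level_c  return_period_years
             1.0          7507.662348
             1.5           308.527659
             2.0            35.118425
             2.5             7.069148
             3.0             2.258824
             3.5             1.196911
```

Reading it: the fitted curve reproduces the generating quadratic
(R² ≈ 1); seven of eight synthetic stations pass QC and all selected the
GMST-trend model; the first station's fitted location trend (3.09 scalar
units per °C of global warming) recovers the planted value 3.0; and its
return period for a 6-hour noncompensable event collapses from effectively
never (≈ 7500 years) at 1 °C of warming to nearly annual at 3.5 °C — the
characteristic emergence signature the pipeline is built to quantify.
`result.class_shares` aggregates stations into
more-frequent-than-decadal / decadal-to-centennial / rarer-than-centennial
classes per warming level.

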