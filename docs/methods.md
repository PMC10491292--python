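# Methods

## Problem and model

`heatlimits` asks when and where outdoor conditions cross the limit beyond
which a healthy human cannot shed metabolic heat fast enough to hold core
temperature steady — *noncompensable* heat stress — and how the recurrence
of such conditions changes with global warming.

The limit is an empirical curve in dry-bulb temperature / relative humidity
space: a quadratic critical humidity q(T) fit by ordinary least squares
(vertical residuals) to averaged laboratory calibration points, three from
hot-humid and three from hot-dry exposure protocols.  A state (T, RH) is
summarized by the signed exceedance scalar s = RH − q(T): zero on the
curve, positive above it.  The binary noncompensable flag is s > 0; a state
exactly on the curve counts as compensable.  Any strictly monotone,
zero-preserving redefinition of s (perpendicular distance, rescaling)
yields the same flag, so downstream event counts and exceedance-of-zero
return periods do not depend on this choice.

Sustained noncompensable exposure drives core temperature up at roughly
1 °C/hour; from a healthy 37 °C, the 43 °C lethal limit is ~6 hours away,
which fixes the default 6-hour analysis window (9- and 12-hour windows are
supported for sensitivity work).

## Diurnal reconstruction

Archives deliver daily statistics (max/min/mean of T and RH).  Each day is
rebuilt as a 24-hour sinusoid: offset = the daily mean, amplitude = half
the daily range, temperature peaking at 15:00 local time and humidity
exactly 12 h out of phase.  A pure sinusoid cannot simultaneously honor
max, min, and a mean different from (max+min)/2; the mean and amplitude
are honored and the residual against the recorded extremes is logged.
Only the relative phase (180°) matters for window maxima on stationary
days; the absolute 15:00 peak is a climatological convention.  Reconstructed
humidity is clipped to [0, 100] %.

The annual block maximum is the largest mean of the exceedance scalar over
any contiguous 6-hour window of the year; windows roll hourly and may cross
day and year boundaries, with attribution by the window's starting hour.
Event counting tiles runs of consecutive noncompensable hours greedily from
the left with non-overlapping windows (a 13-hour run holds two 6-hour
events); whether real-world counts should use overlapping windows is
ambiguous, and the greedy rule was chosen as the stricter one.

## Station quality control

Filters run in a fixed order, each removal attributed to the first failing
test: nonland stations; stations poleward of 60°; stations missing more
than 50 % of daily records in the analysis period; stations whose highest
6-h exceedance during 1950–1990 beats everything after 2000 (a cooling
extreme record is more plausibly a site artifact); stations with missing
or > 1 °C pairwise temperature-inhomogeneity values (inhomogeneity is
consumed as metadata — computing it is out of scope).  Analysis periods
are half-open year ranges, so 1970–2020 spans 50 analysis years.

Gaps shorter than five consecutive days are filled from the station's own
series with least squares on an intercept + linear-trend + annual +
semiannual harmonic basis — the concrete choice for an otherwise
under-specified "smooth seasonal regression"; the basis is pluggable.
Longer gaps are filled by multivariate linear regression on the three
nearest (great-circle) stations with complete records; a station without
three complete neighbors within 100 km is rejected.  Gap filling never
alters observed values.  Annual maxima are screened for lag-1
autocorrelation (|r₁| > 2/√n flag, informational only).

## Extreme-value inference

Annual block maxima x follow the GEV

F(x; μ, σ, ξ) = exp{ −[1 + ξ(x−μ)/σ]^(−1/ξ) },   1 + ξ(x−μ)/σ > 0,

with ξ > 0 the heavy-tailed and ξ < 0 the bounded-tail domain (heat maxima
typically ξ < 0); |ξ| < 10⁻⁶ switches to the Gumbel form to avoid
overflow.  The nonstationary variant sets μ(Tₜ) = a₁ + a₂·Tₜ with Tₜ the
annual global-mean surface temperature (GMST) anomaly in °C above
preindustrial; σ and ξ stay constant and are estimated per station.

Fitting is maximum likelihood by Nelder-Mead (function/vertex tolerance
10⁻⁸, 10,000-evaluation budget), with Gumbel method-of-moments
initialization for the stationary fit and the stationary optimum with
a₂ = 0 seeding the nonstationary fit — which guarantees the nested
log-likelihood ordering up to optimizer tolerance.  Support violations and
σ ≤ 0 are rejected inside the objective (infinite penalty).  Fits require
at least 20 yearly maxima by default.

Model screening: a Kolmogorov-Smirnov test of the maxima against the
fitted stationary GEV (pass at p ≥ 0.05).  The plain KS null distribution
is only approximate when parameters are estimated from the same sample —
in practice strongly conservative (self-consistent samples pass ≈100 % of
the time); the plain test is used deliberately and this caveat is the
reason the KS stage screens out only gross misfits.  Model choice:
Λ = 2(ℓ_nonstat − ℓ_stat) against χ²(1) at α = 0.05.  **Known
limitation:** with the shape estimated, the plain χ²(1) reference is
anti-conservative in small samples — Monte Carlo with 50-year records puts
the actual type-I rate near 0.064 rather than 0.050 (mean Λ ≈ 1.15; with ξ
fixed the test is calibrated).  The package reports the plain test because
that is the standard screening practice it models; a Bartlett-type
correction would repair calibration but is intentionally not applied.
Across many stations, ≈5 % (nominally) of truly trendless records will be
selected as trending; summaries surface this expectation and apply no
multiplicity correction.

Return periods at a warming level ΔT ∈ {1.0, 1.5, 2.0, 2.5, 3.0, 3.5} °C:
p = 1 − F(0; a₁ + a₂ΔT, σ, ξ) and RP = 1/p years, right-censored at
10,000 years when p underflows (including thresholds beyond a bounded
upper endpoint).  Station shares are classified as more frequent than
1-in-10 (RP < 10), decadal-to-centennial (10 ≤ RP < 100), and rarer than
1-in-100 (RP ≥ 100, censored included), computed over the stations the GEV
pipeline retained.

## Ensemble branch

Members of a model ensemble are sampled by warming level, not calendar:
each member contributes the earliest 30-year window whose mean GMST
anomaly reaches the level.  Pooled return periods are the direct frequency
N/k over the pooled member-years (17 members × 30 years = 510), with k = 0
right-censored as "> N years".  The empirical N/k estimator (rather than
(N+1)/(k+1)) matches direct calculation from observations; censoring
replaces smoothing.  Note p(g) is convex in the within-window anomaly g,
so the pooled frequency sits above p evaluated at the window mean;
validation against analytic values therefore averages p over the actual
window anomalies.

## Synthetic data: what it does and does not emulate

The generator emulates: seasonal and diurnal cycles, a local warming trend
proportional to GMST, spatially clustered stations sharing weather noise
and regional extremes, missing-data runs of both tiers, inhomogeneity
metadata, and — crucially — annual block maxima that are *exactly*
GEV(a₁ + a₂·GMST, σ, ξ) distributed.  The GEV structure is induced through
the pipeline: once per year a regional extreme day is planted whose flat
daily humidity is solved, via the same sinusoid + rolling-window code the
analysis uses, so the year's best 6-h mean exceedance equals the target
GEV draw (verified to ~10⁻¹³ in tests).  Defaults: a₁ = 5, a₂ = 3, σ = 1,
ξ = −0.1 scalar units; 12 stations in 4 clusters; 50-year records;
GMST trend 0.02 °C/yr with 0.08 °C noise; ensemble members with quadratic
GMST ramps reaching 4.5–6.5 °C by 2100 so every member attains the
3.5 °C level at a member-specific date.

Not emulated: synoptic weather (fronts, blocking, monsoons), skewed or
double-peaked diurnal shapes, humidity-temperature covariance beyond the
fixed 180° phase, instrument drift within a record (inhomogeneity is
metadata only), and observation-operator error.  Passing tests therefore
demonstrate that the statistical machinery recovers known structure of the
assumed form — not that real station archives satisfy those assumptions.
Planted extreme days are never overwritten by injected missing runs, so
gap-filled series retain their annual maxima; in real data an extreme
hidden inside a gap is unrecoverable.

## Numerical choices and degenerate inputs

- Threshold fit requires ≥ 3 distinct temperatures (quadratic design);
  R² is clamped to [0, 1] and equals 1 exactly when residuals vanish.
- Wet-bulb temperature (diagnostic only) solves the psychrometer equation
  e = e_s(T_w) − γ(T_w)·P·(T − T_w) with the Magnus saturation curve and
  Assmann coefficient γ = 6.6·10⁻⁴(1 + 0.00115·T_w) K⁻¹ by damped Newton
  iteration at standard pressure 1013.25 hPa; T_w ≤ T with equality at
  saturation.
- Rolling window means use an exact convolution; windows containing missing
  hours are excluded, and an all-missing year yields a flagged NaN maximum.
- A constant covariate refuses the nonstationary fit; a constant maxima
  series is flagged degenerate by the autocorrelation screen.
- Tiny negative Λ from optimizer tolerance is clamped to 0 (p = 1).
- Censoring: return periods are reported at the cap with a censored flag,
  never as infinities.

## Problem sizes

The test and validation runs use sizes chosen to make sampling error small
relative to the asserted tolerances while staying desk-scale: 500-year
records for parameter recovery (tolerances ≈ 4× the replicate spread of a
100-replicate experiment), 100 pipeline replicates for trend-sign
recovery, 2000 null simulations for LLR calibration, 500 replicates for
the KS pass rate, 10⁶ draws for the return-period sampling oracle, and
12-station networks for end-to-end runs.
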