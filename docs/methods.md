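# Methods

This note documents the models, the defaults and the design choices behind
`chingke`, in the spirit of a model-description appendix: what is computed,
under which assumptions, and what the synthetic experiments do and do not
demonstrate.

## Weather derivation

Raw station observations carry mean/max/min temperature, sunshine hours,
10-m wind, relative humidity and precipitation. Derived quantities:

* **Extraterrestrial radiation and daylength** from the FAO-56 astronomy:
  solar declination `0.409·sin(2πJ/365 − 1.39)`, inverse relative Earth–Sun
  distance `1 + 0.033·cos(2πJ/365)`, sunset hour angle
  `ωs = arccos(−tanφ·tanδ)` (clipped for polar situations), daylength
  `N = 24ωs/π`. Internal radiation unit is kJ/m²/day; seasonal totals are
  reported in MJ/m², converting only at the reporting boundary.
* **Global radiation** by Angstrom–Prescott with `a = 0.27`, `b = 0.55`
  (high-plateau calibration): overcast days deliver 27%, clear days 82% of
  the astronomical maximum. By convention a zero-daylength day returns the
  overcast limit; sunshine recorded during polar night is a data error.
* **Vapour pressure** from the Tetens curve
  `e⁰(T) = 0.6108·exp(17.27T/(T+237.3))`, averaged at Tmax and Tmin and
  scaled by mean relative humidity.
* **Wind at 2 m** by the power-law profile with exponent 0.16.
* **Gap policy.** A missing daily mean temperature is imputed as
  `(Tmax+Tmin)/2`; a record missing any other required field, or violating
  `Tmin ≤ Tmax` or the humidity range, is dropped with a logged count.

Growing-season summaries use the *simulated phenological window*
[sowing, maturity], falling back to [sowing, 30 September] when a run never
matures; the effective accumulated temperature (EAT) is the base-0 sum of
daily mean temperature over that window, and the zoning quantity is the
base-0 sum over the full calendar year. A fixed calendar window can be
passed instead — the window is an argument, not a hard-coded rule.

## Crop simulator

A daily-timestep potential-production model of the WOFOST family,
instantiated for spring-type highland barley. "Potential" means water,
nutrients, pests and management are assumed non-limiting; radiation,
temperature and crop traits set the ceiling.

**Phenology.** Thermal time above a 0 °C base (the zoning convention of the
region; no other base is defensible from the variety data). Variety
requirements (°C·day):

| variety | sowing→emergence | emergence→anthesis | anthesis→maturity | sowing date |
|---|---|---|---|---|
| Chaiqing-1 | 100 | 650 | 850 | 10 April |
| Zangqing-2000 | 100 | 700 | 950 | 20 April |
| Diqing-1 | 100 | 800 | 1050 | 30 April |

Each day's effective temperature accrues wholly to the current phase; a
transition fires on the first day its phase sum reaches the requirement
(half-open phase intervals, consistent with the TSUM calibration routine).
Runs that have not matured by 31 October stop with reason `season_end` and
report the storage-organ weight at termination. Such runs are kept in yield
statistics but excluded from trend statistics by default (configurable):
truncated yields are real model output, but their year-to-year variation
mixes phenological censoring with climate signal. No vernalization or
photoperiod response is modelled; the pre-emergence thermal requirement is
the only sowing–emergence control.

**Canopy assimilation.** Instantaneous gross CO₂ uptake follows the
sunlit/shaded-leaf formulation: incoming PAR (half of global radiation) is
split into direct and diffuse by the per-hour atmospheric transmission;
diffuse and scattered-beam components attenuate exponentially (extinction
0.60 diffuse; black-leaf direct extinction `0.5/sinβ · KDIF/(0.8·√(1−σ))`
with scattering σ = 0.2); sunlit leaves add the unscattered beam averaged
over leaf angles. The leaf response is `AMAX·(1−exp(−EFF·I/AMAX))` with
AMAX = 35 kg CO₂/ha/h and EFF = 0.45 (kg CO₂/ha/h)/(J/m²/s). AMAX is
modulated by daytime temperature (zero below 0 °C, optimum 15–25 °C,
collapsing at 35 °C), by development stage (full to anthesis, ~63% at
DVS 1.3, ~22% at maturity — the barley flag-leaf/ear ageing shape), and by
a cold-night factor rising from 0 at a 7-day running Tmin of −5 °C to 1 at
+3 °C. Canopy depth and the diurnal course are each integrated with a
three-point Gaussian; the tests verify agreement within 2% against a dense
trapezoid integration of the same leaf-level response.

**Respiration, partitioning, leaves.** Maintenance respiration is
`(0.03·WLV + 0.015·WST + 0.01·WSO + 0.01·WRT)·2^((T−25)/10)`, capped at
the day's gross assimilation so cold overcast days cannot shrink organs.
Net assimilate is split root/shoot and then leaf/stem/storage by
development-indexed tables (stem fraction defined as the shoot complement,
so fractions sum to one identically); organ growth applies conversion
efficiencies CVL/CVS/CVO/CVR = 0.685/0.662/0.709/0.694. Leaf area grows
exponentially (relative rate 0.0075 per °C·day) while the canopy is young
(DVS < 0.3, LAI < 0.75), source-limited through SLA = 0.0022 ha/kg
afterwards; cohorts age at `T/35` per day and die at a 25-day life span
(at 35 °C), plus a smooth relative death rate above a critical LAI of 4.
Initial dry weight at emergence is 120 kg/ha.

**Carbon audit.** Each run tracks gross assimilation, maintenance,
conversion losses and senesced biomass; closure
`gross − maint − losses − senesced = Δ(live weight)` holds to ~1e-16
relative and is asserted below 1e-6 in the tests.

**Numerical behaviour worth knowing.** Yield responds monotonically to
radiation across the Angstrom-admissible range (overcast to clear sky).
Beyond clear-sky levels the response saturates and can decline by well
under 1%: extra vegetative biomass then costs more grain-fill maintenance
than the light-saturated canopy gains. This is a property of the model
class, not an integration artifact.

**Scale.** On climatology-matched synthetic weather the simulator produces
station-mean potential yields of roughly 6–9 t/ha (harvest index ≈ 0.5).
Published station estimates for the region span 3.5–8.1 t/ha — partly
below the best *experimental* trial yields (up to ~7.5 t/ha), which a
potential-production ceiling should bound from above. Independent
radiation-use-efficiency arithmetic (≈1.3 g DM per MJ intercepted solar,
seasonal totals 2400–3200 MJ/m², HI 0.5) supports the 6–10 t/ha scale.
The end-to-end plausibility check against the published 3.5–8.1 band is
kept strict and currently fails for the sunniest cool stations; we regard
the discrepancy as an open calibration question rather than adjust
physiology parameters post hoc.

## Trend statistics

`S`, the tie-adjusted (default) or plain variance, the continuity-corrected
`Z`, two-sided normal significance classes at 0.1/0.05/0.01 with the
marker convention (`+`, `×`, `*`), Sen's slope by the exact odd/even median
rule on the sorted pairwise-slope list, the median-based intercept
`median(Y − slope·t)`, and per-decade rates as 10× the annual slope.
Testing requires n ≥ 4 (the normal approximation is meaningless below).
Both variance modes are exposed because spreadsheet implementations in
circulation differ; the tie adjustment is the statistically correct choice
and the default. No prewhitening is applied: with AR(1) autocorrelation the
test is mildly anticonservative, which matters for significance classes but
not for slope magnitudes.

## Attribution

First differences `Δx_t = x_t − x_{t−1}` remove linear trends exactly and
are never taken across year gaps. Zones partition the positive axis with
left-closed intervals [2000, 2500) etc., resolving the boundary ambiguity
of conventional "2000–2500 / 2500–3000" labels deterministically; a station
is assigned by the long-term mean of its annual base-0 accumulated
temperature, which is an explicit input (observed EAT definitions vary
between sources). Panels pool station-years without station fixed effects,
matching the single-equation-per-zone reporting form. Stepwise regression
uses entry p = 0.05 / removal p = 0.10 (conventional defaults; both
configurable), refuses rank-deficient additions, and stops once the fit is
numerically perfect. With six candidates at entry p = 0.05 the family-wise
probability of a spurious selection on pure noise is 1 − 0.95⁶ ≈ 26.5%;
the Monte-Carlo tests bound the empirical rate by that quantity. Selected
models are refit by ordinary least squares, so reported coefficients,
F, R² and RMSE are exact OLS quantities on the selected columns.

## Synthetic data

The weather generator emulates what a plateau station archive looks like,
not any particular station: latitude 28–38° N, elevation 2,300–4,500 m, a
lapse-tied annual mean temperature (16.5 °C − 0.0033 °C/m), a mid-summer
cosine harmonic (amplitude 9.5–12 °C), correlated AR(1) anomalies of
Tmax/Tmin (φ = 0.65, σ = 1.9/1.6 °C, cross-correlation 0.7, order-repaired
by swap on the rare inverted draw), imposed warming of 0.33 (Tmax) and
0.47 °C/decade (Tmin), and a sunshine-fraction process whose station mean
is coupled to station warmth (cool eastern-margin stations sit under the
summer monsoon cloud band; warm cropping valleys are sunny) with a slight
dimming trend. Defaults were chosen so growing-season means land inside the
observed regional climatology (season Tave ≈ 10–19 °C, EAT ≈ 1,400–2,700
°C·day, seasonal radiation ≈ 2,400–3,700 MJ/m²).

What the generator does *not* emulate: orographic geography (stations are
exchangeable draws, not a map), precipitation realism (unused at the
potential level), observational gaps and inhomogeneities, and
frost/hail events. Passing tests therefore demonstrate correctness of the
pipeline's statistics and physics under controlled truth — trend recovery,
type-I calibration, coefficient recovery — not skill against real archives.

The panel generator draws the six Δ-predictors from an equicorrelated
Gaussian (pairwise r = 0.2, marginal scales matching plateau panels) and
builds ΔYp from configured coefficients plus Gaussian noise, recording the
truth alongside.

## Reproducibility and problem sizes

All randomness descends from a single seed per run (per-station
sub-streams via seed-sequence spawning), and identical configurations
produce byte-identical archives and pipeline manifests. The default
experiment sizes — 50 stations × 40 years for the pipeline, 5,000 null
series for test calibration, 1,000 replicates for trend and selection
rates, 300 fuzzed series against enumeration oracles — run in about two
minutes total and were chosen to keep Monte-Carlo error comfortably inside
the tolerances they are checked against.

## Known limitations

* Only the potential production level exists: no water- or
  nutrient-limited yields, no transpiration, no soil.
* The vernalization requirement of highland barley (~5–8 days) is not
  modelled separately; it is absorbed into the sowing–emergence TSUM.
* Physiology defaults beyond the variety TSUMs and the parameters listed
  above are standard spring-barley values; the absolute yield scale
  inherits their uncertainty (see "Scale" above).
* The Mann–Kendall implementation is annual-series only (no seasonal
  variant) and applies no prewhitening.
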