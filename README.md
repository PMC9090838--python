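# chingke

Potential-yield simulation of highland barley (qingke, *Hordeum vulgare*
var. *nudum*) on high alpine plateaus, and attribution of its year-to-year
change to climate drivers.

Highland barley is the staple cereal of the Qinghai–Tibet Plateau, grown at
2,300–4,500 m where radiation is abundant, seasons are short, and recent
decades have brought pronounced warming alongside declining sunshine. This
package asks two questions a crop scientist or agroclimatologist would put
to a 40-year daily weather archive:

1. **What yield could the crop reach if only radiation, temperature and its
   own physiology limited growth?** — answered by a daily-timestep
   potential-production crop simulator.
2. **Which climate factor drives the interannual change of that potential
   yield, and does the answer differ between cold and warm zones?** —
   answered by Mann–Kendall/Sen trend statistics and zone-stratified
   first-difference regression.

## The models at the core

**Weather derivation.** Global radiation from relative sunshine duration by
the Angstrom–Prescott relation, `Ra = Ra_max · [a + b·(n/N)]` with plateau
coefficients `a = 0.27`, `b = 0.55` and `Ra_max`, `N` from the FAO-56 solar
geometry; actual vapour pressure `ea = (RH/100)·(e⁰(Tmax)+e⁰(Tmin))/2` with
the Tetens curve; 10-m wind rescaled to 2 m by `V = V₁₀·(2/10)^0.16`.

**Crop simulator.** A WOFOST-style potential-production model: phenology on
thermal time above 0 °C (variety TSUMs: sowing→emergence 100, emergence→
anthesis 650–800, anthesis→maturity 850–1050 °C·day); canopy gross
assimilation as a 3×3 Gaussian integral of the saturating leaf response
`AMAX·(1−exp(−EFF·I/AMAX))` over canopy depth and the diurnal course, with
a sunlit/shaded direct–diffuse light split; Q10 maintenance respiration;
development-indexed partitioning to root, leaf, stem and storage organ;
leaf-cohort senescence by a thermal life span. Potential yield is the
storage-organ dry weight at maturity. Every run carries a carbon ledger
closing to machine precision.

**Trend statistics.** Mann–Kendall `S = ΣΣ sgn(Xj−Xi)` with the
continuity-corrected normal approximation `Z = (S∓1)/σ`,
`σ² = n(n−1)(2n+5)/18` (tie-adjusted by default, "as-printed" mode
available), MAKESENS-style significance classes at 0.1/0.05/0.01, and Sen's
slope — the median of all pairwise slopes — with a median-based intercept.

**Attribution.** Station-year series of potential yield and growing-season
climate (Tave, Tmax, Tmin, EAT, TDR, RA) are first-differenced (removing
long-term trends), pooled into five accumulated-temperature zones
(<2000 … >3500 °C·day), and analysed per zone by Pearson correlation and
bidirectional stepwise multiple linear regression (entry p ≤ 0.05, removal
p ≥ 0.10).

A seeded synthetic-weather generator emulates multi-decade alpine station
archives (elevation-tied seasonal cycles, correlated AR(1) anomalies,
configurable warming/dimming trends) so the whole pipeline is testable
without any external data.

## Worked example

```bash
python examples/02_potential_yield.py
```

```
variety Chaiqing-1: TSUMs 100 / 650 / 850 C d
sown      2001-04-10
emergence 2001-04-28
anthesis  2001-06-22
maturity  2001-08-11 (maturity, 105 days)
potential yield 7.51 t/ha of 14.77 t/ha total dry matter (max LAI 4.1)
carbon-balance closure error 1.4e-16 (relative; assimilate in = growth + respiration + losses)
```

The crop needed 18 days to accumulate the 100 °C·day emergence requirement,
flowered after a further 650 °C·day, and matured 105 days after emergence.
7.51 t/ha is the radiation- and temperature-limited ceiling for that
station-year — what the stand could produce with no water or nutrient
stress; the harvest index is 7.51/14.77 ≈ 0.51.

The other examples cover weather preprocessing (`01`), trend testing on a
warming Tmin series (`03`), stepwise attribution recovering a known
2.34 kg/ha per MJ/m² radiation coefficient (`04`), and the full pipeline
with per-zone regression tables (`05`). The same stages are scriptable from
the shell:

```bash
chingke run-all -o demo_run --seed 5 --n-stations 8 --year-start 1990 --year-end 2009
```

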