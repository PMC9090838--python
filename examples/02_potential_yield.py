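"""Simulate one potential-production season of highland barley.

Runs the daily crop model on a synthetic station-year: thermal-time
phenology, canopy assimilation, Q10 maintenance respiration, dry-matter
partitioning and leaf senescence. Prints the phenological calendar, the
potential yield (storage-organ dry matter, water and nutrients assumed
non-limiting) and the carbon-balance audit of the run.
"""

import pandas as pd

import chingke as ck
from chingke.weather import derive_daily

meta, daily = ck.gen_station_weather(
    ck.WeatherGenConfig(seed=7, n_stations=1, year_start=2000, year_end=2003)
)
row = meta.iloc[0]
station = ck.StationMeta(row.station_id, row["name"], row.lat, row.lon,
                         row.elev, row.variety)
derived = derive_daily(daily, station)

params = ck.get_params(station.variety)
month, day = ck.SOWING_DATE[station.variety]
result = ck.run_potential(derived, params, pd.Timestamp(2001, month, day),
                          latitude=station.latitude)

print(f"variety {params.variety}: TSUMs {params.tsum_em:.0f} / "
      f"{params.tsum1:.0f} / {params.tsum2:.0f} C d")
print(f"sown      {result.sowing_date.date()}")
print(f"emergence {result.emergence_date.date()}")
print(f"anthesis  {result.anthesis_date.date()}")
print(f"maturity  {result.maturity_date.date()} "
      f"({result.termination_reason}, {result.growing_duration} days)")
print(f"potential yield {result.potential_yield / 1000:.2f} t/ha "
      f"of {result.total_biomass / 1000:.2f} t/ha total dry matter "
      f"(max LAI {result.max_lai:.1f})")
print(f"carbon-balance closure error {result.carbon_closure_error:.1e} "
      "(relative; assimilate in = growth + respiration + losses)")
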