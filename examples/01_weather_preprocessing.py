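"""Derive simulation-ready weather from raw station observations.

Generates one synthetic alpine station, derives solar radiation
(Angstrom-Prescott on FAO-56 extraterrestrial radiation), actual vapour
pressure (Tetens), 2-m wind and the diurnal temperature range, then prints
a growing-season summary.
"""

import pandas as pd

import chingke as ck
from chingke.weather import derive_daily, seasonal_summary

meta, daily = ck.gen_station_weather(
    ck.WeatherGenConfig(seed=7, n_stations=1, year_start=2000, year_end=2003)
)
row = meta.iloc[0]
station = ck.StationMeta(row.station_id, row["name"], row.lat, row.lon,
                         row.elev, row.variety)
derived = derive_daily(daily, station)

print(f"station at {station.latitude:.2f}N, {station.elevation:.0f} m, "
      f"variety {station.variety}")
print(derived.loc[200:203, ["date", "tave", "tdr", "ra", "ea", "wind2"]]
      .to_string(index=False))

summary = seasonal_summary(derived, (pd.Timestamp("2001-04-10"),
                                     pd.Timestamp("2001-09-30")))
print(f"\ngrowing season 2001 (10 Apr - 30 Sep):")
print(f"  mean Tave {summary.tave:.1f} C, mean TDR {summary.tdr:.1f} C")
print(f"  EAT {summary.eat:.0f} C d  (base-0 accumulated mean temperature)")
print(f"  seasonal radiation total {summary.ra_total:.0f} MJ/m2")
print(f"  annual accumulated temperature {summary.annual_at0:.0f} C d "
      f"-> zone {ck.classify_zone(summary.annual_at0)}")
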