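"""Photoperiod at the study site and the energy value of hypothermia.

The study site (67.00N, 17.67E, northern Sweden) has ~1.5 h of daylight at
the December solstice and polar day around the June solstice. Sunrise and
sunset use the sun's top edge at the horizon (centre altitude -0.833 deg);
dawn/dusk are civil twilight (-6 deg).

The energetics model treats thermoregulatory heat loss as proportional to
the T_b - T_a gradient, so a sustained T_b reduction saves
(tb_ref - tb_low) / (tb_ref - ta) of that cost.
"""

import datetime as dt

from gulotherm import EnergyScenario, energy_saving, season_of, sun_events
from gulotherm.solar import annual_day_lengths

LAT, LON = 67.0, 17.67

for date in (dt.date(2013, 3, 20), dt.date(2013, 6, 21),
             dt.date(2013, 12, 21)):
    day = sun_events(date, LAT, LON)
    rise = day.sunrise.strftime("%H:%M") if day.sunrise else "--"
    sett = day.sunset.strftime("%H:%M") if day.sunset else "--"
    print(f"{date} ({season_of(date):6s}): day length "
          f"{day.day_length_h:5.2f} h  sunrise {rise} sunset {sett} UTC  "
          f"[{day.regime.value}]")

df = annual_day_lengths(2013, LAT, LON)
print(f"\nannual minimum day length: {df['day_length_h'].min():.2f} h "
      "(December)")
print(f"annual maximum day length: {df['day_length_h'].max():.2f} h "
      "(polar day)")

saving = energy_saving(EnergyScenario(tb_ref=38.5, tb_low=35.8, ta=-10.0))
print(f"\ncooling 38.5 -> 35.8 degC at T_a = -10 degC saves "
      f"{100 * saving:.1f}% of thermoregulatory cost")
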