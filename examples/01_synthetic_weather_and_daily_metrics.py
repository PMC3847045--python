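"""Generate a synthetic multi-year hourly weather series and collapse it to daily metrics.

Each day is characterized by a single value per parameter: mean
(temperature, pressure, humidity), max (gusts), daily sum
(precipitation), and sunshine minutes in the fixed 10-15 UTC window.
"""

import datetime

import meteotrigger as mt

period = (datetime.date(2005, 1, 1), datetime.date(2011, 12, 31))
weather = mt.generate_weather(mt.WeatherGenConfig(period=period, seed=42))["SYN"]
print(f"generated {weather.n_hours} station-hours "
      f"({weather.data.isna().to_numpy().mean():.1%} missing cells)")

dailies = mt.daily_series(weather)
temp = dailies["temperature"]
jan = temp.values[temp.values.index.month == 1]
jul = temp.values[temp.values.index.month == 7]
print(f"daily mean temperature: January {jan.mean():.1f} degC, July {jul.mean():.1f} degC")
# The ~19 degC January-July gap is the generator's seasonal cycle (amplitude 9.5 degC);
# days failing the >=20-of-24-hours completeness rule are missing, not zero:
print(f"usable temperature days: {int(temp.values.notna().sum())} of {len(temp.values)}")
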