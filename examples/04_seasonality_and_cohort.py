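"""Descriptive views: monthly event counts and the clinical cohort table.

Monthly peaks in single years level out when all years are pooled; the
cohort summary reports counts and half-up percentages per category.
"""

import datetime

import meteotrigger as mt

period = (datetime.date(2005, 1, 1), datetime.date(2011, 12, 31))
weather = mt.generate_weather(mt.WeatherGenConfig(period=period, seed=42))["SYN"]
daily = mt.daily_series(weather, parameters=("temperature",))["temperature"]
clim = mt.build_climatology(daily, period)
events = mt.generate_events(
    mt.EventGenConfig(study_period=period, n_events=511, seed=7),
    mt.anomaly_series(daily, clim),
)

dist = mt.seasonal_distribution(events)
print("pooled monthly event counts:", dist.monthly_totals.tolist())
peak = dist.counts.max().max()
print(f"largest single-year monthly count: {int(peak)} "
      f"(pooled counts are much flatter)")

print()
print(mt.summarize_cohort(events).format_text())
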