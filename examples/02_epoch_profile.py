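"""Superposed-epoch view: daily temperature relative to the event day, -5..+5 days.

With uncoupled events (beta = 0) the mean difference at every offset is
tiny compared with the event-to-event spread — no systematic weather
shift accompanies the events.
"""

import datetime

import meteotrigger as mt

period = (datetime.date(2005, 1, 1), datetime.date(2011, 12, 31))
weather = mt.generate_weather(mt.WeatherGenConfig(period=period, seed=42))["SYN"]
daily = mt.daily_series(weather, parameters=("temperature",))["temperature"]
clim = mt.build_climatology(daily, period)
anoms = mt.anomaly_series(daily, clim)
events = mt.generate_events(
    mt.EventGenConfig(study_period=period, n_events=511, effect_size=0.0, seed=7), anoms
)

profile = mt.epoch_profile(daily, events)
print("offset  n    mean    IQR")
for k in range(-5, 6):
    s = profile.summaries[k]
    print(f"{k:+3d}   {s.n:4d}  {s.mean:+6.2f}  [{s.q1:+6.2f}, {s.q3:+6.2f}]")
# offset 0 is identically zero by construction; elsewhere the mean stays
# near 0 degC while the interquartile spread is several degC.
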