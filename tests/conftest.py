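"""Shared fixtures: synthetic worlds reused across test modules.

Everything is generated programmatically at test time; there are no data
files.  Session scope keeps the multi-year worlds to one generation each.
"""

import datetime

import numpy as np
import pandas as pd
import pytest

import meteotrigger as mt


def make_events(dates, period) -> mt.EventSample:
    """EventSample with the given onset dates and no clinical attributes."""
    df = pd.DataFrame({"event_date": list(dates)})
    for c in ("sex", "circulation"):
        df[c] = None
    for c in ("age", "gcs", "hh_grade", "fisher_grade", "wfns_grade"):
        df[c] = np.nan
    cols = ["event_date", "sex", "age", "gcs", "hh_grade", "fisher_grade",
            "wfns_grade", "circulation"]
    return mt.EventSample(data=df[cols], study_period=period)

PERIOD_7Y = (datetime.date(2005, 1, 1), datetime.date(2011, 12, 31))
PERIOD_1Y = (datetime.date(2010, 1, 1), datetime.date(2010, 12, 31))


@pytest.fixture(scope="session")
def weather_1y():
    """One clean (no missingness) synthetic year, one station."""
    conf = mt.WeatherGenConfig(period=PERIOD_1Y, stations=("SYN",), missingness=0.0, seed=11)
    return mt.generate_weather(conf)["SYN"]


@pytest.fixture(scope="session")
def world_7y():
    """Seven-year world with default missingness: weather, dailies, climatology, events.

    The study, reference and sampling periods all coincide with the
    weather period; events are uncoupled (beta = 0).
    """
    conf = mt.WeatherGenConfig(period=PERIOD_7Y, stations=("SYN",), seed=123)
    weather = mt.generate_weather(conf)["SYN"]
    dailies = mt.daily_series(weather)
    clim = mt.build_climatology(dailies["temperature"], PERIOD_7Y)
    anoms = mt.anomaly_series(dailies["temperature"], clim)
    events = mt.generate_events(
        mt.EventGenConfig(study_period=PERIOD_7Y, n_events=511, seed=321), anoms
    )
    return {
        "period": PERIOD_7Y,
        "weather": weather,
        "dailies": dailies,
        "clim": clim,
        "anomalies": anoms,
        "events": events,
    }
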