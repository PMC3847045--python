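"""Round trips and validation of the canonical weather and event CSVs."""

import datetime

import numpy as np
import pandas as pd
import pytest

import meteotrigger as mt
from meteotrigger.io import (
    EventValidationError,
    WeatherValidationError,
    VALUE_COLUMNS,
)


def _one_day_frame(temp=7.3):
    idx = pd.date_range("2010-06-01", periods=24, freq="h", tz="UTC")
    return pd.DataFrame(
        {
            "temp_c": temp,
            "rh_pct": 60.0,
            "gust_ms": 4.0,
            "pressure_hpa": 965.0,
            "precip_mm": 0.0,
            "sunshine_min": 30.0,
        },
        index=idx,
    )


def test_full_day_round_trip(tmp_path):
    s = mt.HourlyWeatherSeries("SMA", _one_day_frame())
    path = tmp_path / "w.csv"
    mt.write_weather(s, path)
    back = mt.read_weather(path, "SMA")
    assert back.n_hours == 24
    assert not back.data.isna().any().any()
    pd.testing.assert_frame_equal(back.data, s.data, check_freq=False)


def test_year_round_trip_preserves_values_and_missing(tmp_path, weather_1y):
    path = tmp_path / "w.csv"
    mt.write_weather(weather_1y, path)
    back = mt.read_weather(path, weather_1y.station_id)
    pd.testing.assert_frame_equal(back.data, weather_1y.data, check_freq=False)


def test_missing_cell_round_trip(tmp_path):
    df = _one_day_frame()
    df.loc[df.index[5], "temp_c"] = np.nan
    s = mt.HourlyWeatherSeries("SMA", df)
    path = tmp_path / "w.csv"
    mt.write_weather(s, path)
    back = mt.read_weather(path, "SMA")
    assert back.data["temp_c"].isna().sum() == 1
    assert back.data["temp_c"].isna().iloc[5]


def test_empty_series_round_trip(tmp_path):
    empty = pd.DataFrame(
        {c: pd.Series(dtype=float) for c in VALUE_COLUMNS},
        index=pd.DatetimeIndex([], tz="UTC"),
    )
    s = mt.HourlyWeatherSeries("SMA", empty)
    path = tmp_path / "w.csv"
    mt.write_weather(s, path)
    back = mt.read_weather(path, "SMA")
    assert back.n_hours == 0


@pytest.mark.parametrize(
    "column,value,needle",
    [
        ("rh_pct", 135.0, "relative_humidity"),
        ("sunshine_min", 75.0, "sunshine"),
        ("precip_mm", -1.0, "precipitation"),
        ("gust_ms", -0.5, "gust"),
    ],
)
def test_out_of_range_value_rejected(tmp_path, column, value, needle):
    df = _one_day_frame()
    df.loc[df.index[3], column] = value
    with pytest.raises(WeatherValidationError, match=needle):
        mt.HourlyWeatherSeries("SMA", df)


def test_duplicate_timestamp_rejected(tmp_path):
    df = _one_day_frame()
    df2 = pd.concat([df, df.iloc[[0]]]).sort_index()
    with pytest.raises(WeatherValidationError, match="duplicate"):
        mt.HourlyWeatherSeries("SMA", df2)


def test_malformed_timestamp_names_line(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "station_id,timestamp_utc,temp_c,rh_pct,gust_ms,pressure_hpa,precip_mm,sunshine_min\n"
        "SMA,2010-06-01T00:00:00Z,7.3,60,4.0,965.0,0.0,30\n"
        "SMA,not-a-time,7.3,60,4.0,965.0,0.0,30\n"
    )
    with pytest.raises(WeatherValidationError, match="line 3"):
        mt.read_weather(path, "SMA")


def test_reader_sorts_rows(tmp_path):
    s = mt.HourlyWeatherSeries("SMA", _one_day_frame())
    path = tmp_path / "w.csv"
    mt.write_weather(s, path)
    lines = path.read_text().splitlines()
    shuffled = [lines[0]] + lines[1:][::-1]
    path.write_text("\n".join(shuffled) + "\n")
    back = mt.read_weather(path, "SMA")
    assert back.data.index.is_monotonic_increasing


def _write_events_csv(path, rows):
    header = "event_date,sex,age,gcs,hh_grade,fisher_grade,wfns_grade,circulation"
    path.write_text("\n".join([header] + rows) + "\n")


PERIOD = (datetime.date(2004, 1, 1), datetime.date(2012, 3, 31))


def test_events_duplicates_preserved(tmp_path):
    path = tmp_path / "e.csv"
    _write_events_csv(path, ["2005-03-01,F,52,15,2,3,1,anterior",
                             "2005-03-01,M,60,14,1,4,2,posterior"])
    sample = mt.read_events(path, PERIOD)
    assert sample.n == 2
    assert sample.dates == [datetime.date(2005, 3, 1)] * 2


def test_events_count_equals_rows(tmp_path):
    path = tmp_path / "e.csv"
    rows = [f"2005-{m:02d}-15,,,,,,," for m in range(1, 13)] * 3
    _write_events_csv(path, rows)
    assert mt.read_events(path, PERIOD).n == 36


def test_event_outside_study_period_rejected(tmp_path):
    path = tmp_path / "e.csv"
    _write_events_csv(path, ["2003-12-31,,,,,,,"])
    with pytest.raises(EventValidationError, match="study period"):
        mt.read_events(path, PERIOD)


def test_unparseable_grade_rejected(tmp_path):
    path = tmp_path / "e.csv"
    _write_events_csv(path, ["2005-03-01,,,x,,,,"])
    with pytest.raises(EventValidationError, match="gcs"):
        mt.read_events(path, PERIOD)


def test_grade_out_of_range_rejected(tmp_path):
    path = tmp_path / "e.csv"
    _write_events_csv(path, ["2005-03-01,,,15,6,,,"])
    with pytest.raises(EventValidationError, match="hh_grade"):
        mt.read_events(path, PERIOD)


def test_events_round_trip(tmp_path, world_7y):
    path = tmp_path / "e.csv"
    mt.write_events(world_7y["events"], path)
    back = mt.read_events(path, world_7y["events"].study_period)
    assert back.n == world_7y["events"].n
    assert back.dates == world_7y["events"].dates
    pd.testing.assert_series_equal(back.data["hh_grade"], world_7y["events"].data["hh_grade"])
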