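"""Reading, writing and validating the canonical on-disk formats.

Two file formats are defined here:

* **Hourly weather CSV** (wide, one row per station-hour)::

      station_id,timestamp_utc,temp_c,rh_pct,gust_ms,pressure_hpa,precip_mm,sunshine_min

  Timestamps are ISO 8601 UTC with a ``Z`` suffix and label the *start* of
  the hour.  Missing measurements are empty cells, never sentinel numbers.
  Values are written at measurement precision: one decimal for temperature,
  pressure, gusts and precipitation; whole numbers for relative humidity
  and sunshine minutes.

* **Event-list CSV** (one row per patient event)::

      event_date,sex,age,gcs,hh_grade,fisher_grade,wfns_grade,circulation

  ``event_date`` is the day of symptom onset (ISO 8601 date); all clinical
  attributes are optional and may be blank.  Duplicate dates are allowed —
  several patients can share one onset day.

All timestamps and calendar days in this package are UTC; a "day" is the
UTC calendar day.
"""

from __future__ import annotations

import dataclasses
import datetime
from pathlib import Path

import numpy as np
import pandas as pd

#: analysis-level parameter names, in canonical order
PARAMETERS = (
    "temperature",
    "relative_humidity",
    "gust",
    "pressure",
    "precipitation",
    "sunshine",
)

#: map from parameter name to its weather-CSV column
PARAM_TO_COLUMN = {
    "temperature": "temp_c",
    "relative_humidity": "rh_pct",
    "gust": "gust_ms",
    "pressure": "pressure_hpa",
    "precipitation": "precip_mm",
    "sunshine": "sunshine_min",
}

VALUE_COLUMNS = tuple(PARAM_TO_COLUMN.values())
WEATHER_COLUMNS = ("station_id", "timestamp_utc") + VALUE_COLUMNS

#: decimals used when writing each value column
WRITE_DECIMALS = {
    "temp_c": 1,
    "rh_pct": 0,
    "gust_ms": 1,
    "pressure_hpa": 1,
    "precip_mm": 1,
    "sunshine_min": 0,
}

EVENT_COLUMNS = (
    "event_date",
    "sex",
    "age",
    "gcs",
    "hh_grade",
    "fisher_grade",
    "wfns_grade",
    "circulation",
)

_GRADE_RANGES = {
    "gcs": (3, 15),
    "hh_grade": (1, 5),
    "fisher_grade": (1, 4),
    "wfns_grade": (1, 5),
}


class WeatherValidationError(ValueError):
    """A weather file or series violates a documented invariant."""


class EventValidationError(ValueError):
    """An event file violates a documented invariant."""


@dataclasses.dataclass
class HourlyWeatherSeries:
    """Hourly meteorological measurements for one station.

    Parameters
    ----------
    station_id
        Short station identifier (e.g. ``"SMA"``).
    data
        DataFrame indexed by a strictly increasing, tz-aware UTC
        :class:`~pandas.DatetimeIndex` on whole hours, with the six value
        columns of :data:`VALUE_COLUMNS` (float; NaN marks missing).
    """

    station_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data.index.name = "timestamp_utc"
        self.validate()

    def validate(self) -> None:
        df = self.data
        idx = df.index
        if not isinstance(idx, pd.DatetimeIndex) or idx.tz is None:
            raise WeatherValidationError("index must be a tz-aware DatetimeIndex (UTC)")
        if len(idx) == 0:
            return
        if not idx.is_unique:
            dup = idx[idx.duplicated()][0]
            raise WeatherValidationError(f"duplicate timestamp {dup.isoformat()}")
        if not idx.is_monotonic_increasing:
            raise WeatherValidationError("timestamps must be sorted increasing")
        if ((idx.minute != 0) | (idx.second != 0) | (idx.microsecond != 0)).any():
            raise WeatherValidationError("timestamps must fall on whole hours")
        _check_ranges(df, context=f"station {self.station_id}")

    @property
    def n_hours(self) -> int:
        return len(self.data)

    def parameter(self, name: str) -> pd.Series:
        """Hourly values of one analysis parameter (NaN = missing)."""
        return self.data[PARAM_TO_COLUMN[name]]


def _check_ranges(df: pd.DataFrame, context: str = "") -> None:
    """Raise on out-of-range values, naming the offending row and field."""
    checks = [
        ("rh_pct", lambda s: (s < 0) | (s > 100), "relative_humidity outside [0, 100]"),
        ("sunshine_min", lambda s: (s < 0) | (s > 60), "sunshine outside [0, 60]"),
        ("precip_mm", lambda s: s < 0, "negative precipitation"),
        ("gust_ms", lambda s: s < 0, "negative gust"),
        ("pressure_hpa", lambda s: s <= 0, "non-positive pressure"),
    ]
    for col, bad_fn, msg in checks:
        bad = bad_fn(df[col]) & df[col].notna()
        if bad.any():
            where = df.index[bad][0]
            raise WeatherValidationError(
                f"{msg} (column {col}) at row {where} {context}".strip()
            )


@dataclasses.dataclass
class EventSample:
    """A sample of event days with optional clinical attributes.

    ``data`` has the columns of :data:`EVENT_COLUMNS`; ``event_date`` holds
    :class:`datetime.date` objects, duplicates allowed.  ``study_period``
    is the inclusive (start, end) date interval every event must fall in.
    """

    data: pd.DataFrame
    study_period: tuple[datetime.date, datetime.date]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        start, end = self.study_period
        for d in self.data["event_date"]:
            if not (start <= d <= end):
                raise EventValidationError(
                    f"event_date {d} outside study period {start}..{end}"
                )
        for col, (lo, hi) in _GRADE_RANGES.items():
            vals = pd.to_numeric(self.data[col], errors="coerce")
            present = self.data[col].notna()
            bad = present & (vals.isna() | (vals < lo) | (vals > hi))
            if bad.any():
                raise EventValidationError(
                    f"{col} value {self.data[col][bad].iloc[0]!r} outside {lo}..{hi}"
                )
        sex_bad = self.data["sex"].notna() & ~self.data["sex"].isin(["F", "M"])
        if sex_bad.any():
            raise EventValidationError(f"sex must be F or M, got {self.data['sex'][sex_bad].iloc[0]!r}")
        circ_bad = self.data["circulation"].notna() & ~self.data["circulation"].isin(
            ["anterior", "posterior"]
        )
        if circ_bad.any():
            raise EventValidationError("circulation must be anterior or posterior")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def dates(self) -> list[datetime.date]:
        """Event dates in file order, duplicates preserved."""
        return list(self.data["event_date"])


def read_weather(path: str | Path, station_id: str) -> HourlyWeatherSeries:
    """Read the hourly weather CSV at ``path`` for one station.

    Rows of other stations in the same file are ignored.  Empty cells
    become NaN; rows are sorted by timestamp.  Malformed timestamps,
    duplicate timestamps and out-of-range values raise
    :class:`WeatherValidationError` naming the offending line.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"station_id": str, "timestamp_utc": str})
    missing_cols = set(WEATHER_COLUMNS) - set(df.columns)
    if missing_cols:
        raise WeatherValidationError(f"missing columns: {sorted(missing_cols)}")
    df = df[df["station_id"] == station_id].copy()
    ts = pd.to_datetime(df["timestamp_utc"], utc=True, format="ISO8601", errors="coerce")
    if ts.isna().any():
        line = int(df.index[ts.isna()][0]) + 2  # +1 header, +1 one-based
        raise WeatherValidationError(
            f"malformed timestamp {df['timestamp_utc'][ts.isna()].iloc[0]!r} at line {line} of {path.name}"
        )
    for col in VALUE_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    df = df.set_index(pd.DatetimeIndex(ts, name="timestamp_utc"))
    df = df[list(VALUE_COLUMNS)].sort_index()
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated()][0]
        raise WeatherValidationError(f"duplicate timestamp {dup.isoformat()} in {path.name}")
    return HourlyWeatherSeries(station_id=station_id, data=df)


def write_weather(series_list, path: str | Path) -> None:
    """Write one or more :class:`HourlyWeatherSeries` to a single CSV.

    Values are rounded to the declared precision (:data:`WRITE_DECIMALS`);
    missing values become empty cells.  ``read_weather(path, sid)``
    reproduces each series exactly for data already at that precision.
    """
    if isinstance(series_list, HourlyWeatherSeries):
        series_list = [series_list]
    frames = []
    for s in series_list:
        out = pd.DataFrame(index=s.data.index)
        out.insert(0, "station_id", s.station_id)
        out.insert(1, "timestamp_utc", s.data.index.strftime("%Y-%m-%dT%H:%M:%SZ"))
        for col in VALUE_COLUMNS:
            dec = WRITE_DECIMALS[col]
            fmt = f"%.{dec}f"
            vals = s.data[col]
            out[col] = [("" if pd.isna(v) else fmt % v) for v in vals]
        frames.append(out)
    all_out = pd.concat(frames, axis=0) if frames else pd.DataFrame(columns=WEATHER_COLUMNS)
    all_out.to_csv(path, index=False, columns=list(WEATHER_COLUMNS))


def read_events(
    path: str | Path,
    study_period: tuple[datetime.date, datetime.date],
) -> EventSample:
    """Read an event-list CSV; every data row becomes one event.

    Duplicate dates are preserved.  Dates outside ``study_period`` and
    unparseable grades raise :class:`EventValidationError`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sex": str, "circulation": str})
    if "event_date" not in df.columns:
        raise EventValidationError("missing event_date column")
    dates = pd.to_datetime(df["event_date"], format="%Y-%m-%d", errors="coerce")
    if dates.isna().any():
        line = int(df.index[dates.isna()][0]) + 2
        raise EventValidationError(f"malformed event_date at line {line} of {path.name}")
    out = pd.DataFrame({"event_date": [d.date() for d in dates]})
    for col in EVENT_COLUMNS[1:]:
        if col in ("sex", "circulation"):
            out[col] = df[col] if col in df.columns else pd.Series([None] * len(df), dtype=object)
            out[col] = out[col].where(out[col].notna() & (out[col] != ""), None)
        else:
            raw = df[col] if col in df.columns else pd.Series([np.nan] * len(df))
            num = pd.to_numeric(raw, errors="coerce")
            unparseable = raw.notna() & (raw.astype(str).str.strip() != "") & num.isna()
            if unparseable.any():
                raise EventValidationError(
                    f"unparseable {col} value {raw[unparseable].iloc[0]!r} in {path.name}"
                )
            out[col] = num
    return EventSample(data=out, study_period=study_period)


def write_events(sample: EventSample, path: str | Path) -> None:
    """Write an :class:`EventSample` back to the canonical event CSV."""
    df = sample.data.copy()
    df["event_date"] = [d.isoformat() for d in df["event_date"]]
    for col in ("age", "gcs", "hh_grade", "fisher_grade", "wfns_grade"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    for col in ("sex", "circulation"):
        df[col] = df[col].map(lambda v: "" if v is None or pd.isna(v) else v)
    df.to_csv(path, index=False, columns=list(EVENT_COLUMNS))
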