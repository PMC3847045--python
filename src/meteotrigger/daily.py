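"""Collapse hourly series into one value per day per parameter.

Each day is characterized by a single daily value for each parameter:
the daily mean for temperature, pressure and relative humidity; the daily
maximum for wind gusts; the daily sum for precipitation (mm/day); and the
sunshine minutes integrated over the five hours starting 10:00 through
14:00 UTC (half-open [10:00, 15:00); maximum 300 min).  The fixed UTC
sunshine window keeps the measure comparable across the seasonal shift of
sunrise and sunset.

Completeness rules (days failing them yield a missing value, never zero):

* mean and max metrics need >= 20 of the 24 hourly values;
* the precipitation sum needs >= 20 hourly values and treats the missing
  hours as 0 mm (a conservative under-count);
* sunshine needs all 5 window hours.

Missing hours are never interpolated — incomplete days are excluded
downstream rather than imputed.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging

import numpy as np
import pandas as pd

from .io import PARAMETERS, PARAM_TO_COLUMN, HourlyWeatherSeries

log = logging.getLogger(__name__)

#: minimum hourly values for mean/max/sum metrics
MIN_HOURS = 20
#: UTC hours (interval starts) of the sunshine integration window
SUNSHINE_HOURS = (10, 11, 12, 13, 14)

_MEAN_PARAMS = ("temperature", "pressure", "relative_humidity")


@dataclasses.dataclass
class DailyMetricSeries:
    """One value per calendar day for one parameter at one station.

    ``values`` is a float Series indexed by normalized (midnight,
    tz-naive) daily timestamps; NaN marks missing days.
    """

    station_id: str
    parameter: str
    values: pd.Series

    def get(self, date: datetime.date) -> float:
        """Value on ``date``; NaN when missing or outside the series."""
        return float(self.values.get(pd.Timestamp(date), np.nan))

    @property
    def dates(self) -> list[datetime.date]:
        return [ts.date() for ts in self.values.index]

    @property
    def period(self) -> tuple[datetime.date, datetime.date]:
        return self.values.index[0].date(), self.values.index[-1].date()

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: station_id, date, parameter, value."""
        return pd.DataFrame(
            {
                "station_id": self.station_id,
                "date": [d.isoformat() for d in self.dates],
                "parameter": self.parameter,
                "value": self.values.to_numpy(),
            }
        )


def _full_day_span(index: pd.DatetimeIndex) -> tuple[pd.Timestamp, pd.Timestamp] | None:
    """First/last calendar day fully covered by the series' time span."""
    if len(index) == 0:
        return None
    first, last = index[0], index[-1]
    day0 = first.normalize() if first.hour == 0 else first.normalize() + pd.Timedelta(days=1)
    dayN = last.normalize() if last.hour == 23 else last.normalize() - pd.Timedelta(days=1)
    if dayN < day0:
        return None
    return day0, dayN


def _hour_matrix(series: HourlyWeatherSeries, column: str) -> tuple[pd.DatetimeIndex, np.ndarray]:
    """Reindex to the full hourly grid and reshape to (n_days, 24)."""
    span = _full_day_span(series.data.index)
    if span is None:
        empty = pd.DatetimeIndex([], tz="UTC")
        return empty, np.empty((0, 24))
    day0, dayN = span
    grid = pd.date_range(day0, dayN + pd.Timedelta(hours=23), freq="h", tz="UTC")
    vals = series.data[column].reindex(grid).to_numpy(dtype=float)
    days = pd.date_range(day0, dayN, freq="D", tz="UTC")
    return days, vals.reshape(len(days), 24)


def _reduce_day(parameter: str, mat: np.ndarray) -> np.ndarray:
    """Apply the per-parameter daily reduction to an (n_days, 24) matrix."""
    counts = np.sum(~np.isnan(mat), axis=1)
    with np.errstate(invalid="ignore"):
        if parameter in _MEAN_PARAMS:
            out = np.where(counts >= MIN_HOURS, np.nanmean(np.where(np.isnan(mat), np.nan, mat), axis=1), np.nan)
        elif parameter == "gust":
            safe = np.where(counts > 0, np.nanmax(np.where(np.isnan(mat), -np.inf, mat), axis=1), np.nan)
            out = np.where(counts >= MIN_HOURS, safe, np.nan)
        elif parameter == "precipitation":
            out = np.where(counts >= MIN_HOURS, np.nansum(mat, axis=1), np.nan)
        elif parameter == "sunshine":
            win = mat[:, list(SUNSHINE_HOURS)]
            complete = np.sum(~np.isnan(win), axis=1) == len(SUNSHINE_HOURS)
            out = np.where(complete, np.nansum(win, axis=1), np.nan)
        else:
            raise ValueError(f"unknown parameter {parameter!r}")
    return out


def daily_metric(series: HourlyWeatherSeries, parameter: str, date: datetime.date) -> float:
    """The single daily value of ``parameter`` on ``date`` (NaN if missing)."""
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}")
    day0 = pd.Timestamp(date, tz="UTC")
    grid = pd.date_range(day0, day0 + pd.Timedelta(hours=23), freq="h")
    mat = series.data[PARAM_TO_COLUMN[parameter]].reindex(grid).to_numpy(dtype=float)
    return float(_reduce_day(parameter, mat.reshape(1, 24))[0])


def daily_series(
    series: HourlyWeatherSeries, parameters: tuple[str, ...] | None = None
) -> dict[str, DailyMetricSeries]:
    """Daily metric series for each parameter, over fully covered days only.

    Days on which the completeness rule fails are present with NaN.
    """
    parameters = tuple(parameters) if parameters is not None else PARAMETERS
    out: dict[str, DailyMetricSeries] = {}
    for p in parameters:
        if p not in PARAMETERS:
            raise ValueError(f"unknown parameter {p!r}")
        days, mat = _hour_matrix(series, PARAM_TO_COLUMN[p])
        vals = _reduce_day(p, mat)
        if p == "precipitation":
            counts = np.sum(~np.isnan(mat), axis=1)
            partial = int(np.sum((counts >= MIN_HOURS) & (counts < 24)))
            if partial:
                log.info(
                    "station %s: %d precipitation day(s) summed with missing hours treated as 0 mm",
                    series.station_id, partial,
                )
        idx = pd.DatetimeIndex([d.tz_localize(None) for d in days])
        out[p] = DailyMetricSeries(
            station_id=series.station_id,
            parameter=p,
            values=pd.Series(vals, index=idx, name=p),
        )
    return out
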