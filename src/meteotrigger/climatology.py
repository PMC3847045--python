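"""Monthly climatology of daily metrics and anomalies against it.

The climatological baseline is the arithmetic mean of the daily metric for
each calendar month over a multi-year reference period (ten whole years by
default, configurable).  An *anomaly* is a day's metric minus the mean of
its calendar month; the mean anomaly over the reference period itself is
zero by construction (month by month, up to missing data).

Plain monthly bins are used — no harmonic smoothing across months.
"""

from __future__ import annotations

import dataclasses
import datetime

import numpy as np
import pandas as pd

from .daily import DailyMetricSeries

#: fewest usable daily values a calendar month may have in the reference period
MIN_DAYS_PER_MONTH = 28


class ClimatologyError(ValueError):
    """Reference period too sparse to define a monthly climatology."""


@dataclasses.dataclass
class MonthlyClimatology:
    """Calendar-month means of one daily metric over a reference period."""

    station_id: str
    parameter: str
    reference_period: tuple[datetime.date, datetime.date]
    means: dict[int, float]  # calendar month 1..12 -> mean

    def __post_init__(self) -> None:
        if sorted(self.means) != list(range(1, 13)):
            raise ClimatologyError("climatology must have exactly months 1..12")

    def month_mean(self, month: int) -> float:
        return self.means[month]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "station_id": self.station_id,
                "parameter": self.parameter,
                "month": list(range(1, 13)),
                "mean": [self.means[m] for m in range(1, 13)],
            }
        )


def build_climatology(
    daily: DailyMetricSeries,
    reference_period: tuple[datetime.date, datetime.date],
) -> MonthlyClimatology:
    """Mean of the daily metric per calendar month over ``reference_period``.

    Raises :class:`ClimatologyError` (naming the month) when any calendar
    month has fewer than :data:`MIN_DAYS_PER_MONTH` usable daily values.
    """
    start, end = reference_period
    if end < start + datetime.timedelta(days=364):
        raise ClimatologyError("reference period must span at least one full year")
    vals = daily.values
    mask = (vals.index >= pd.Timestamp(start)) & (vals.index <= pd.Timestamp(end))
    ref = vals[mask]
    means: dict[int, float] = {}
    for m in range(1, 13):
        month_vals = ref[ref.index.month == m].dropna()
        if len(month_vals) < MIN_DAYS_PER_MONTH:
            raise ClimatologyError(
                f"month {m} has only {len(month_vals)} usable days "
                f"(< {MIN_DAYS_PER_MONTH}) in reference period {start}..{end}"
            )
        means[m] = float(month_vals.mean())
    return MonthlyClimatology(
        station_id=daily.station_id,
        parameter=daily.parameter,
        reference_period=reference_period,
        means=means,
    )


def anomaly(daily: DailyMetricSeries, clim: MonthlyClimatology, date: datetime.date) -> float:
    """Daily metric on ``date`` minus its calendar month's climatological mean.

    Missing daily values propagate to NaN.
    """
    v = daily.get(date)
    if np.isnan(v):
        return float("nan")
    return v - clim.means[date.month]


def anomaly_series(
    daily: DailyMetricSeries,
    clim: MonthlyClimatology,
    period: tuple[datetime.date, datetime.date] | None = None,
) -> DailyMetricSeries:
    """The whole daily series expressed as anomalies (optionally windowed)."""
    vals = daily.values
    if period is not None:
        mask = (vals.index >= pd.Timestamp(period[0])) & (vals.index <= pd.Timestamp(period[1]))
        vals = vals[mask]
    clim_by_month = np.array([clim.means[m] for m in range(1, 13)])
    anoms = vals.to_numpy(dtype=float) - clim_by_month[vals.index.month - 1]
    return DailyMetricSeries(
        station_id=daily.station_id,
        parameter=daily.parameter,
        values=pd.Series(anoms, index=vals.index, name=f"{daily.parameter}_anomaly"),
    )
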