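"""Seasonal distribution of events and the cold/warm season split.

Counts events per (year, month) and pooled per calendar month over a
whole-year window, the descriptive view in which single-year monthly peaks
level out over a long enough study period.  The cold season is Oct–Mar,
the warm season Apr–Sep (a documented convention; each date belongs to
exactly one season).
"""

from __future__ import annotations

import dataclasses
import datetime

import pandas as pd

from .io import EventSample

COLD_MONTHS = frozenset({10, 11, 12, 1, 2, 3})


def season_of(date: datetime.date) -> str:
    """``"cold"`` for Oct–Mar, ``"warm"`` for Apr–Sep."""
    return "cold" if date.month in COLD_MONTHS else "warm"


@dataclasses.dataclass
class SeasonalDistribution:
    """Per-(year, month) and pooled per-month event counts."""

    counts: pd.DataFrame      # index: year, columns: month 1..12
    monthly_totals: pd.Series  # index: month 1..12
    window: tuple[datetime.date, datetime.date]
    n_events: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: year, month, count."""
        long = self.counts.stack().rename("count").reset_index()
        long.columns = ["year", "month", "count"]
        return long


def default_whole_year_window(
    events: EventSample,
) -> tuple[datetime.date, datetime.date]:
    """First through last full calendar year covered by the study period."""
    start, end = events.study_period
    y0 = start.year if start == datetime.date(start.year, 1, 1) else start.year + 1
    y1 = end.year if end == datetime.date(end.year, 12, 31) else end.year - 1
    if y1 < y0:
        raise ValueError("study period contains no whole calendar year")
    return datetime.date(y0, 1, 1), datetime.date(y1, 12, 31)


def seasonal_distribution(
    events: EventSample,
    whole_year_window: tuple[datetime.date, datetime.date] | None = None,
) -> SeasonalDistribution:
    """Event counts per (year, month) within a whole-year window."""
    if whole_year_window is None:
        whole_year_window = default_whole_year_window(events)
    start, end = whole_year_window
    if start != datetime.date(start.year, 1, 1) or end != datetime.date(end.year, 12, 31):
        raise ValueError(f"window {start}..{end} is not whole-year aligned")
    years = list(range(start.year, end.year + 1))
    counts = pd.DataFrame(0, index=pd.Index(years, name="year"),
                          columns=pd.Index(range(1, 13), name="month"))
    n = 0
    for d in events.dates:
        if start <= d <= end:
            counts.loc[d.year, d.month] += 1
            n += 1
    return SeasonalDistribution(
        counts=counts,
        monthly_totals=counts.sum(axis=0),
        window=whole_year_window,
        n_events=n,
    )


def plot_seasonality(dist: SeasonalDistribution, ax=None):
    """Pooled monthly bar chart of event counts."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.bar(dist.monthly_totals.index, dist.monthly_totals.to_numpy(), color="slategray")
    ax.set_xlabel("calendar month")
    ax.set_ylabel("events")
    y0, y1 = dist.window[0].year, dist.window[1].year
    ax.set_title(f"Events per month, {y0}–{y1} pooled (n={dist.n_events})")
    return ax
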