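"""Superposed epoch analysis around event days.

For every event the same daily metric is looked up on the event day and on
the five preceding and five following days, and only the *difference
relative to the event day* is kept.  Aligning all events at offset 0 and
summarizing each offset's differences shows whether systematic weather
shifts accompany the events; by construction the offset-0 distribution is
a point mass at zero.  The analysis is purely descriptive — significance
testing lives in :mod:`meteotrigger.resampling`.

Missing data are handled pairwise per offset: an event whose day −3 metric
is missing still contributes to the other offsets.  Events within five
days of the daily series' boundary are excluded (counted, logged).
Boxplot whiskers follow the 1.5×IQR convention.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging

import numpy as np
import pandas as pd

from .daily import DailyMetricSeries
from .io import EventSample

log = logging.getLogger(__name__)

OFFSETS = tuple(range(-5, 6))


@dataclasses.dataclass
class OffsetSummary:
    """Distribution summary of the event-relative differences at one offset."""

    n: int
    mean: float
    q1: float
    median: float
    q3: float
    lo_whisker: float
    hi_whisker: float


@dataclasses.dataclass
class EpochProfile:
    station_id: str
    parameter: str
    summaries: dict[int, OffsetSummary]
    n_events_used: int
    n_events_edge_dropped: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: station,parameter,offset,n,mean,q1,median,q3,whiskers."""
        rows = []
        for k in OFFSETS:
            s = self.summaries[k]
            rows.append(
                {
                    "station_id": self.station_id,
                    "parameter": self.parameter,
                    "offset": k,
                    "n": s.n,
                    "mean": s.mean,
                    "q1": s.q1,
                    "median": s.median,
                    "q3": s.q3,
                    "lo_whisker": s.lo_whisker,
                    "hi_whisker": s.hi_whisker,
                }
            )
        return pd.DataFrame(rows)


def _summarize(diffs: np.ndarray) -> OffsetSummary:
    q1, med, q3 = np.percentile(diffs, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = diffs[(diffs >= lo_fence) & (diffs <= hi_fence)]
    # fences with no data inside collapse onto the quartiles
    lo = float(inside.min()) if len(inside) else float(q1)
    hi = float(inside.max()) if len(inside) else float(q3)
    return OffsetSummary(
        n=int(len(diffs)),
        mean=float(diffs.mean()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        lo_whisker=lo,
        hi_whisker=hi,
    )


def event_offset_differences(
    daily: DailyMetricSeries, events: EventSample
) -> tuple[dict[int, np.ndarray], int, int]:
    """Per-offset arrays of value(d+k) − value(d); returns (diffs, used, edge-dropped).

    Duplicate event dates contribute once per event.  Pairs with either
    value missing are excluded from that offset only.
    """
    first, last = daily.period
    lo_ok = first + datetime.timedelta(days=5)
    hi_ok = last - datetime.timedelta(days=5)
    value = daily.values
    by_date = {ts.date(): v for ts, v in value.items()}

    usable = [d for d in events.dates if lo_ok <= d <= hi_ok]
    dropped = len(events.dates) - len(usable)
    if dropped:
        log.info(
            "epoch %s/%s: dropped %d event(s) within 5 days of the series boundary",
            daily.station_id, daily.parameter, dropped,
        )
    if not usable:
        raise ValueError("no usable events: all fall within 5 days of the series boundary")

    diffs: dict[int, list[float]] = {k: [] for k in OFFSETS}
    for d in usable:
        v0 = by_date.get(d, np.nan)
        if np.isnan(v0):
            continue
        for k in OFFSETS:
            vk = by_date.get(d + datetime.timedelta(days=k), np.nan)
            if not np.isnan(vk):
                diffs[k].append(vk - v0)
    return {k: np.asarray(v, dtype=float) for k, v in diffs.items()}, len(usable), dropped


def epoch_profile(daily: DailyMetricSeries, events: EventSample) -> EpochProfile:
    """Summarize event-relative differences at offsets −5..+5."""
    diffs, used, dropped = event_offset_differences(daily, events)
    summaries = {}
    for k in OFFSETS:
        arr = diffs[k]
        if len(arr) == 0:
            summaries[k] = OffsetSummary(0, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan)
        else:
            summaries[k] = _summarize(arr)
    return EpochProfile(
        station_id=daily.station_id,
        parameter=daily.parameter,
        summaries=summaries,
        n_events_used=used,
        n_events_edge_dropped=dropped,
    )


def plot_epoch(profile: EpochProfile, ax=None):
    """Boxplot-style figure of an epoch profile (offset vs difference)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    stats = []
    for k in OFFSETS:
        s = profile.summaries[k]
        stats.append(
            {
                "label": str(k),
                "mean": s.mean,
                "med": s.median,
                "q1": s.q1,
                "q3": s.q3,
                "whislo": s.lo_whisker,
                "whishi": s.hi_whisker,
                "fliers": [],
            }
        )
    ax.bxp(stats, showmeans=True)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("day relative to event")
    ax.set_ylabel(f"{profile.parameter} difference vs event day")
    ax.set_title(f"{profile.station_id}: {profile.parameter}")
    return ax
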