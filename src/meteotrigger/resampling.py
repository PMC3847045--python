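"""Monte Carlo resampling tests for event-day weather statistics.

Two per-event statistics are supported:

* ``climatology_anomaly`` — the daily metric on the event day minus the
  monthly climatological mean (is event-day weather *unusual for the time
  of year*?);
* ``two_day_change`` — the daily metric on the event day minus its value
  on a baseline day at least two days earlier (did a *short-term weather
  shift* precede the event?).  If the days two (or three…) days before are
  themselves event days, the baseline walks further back so that the
  comparison is always against a non-event day; the walk gives up after a
  7-day lookback and the event is excluded (counted).

Significance is assessed against a Monte Carlo null that preserves the
seasonal make-up of the sample: each of ``B`` replicates draws random days
from the sampling period with *exactly the observed calendar-month
frequencies* (uniformly, without replacement within each month's pool of
days across years), recomputes the mean statistic, and the observed mean
is located within the resulting null distribution.  ``p_right`` is the
fraction of null means at or above the observed mean (ties count in the
tail — the conservative convention); the effect is declared significant
when the observed mean falls outside the empirical 5th–95th percentile
band (a 10% two-sided level; percentiles are type-7 order statistics).

The seasonal split repeats everything on the cold (Oct–Mar) or warm
(Apr–Sep) events only, to expose effects of opposite sign in the two
half-years that would cancel in the full sample.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging

import numpy as np
import pandas as pd

from .climatology import MonthlyClimatology, anomaly_series
from .daily import DailyMetricSeries
from .io import EventSample
from .seasonality import season_of

log = logging.getLogger(__name__)

KINDS = ("climatology_anomaly", "two_day_change")
SEASONS = ("all", "cold", "warm")

#: maximum lookback (days) for the two-day-change baseline
MAX_LOOKBACK = 7


class ResamplingError(ValueError):
    """Inputs too sparse or inconsistent for a resampling test."""


@dataclasses.dataclass
class StatisticSpec:
    """Which statistic to test, where, and on which seasonal subset."""

    kind: str
    parameter: str
    station_id: str
    season_filter: str = "all"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ResamplingError(f"unknown statistic kind {self.kind!r}")
        if self.season_filter not in SEASONS:
            raise ResamplingError(f"unknown season filter {self.season_filter!r}")


@dataclasses.dataclass
class EventStatistic:
    """Per-event statistic values and their mean."""

    values: np.ndarray
    mean: float
    n_used: int
    n_excluded: int


@dataclasses.dataclass
class ResampleResult:
    """Observed mean statistic located within its Monte Carlo null."""

    kind: str
    parameter: str
    station_id: str
    season_filter: str
    observed_mean: float
    observed_values: np.ndarray
    null_means: np.ndarray
    p_right: float
    p_left: float
    p_two_sided: float
    percentile_05: float
    percentile_95: float
    significant: bool
    B: int
    seed: int
    n_events_used: int
    n_events_excluded: int

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["observed_values"] = [float(v) for v in self.observed_values]
        d["null_means"] = [float(v) for v in self.null_means]
        return d


def _season_mask(dates: list[datetime.date], season: str) -> list[bool]:
    if season == "all":
        return [True] * len(dates)
    return [season_of(d) == season for d in dates]


def _two_day_value(
    d: datetime.date,
    by_date: dict[datetime.date, float],
    event_day_set: set[datetime.date],
) -> float:
    """value(d) − value(baseline), baseline walking back from d−2 past event days."""
    v0 = by_date.get(d, np.nan)
    if np.isnan(v0):
        return np.nan
    for k in range(2, MAX_LOOKBACK + 1):
        b = d - datetime.timedelta(days=k)
        if b in event_day_set:
            continue
        vb = by_date.get(b, np.nan)
        if not np.isnan(vb):
            return v0 - vb
    return np.nan


def event_statistic(
    spec: StatisticSpec,
    daily: DailyMetricSeries,
    clim: MonthlyClimatology | None,
    events: EventSample | list[datetime.date],
    event_day_set: set[datetime.date] | None = None,
) -> EventStatistic:
    """Per-event statistic values over (season-filtered) events, plus the mean.

    ``event_day_set`` is the set of days treated as event days by the
    two-day-change baseline shift; it defaults to the events' own days and
    deliberately is *not* season-filtered — a preceding day occupied by an
    out-of-season event is still an event day.
    """
    dates = events.dates if isinstance(events, EventSample) else list(events)
    if event_day_set is None:
        event_day_set = set(dates)
    keep = _season_mask(dates, spec.season_filter)
    dates = [d for d, k in zip(dates, keep) if k]
    if not dates:
        raise ResamplingError(f"no events in season {spec.season_filter!r}")

    if spec.kind == "climatology_anomaly":
        if clim is None:
            raise ResamplingError("climatology_anomaly requires a MonthlyClimatology")
        anom = anomaly_series(daily, clim)
        by_date = {ts.date(): v for ts, v in anom.values.items()}
        vals = np.array([by_date.get(d, np.nan) for d in dates])
    else:
        by_date = {ts.date(): v for ts, v in daily.values.items()}
        vals = np.array([_two_day_value(d, by_date, event_day_set) for d in dates])

    used = vals[~np.isnan(vals)]
    n_excluded = len(vals) - len(used)
    if n_excluded > 0.5 * len(vals):
        raise ResamplingError(
            f"{n_excluded} of {len(vals)} events excluded (missing data / no baseline): too sparse"
        )
    if n_excluded:
        log.info(
            "%s %s/%s: excluded %d of %d events (missing metric or no eligible baseline)",
            spec.kind, spec.station_id, spec.parameter, n_excluded, len(vals),
        )
    return EventStatistic(
        values=used, mean=float(used.mean()), n_used=len(used), n_excluded=n_excluded
    )


def default_sampling_period(
    study_period: tuple[datetime.date, datetime.date],
) -> tuple[datetime.date, datetime.date]:
    """Largest whole-calendar-year window inside the study period."""
    start, end = study_period
    y0 = start.year if start == datetime.date(start.year, 1, 1) else start.year + 1
    y1 = end.year if end == datetime.date(end.year, 12, 31) else end.year - 1
    if y1 < y0:
        raise ResamplingError("study period contains no whole calendar year")
    return datetime.date(y0, 1, 1), datetime.date(y1, 12, 31)


def _month_pools(
    daily: DailyMetricSeries,
    sampling_period: tuple[datetime.date, datetime.date],
    exclude: set[datetime.date] | None = None,
) -> dict[int, list[datetime.date]]:
    """Eligible days (metric present) per calendar month, pooled across years."""
    start, end = sampling_period
    vals = daily.values
    mask = (vals.index >= pd.Timestamp(start)) & (vals.index <= pd.Timestamp(end))
    vals = vals[mask].dropna()
    pools: dict[int, list[datetime.date]] = {m: [] for m in range(1, 13)}
    for ts, _ in vals.items():
        d = ts.date()
        if exclude and d in exclude:
            continue
        pools[d.month].append(d)
    return pools


def _month_counts(dates: list[datetime.date]) -> dict[int, int]:
    counts: dict[int, int] = {}
    for d in dates:
        counts[d.month] = counts.get(d.month, 0) + 1
    return {m: c for m, c in counts.items() if c > 0}


def draw_null_sample(
    events: EventSample | list[datetime.date],
    sampling_period: tuple[datetime.date, datetime.date],
    daily: DailyMetricSeries,
    rng: np.random.Generator,
    exclude_event_days: bool = False,
    replace: bool = False,
) -> list[datetime.date]:
    """One frequency-matched random day sample.

    Returns as many days as there are events; for every calendar month the
    drawn count equals the observed count exactly.  Days are drawn
    uniformly (without replacement unless ``replace``) from the month's
    pool of eligible days across all years of ``sampling_period``; days
    whose daily metric is missing are never eligible.
    """
    dates = events.dates if isinstance(events, EventSample) else list(events)
    counts = _month_counts(dates)
    exclude = set(dates) if exclude_event_days else None
    pools = _month_pools(daily, sampling_period, exclude)
    return _draw_from_pools(counts, pools, rng, replace)


def _draw_from_pools(
    counts: dict[int, int],
    pools: dict[int, list[datetime.date]],
    rng: np.random.Generator,
    replace: bool = False,
) -> list[datetime.date]:
    out: list[datetime.date] = []
    for m in sorted(counts):
        pool = pools[m]
        n_m = counts[m]
        if not replace and len(pool) < n_m:
            raise ResamplingError(
                f"month {m}: pool of {len(pool)} eligible days < {n_m} required"
            )
        idx = rng.choice(len(pool), size=n_m, replace=replace)
        out.extend(pool[i] for i in idx)
    return out


def monte_carlo_test(
    spec: StatisticSpec,
    daily: DailyMetricSeries,
    clim: MonthlyClimatology | None,
    events: EventSample,
    B: int = 1000,
    sampling_period: tuple[datetime.date, datetime.date] | None = None,
    seed: int = 0,
    exclude_event_days: bool = False,
) -> ResampleResult:
    """Observed mean statistic vs. a B-member frequency-matched null.

    Each replicate draws a random day set with the observed monthly
    frequencies and recomputes the mean statistic treating the drawn set
    as the event days (so the two-day-change baseline shift applies to the
    drawn set itself).  Deterministic given ``seed``.
    """
    if sampling_period is None:
        sampling_period = default_sampling_period(events.study_period)
    obs = event_statistic(spec, daily, clim, events)

    keep = _season_mask(events.dates, spec.season_filter)
    season_dates = [d for d, k in zip(events.dates, keep) if k]
    counts = _month_counts(season_dates)
    exclude = set(events.dates) if exclude_event_days else None
    pools = _month_pools(daily, sampling_period, exclude)
    for m, n_m in counts.items():
        if len(pools[m]) < n_m:
            raise ResamplingError(
                f"month {m}: pool of {len(pools[m])} eligible days < {n_m} required"
            )

    rng = np.random.default_rng(seed)
    if spec.kind == "climatology_anomaly":
        null_means = _null_means_anomaly(daily, clim, counts, pools, B, rng)
    else:
        by_date = {ts.date(): v for ts, v in daily.values.items()}
        null_means = np.empty(B)
        for b in range(B):
            drawn = _draw_from_pools(counts, pools, rng)
            day_set = set(drawn)
            vals = np.array([_two_day_value(d, by_date, day_set) for d in drawn])
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0:
                raise ResamplingError("null replicate lost all days to missing baselines")
            null_means[b] = vals.mean()

    p_right = float(np.mean(null_means >= obs.mean))
    p_left = float(np.mean(null_means <= obs.mean))
    p_two = float(min(1.0, 2.0 * min(p_left, p_right)))
    p05, p95 = np.percentile(null_means, [5, 95])  # type-7 interpolation
    return ResampleResult(
        kind=spec.kind,
        parameter=spec.parameter,
        station_id=spec.station_id,
        season_filter=spec.season_filter,
        observed_mean=obs.mean,
        observed_values=obs.values,
        null_means=null_means,
        p_right=p_right,
        p_left=p_left,
        p_two_sided=p_two,
        percentile_05=float(p05),
        percentile_95=float(p95),
        significant=bool(obs.mean < p05 or obs.mean > p95),
        B=B,
        seed=seed,
        n_events_used=obs.n_used,
        n_events_excluded=obs.n_excluded,
    )


def _null_means_anomaly(
    daily: DailyMetricSeries,
    clim: MonthlyClimatology | None,
    counts: dict[int, int],
    pools: dict[int, list[datetime.date]],
    B: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized null means for the climatology-anomaly statistic.

    Within each month, B draws of n_m pool indices without replacement are
    obtained by rank-selecting a B×P uniform matrix; the overall mean is
    assembled from the per-month anomaly sums.
    """
    if clim is None:
        raise ResamplingError("climatology_anomaly requires a MonthlyClimatology")
    anom = anomaly_series(daily, clim)
    by_date = {ts.date(): v for ts, v in anom.values.items()}
    n_total = sum(counts.values())
    totals = np.zeros(B)
    for m in sorted(counts):
        pool_vals = np.array([by_date[d] for d in pools[m]])
        if np.isnan(pool_vals).any():  # pools exclude missing days already
            raise ResamplingError(f"month {m}: pool contains missing anomalies")
        n_m = counts[m]
        u = rng.random((B, len(pool_vals)))
        idx = np.argpartition(u, n_m - 1, axis=1)[:, :n_m]
        totals += pool_vals[idx].sum(axis=1)
    return totals / n_total


@dataclasses.dataclass
class CenteredHistogram:
    """Null distribution and observed mean shifted so the null median is 0."""

    shift: float
    null_means_centered: np.ndarray
    observed_centered: float
    p_right: float


def centered_histogram(result: ResampleResult) -> CenteredHistogram:
    """Shift null means and observed mean by −median(null); p_right is preserved."""
    shift = float(np.median(result.null_means))
    centered = result.null_means - shift
    obs = result.observed_mean - shift
    return CenteredHistogram(
        shift=shift,
        null_means_centered=centered,
        observed_centered=obs,
        p_right=float(np.mean(centered >= obs)),
    )


def plot_resample(result: ResampleResult, ax=None, center: bool = True):
    """Histogram of null means with the observed mean as a vertical line."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    if center:
        c = centered_histogram(result)
        nulls, obs = c.null_means_centered, c.observed_centered
    else:
        nulls, obs = result.null_means, result.observed_mean
    ax.hist(nulls, bins=30, color="steelblue", alpha=0.8)
    ax.axvline(obs, color="green", lw=2, label=f"observed (p_right={result.p_right:.3f})")
    ax.set_xlabel(f"mean {result.parameter} {result.kind}")
    ax.set_ylabel("Monte Carlo members")
    ax.legend()
    ax.set_title(f"{result.station_id} {result.parameter} [{result.season_filter}]")
    return ax
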