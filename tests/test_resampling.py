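"""Event statistics, frequency-matched null draws and the Monte Carlo test."""

import datetime
import itertools

import numpy as np
import pandas as pd
import pytest

import meteotrigger as mt
from conftest import make_events
from meteotrigger.resampling import ResamplingError, default_sampling_period

PERIOD = (datetime.date(2009, 1, 1), datetime.date(2010, 12, 31))


def _daily(values, param="temperature") -> mt.DailyMetricSeries:
    idx = pd.date_range(PERIOD[0], PERIOD[1], freq="D")
    return mt.DailyMetricSeries("T", param, pd.Series(values, index=idx))


def _flat_clim(c=0.0) -> mt.MonthlyClimatology:
    return mt.MonthlyClimatology(
        station_id="T", parameter="temperature", reference_period=PERIOD,
        means={m: float(c) for m in range(1, 13)},
    )


def _value_series(pairs, default=0.0):
    idx = pd.date_range(PERIOD[0], PERIOD[1], freq="D")
    s = pd.Series(float(default), index=idx)
    for d, v in pairs:
        s[pd.Timestamp(d)] = v
    return _daily(s)


class TestEventStatistic:
    def test_constant_series_two_day_change_zero(self):
        daily = _daily(5.0)
        events = make_events([datetime.date(2009, 6, 1), datetime.date(2010, 3, 3)], PERIOD)
        spec = mt.StatisticSpec("two_day_change", "temperature", "T")
        stat = mt.event_statistic(spec, daily, None, events)
        assert stat.mean == 0.0
        assert (stat.values == 0).all()

    def test_plain_two_day_difference(self):
        d = datetime.date(2009, 6, 10)
        daily = _value_series([(d, 10.0), (d - datetime.timedelta(days=2), 7.0)])
        events = make_events([d], PERIOD)
        spec = mt.StatisticSpec("two_day_change", "temperature", "T")
        stat = mt.event_statistic(spec, daily, None, events)
        assert stat.values[0] == pytest.approx(3.0)

    def test_baseline_shifts_past_preceding_event_day(self):
        """Event on d−2 pushes the baseline to the event-free d−3."""
        d = datetime.date(2009, 6, 10)
        daily = _value_series([
            (d, 10.0),
            (d - datetime.timedelta(days=2), 9.0),
            (d - datetime.timedelta(days=3), 6.0),
        ])
        events = make_events([d - datetime.timedelta(days=2), d], PERIOD)
        spec = mt.StatisticSpec("two_day_change", "temperature", "T")
        stat = mt.event_statistic(spec, daily, None, events)
        # hand-traced oracle: d-2 is an event day, so baseline = d-3: 10 - 6 = 4;
        # the d-2 event itself compares to d-4: 9 - 0 = 9
        assert sorted(stat.values) == [pytest.approx(4.0), pytest.approx(9.0)]

    def test_baseline_skips_missing_days(self):
        d = datetime.date(2009, 6, 10)
        daily = _value_series([(d, 10.0), (d - datetime.timedelta(days=3), 8.0)])
        daily.values[pd.Timestamp(d - datetime.timedelta(days=2))] = np.nan
        events = make_events([d], PERIOD)
        spec = mt.StatisticSpec("two_day_change", "temperature", "T")
        stat = mt.event_statistic(spec, daily, None, events)
        assert stat.values[0] == pytest.approx(2.0)

    def test_lookback_cap_excludes_event(self):
        """No event-free, non-missing baseline within 7 days -> excluded."""
        d = datetime.date(2009, 6, 20)
        block = [d - datetime.timedelta(days=k) for k in range(2, 8)]
        daily = _daily(1.0)
        events = make_events(block + [d, datetime.date(2010, 2, 2)], PERIOD)
        spec = mt.StatisticSpec("two_day_change", "temperature", "T")
        stat = mt.event_statistic(spec, daily, None, [d, datetime.date(2010, 2, 2)],
                                  event_day_set=set(block + [d]))
        assert stat.n_excluded == 1
        assert stat.n_used == 1

    def test_climatology_anomaly_statistic(self, world_7y):
        spec = mt.StatisticSpec("climatology_anomaly", "temperature", "SYN")
        stat = mt.event_statistic(
            spec, world_7y["dailies"]["temperature"], world_7y["clim"], world_7y["events"]
        )
        # oracle: anomaly() per event date
        expected = [
            mt.anomaly(world_7y["dailies"]["temperature"], world_7y["clim"], d)
            for d in world_7y["events"].dates
        ]
        expected = [v for v in expected if not np.isnan(v)]
        assert stat.n_used == len(expected)
        assert stat.mean == pytest.approx(np.mean(expected))

    def test_season_filter_partitions_events(self, world_7y):
        daily, clim, events = (world_7y["dailies"]["temperature"], world_7y["clim"],
                               world_7y["events"])
        ns = {}
        for season in ("all", "cold", "warm"):
            spec = mt.StatisticSpec("climatology_anomaly", "temperature", "SYN", season)
            st = mt.event_statistic(spec, daily, clim, events)
            ns[season] = st.n_used + st.n_excluded
        assert ns["cold"] + ns["warm"] == ns["all"] == events.n


class TestNullDraws:
    def test_month_histogram_matches_exactly_every_draw(self, world_7y):
        daily = world_7y["dailies"]["temperature"]
        events = world_7y["events"]
        want = {}
        for d in events.dates:
            want[d.month] = want.get(d.month, 0) + 1
        rng = np.random.default_rng(5)
        for _ in range(25):
            drawn = mt.draw_null_sample(events, world_7y["period"], daily, rng)
            got = {}
            for d in drawn:
                got[d.month] = got.get(d.month, 0) + 1
            assert got == want
            assert len(drawn) == len(set(drawn))  # without replacement

    def test_single_month_sample_forced(self):
        daily = _daily(1.0)
        july = [datetime.date(2009, 7, i) for i in (1, 2, 3, 4, 5)]
        events = make_events(july, PERIOD)
        rng = np.random.default_rng(0)
        drawn = mt.draw_null_sample(events, PERIOD, daily, rng)
        assert len(drawn) == 5
        assert all(d.month == 7 for d in drawn)
        assert len(set(drawn)) == 5

    def test_missing_metric_days_never_drawn(self):
        daily = _daily(1.0)
        missing_day = datetime.date(2009, 7, 10)
        daily.values[pd.Timestamp(missing_day)] = np.nan
        events = make_events([datetime.date(2009, 7, 1)] * 10, PERIOD)
        rng = np.random.default_rng(1)
        for _ in range(50):
            assert missing_day not in mt.draw_null_sample(events, PERIOD, daily, rng)

    def test_pool_too_small_names_month(self):
        daily = _daily(1.0)
        events = make_events([datetime.date(2009, 2, 1)] * 70, PERIOD)  # 57 Februaries
        rng = np.random.default_rng(1)
        with pytest.raises(ResamplingError, match="month 2"):
            mt.draw_null_sample(events, PERIOD, daily, rng)

    def test_tiny_calendar_pairs_uniform(self):
        """6 eligible days, n=2: each of the 15 unordered pairs ~ 1/15."""
        idx = pd.date_range("2009-07-01", "2009-07-06", freq="D")
        daily = mt.DailyMetricSeries("T", "temperature",
                                     pd.Series(np.arange(6.0), index=idx))
        window = (datetime.date(2009, 7, 1), datetime.date(2009, 7, 6))
        events = make_events([datetime.date(2009, 7, 1), datetime.date(2009, 7, 2)], PERIOD)
        rng = np.random.default_rng(12)
        n_draws = 6000
        counts: dict[frozenset, int] = {}
        for _ in range(n_draws):
            pair = frozenset(mt.draw_null_sample(events, window, daily, rng))
            counts[pair] = counts.get(pair, 0) + 1
        assert len(counts) == 15
        # multinomial oracle: each cell Binomial(n_draws, 1/15); allow 4 sd
        exp = n_draws / 15
        sd = np.sqrt(n_draws * (1 / 15) * (14 / 15))
        for c in counts.values():
            assert abs(c - exp) < 4 * sd


class TestMonteCarloTest:
    def test_extreme_observed_mean_gives_p_zero(self):
        daily = _daily(np.zeros((PERIOD[1] - PERIOD[0]).days + 1))
        d = datetime.date(2009, 6, 10)
        daily.values[pd.Timestamp(d)] = 100.0  # only event day is extreme
        events = make_events([d], PERIOD)
        spec = mt.StatisticSpec("climatology_anomaly", "temperature", "T")
        res = mt.monte_carlo_test(spec, daily, _flat_clim(), events, B=200,
                                  sampling_period=PERIOD, seed=3,
                                  exclude_event_days=True)
        assert res.p_right == 0.0  # observed mean beats every null mean
        assert res.significant

    def test_seed_determinism(self, world_7y):
        spec = mt.StatisticSpec("two_day_change", "pressure", "SYN")
        kw = dict(B=150, sampling_period=world_7y["period"], seed=42)
        r1 = mt.monte_carlo_test(spec, world_7y["dailies"]["pressure"], None,
                                 world_7y["events"], **kw)
        r2 = mt.monte_carlo_test(spec, world_7y["dailies"]["pressure"], None,
                                 world_7y["events"], **kw)
        assert r1.observed_mean == r2.observed_mean
        assert np.array_equal(r1.null_means, r2.null_means)
        assert r1.p_right == r2.p_right

    def test_result_invariants(self, world_7y):
        spec = mt.StatisticSpec("climatology_anomaly", "temperature", "SYN")
        res = mt.monte_carlo_test(spec, world_7y["dailies"]["temperature"],
                                  world_7y["clim"], world_7y["events"],
                                  B=300, sampling_period=world_7y["period"], seed=9)
        assert len(res.null_means) == 300
        assert res.p_right + res.p_left >= 1 - 1 / 300
        assert res.significant == (
            res.observed_mean < res.percentile_05 or res.observed_mean > res.percentile_95
        )
        assert res.percentile_05 == pytest.approx(np.percentile(res.null_means, 5))

    def test_tiny_calendar_matches_exhaustive_enumeration(self):
        """Monte Carlo p converges to the exactly enumerated p over all 15 pairs."""
        idx = pd.date_range("2009-07-01", "2009-07-06", freq="D")
        vals = np.array([3.0, -1.0, 2.0, 0.5, -2.0, 1.0])
        daily = mt.DailyMetricSeries("T", "temperature", pd.Series(vals, index=idx))
        window = (datetime.date(2009, 7, 1), datetime.date(2009, 7, 6))
        events = make_events([datetime.date(2009, 7, 1), datetime.date(2009, 7, 3)], PERIOD)
        spec = mt.StatisticSpec("climatology_anomaly", "temperature", "T")
        B = 4000
        res = mt.monte_carlo_test(spec, daily, _flat_clim(), events, B=B,
                                  sampling_period=window, seed=21)
        observed = (3.0 + 2.0) / 2
        exact_means = [np.mean(pair) for pair in itertools.combinations(vals, 2)]
        p_exact = np.mean([m >= observed for m in exact_means])
        assert res.observed_mean == pytest.approx(observed)
        assert abs(res.p_right - p_exact) < 2 / np.sqrt(B)

    def test_two_day_change_null_uses_drawn_set_for_baseline(self):
        """Drawn days block each other as baselines, mirroring the observed rule."""
        idx = pd.date_range("2009-06-24", "2009-07-04", freq="D")
        series = pd.Series(0.0, index=idx)
        july = [datetime.date(2009, 7, i) for i in (1, 2, 3, 4)]
        for d, v in zip(july, [0.0, 5.0, 0.0, 7.0]):
            series[pd.Timestamp(d)] = v
        daily = mt.DailyMetricSeries("T", "temperature", series)
        window = (datetime.date(2009, 7, 1), datetime.date(2009, 7, 4))
        events = make_events([datetime.date(2009, 7, 3), datetime.date(2009, 7, 4)], PERIOD)
        spec = mt.StatisticSpec("two_day_change", "temperature", "T")
        # pool = 4 July days, n=2: enumerate every 2-subset's null mean by hand
        # and check each simulated mean is one of them
        by_date = {ts.date(): v for ts, v in series.items()}
        enumerated = set()
        for pair in itertools.combinations(july, 2):
            day_set = set(pair)
            chs = []
            for d in pair:
                for k in range(2, 8):
                    b = d - datetime.timedelta(days=k)
                    if b in day_set:
                        continue
                    if b in by_date:
                        chs.append(by_date[d] - by_date[b])
                        break
            enumerated.add(round(float(np.mean(chs)), 9))
        res = mt.monte_carlo_test(spec, daily, None, events, B=100,
                                  sampling_period=window, seed=2)
        for m in res.null_means:
            assert round(float(m), 9) in enumerated

    def test_default_sampling_period_whole_years(self):
        period = (datetime.date(2004, 1, 5), datetime.date(2012, 3, 31))
        assert default_sampling_period(period) == (
            datetime.date(2005, 1, 1), datetime.date(2011, 12, 31)
        )


class TestCenteredHistogram:
    def test_median_shifted_to_zero_and_p_preserved(self, world_7y):
        spec = mt.StatisticSpec("climatology_anomaly", "temperature", "SYN")
        res = mt.monte_carlo_test(spec, world_7y["dailies"]["temperature"],
                                  world_7y["clim"], world_7y["events"],
                                  B=201, sampling_period=world_7y["period"], seed=17)
        c = mt.centered_histogram(res)
        assert np.median(c.null_means_centered) == pytest.approx(0.0, abs=1e-12)
        assert c.p_right == res.p_right
        assert c.observed_centered == pytest.approx(res.observed_mean - c.shift)
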