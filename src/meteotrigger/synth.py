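"""Synthetic multi-year hourly weather and event samples.

The generator emulates the statistical texture of mid-latitude hourly
station data — seasonal cycle, diurnal cycle, day-to-day autocorrelation,
wet/dry spells, and realistic missingness — well enough to exercise every
downstream stage (daily metrics, climatology, epoch profiles, resampling
tests) without any real download.  It makes no attempt at physical realism
(fronts, pressure–wind covariance beyond a shared storminess state).

Model, per station:

* temperature (°C, hourly) =
  ``mean + seasonal_amp*cos(2*pi*(doy-200)/365.25)
  + diurnal_amp*cos(2*pi*(hod-14)/24) + a_d + eps_h``
  where ``a_d`` is a stationary daily AR(1) anomaly (coefficient ``rho``,
  marginal sd ``anomaly_sd``) shared by all hours of a day, so daily means
  inherit the intended autocorrelation, and ``eps_h`` is white hourly noise.
  Day-of-year phase 200 (mid/late July maximum) and hour-of-day phase
  14 UTC are conventional mid-latitude choices.
* pressure (hPa): mean + daily AR(1) + small hourly noise.
* precipitation (mm/h): hourly two-state wet/dry Markov chain
  (``p_wd`` dry->wet, ``p_ww`` wet->wet); wet-hour amounts ~ Gamma.
* relative humidity (%): wet-day vs dry-day mean + daily and hourly noise,
  clamped to [0, 100].
* wind gust (m/s): log-normal, its location coupled to a shared
  "storminess" AR(1) state.
* sunshine (min/h): zero outside a day-of-year-dependent daylight window;
  inside it, a Beta-distributed fraction of 60 min, cloudier on wet days.

Stations are correlated: daily anomaly innovations mix a shared component
with station noise (weight 0.8 on the shared part), emulating the
cross-station consistency of neighbouring sites.

Event days are drawn i.i.d. from ``P(day d) ∝ exp(beta * x_d)`` where
``x_d`` is a standardized daily quantity (climatology anomaly, or 2-day
change); ``beta = 0`` gives days uniform over the study period, the null
world used for calibration.
"""

from __future__ import annotations

import dataclasses
import datetime

import numpy as np
import pandas as pd

from .io import EVENT_COLUMNS, EventSample, HourlyWeatherSeries, VALUE_COLUMNS
from .daily import DailyMetricSeries


class ConfigError(ValueError):
    """A generator configuration violates its invariants."""


@dataclasses.dataclass
class TemperatureConfig:
    mean: float = 9.3            # °C, annual mean (Zurich-like lowland)
    seasonal_amp: float = 9.5    # °C, annual-cycle amplitude
    diurnal_amp: float = 3.5     # °C, diurnal-cycle amplitude
    rho: float = 0.75            # daily AR(1) coefficient
    anomaly_sd: float = 2.8      # °C, marginal sd of daily anomaly
    hourly_sd: float = 0.7       # °C, white hourly noise


@dataclasses.dataclass
class PressureConfig:
    mean: float = 965.0          # hPa, station-level pressure at ~550 m
    rho: float = 0.85
    sd: float = 7.0              # hPa, marginal sd of daily anomaly
    hourly_sd: float = 0.4


@dataclasses.dataclass
class PrecipitationConfig:
    p_wd: float = 0.055          # dry hour -> wet hour
    p_ww: float = 0.62           # wet hour -> wet hour
    gamma_shape: float = 0.65    # wet-hour amount, mm
    gamma_scale: float = 1.3


@dataclasses.dataclass
class HumidityConfig:
    dry_day_mean: float = 68.0   # %
    wet_day_mean: float = 86.0
    day_sd: float = 8.0
    hourly_sd: float = 4.0


@dataclasses.dataclass
class GustConfig:
    log_loc: float = 1.15        # log m/s
    log_scale: float = 0.45
    storm_coupling: float = 0.35  # shift of log_loc per storminess sd
    storm_rho: float = 0.6


@dataclasses.dataclass
class SunshineConfig:
    dry_alpha: float = 2.2       # Beta params of the per-hour sunshine fraction
    dry_beta: float = 0.9
    wet_alpha: float = 0.6
    wet_beta: float = 2.2


@dataclasses.dataclass
class WeatherGenConfig:
    """Configuration for the hourly weather generator."""

    period: tuple[datetime.date, datetime.date]
    stations: tuple[str, ...] = ("SYN",)
    temperature: TemperatureConfig = dataclasses.field(default_factory=TemperatureConfig)
    pressure: PressureConfig = dataclasses.field(default_factory=PressureConfig)
    precipitation: PrecipitationConfig = dataclasses.field(default_factory=PrecipitationConfig)
    humidity: HumidityConfig = dataclasses.field(default_factory=HumidityConfig)
    gust: GustConfig = dataclasses.field(default_factory=GustConfig)
    sunshine: SunshineConfig = dataclasses.field(default_factory=SunshineConfig)
    missingness: float = 0.02    # i.i.d. per parameter per hour
    station_mixing: float = 0.8  # weight of the shared innovation
    seed: int = 0

    def validate(self) -> None:
        start, end = self.period
        if end < start + datetime.timedelta(days=364):
            raise ConfigError("period must span at least one year (climatology impossible)")
        for name, rho in (("temperature.rho", self.temperature.rho),
                          ("pressure.rho", self.pressure.rho),
                          ("gust.storm_rho", self.gust.storm_rho)):
            if not 0 <= rho < 1:
                raise ConfigError(f"{name} must be in [0, 1)")
        if not 0 <= self.missingness < 1:
            raise ConfigError("missingness must be in [0, 1)")
        if not 0 <= self.station_mixing <= 1:
            raise ConfigError("station_mixing must be in [0, 1]")


def _ar1(innov: np.ndarray, rho: float, marginal_sd: float) -> np.ndarray:
    """Stationary AR(1) path with the given marginal sd from N(0,1) innovations."""
    from scipy.signal import lfilter

    n = len(innov)
    if n == 0:
        return np.zeros(0)
    out = np.empty(n)
    out[0] = innov[0] * marginal_sd  # start from the stationary distribution
    if n > 1:
        scaled = innov[1:] * marginal_sd * np.sqrt(1.0 - rho**2)
        rest, _ = lfilter([1.0], [1.0, -rho], scaled, zi=np.array([rho * out[0]]))
        out[1:] = rest
    return out


def _round_to(x: np.ndarray, decimals: int) -> np.ndarray:
    return np.round(x, decimals)


def generate_weather(config: WeatherGenConfig) -> dict[str, HourlyWeatherSeries]:
    """Generate one :class:`HourlyWeatherSeries` per configured station.

    Deterministic in ``config.seed``.  Output values are emitted at the
    on-disk measurement precision, so a write/read round trip is exact.
    """
    config.validate()
    start, end = config.period
    days = pd.date_range(pd.Timestamp(start), pd.Timestamp(end), freq="D")
    n_days = len(days)
    hours = pd.date_range(
        pd.Timestamp(start, tz="UTC"),
        pd.Timestamp(end, tz="UTC") + pd.Timedelta(hours=23),
        freq="h",
    )
    n_hours = len(hours)
    day_of_hour = np.repeat(np.arange(n_days), 24)
    doy = days.dayofyear.to_numpy()
    hod = np.tile(np.arange(24), n_days)

    seasonal_t = config.temperature.seasonal_amp * np.cos(2 * np.pi * (doy - 200) / 365.25)
    diurnal_t = config.temperature.diurnal_amp * np.cos(2 * np.pi * (hod - 14) / 24)
    # daylight half-width (hours) around 12 UTC: ~8 h days in winter, ~16 h in summer
    half_width = 6.0 + 2.0 * np.cos(2 * np.pi * (doy - 172) / 365.25)
    daylight = np.abs(hod + 0.5 - 12.0) < half_width[day_of_hour]

    rng = np.random.default_rng(config.seed)
    w = config.station_mixing
    w_own = np.sqrt(max(0.0, 1.0 - w**2))
    shared_t = rng.standard_normal(n_days)
    shared_p = rng.standard_normal(n_days)
    shared_s = rng.standard_normal(n_days)

    out: dict[str, HourlyWeatherSeries] = {}
    for sid in config.stations:
        srng = np.random.default_rng(rng.integers(2**31))
        innov_t = w * shared_t + w_own * srng.standard_normal(n_days)
        innov_p = w * shared_p + w_own * srng.standard_normal(n_days)
        innov_s = w * shared_s + w_own * srng.standard_normal(n_days)

        temp_anom = _ar1(innov_t, config.temperature.rho, config.temperature.anomaly_sd)
        temp = (
            config.temperature.mean
            + seasonal_t[day_of_hour]
            + diurnal_t
            + temp_anom[day_of_hour]
            + srng.standard_normal(n_hours) * config.temperature.hourly_sd
        )

        pres_anom = _ar1(innov_p, config.pressure.rho, config.pressure.sd)
        pres = (
            config.pressure.mean
            + pres_anom[day_of_hour]
            + srng.standard_normal(n_hours) * config.pressure.hourly_sd
        )

        # hourly wet/dry Markov chain
        u = srng.random(n_hours)
        p_wd, p_ww = config.precipitation.p_wd, config.precipitation.p_ww
        wet = np.zeros(n_hours, dtype=bool)
        state = u[0] < p_wd / (1.0 - p_ww + p_wd)  # stationary start
        wet[0] = state
        for i in range(1, n_hours):
            state = u[i] < (p_ww if state else p_wd)
            wet[i] = state
        precip = np.zeros(n_hours)
        n_wet = int(wet.sum())
        if n_wet:
            precip[wet] = srng.gamma(
                config.precipitation.gamma_shape, config.precipitation.gamma_scale, n_wet
            )

        wet_day = np.add.reduceat(precip, np.arange(0, n_hours, 24)) > 0.1

        rh_day_mean = np.where(wet_day, config.humidity.wet_day_mean, config.humidity.dry_day_mean)
        rh_day = rh_day_mean + srng.standard_normal(n_days) * config.humidity.day_sd
        rh = rh_day[day_of_hour] + srng.standard_normal(n_hours) * config.humidity.hourly_sd
        rh = np.clip(rh, 0.0, 100.0)

        storm = _ar1(innov_s, config.gust.storm_rho, 1.0)
        gust = np.exp(
            config.gust.log_loc
            + config.gust.storm_coupling * storm[day_of_hour]
            + srng.standard_normal(n_hours) * config.gust.log_scale
        )

        wet_h = wet | wet_day[day_of_hour]  # clouds linger on wet days
        alpha = np.where(wet_h, config.sunshine.wet_alpha, config.sunshine.dry_alpha)
        beta_ = np.where(wet_h, config.sunshine.wet_beta, config.sunshine.dry_beta)
        frac = srng.beta(alpha, beta_)
        sunshine = np.where(daylight, frac * 60.0, 0.0)

        df = pd.DataFrame(
            {
                "temp_c": _round_to(temp, 1),
                "rh_pct": _round_to(rh, 0),
                "gust_ms": _round_to(gust, 1),
                "pressure_hpa": _round_to(pres, 1),
                "precip_mm": _round_to(precip, 1),
                "sunshine_min": np.clip(_round_to(sunshine, 0), 0, 60),
            },
            index=hours,
        )
        if config.missingness > 0:
            for col in VALUE_COLUMNS:
                mask = srng.random(n_hours) < config.missingness
                df.loc[mask, col] = np.nan
        df.index.name = "timestamp_utc"
        out[sid] = HourlyWeatherSeries(station_id=sid, data=df)
    return out


# marginal frequencies used to fill optional clinical attributes; they mirror
# the descriptive mix of a large single-center aneurysmal-SAH cohort
ATTRIBUTE_MARGINALS = {
    "sex": (("F", "M"), (0.665, 0.335)),
    "circulation": (("anterior", "posterior"), (0.841, 0.159)),
    "gcs_band": ((("13-15"), ("9-12"), ("3-8")), (0.577, 0.070, 0.352)),
    "hh_grade": ((1, 2, 3, 4, 5), (0.076, 0.444, 0.167, 0.133, 0.180)),
    "fisher_grade": ((1, 2, 3, 4), (0.055, 0.149, 0.356, 0.440)),
    "wfns_grade": ((1, 2, 3, 4, 5), (0.352, 0.196, 0.059, 0.153, 0.240)),
}

_GCS_BAND_RANGE = {"13-15": (13, 15), "9-12": (9, 12), "3-8": (3, 8)}


@dataclasses.dataclass
class EventGenConfig:
    """Configuration for the event-day sampler."""

    study_period: tuple[datetime.date, datetime.date]
    n_events: int = 511
    effect_size: float = 0.0          # log-relative-risk per 1 sd of x_d
    coupling_mode: str = "anomaly"    # or "two_day_change"
    fill_attributes: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_events < 1:
            raise ConfigError("n_events must be >= 1")
        if self.coupling_mode not in ("anomaly", "two_day_change"):
            raise ConfigError(f"unknown coupling_mode {self.coupling_mode!r}")


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = np.nanstd(x)
    if sd == 0:
        return np.zeros_like(x)
    return (x - np.nanmean(x)) / sd


def generate_events(
    config: EventGenConfig, daily_anomalies: DailyMetricSeries
) -> EventSample:
    """Draw event days with relative risk ``exp(beta * x_d)``.

    ``daily_anomalies`` supplies the coupled daily quantity (typically
    climatology anomalies); under ``coupling_mode="two_day_change"`` the
    coupled quantity is its 2-day difference.  Either way it is
    standardized over the study period, so ``effect_size`` is a
    log-relative-risk per standard deviation.  ``beta = 0`` draws days
    uniformly.  Days with a missing coupled value are ineligible; more
    than 20% missing study days is an error (lower the missingness).
    """
    config.validate()
    start, end = config.study_period
    vals = daily_anomalies.values
    mask = (vals.index >= pd.Timestamp(start)) & (vals.index <= pd.Timestamp(end))
    vals = vals[mask]
    n_study_days = (end - start).days + 1
    if len(vals) < n_study_days:
        raise ConfigError("daily anomalies do not cover the whole study period")

    x = vals.to_numpy(dtype=float)
    if config.coupling_mode == "two_day_change":
        lag = np.full_like(x, np.nan)
        lag[2:] = x[:-2]
        x = x - lag
    eligible = ~np.isnan(x)
    if eligible.sum() < 0.8 * n_study_days:
        raise ConfigError(
            "more than 20% of study days have a missing coupled value; lower the missingness"
        )
    days = vals.index[eligible]
    z = _standardize(x[eligible])
    logw = config.effect_size * z
    logw -= logw.max()  # overflow-safe
    p = np.exp(logw)
    p /= p.sum()

    def _norm(probs):
        a = np.asarray(probs, dtype=float)
        return a / a.sum()

    rng = np.random.default_rng(config.seed)
    picks = rng.choice(len(days), size=config.n_events, replace=True, p=p)
    picks.sort()
    dates = [days[i].date() for i in picks]

    n = config.n_events
    cols: dict[str, list] = {c: [None] * n for c in EVENT_COLUMNS}
    cols["event_date"] = dates
    if config.fill_attributes:
        sexes, p_sex = ATTRIBUTE_MARGINALS["sex"]
        cols["sex"] = list(rng.choice(sexes, size=n, p=_norm(p_sex)))
        cols["age"] = list(np.clip(np.round(rng.normal(53, 14, n)), 15, 97))
        circs, p_circ = ATTRIBUTE_MARGINALS["circulation"]
        cols["circulation"] = list(rng.choice(circs, size=n, p=_norm(p_circ)))
        bands, p_band = ATTRIBUTE_MARGINALS["gcs_band"]
        gcs = []
        for b in rng.choice(bands, size=n, p=_norm(p_band)):
            lo, hi = _GCS_BAND_RANGE[b]
            gcs.append(int(rng.integers(lo, hi + 1)))
        cols["gcs"] = gcs
        for grade in ("hh_grade", "fisher_grade", "wfns_grade"):
            levels, probs = ATTRIBUTE_MARGINALS[grade]
            cols[grade] = [int(v) for v in rng.choice(levels, size=n, p=_norm(probs))]
    df = pd.DataFrame({c: cols[c] for c in EVENT_COLUMNS})
    for c in ("age", "gcs", "hh_grade", "fisher_grade", "wfns_grade"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return EventSample(data=df, study_period=config.study_period)
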