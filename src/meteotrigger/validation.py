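"""Statistical validation of the resampling test on synthetic worlds.

Each *world* is an independent synthetic realization: multi-year hourly
weather for one station, daily temperature metrics, a monthly climatology,
and an event sample drawn with a chosen weather–event coupling strength
``beta`` (log-relative-risk per standard deviation of the daily anomaly).
Running the Monte Carlo test in many such worlds measures:

* **type-I calibration** — with ``beta = 0`` the two-sided rejection rate
  (observed mean outside the null's 5th–95th percentile band) should be
  10%, and the right-tail p-values should be uniform on (0, 1);
* **power** — with ``beta > 0`` the rejection rate should rise with beta.

The worlds are scaled down relative to a full multi-station study —
a 7-year period serving as climatology reference and sampling period at
once, one station, 100 events, B=500 replicates — sizes at which several
hundred worlds run in a few minutes while the calibration property being
checked is unchanged.
"""

from __future__ import annotations

import dataclasses
import datetime

import numpy as np

from .climatology import build_climatology, anomaly_series
from .daily import daily_series
from .resampling import StatisticSpec, monte_carlo_test
from .synth import EventGenConfig, WeatherGenConfig, generate_events, generate_weather

DEFAULT_YEARS = (2005, 2011)


def _world_seeds(seed: int, index: int) -> tuple[int, int, int]:
    ss = np.random.SeedSequence([int(seed), int(index)])
    a, b, c = ss.generate_state(3)
    return int(a % 2**31), int(b % 2**31), int(c % 2**31)


@dataclasses.dataclass
class WorldResult:
    p_right: float
    significant: bool
    observed_mean: float


def run_world(
    seed: int,
    index: int,
    n_events: int = 100,
    B: int = 500,
    beta: float = 0.0,
    years: tuple[int, int] = DEFAULT_YEARS,
    kind: str = "climatology_anomaly",
    coupling_mode: str = "anomaly",
    missingness: float = 0.0,
) -> WorldResult:
    """One synthetic world end-to-end: generate, couple, test (temperature)."""
    period = (datetime.date(years[0], 1, 1), datetime.date(years[1], 12, 31))
    w_seed, e_seed, mc_seed = _world_seeds(seed, index)
    wconf = WeatherGenConfig(period=period, stations=("SYN",), seed=w_seed,
                             missingness=missingness)
    weather = generate_weather(wconf)["SYN"]
    daily = daily_series(weather, parameters=("temperature",))["temperature"]
    clim = build_climatology(daily, period)
    anoms = anomaly_series(daily, clim)
    events = generate_events(
        EventGenConfig(
            study_period=period,
            n_events=n_events,
            effect_size=beta,
            coupling_mode=coupling_mode,
            fill_attributes=False,
            seed=e_seed,
        ),
        anoms,
    )
    spec = StatisticSpec(kind=kind, parameter="temperature", station_id="SYN")
    res = monte_carlo_test(
        spec, daily, clim, events, B=B, sampling_period=period, seed=mc_seed
    )
    return WorldResult(
        p_right=res.p_right, significant=res.significant, observed_mean=res.observed_mean
    )


@dataclasses.dataclass
class CalibrationResult:
    n_worlds: int
    p_right: np.ndarray
    rejection_rate: float
    observed_means: np.ndarray


def null_calibration(
    n_worlds: int = 200,
    n_events: int = 100,
    B: int = 500,
    seed: int = 0,
    beta: float = 0.0,
    **world_kwargs,
) -> CalibrationResult:
    """Rejection rate and p-value sample across independent worlds."""
    ps, rejects, means = [], [], []
    for i in range(n_worlds):
        w = run_world(seed, i, n_events=n_events, B=B, beta=beta, **world_kwargs)
        ps.append(w.p_right)
        rejects.append(w.significant)
        means.append(w.observed_mean)
    return CalibrationResult(
        n_worlds=n_worlds,
        p_right=np.asarray(ps),
        rejection_rate=float(np.mean(rejects)),
        observed_means=np.asarray(means),
    )


def power_curve(
    betas=(0.0, 0.5, 1.0, 2.0),
    n_worlds: int = 50,
    n_events: int = 100,
    B: int = 500,
    seed: int = 0,
    **world_kwargs,
) -> dict[float, float]:
    """Rejection rate per coupling strength beta (worlds independent per beta)."""
    rates = {}
    for j, beta in enumerate(betas):
        rejects = [
            run_world(seed, j * 100_000 + i, n_events=n_events, B=B, beta=beta, **world_kwargs).significant
            for i in range(n_worlds)
        ]
        rates[float(beta)] = float(np.mean(rejects))
    return rates
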