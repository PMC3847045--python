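"""End-to-end pipeline: weather + events in, consolidated report bundle out.

``run_all`` reads the canonical CSVs, builds daily metrics and
climatologies per station/parameter, and writes

* one tidy epoch-profile CSV per station × parameter,
* one ResampleResult JSON per station × parameter × test kind ×
  season (the full null-mean vector is serialized so p-values and
  histograms are re-derivable without re-running),
* the seasonality year×month CSV, the cohort summary (CSV + text),
* ``index.json`` listing every p-value.

Identical config + seed gives byte-identical JSON results.  Per-test
seeds are derived from the master seed through a SeedSequence spawned in
a fixed (station, parameter, kind, season) order.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from .climatology import build_climatology
from .cohort import summarize_cohort
from .daily import daily_series
from .epoch import epoch_profile, plot_epoch
from .io import PARAMETERS, read_events, read_weather
from .resampling import (
    StatisticSpec,
    default_sampling_period,
    monte_carlo_test,
    plot_resample,
)
from .seasonality import plot_seasonality, seasonal_distribution

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    weather_csv: str
    events_csv: str
    output_dir: str
    stations: tuple[str, ...]
    study_period: tuple[datetime.date, datetime.date]
    reference_period: tuple[datetime.date, datetime.date]
    sampling_period: tuple[datetime.date, datetime.date] | None = None
    parameters: tuple[str, ...] = PARAMETERS
    seasons: tuple[str, ...] = ("all", "cold", "warm")
    B: int = 1000
    seed: int = 0
    figures: bool = False

    def validate(self) -> None:
        if self.B < 100:
            raise PipelineError("B must be >= 100")
        for p in self.parameters:
            if p not in PARAMETERS:
                raise PipelineError(f"unknown parameter {p!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)

        def _dates(pair):
            if pair is None:
                return None
            return tuple(
                datetime.date.fromisoformat(x) if isinstance(x, str) else x for x in pair
            )

        return cls(
            weather_csv=raw["weather_csv"],
            events_csv=raw["events_csv"],
            output_dir=raw["output_dir"],
            stations=tuple(raw["stations"]),
            study_period=_dates(raw["study_period"]),
            reference_period=_dates(raw["reference_period"]),
            sampling_period=_dates(raw.get("sampling_period")),
            parameters=tuple(raw.get("parameters", PARAMETERS)),
            seasons=tuple(raw.get("seasons", ("all", "cold", "warm"))),
            B=int(raw.get("B", 1000)),
            seed=int(raw.get("seed", 0)),
            figures=bool(raw.get("figures", False)),
        )


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


def run_all(config: RunConfig) -> dict:
    """Run the whole pipeline; returns the report index (also written to disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setLevel(logging.INFO)
    root = logging.getLogger("meteotrigger")
    root.addHandler(fh)
    try:
        return _run_all_inner(config, out)
    finally:
        root.removeHandler(fh)
        fh.close()


def _run_all_inner(config: RunConfig, out: Path) -> dict:
    sampling = config.sampling_period or default_sampling_period(config.study_period)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    events = _stage("read_events", read_events, config.events_csv, config.study_period)
    log.info("events: %d rows from %s", events.n, config.events_csv)

    # deterministic per-test seeds from the master seed
    combos = [
        (sid, p, kind, season)
        for sid in config.stations
        for p in config.parameters
        for kind in ("climatology_anomaly", "two_day_change")
        for season in config.seasons
    ]
    children = np.random.SeedSequence(config.seed).spawn(len(combos))
    seed_for = {
        combo: int(child.generate_state(1)[0] % 2**31)
        for combo, child in zip(combos, children)
    }

    index: dict = {
        "n_events": events.n,
        "B": config.B,
        "seed": config.seed,
        "sampling_period": [sampling[0].isoformat(), sampling[1].isoformat()],
        "tests": [],
    }

    for sid in config.stations:
        weather = _stage("read_weather", read_weather, config.weather_csv, sid)
        dailies = _stage("daily_metrics", daily_series, weather, config.parameters)
        for p in config.parameters:
            daily = dailies[p]
            clim = _stage(f"climatology {sid}/{p}", build_climatology, daily,
                          config.reference_period)
            clim.to_frame().to_csv(out / f"climatology_{sid}_{p}.csv", index=False)

            prof = _stage(f"epoch {sid}/{p}", epoch_profile, daily, events)
            prof.to_frame().to_csv(out / f"epoch_{sid}_{p}.csv", index=False)
            if config.figures:
                ax = plot_epoch(prof)
                ax.figure.savefig(out / f"epoch_{sid}_{p}.png", dpi=100)

            for kind in ("climatology_anomaly", "two_day_change"):
                for season in config.seasons:
                    spec = StatisticSpec(kind=kind, parameter=p, station_id=sid,
                                         season_filter=season)
                    res = _stage(
                        f"{kind} {sid}/{p}/{season}",
                        monte_carlo_test,
                        spec, daily, clim, events,
                        B=config.B,
                        sampling_period=sampling,
                        seed=seed_for[(sid, p, kind, season)],
                    )
                    name = f"test_{sid}_{p}_{kind}_{season}.json"
                    _dump_json(res.to_dict(), out / name)
                    if config.figures:
                        ax = plot_resample(res)
                        ax.figure.savefig(out / (name[:-5] + ".png"), dpi=100)
                    index["tests"].append(
                        {
                            "station_id": sid,
                            "parameter": p,
                            "kind": kind,
                            "season": season,
                            "file": name,
                            "observed_mean": res.observed_mean,
                            "p_right": res.p_right,
                            "p_two_sided": res.p_two_sided,
                            "significant": res.significant,
                            "n_events_used": res.n_events_used,
                            "n_events_excluded": res.n_events_excluded,
                        }
                    )

    dist = _stage("seasonality", seasonal_distribution, events)
    dist.to_frame().to_csv(out / "seasonality.csv", index=False)
    if config.figures:
        ax = plot_seasonality(dist)
        ax.figure.savefig(out / "seasonality.png", dpi=100)
    index["seasonality"] = {
        "window": [dist.window[0].isoformat(), dist.window[1].isoformat()],
        "n_events_in_window": dist.n_events,
    }

    summary = _stage("cohort", summarize_cohort, events)
    summary.to_frame().to_csv(out / "cohort.csv", index=False)
    (out / "cohort.txt").write_text(summary.format_text() + "\n")
    index["cohort_n"] = summary.n

    _dump_json(index, out / "index.json")
    log.info("report bundle complete: %d test results", len(index["tests"]))
    return index
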