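"""Descriptive summary of the event sample's clinical attributes.

Counts and percentages by category for sex, aneurysm circulation, GCS
bands (13–15 / 9–12 / 3–8), Hunt & Hess 1–5, Fisher 1–4 and WFNS 1–5,
plus mean and range of age.  Percentages are 100·count/n rounded half-up
to one decimal; attributes may be missing, so an attribute's counts can
sum to less than n.
"""

from __future__ import annotations

import dataclasses
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .io import EventSample

GCS_BANDS = (("13-15", 13, 15), ("9-12", 9, 12), ("3-8", 3, 8))


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (0.05 -> 0.1), not banker's rounding."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclasses.dataclass
class CategoryCount:
    count: int
    percent: float  # of total n, rounded half-up to 1 decimal


@dataclasses.dataclass
class CohortSummary:
    n: int
    sex: dict[str, CategoryCount]
    circulation: dict[str, CategoryCount]
    gcs_bands: dict[str, CategoryCount]
    hh_grades: dict[int, CategoryCount]
    fisher_grades: dict[int, CategoryCount]
    wfns_grades: dict[int, CategoryCount]
    age_mean: float
    age_min: float
    age_max: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for attr, table in (
            ("sex", self.sex),
            ("circulation", self.circulation),
            ("gcs", self.gcs_bands),
            ("hh_grade", self.hh_grades),
            ("fisher_grade", self.fisher_grades),
            ("wfns_grade", self.wfns_grades),
        ):
            for cat, cc in table.items():
                rows.append({"attribute": attr, "category": str(cat),
                             "count": cc.count, "percent": cc.percent})
        return pd.DataFrame(rows)

    def format_text(self) -> str:
        lines = [f"n = {self.n}"]
        if not np.isnan(self.age_mean):
            lines.append(
                f"age: mean {self.age_mean:.1f} (range {self.age_min:.0f}-{self.age_max:.0f})"
            )
        for attr, table in (
            ("sex", self.sex),
            ("circulation", self.circulation),
            ("GCS", self.gcs_bands),
            ("Hunt&Hess", self.hh_grades),
            ("Fisher", self.fisher_grades),
            ("WFNS", self.wfns_grades),
        ):
            parts = [f"{cat}: {cc.count} ({cc.percent}%)" for cat, cc in table.items()]
            lines.append(f"{attr} — " + "; ".join(parts))
        return "\n".join(lines)


def _tabulate(values, categories, n) -> dict:
    out = {}
    for cat in categories:
        count = int(sum(1 for v in values if v == cat))
        out[cat] = CategoryCount(count=count, percent=round_half_up(100.0 * count / n))
    return out


def summarize_cohort(events: EventSample) -> CohortSummary:
    """Counts and half-up percentages of every clinical attribute."""
    df = events.data
    n = len(df)
    if n == 0:
        raise ValueError("empty event sample")

    sex = _tabulate([v for v in df["sex"] if v is not None and not pd.isna(v)], ("F", "M"), n)
    circ = _tabulate(
        [v for v in df["circulation"] if v is not None and not pd.isna(v)],
        ("anterior", "posterior"), n,
    )

    gcs_vals = df["gcs"].dropna()
    gcs = {}
    for label, lo, hi in GCS_BANDS:
        count = int(((gcs_vals >= lo) & (gcs_vals <= hi)).sum())
        gcs[label] = CategoryCount(count=count, percent=round_half_up(100.0 * count / n))

    hh = _tabulate(df["hh_grade"].dropna().astype(int).tolist(), range(1, 6), n)
    fisher = _tabulate(df["fisher_grade"].dropna().astype(int).tolist(), range(1, 5), n)
    wfns = _tabulate(df["wfns_grade"].dropna().astype(int).tolist(), range(1, 6), n)

    ages = df["age"].dropna()
    return CohortSummary(
        n=n,
        sex=sex,
        circulation=circ,
        gcs_bands=gcs,
        hh_grades=hh,
        fisher_grades=fisher,
        wfns_grades=wfns,
        age_mean=float(ages.mean()) if len(ages) else float("nan"),
        age_min=float(ages.min()) if len(ages) else float("nan"),
        age_max=float(ages.max()) if len(ages) else float("nan"),
    )
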