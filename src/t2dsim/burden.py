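"""Burden accounting: incidence, prevalence, mortality, YLL/YLD/DALY.

Rates are per 100,000 mid-year person-years restricted to a reporting
age window (default 35-80).  YLL counts remaining reference life
expectancy at death for T2D-attributed deaths only; YLD is prevalent
person-years times the disability weight; DALY = YLL + YLD exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: stratification levels reported by default (finer rows carry the
#: coarser levels as All/Both)
GROUPINGS = [
    (),
    ("sex",),
    ("region",),
    ("region", "sex"),
    ("region", "sex", "education"),
]

RATE_SCALE = 100_000.0


@dataclass
class BurdenParams:
    disability_weight: float = 0.049
    life_table: pd.DataFrame | None = None  # columns: age, ex

    def __post_init__(self):
        if not 0 < self.disability_weight < 1:
            raise ValueError("disability weight must be in (0, 1)")
        if self.life_table is None:
            from .defaults import default_life_table

            self.life_table = default_life_table()
        lt = self.life_table.sort_values("age")
        if not (np.diff(lt["ex"].to_numpy()) <= 0).all():
            raise ValueError("life expectancy must be non-increasing in age")
        self._ages = lt["age"].to_numpy()
        self._ex = lt["ex"].to_numpy()

    def remaining_years(self, age):
        age = np.asarray(age)
        if (age > self._ages[-1]).any():
            warnings.warn("death age beyond life table; extrapolating with last row")
        idx = np.clip(np.searchsorted(self._ages, age), 0, len(self._ages) - 1)
        return self._ex[idx]


def _fill_labels(row: dict, grouping) -> dict:
    out = {"region": "All", "sex": "Both", "education": "All"}
    out.update({g: row[g] for g in grouping})
    return out


def compute_rates(events: pd.DataFrame, history: pd.DataFrame, ages=(35, 80)) -> pd.DataFrame:
    """Per-year, per-stratum counts and per-100,000 rates.

    ``history`` is the engine's mid-year person-count table; ``events``
    the onset/death log.  One output row per year and stratification
    level in :data:`GROUPINGS`; strata with zero denominator are absent.
    """
    lo, hi = ages
    hist = history[(history["age"] >= lo) & (history["age"] <= hi)]
    ev = events[(events["age"] >= lo) & (events["age"] <= hi)] if len(events) else events

    out = []
    for grouping in GROUPINGS:
        keys = ["year", *grouping]
        denom = hist.groupby(keys)[["alive_count", "t2d_count"]].sum()
        if len(ev):
            onsets = ev[ev["event"] == "t2d_onset"].groupby(keys).size()
            deaths = ev[ev["event"] == "death"].groupby(keys).size()
            deaths_t2d = (
                ev[(ev["event"] == "death") & (ev["cause"] == "t2d_attributable")]
                .groupby(keys)
                .size()
            )
        else:
            onsets = deaths = deaths_t2d = pd.Series(dtype=float)
        for key, row in denom.iterrows():
            key = (key,) if not isinstance(key, tuple) else key
            alive = row["alive_count"]
            if alive <= 0:
                continue
            rec = dict(zip(keys, key))
            labels = _fill_labels(rec, grouping)
            inc = float(onsets.get(key if len(key) > 1 else key[0], 0.0))
            dth = float(deaths.get(key if len(key) > 1 else key[0], 0.0))
            dtd = float(deaths_t2d.get(key if len(key) > 1 else key[0], 0.0))
            out.append(
                {
                    "year": rec["year"],
                    **labels,
                    "alive": alive,
                    "incident": inc,
                    "prevalent": row["t2d_count"],
                    "deaths": dth,
                    "deaths_t2d": dtd,
                    "incidence_rate": inc / alive * RATE_SCALE,
                    "prevalence_rate": row["t2d_count"] / alive * RATE_SCALE,
                    "mortality_rate": dth / alive * RATE_SCALE,
                }
            )
    return pd.DataFrame(out)


def compute_dalys(
    burden: pd.DataFrame, events: pd.DataFrame, params: BurdenParams, ages=(35, 80)
) -> pd.DataFrame:
    """Fill YLL, YLD and DALY columns (counts and per-100,000 rates)."""
    lo, hi = ages
    burden = burden.copy()
    att = events[
        (events["event"] == "death")
        & (events["cause"] == "t2d_attributable")
        & (events["age"] >= lo)
        & (events["age"] <= hi)
    ].copy()
    if len(att):
        att["yll"] = params.remaining_years(att["age"].to_numpy())

    yll = np.zeros(len(burden))
    for i, row in enumerate(burden.itertuples()):
        if not len(att):
            break
        sub = att[att["year"] == row.year]
        if row.region != "All":
            sub = sub[sub["region"] == row.region]
        if row.sex != "Both":
            sub = sub[sub["sex"] == row.sex]
        if row.education != "All":
            sub = sub[sub["education"] == row.education]
        yll[i] = sub["yll"].sum()

    burden["yll"] = yll
    burden["yld"] = burden["prevalent"] * params.disability_weight
    burden["daly"] = burden["yll"] + burden["yld"]
    for col in ["yll", "yld", "daly"]:
        burden[f"{col}_rate"] = burden[col] / burden["alive"] * RATE_SCALE
    return burden


def percent_change(rate_a: float, rate_b: float):
    """``100 * (b - a) / a``, one decimal; undefined (None) when ``a <= 0``."""
    if rate_a is None or rate_a <= 0:
        return None
    return round(100.0 * (rate_b - rate_a) / rate_a, 1)
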