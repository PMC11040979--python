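"""Annual death probabilities by stratum and health state.

Healthy individuals face cause-deleted mortality (all-cause minus the
disease-specific component); individuals with T2D face all-cause
mortality multiplied by an age- and sex-specific relative risk.  Rates
convert to probabilities under a constant hazard within the year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import REGIONS, SEXES

#: probability cap for the RR-adjusted hazard
_MAX_PROB = 0.999


@dataclass
class MortalityTable:
    """All-cause and T2D-cause annual mortality rates by age, sex, region.

    Ages beyond the last tabulated row reuse the last row (open interval).
    """

    table: pd.DataFrame  # age, sex, region, all_cause_rate, t2d_cause_rate

    def __post_init__(self):
        t = self.table
        if (t["t2d_cause_rate"] > t["all_cause_rate"] + 1e-12).any():
            raise ValueError("t2d-cause rate may not exceed all-cause rate")
        if not np.isfinite(t[["all_cause_rate", "t2d_cause_rate"]].to_numpy()).all():
            raise ValueError("rates must be finite")
        self._max_age = int(t["age"].max())
        self._grid = {}
        for (sex, region), sub in t.groupby(["sex", "region"]):
            sub = sub.sort_values("age")
            if len(sub) != self._max_age + 1:
                raise ValueError(f"incomplete age grid for stratum ({sex}, {region})")
            self._grid[(sex, region)] = (
                sub["all_cause_rate"].to_numpy(),
                sub["t2d_cause_rate"].to_numpy(),
            )

    def rates(self, age, sex: str, region: str):
        """(all_cause, t2d_cause) rate arrays for ages (clamped to the grid)."""
        key = (sex, region)
        if key not in self._grid:
            raise KeyError(f"no mortality rates for stratum {key}")
        idx = np.clip(np.asarray(age), 0, self._max_age)
        ac, td = self._grid[key]
        return ac[idx], td[idx]

    @classmethod
    def from_csv(cls, path) -> "MortalityTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class RRTable:
    """Relative risk of all-cause mortality for T2D, by age band and sex."""

    table: pd.DataFrame  # age_lo, age_hi, sex, rr, rr_lo, rr_hi

    def __post_init__(self):
        t = self.table
        bad = (t["rr"] < t["rr_lo"] - 1e-12) | (t["rr"] > t["rr_hi"] + 1e-12)
        if bad.any():
            raise ValueError("RR point estimate outside its confidence interval")

    def rr(self, age, sex: str):
        sub = self.table[self.table["sex"] == sex]
        if sub.empty:
            raise KeyError(f"no RR rows for sex {sex!r}")
        scalar = np.ndim(age) == 0
        age = np.atleast_1d(age)
        out = np.full(age.shape, np.nan, dtype=float)
        for row in sub.itertuples():
            out[(age >= row.age_lo) & (age <= row.age_hi)] = row.rr
        # open-ended: ages above the last band reuse it
        top = sub.loc[sub["age_hi"].idxmax()]
        out[age > top["age_hi"]] = top["rr"]
        if np.isnan(out).any():
            missing = int(age[np.isnan(out)][0])
            raise KeyError(f"no RR band covering age {missing} for sex {sex!r}")
        return float(out[0]) if scalar else out

    def perturbed(self, rng) -> "RRTable":
        """Lognormal draw per band from the 95% CI (sigma = CI width / 3.92)."""
        t = self.table.copy()
        sigma = (np.log(t["rr_hi"]) - np.log(t["rr_lo"])) / (2 * 1.959964)
        t["rr"] = np.exp(rng.normal(np.log(t["rr"].to_numpy()), sigma.to_numpy()))
        t["rr_lo"] = np.minimum(t["rr_lo"], t["rr"])
        t["rr_hi"] = np.maximum(t["rr_hi"], t["rr"])
        return RRTable(t)

    @classmethod
    def from_csv(cls, path) -> "RRTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def rate_to_probability(rate):
    """Annual event probability under a constant hazard: ``1 - exp(-rate)``."""
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate must be >= 0")
    out = 1.0 - np.exp(-rate)
    return float(out) if out.ndim == 0 else out


def death_probability_arrays(age, sex: str, region: str, t2d, mt: MortalityTable, rrt: RRTable):
    """Vectorised annual death probability and T2D-attribution weight.

    Healthy: hazard = all-cause minus T2D-cause (cause-deleted), weight 0.
    T2D: hazard = RR x all-cause (capped), weight = excess fraction
    ``(RR*r_ac - (r_ac - r_t2d)) / (RR*r_ac)`` clipped to [0, 1].
    """
    age = np.asarray(age)
    t2d = np.asarray(t2d, dtype=bool)
    r_ac, r_td = mt.rates(age, sex, region)
    healthy_hazard = np.maximum(r_ac - r_td, 0.0)

    rr = np.asarray(rrt.rr(age, sex), dtype=float)
    cap = -np.log(1.0 - _MAX_PROB)
    t2d_hazard = np.minimum(rr * r_ac, cap)
    with np.errstate(invalid="ignore", divide="ignore"):
        weight = np.where(rr * r_ac > 0, (rr * r_ac - healthy_hazard) / (rr * r_ac), 0.0)
    weight = np.clip(weight, 0.0, 1.0)

    hazard = np.where(t2d, t2d_hazard, healthy_hazard)
    prob = 1.0 - np.exp(-hazard)
    return prob, np.where(t2d, weight, 0.0)


def death_probability(ind, mt: MortalityTable, rrt: RRTable):
    """Single-individual wrapper: ``(annual death probability, attribution weight)``."""
    if not ind.get("alive", True):
        raise ValueError("death probability undefined for dead individual")
    p, w = death_probability_arrays(
        np.asarray([int(ind["age"])]),
        ind["sex"],
        ind["region"],
        np.asarray([bool(ind["t2d"])]),
        mt,
        rrt,
    )
    return float(p[0]), float(w[0])
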