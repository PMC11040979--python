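"""Annual-cycle discrete-event simulation.

Per alive individual and year, in order: (1) age increments; (2) the
modifiable risk factors move through their calibrated net-transition
matrices; (3) healthy adults at or above the incidence age floor face a
Bernoulli T2D-onset draw at the annualised FINDRISC risk; (4) everyone
faces a Bernoulli death draw at the state-appropriate probability, so
onset and death can land in the same year.  Demographics other than age
never change; dead individuals are never touched again.

A single seeded generator drives the run; draws are consumed in a fixed
operation order and in id order within each operation, so identical
seeds and inputs give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    ADULT_AGE,
    EDUCATION_LEVELS,
    INDIVIDUAL_COLUMNS,
    PROVINCES,
    REGIONS,
    RISK_FACTOR_STATES,
    SEXES,
)
from .findrisc import FindriscParams, risk_arrays
from .mortality import MortalityTable, RRTable, death_probability_arrays

logger = logging.getLogger("t2dsim.engine")

EVENT_COLUMNS = ["year", "id", "event", "cause", "age", "sex", "region", "education"]
HISTORY_COLUMNS = ["year", "region", "sex", "education", "age", "alive_count", "t2d_count"]


@dataclass
class SimulationConfig:
    start_year: int = 2018
    end_year: int = 2030
    seed: int = 0
    births_enabled: bool = True
    annual_birth_cohort: int | None = None  # default: baseline age-0 count
    incidence_age_floor: int = 35

    def __post_init__(self):
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year")


@dataclass
class SimTables:
    """Everything the annual cycle needs, pre-assembled."""

    transitions: dict  # {factor: {(sex, region, education): TransitionTable}}
    mortality: MortalityTable
    rr: RRTable
    findrisc: FindriscParams
    _dense: dict = field(default_factory=dict, repr=False)

    def dense_transitions(self):
        """{factor: (age0, Q[sex, region, edu, age, from, to])} for fast gather."""
        if self._dense:
            return self._dense
        for factor, by_stratum in self.transitions.items():
            k = len(RISK_FACTOR_STATES[factor])
            any_table = next(iter(by_stratum.values()))
            ages = any_table.ages
            q = np.zeros((len(SEXES), len(REGIONS), len(EDUCATION_LEVELS), len(ages), k, k))
            q[..., :, :] = np.eye(k)
            for (sex, region, edu), table in by_stratum.items():
                si, ri, ei = SEXES.index(sex), REGIONS.index(region), EDUCATION_LEVELS.index(edu)
                if len(table.ages) != len(ages) or table.ages[0] != ages[0]:
                    raise ValueError(f"inconsistent age grids across strata for {factor}")
                q[si, ri, ei] = table.matrices
            self._dense[factor] = (int(ages[0]), q)
        return self._dense


def encode_population(pop: pd.DataFrame) -> dict:
    enc = {
        "id": pop["id"].to_numpy(dtype=np.int64),
        "age": pop["age"].to_numpy(dtype=np.int64),
        "sex": pd.Categorical(pop["sex"], categories=SEXES).codes.astype(np.int64),
        "region": pd.Categorical(pop["region"], categories=REGIONS).codes.astype(np.int64),
        "province": pd.Categorical(pop["province"], categories=PROVINCES).codes.astype(np.int64),
        "education": pd.Categorical(pop["education"], categories=EDUCATION_LEVELS).codes.astype(
            np.int64
        ),
        "income": pop["income"].to_numpy(dtype=object),
        "t2d": pop["t2d"].to_numpy(dtype=bool),
        "alive": pop["alive"].to_numpy(dtype=bool),
        "t2d_onset_year": pop["t2d_onset_year"].to_numpy(dtype=float),
        "death_year": pop["death_year"].to_numpy(dtype=float),
        "death_cause": pop["death_cause"].to_numpy(dtype=object),
    }
    for factor, states in RISK_FACTOR_STATES.items():
        enc[factor] = pd.Categorical(pop[factor], categories=states).codes.astype(np.int64)
    for col in ["sex", "region", "province", "education"]:
        if (enc[col] < 0).any():
            raise ValueError(f"unknown category in column {col!r}")
    return enc


def decode_population(enc: dict) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "id": enc["id"],
            "age": enc["age"],
            "sex": np.array(SEXES, dtype=object)[enc["sex"]],
            "region": np.array(REGIONS, dtype=object)[enc["region"]],
            "province": np.array(PROVINCES, dtype=object)[enc["province"]],
            "education": np.array(EDUCATION_LEVELS, dtype=object)[enc["education"]],
            "income": enc["income"],
            "t2d": enc["t2d"],
            "alive": enc["alive"],
            "t2d_onset_year": enc["t2d_onset_year"],
            "death_year": enc["death_year"],
            "death_cause": enc["death_cause"],
        }
    )
    for factor, states in RISK_FACTOR_STATES.items():
        df[factor] = np.array(states, dtype=object)[enc[factor]]
    return df[INDIVIDUAL_COLUMNS]


def _step_encoded(enc: dict, year: int, tables: SimTables, config: SimulationConfig, rng):
    """One annual cycle, in place.  Returns the list of event records."""
    events = []
    alive = enc["alive"]
    n_alive = int(alive.sum())
    if n_alive == 0:
        return events

    enc["age"][alive] += 1
    age = enc["age"]

    # (2) risk-factor updates via net transition matrices
    dense = tables.dense_transitions()
    adult = alive & (age >= ADULT_AGE)
    idx = np.flatnonzero(adult)
    for factor in RISK_FACTOR_STATES:
        age0, q = dense[factor]
        n_ages = q.shape[3]
        a = np.clip(age[idx] - age0, 0, n_ages - 1)
        rows = q[enc["sex"][idx], enc["region"][idx], enc["education"][idx], a, enc[factor][idx]]
        u = rng.random(len(idx))
        enc[factor][idx] = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1).clip(
            0, rows.shape[1] - 1
        )

    # (3) T2D incidence for healthy adults at/above the age floor
    at_risk = alive & ~enc["t2d"] & (age >= config.incidence_age_floor)
    ridx = np.flatnonzero(at_risk)
    if len(ridx):
        icpt, age_c, bmi_c, waist_c, bp_c, glu_c = risk_arrays(tables.findrisc)
        lp = (
            icpt
            + age_c[np.clip(age[ridx], 0, 200)]
            + bmi_c[enc["bmi_class"][ridx]]
            + waist_c[enc["waist_class"][ridx]]
            + bp_c[enc["bp_medication"][ridx]]
            + glu_c[enc["high_glucose_history"][ridx]]
        )
        p10 = 1.0 / (1.0 + np.exp(-lp))
        p1 = 1.0 - np.power(1.0 - p10, 0.1)
        onset = ridx[rng.random(len(ridx)) < p1]
        enc["t2d"][onset] = True
        enc["t2d_onset_year"][onset] = year
        for i in onset:
            events.append(
                {
                    "year": year,
                    "id": int(enc["id"][i]),
                    "event": "t2d_onset",
                    "cause": None,
                    "age": int(age[i]),
                    "sex": SEXES[enc["sex"][i]],
                    "region": REGIONS[enc["region"][i]],
                    "education": EDUCATION_LEVELS[enc["education"][i]],
                }
            )

    # (4) death draw at post-update state
    didx = np.flatnonzero(alive)
    prob = np.zeros(len(didx))
    weight = np.zeros(len(didx))
    for si, sex in enumerate(SEXES):
        for ri, region in enumerate(REGIONS):
            m = (enc["sex"][didx] == si) & (enc["region"][didx] == ri)
            if not m.any():
                continue
            p, w = death_probability_arrays(
                age[didx[m]], sex, region, enc["t2d"][didx[m]], tables.mortality, tables.rr
            )
            prob[m], weight[m] = p, w
    u = rng.random(len(didx))
    dying = didx[u < prob]
    w_dying = weight[u < prob]
    cause_u = rng.random(len(dying))
    for i, wi, cu in zip(dying, w_dying, cause_u):
        cause = "t2d_attributable" if (enc["t2d"][i] and cu < wi) else "other"
        enc["alive"][i] = False
        enc["death_year"][i] = year
        enc["death_cause"][i] = cause
        events.append(
            {
                "year": year,
                "id": int(enc["id"][i]),
                "event": "death",
                "cause": cause,
                "age": int(age[i]),
                "sex": SEXES[enc["sex"][i]],
                "region": REGIONS[enc["region"][i]],
                "education": EDUCATION_LEVELS[enc["education"][i]],
            }
        )
    return events


def step_year(pop: pd.DataFrame, year: int, tables: SimTables, config: SimulationConfig, rng):
    """One annual cycle on a population frame.  Returns ``(pop, events)``."""
    enc = encode_population(pop)
    events = _step_encoded(enc, year, tables, config, rng)
    return decode_population(enc), events


def _snapshot_fast(enc: dict, year: int) -> pd.DataFrame:
    """Mid-year person counts by stratum and single year of age.

    Individuals dying within the year contribute half a person-year
    (mid-year convention); survivors contribute one.
    """
    alive = enc["alive"]
    died_now = (~alive) & (enc["death_year"] == year)
    sel = alive | died_now
    w = np.where(alive[sel], 1.0, 0.5)
    df = pd.DataFrame(
        {
            "region": np.array(REGIONS, dtype=object)[enc["region"][sel]],
            "sex": np.array(SEXES, dtype=object)[enc["sex"][sel]],
            "education": np.array(EDUCATION_LEVELS, dtype=object)[enc["education"][sel]],
            "age": enc["age"][sel],
            "alive_count": w,
            "t2d_count": w * enc["t2d"][sel],
        }
    )
    out = (
        df.groupby(["region", "sex", "education", "age"], as_index=False)[
            ["alive_count", "t2d_count"]
        ].sum()
    )
    out.insert(0, "year", year)
    return out


def run_simulation(pop0: pd.DataFrame, config: SimulationConfig, tables: SimTables):
    """Run from the baseline year to the horizon.

    Returns ``(events, history)``: an event log (one row per onset/death)
    and a per-year mid-year person-count table by region, sex, education
    and single year of age.
    """
    rng = np.random.default_rng(config.seed)
    enc = encode_population(pop0.sort_values("id").reset_index(drop=True))
    next_id = int(enc["id"].max()) + 1 if len(enc["id"]) else 0

    baseline_newborns = pop0[pop0["age"] == 0]
    n_births = (
        config.annual_birth_cohort
        if config.annual_birth_cohort is not None
        else len(baseline_newborns)
    )

    all_events = []
    history = [_snapshot_fast(enc, config.start_year)]
    for year in range(config.start_year + 1, config.end_year + 1):
        events = _step_encoded(enc, year, tables, config, rng)
        all_events.extend(events)
        if config.births_enabled and n_births > 0 and len(baseline_newborns):
            pick = rng.choice(len(baseline_newborns), size=n_births, replace=True)
            babies = baseline_newborns.iloc[pick].copy()
            babies["age"] = 0
            for factor, states in RISK_FACTOR_STATES.items():
                babies[factor] = states[0]
            babies["bmi_class"] = RISK_FACTOR_STATES["bmi_class"][0]
            babies["t2d"] = False
            babies["alive"] = True
            babies["t2d_onset_year"] = np.nan
            babies["death_year"] = np.nan
            babies["death_cause"] = None
            babies["id"] = np.arange(next_id, next_id + n_births)
            next_id += n_births
            benc = encode_population(babies.reset_index(drop=True))
            for key in enc:
                enc[key] = np.concatenate([enc[key], benc[key]])
        history.append(_snapshot_fast(enc, year))
        logger.info(
            "year=%d alive=%d t2d=%d events=%d",
            year,
            int(enc["alive"].sum()),
            int((enc["alive"] & enc["t2d"]).sum()),
            len(events),
        )

    events_df = pd.DataFrame(all_events, columns=EVENT_COLUMNS)
    history_df = pd.concat(history, ignore_index=True)
    return events_df, history_df, decode_population(enc)
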