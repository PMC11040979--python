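"""Probabilistic sensitivity analysis.

Each run draws the risk-equation coefficients from Normal(point, SE)
and the mortality relative risks from a lognormal implied by their 95%
CI (structural parameters held as per-run constants), subsamples the
population (stratified by age group x sex x region), runs the full
simulation and records per-100,000 burden outputs.  Uncertainty
intervals are the 2.5th/97.5th empirical percentiles across runs; the
point estimate comes from an all-parameters-at-point run on the full
population.  The simulation seed is shared across runs, so degenerate
parameter distributions at full sampling fraction collapse the interval
onto the point run exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .burden import BurdenParams, compute_dalys, compute_rates
from .constants import age_group_of
from .engine import SimTables, SimulationConfig, run_simulation

#: outcome columns extracted from the overall burden rows
OUTCOMES = ["incidence_rate", "prevalence_rate", "daly_rate"]


@dataclass
class PsaConfig:
    n_runs: int = 100
    sample_fraction: float = 0.01
    seed: int = 0
    perturb_findrisc: bool = True
    perturb_rr: bool = True
    redraw_sample: bool = True  # a fresh subsample per run

    def __post_init__(self):
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")


def _stratified_subsample(pop: pd.DataFrame, fraction: float, rng) -> pd.DataFrame:
    if fraction >= 1.0:
        return pop
    groups = pop.groupby(
        [age_group_of(pop["age"].to_numpy()), pop["sex"], pop["region"]]
    ).indices
    keep = []
    for key in sorted(groups):
        idx = groups[key]
        k = max(1, int(round(fraction * len(idx))))
        keep.append(rng.choice(idx, size=k, replace=False))
    return pop.iloc[np.sort(np.concatenate(keep))].reset_index(drop=True)


def _overall_rates(pop, sim_config, tables, burden_params) -> pd.DataFrame:
    events, history, _ = run_simulation(pop, sim_config, tables)
    burden = compute_rates(events, history)
    burden = compute_dalys(burden, events, burden_params)
    overall = burden[
        (burden["region"] == "All") & (burden["sex"] == "Both") & (burden["education"] == "All")
    ]
    return overall.set_index("year")[OUTCOMES]


def run_psa(
    pop: pd.DataFrame,
    psa_config: PsaConfig,
    sim_config: SimulationConfig,
    tables: SimTables,
    burden_params: BurdenParams | None = None,
) -> pd.DataFrame:
    """95% uncertainty intervals around the overall burden outputs.

    Returns a tidy frame ``(outcome, year, point, lo95, hi95)``.  Any
    failing run aborts the PSA with its run seed in the error message.
    """
    burden_params = burden_params or BurdenParams()
    point = _overall_rates(pop, sim_config, tables, burden_params)

    sample_rng = np.random.default_rng([psa_config.seed, 0xA5])
    fixed_sample = None
    if not psa_config.redraw_sample:
        fixed_sample = _stratified_subsample(pop, psa_config.sample_fraction, sample_rng)

    results = []
    for run in range(psa_config.n_runs):
        rng = np.random.default_rng([psa_config.seed, run])
        try:
            sub = (
                fixed_sample
                if fixed_sample is not None
                else _stratified_subsample(pop, psa_config.sample_fraction, rng)
            )
            run_tables = SimTables(
                transitions=tables.transitions,
                mortality=tables.mortality,
                rr=tables.rr.perturbed(rng) if psa_config.perturb_rr else tables.rr,
                findrisc=(
                    tables.findrisc.perturbed(rng)
                    if psa_config.perturb_findrisc
                    else tables.findrisc
                ),
            )
            # shared simulation seed: parameter and sampling noise only
            results.append(_overall_rates(sub, sim_config, run_tables, burden_params))
        except Exception as exc:  # noqa: BLE001 - abort with run identity
            raise RuntimeError(f"PSA run {run} (seed [{psa_config.seed}, {run}]) failed") from exc

    out = []
    for outcome in OUTCOMES:
        stacked = pd.concat([r[outcome] for r in results], axis=1)
        lo = stacked.quantile(0.025, axis=1)
        hi = stacked.quantile(0.975, axis=1)
        for year in point.index:
            out.append(
                {
                    "outcome": outcome,
                    "stratum": "All/Both/All",
                    "year": int(year),
                    "point": float(point.loc[year, outcome]),
                    "lo95": float(lo.get(year, np.nan)),
                    "hi95": float(hi.get(year, np.nan)),
                }
            )
    return pd.DataFrame(out)


def format_interval(point: float, lo: float, hi: float) -> str:
    """Render ``point (lo; hi)`` in the conventional presentation."""
    return f"{point:.0f} ({lo:.0f}; {hi:.0f})"
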