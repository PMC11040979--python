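"""End-to-end pipeline: configuration, I/O, logging, manifest.

A single YAML config drives synthetic-population generation, transition
calibration, the simulation, burden and inequality outputs and the PSA.
Every output directory carries a ``manifest.json`` recording the config
hash, seeds, input checksums, package version and per-stage runtimes,
so a rerun with the same config and seeds is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from .burden import BurdenParams, compute_dalys, compute_rates, percent_change
from .defaults import (
    DEFAULT_CORRELATION,
    default_marginals,
    default_mortality_table,
    default_prevalence_curves,
    default_rr_table,
)
from .dynamics import build_transition_table, transition_tables_to_frame
from .engine import SimTables, SimulationConfig, run_simulation
from .findrisc import FindriscParams
from .inequality import yearly_inequality
from .mortality import MortalityTable, RRTable
from .synthpop import MarginalSpec, expand_population, generate_survey_fixture
from .uncertainty import PsaConfig, run_psa

logger = logging.getLogger("t2dsim.pipeline")


class PsaSection(BaseModel):
    enabled: bool = True
    n_runs: int = Field(100, ge=2)
    sample_fraction: float = Field(0.01, gt=0, le=1)


class PipelineConfig(BaseModel):
    seed: int = 0
    scale: float = Field(100.0, gt=0, description="divide national counts by this factor")
    survey_n: int = Field(10_000, ge=100)
    start_year: int = 2018
    end_year: int = 2030
    births_enabled: bool = True
    incidence_age_floor: int = 35
    smooth_window: int = Field(5, ge=1)
    disability_weight: float = Field(0.049, gt=0, lt=1)
    inequality_axis: str = "education"
    marginals_file: str | None = None
    survey_file: str | None = None
    findrisc_file: str | None = None
    mortality_file: str | None = None
    rr_file: str | None = None
    correlation: list[dict] | None = None
    psa: PsaSection = PsaSection()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except ValidationError as exc:
            fields = "; ".join(
                "/".join(str(p) for p in e["loc"]) + ": " + e["msg"] for e in exc.errors()
            )
            raise ValueError(f"invalid pipeline config: {fields}") from None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


_TABLES_CACHE: dict = {}


def build_tables(
    smooth_window: int = 5,
    findrisc_file=None,
    mortality_file=None,
    rr_file=None,
    curves=None,
) -> SimTables:
    """Assemble the simulation tables, calibrating transitions from curves.

    Calls with the bundled default curves are memoized per argument set —
    calibration is deterministic, so reuse is safe.
    """
    cache_key = None
    if curves is None:
        cache_key = (smooth_window, findrisc_file, mortality_file, rr_file)
        if cache_key in _TABLES_CACHE:
            return _TABLES_CACHE[cache_key]
    curves = curves or default_prevalence_curves()
    transitions = {
        factor: {
            key: build_transition_table(curve, smooth_window)
            for key, curve in by_stratum.items()
        }
        for factor, by_stratum in curves.items()
    }
    mortality = (
        MortalityTable.from_csv(mortality_file)
        if mortality_file
        else MortalityTable(default_mortality_table())
    )
    rr = RRTable.from_csv(rr_file) if rr_file else RRTable(default_rr_table())
    findrisc = FindriscParams.from_yaml(findrisc_file)
    tables = SimTables(transitions=transitions, mortality=mortality, rr=rr, findrisc=findrisc)
    if cache_key is not None:
        _TABLES_CACHE[cache_key] = tables
    return tables


def run_pipeline(config, out_dir) -> Path:
    """Execute every configured stage and write outputs plus the manifest."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    runtimes: dict[str, float] = {}
    checksums: dict[str, str] = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage=%s status=start", name)

            def __exit__(self, *exc):
                runtimes[name] = round(time.perf_counter() - self.t0, 3)
                logger.info("stage=%s status=done runtime=%.3fs", name, runtimes[name])

        return _Timer()

    with stage("synthpop"):
        if config.marginals_file:
            spec = MarginalSpec.from_csv(config.marginals_file)
            checksums["marginals"] = _sha256(Path(config.marginals_file))
        else:
            spec = default_marginals(config.scale)
        if config.survey_file:
            survey = pd.read_csv(config.survey_file)
            checksums["survey"] = _sha256(Path(config.survey_file))
        else:
            corr = config.correlation if config.correlation is not None else DEFAULT_CORRELATION
            survey = generate_survey_fixture(spec, corr, config.survey_n, config.seed)
        pop = expand_population(survey, spec, config.seed + 1)
        pop.to_csv(out / "population.csv", index=False)

    with stage("calibrate"):
        tables = build_tables(
            config.smooth_window, config.findrisc_file, config.mortality_file, config.rr_file
        )
        frames = [t for by_s in tables.transitions.values() for t in by_s.values()]
        transition_tables_to_frame(frames).to_csv(out / "transitions.csv", index=False)

    with stage("simulate"):
        sim_config = SimulationConfig(
            start_year=config.start_year,
            end_year=config.end_year,
            seed=config.seed + 2,
            births_enabled=config.births_enabled,
            incidence_age_floor=config.incidence_age_floor,
        )
        events, history, _final = run_simulation(pop, sim_config, tables)
        events.to_csv(out / "events.csv", index=False)

    with stage("burden"):
        params = BurdenParams(disability_weight=config.disability_weight)
        burden = compute_dalys(compute_rates(events, history), events, params)
        burden.to_csv(out / "burden.csv", index=False)
        overall = burden[
            (burden["region"] == "All") & (burden["sex"] == "Both") & (burden["education"] == "All")
        ].set_index("year")
        summary = {}
        if config.end_year > config.start_year:
            summary["prevalence_pct_change"] = percent_change(
                float(overall.loc[config.start_year, "prevalence_rate"]),
                float(overall.loc[config.end_year, "prevalence_rate"]),
            )
        (out / "summary.json").write_text(json.dumps(summary, indent=2))

    with stage("inequality"):
        ineq = yearly_inequality(burden, config.inequality_axis)
        ineq.to_csv(out / "inequality.csv", index=False)

    if config.psa.enabled and config.end_year > config.start_year:
        with stage("psa"):
            psa_cfg = PsaConfig(
                n_runs=config.psa.n_runs,
                sample_fraction=config.psa.sample_fraction,
                seed=config.seed + 3,
            )
            psa = run_psa(pop, psa_cfg, sim_config, tables, params)
            psa.to_csv(out / "psa.csv", index=False)

    manifest = {
        "config": json.loads(config.model_dump_json()),
        "config_hash": hashlib.sha256(config.model_dump_json().encode()).hexdigest(),
        "seeds": {
            "survey": config.seed,
            "expand": config.seed + 1,
            "simulation": config.seed + 2,
            "psa": config.seed + 3,
        },
        "input_checksums": checksums,
        "version": __version__,
        "runtimes_s": runtimes,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
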