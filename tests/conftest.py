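import numpy as np
import pandas as pd
import pytest

from t2dsim.constants import (
    EDUCATION_LEVELS,
    INDIVIDUAL_COLUMNS,
    REGIONS,
    RISK_FACTOR_STATES,
    SEXES,
)
from t2dsim.dynamics import TransitionTable
from t2dsim.engine import SimTables
from t2dsim.findrisc import FindriscParams
from t2dsim.mortality import MortalityTable, RRTable


@pytest.fixture(scope="session")
def default_tables():
    """Fully calibrated default tables (expensive; built once per session)."""
    from t2dsim.interface import build_tables

    return build_tables()


@pytest.fixture(scope="session")
def small_population():
    """~1.1k-person expanded population from the bundled demo marginals."""
    from t2dsim.defaults import DEFAULT_CORRELATION, default_marginals
    from t2dsim.synthpop import expand_population, generate_survey_fixture

    spec = default_marginals(scale=1000)
    survey = generate_survey_fixture(spec, DEFAULT_CORRELATION, 3000, seed=11)
    return expand_population(survey, spec, seed=12)


def make_population(
    n,
    age=40,
    sex="male",
    region="Flanders",
    province="Antwerp",
    education="intermediate",
    t2d=False,
    **overrides,
):
    """Homogeneous population frame for controlled engine experiments."""
    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "age": age,
            "sex": sex,
            "region": region,
            "province": province,
            "education": education,
            "income": "Q3",
            "bmi_class": "lt25",
            "waist_class": "low",
            "bp_medication": "no",
            "high_glucose_history": "no",
            "t2d": t2d,
            "alive": True,
            "t2d_onset_year": np.nan,
            "death_year": np.nan,
            "death_cause": None,
        }
    )
    for key, val in overrides.items():
        df[key] = val
    return df[INDIVIDUAL_COLUMNS]


def zero_findrisc(intercept=-700.0):
    """All-zero coefficients; intercept controls the flat 10-year risk."""
    coefficients = {
        "age_band": {"45to54": 0.0, "55to64": 0.0},
        "bmi_class": {"25to30": 0.0, "gt30": 0.0},
        "waist_class": {"mid": 0.0, "high": 0.0},
        "bp_medication": {"yes": 0.0},
        "high_glucose_history": {"yes": 0.0},
    }
    ses = {"intercept": 0.0} | {
        pred: {c: 0.0 for c in cats} for pred, cats in coefficients.items()
    }
    return FindriscParams(intercept=intercept, coefficients=coefficients, ses=ses)


def intercept_for_annual(p_annual):
    """Logit of the 10-year risk whose constant-hazard annualisation is p_annual."""
    p10 = 1.0 - (1.0 - p_annual) ** 10
    return float(np.log(p10 / (1.0 - p10)))


def flat_mortality_table(all_cause=0.0, t2d_cause=0.0):
    rows = [
        {
            "age": a,
            "sex": s,
            "region": r,
            "all_cause_rate": all_cause,
            "t2d_cause_rate": t2d_cause,
        }
        for a in range(111)
        for s in SEXES
        for r in REGIONS
    ]
    return MortalityTable(pd.DataFrame(rows))


def flat_rr_table(rr=1.0, lo=None, hi=None):
    rows = [
        {"age_lo": 0, "age_hi": 110, "sex": s, "rr": rr, "rr_lo": lo or rr, "rr_hi": hi or rr}
        for s in SEXES
    ]
    return RRTable(pd.DataFrame(rows))


def identity_transitions():
    """One identity table per factor (remaining strata default to identity)."""
    ages = np.arange(18, 100)
    out = {}
    for factor, states in RISK_FACTOR_STATES.items():
        k = len(states)
        mats = np.tile(np.eye(k), (len(ages), 1, 1))
        out[factor] = {
            ("male", "Flanders", "intermediate"): TransitionTable(
                factor=factor,
                stratum={"sex": "male", "region": "Flanders", "education": "intermediate"},
                ages=ages,
                matrices=mats,
            )
        }
    return out


def make_tables(p_annual=0.0, all_cause=0.0, t2d_cause=0.0, rr=1.0, transitions=None):
    """Controlled SimTables: identity risk-factor dynamics by default."""
    intercept = -700.0 if p_annual <= 0 else intercept_for_annual(p_annual)
    return SimTables(
        transitions=transitions or identity_transitions(),
        mortality=flat_mortality_table(all_cause, t2d_cause),
        rr=flat_rr_table(rr),
        findrisc=zero_findrisc(intercept),
    )
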