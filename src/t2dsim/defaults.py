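"""Bundled synthetic default inputs.

Everything here is a self-contained stand-in for the national register,
survey and vital-statistics extracts a real deployment would supply:
demo population marginals calibrated to published Belgian 2018
descriptive statistics, Gompertz-like mortality rates, diabetes
mortality relative risks by age band and sex, and age-prevalence curves
for the modifiable risk factors.  All of it is configurable through the
normal file-based interfaces; these functions only provide defaults so
that the package runs out of the box.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import (
    AGE_GROUP_LABELS,
    EDUCATION_LEVELS,
    PROVINCES,
    PROVINCE_REGION,
    REGIONS,
    RISK_FACTOR_STATES,
    SEXES,
)

DEFAULT_BASELINE_YEAR = 2018

#: demo total population per age group (national scale, before division)
AGE_GROUP_TOTALS = {
    "0-17": 2_301_495,
    "18-34": 2_374_218,
    "35-64": 4_561_902,
    "65-80": 2_138_454,
}

#: share of men per age group
MALE_SHARE = {"0-17": 0.5117, "18-34": 0.5027, "35-64": 0.5009, "65-80": 0.4404}

#: region shares per age group (Brussels, Flanders, Wallonia)
REGION_SHARE = {
    "0-17": [0.1194, 0.5525, 0.3280],
    "18-34": [0.1293, 0.5495, 0.3212],
    "35-64": [0.1007, 0.5819, 0.3174],
    "65-80": [0.0737, 0.6183, 0.3080],
}

#: age-group prevalence vectors for the categorical attributes.
#: Minors carry the lowest-risk state for the adult-only variables.
PREVALENCE = {
    "education": {
        "0-17": [0.1221, 0.2797, 0.5982],
        "18-34": [0.1216, 0.3388, 0.5396],
        "35-64": [0.1408, 0.3370, 0.5222],
        "65-80": [0.3844, 0.2990, 0.3166],
    },
    "income": {
        "0-17": [0.0498, 0.0887, 0.1670, 0.2665, 0.4280],
        "18-34": [0.0707, 0.1144, 0.1673, 0.2898, 0.3576],
        "35-64": [0.0961, 0.1113, 0.1875, 0.2661, 0.3389],
        "65-80": [0.2093, 0.2416, 0.2350, 0.2205, 0.0936],
    },
    "bmi_class": {
        "0-17": [0.7475, 0.1497, 0.1028],
        "18-34": [0.6776, 0.2298, 0.0926],
        "35-64": [0.4562, 0.3578, 0.1861],
        "65-80": [0.4129, 0.3886, 0.1985],
    },
    "waist_class": {
        "0-17": [1.0, 0.0, 0.0],
        "18-34": [0.6202, 0.2094, 0.1704],
        "35-64": [0.3483, 0.2680, 0.3837],
        "65-80": [0.1849, 0.2418, 0.5733],
    },
    "bp_medication": {
        "0-17": [1.0, 0.0],
        "18-34": [0.9896, 0.0104],
        "35-64": [0.8516, 0.1484],
        "65-80": [0.6440, 0.3560],
    },
    "high_glucose_history": {
        "0-17": [1.0, 0.0],
        "18-34": [0.9866, 0.0134],
        "35-64": [0.9630, 0.0370],
        "65-80": [0.8805, 0.1195],
    },
    "t2d": {
        "0-17": [1.0, 0.0],
        "18-34": [0.9863, 0.0137],
        "35-64": [0.9493, 0.0507],
        "65-80": [0.8617, 0.1383],
    },
}


def default_marginals(scale: float = 100.0):
    """Demo :class:`~t2dsim.synthpop.MarginalSpec` at ``1/scale`` of national size."""
    from .synthpop import MarginalSpec

    rows = []
    for group in AGE_GROUP_LABELS:
        total = AGE_GROUP_TOTALS[group] / scale
        for sex, sex_share in zip(SEXES, [MALE_SHARE[group], 1 - MALE_SHARE[group]]):
            for region, reg_share in zip(REGIONS, REGION_SHARE[group]):
                provinces = [p for p in PROVINCES if PROVINCE_REGION[p] == region]
                for prov in provinces:
                    count = total * sex_share * reg_share / len(provinces)
                    rows.append(
                        {
                            "age_group": group,
                            "sex": sex,
                            "province": prov,
                            "count": max(1, int(round(count))),
                        }
                    )
    counts = pd.DataFrame(rows)

    prevalence = {}
    for var, per_group in PREVALENCE.items():
        recs = []
        from .constants import CATEGORY_ORDERS

        cats = CATEGORY_ORDERS[var]
        for group, vec in per_group.items():
            vec = np.asarray(vec, dtype=float)
            vec = vec / vec.sum()
            for cat, p in zip(cats, vec):
                recs.append({"age_group": group, "category": cat, "p": p})
        prevalence[var] = pd.DataFrame(recs)

    return MarginalSpec(counts=counts, prevalence=prevalence, year=DEFAULT_BASELINE_YEAR)


#: monotone associations used by the demo survey fixture: each entry ties the
#: ordinal level of ``source`` to the odds of higher ``target`` categories.
DEFAULT_CORRELATION = [
    {"source": "education", "target": "bmi_class", "odds": 0.6},
    {"source": "bmi_class", "target": "waist_class", "odds": 4.0},
    {"source": "bmi_class", "target": "bp_medication", "odds": 2.0},
    {"source": "waist_class", "target": "high_glucose_history", "odds": 2.5},
    {"source": "high_glucose_history", "target": "t2d", "odds": 6.0},
]


def default_mortality_table() -> pd.DataFrame:
    """Gompertz-like annual mortality rates by age, sex and region.

    ``t2d_cause_rate`` is a small share of all-cause mortality from age 35
    upward, mimicking cause-of-death statistics granularity.
    """
    sex_mult = {"male": 1.20, "female": 0.85}
    region_mult = {"Brussels": 1.00, "Flanders": 0.95, "Wallonia": 1.10}
    rows = []
    for age in range(0, 111):
        base = 2e-5 * np.exp(0.10 * age)
        t2d_share = 0.02 if age >= 35 else 0.0
        for sex in SEXES:
            for region in REGIONS:
                r = base * sex_mult[sex] * region_mult[region]
                rows.append(
                    {
                        "age": age,
                        "sex": sex,
                        "region": region,
                        "all_cause_rate": r,
                        "t2d_cause_rate": r * t2d_share,
                    }
                )
    return pd.DataFrame(rows)


def default_rr_table() -> pd.DataFrame:
    """Age-band and sex specific all-cause mortality relative risks for T2D."""
    bands = [
        (0, 49, {"male": (2.6, 1.8, 3.8), "female": (3.1, 2.1, 4.6)}),
        (50, 59, {"male": (2.1, 1.6, 2.8), "female": (2.6, 1.9, 3.5)}),
        (60, 69, {"male": (1.7, 1.4, 2.1), "female": (2.0, 1.6, 2.6)}),
        (70, 110, {"male": (1.4, 1.2, 1.7), "female": (1.6, 1.3, 1.9)}),
    ]
    rows = []
    for lo, hi, by_sex in bands:
        for sex, (rr, rr_lo, rr_hi) in by_sex.items():
            rows.append(
                {"age_lo": lo, "age_hi": hi, "sex": sex, "rr": rr, "rr_lo": rr_lo, "rr_hi": rr_hi}
            )
    return pd.DataFrame(rows)


def default_life_table() -> pd.DataFrame:
    """Reference remaining life expectancy by age (synthetic, decreasing)."""
    anchor_ages = np.array([0, 20, 40, 60, 80, 100, 110])
    anchor_ex = np.array([88.9, 69.4, 49.9, 31.0, 14.7, 4.0, 1.5])
    ages = np.arange(0, 111)
    ex = np.interp(ages, anchor_ages, anchor_ex)
    return pd.DataFrame({"age": ages, "ex": ex})


def _ordered_tilt(p: np.ndarray, delta: float) -> np.ndarray:
    """Shift an ordered probability vector toward higher states (delta > 0)
    by translating the logits of its cumulative distribution."""
    p = np.asarray(p, dtype=float)
    if delta == 0.0:
        return p / p.sum()
    cum = np.clip(np.cumsum(p)[:-1], 1e-12, 1 - 1e-12)
    logit = np.log(cum / (1 - cum)) - delta
    new_cum = 1.0 / (1.0 + np.exp(-logit))
    full = np.concatenate([[0.0], new_cum, [1.0]])
    out = np.diff(full)
    return out / out.sum()


#: education tilt applied to risk-factor age curves (log-odds toward high states)
EDUCATION_TILT = {"low": 0.35, "intermediate": 0.0, "high": -0.35}


def default_prevalence_curves():
    """Age-prevalence curves per modifiable risk factor and stratum.

    National age-group prevalences are interpolated at group midpoints over
    ages 18..100 and tilted by education level; sex and region carry the
    national curve.  Returns ``{factor: {(sex, region, education): PrevalenceCurve}}``.
    """
    from .dynamics import PrevalenceCurve

    midpoints = {"18-34": 26, "35-64": 50, "65-80": 73}
    ages = np.arange(18, 101)
    curves: dict = {}
    for factor, states in RISK_FACTOR_STATES.items():
        k = len(states)
        anchors_x = [midpoints[g] for g in ["18-34", "35-64", "65-80"]]
        anchors = np.array([PREVALENCE[factor][g][:k] for g in ["18-34", "35-64", "65-80"]])
        base = np.column_stack(
            [np.interp(ages, anchors_x, anchors[:, j]) for j in range(k)]
        )
        base = base / base.sum(axis=1, keepdims=True)
        curves[factor] = {}
        for sex in SEXES:
            for region in REGIONS:
                for edu in EDUCATION_LEVELS:
                    delta = EDUCATION_TILT[edu]
                    probs = np.vstack([_ordered_tilt(row, delta) for row in base])
                    curves[factor][(sex, region, edu)] = PrevalenceCurve(
                        factor=factor,
                        stratum={"sex": sex, "region": region, "education": edu},
                        ages=ages.copy(),
                        probs=probs,
                        states=list(states),
                    )
    return curves
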