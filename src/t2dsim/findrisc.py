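"""Concise FINDRISC risk scoring and the 10-year -> 1-year conversion.

The concise model is a logistic regression on age band, BMI class,
waist-circumference class, blood-pressure medication use, and history
of high blood glucose.  Reference categories (age < 45, BMI < 25, low
waist, no medication, no glucose history) carry coefficient zero.
The model's top age band (55-64) is carried forward for ages 65+,
a documented extrapolation; incidence is only simulated from age 35.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

#: age bands of the concise model; ages 65+ reuse the 55-64 coefficient
AGE_BANDS = [(45, 54, "45to54"), (55, 200, "55to64")]

_CAT_PREDICTORS = {
    "bmi_class": ["25to30", "gt30"],
    "waist_class": ["mid", "high"],
    "bp_medication": ["yes"],
    "high_glucose_history": ["yes"],
}


@dataclass
class FindriscParams:
    """Point estimates and standard errors of the concise model."""

    intercept: float
    coefficients: dict  # {predictor: {category: point}}
    ses: dict  # same structure, SEs (incl. "intercept" key)

    def __post_init__(self):
        for pred, cats in self.ses.items():
            if pred == "intercept":
                if cats < 0:
                    raise ValueError("intercept SE must be >= 0")
                continue
            for cat, se in cats.items():
                if se < 0:
                    raise ValueError(f"SE for {pred}={cat} must be >= 0")

    @classmethod
    def from_yaml(cls, path=None) -> "FindriscParams":
        if path is None:
            text = resources.files("t2dsim.data").joinpath("findrisc.yaml").read_text()
            raw = yaml.safe_load(text)
        else:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        coefficients, ses = {}, {"intercept": float(raw["intercept"]["se"])}
        for pred, cats in raw.items():
            if pred == "intercept":
                continue
            coefficients[pred] = {c: float(v["point"]) for c, v in cats.items()}
            ses[pred] = {c: float(v["se"]) for c, v in cats.items()}
        return cls(intercept=float(raw["intercept"]["point"]), coefficients=coefficients, ses=ses)

    def perturbed(self, rng) -> "FindriscParams":
        """Draw a coefficient set from Normal(point, SE) for each parameter."""
        coeffs = {
            pred: {c: rng.normal(v, self.ses[pred][c]) for c, v in cats.items()}
            for pred, cats in self.coefficients.items()
        }
        return FindriscParams(
            intercept=float(rng.normal(self.intercept, self.ses["intercept"])),
            coefficients=coeffs,
            ses={k: (dict(v) if isinstance(v, dict) else v) for k, v in self.ses.items()},
        )


def age_band_category(age: int):
    for lo, hi, label in AGE_BANDS:
        if lo <= age <= hi:
            return label
    return None  # reference (< 45)


def linear_predictor(ind, params: FindriscParams) -> float:
    lp = params.intercept
    band = age_band_category(int(ind["age"]))
    if band is not None:
        try:
            lp += params.coefficients["age_band"][band]
        except KeyError:
            raise KeyError(f"missing coefficient for age_band={band}")
    for pred, nonref in _CAT_PREDICTORS.items():
        val = ind[pred]
        if isinstance(val, (bool, np.bool_)):
            val = "yes" if val else "no"
        if val in nonref:
            try:
                lp += params.coefficients[pred][val]
            except KeyError:
                raise KeyError(f"missing coefficient for {pred}={val}")
    return lp


def ten_year_risk(ind, params: FindriscParams) -> float:
    """10-year probability of developing T2D for a healthy adult (age >= 35)."""
    if not ind.get("alive", True):
        raise ValueError("risk undefined for dead individual")
    if ind.get("t2d", False):
        raise ValueError("risk undefined for prevalent T2D")
    if int(ind["age"]) < 35:
        raise ValueError("10-year risk defined from age 35")
    return float(1.0 / (1.0 + np.exp(-linear_predictor(ind, params))))


def annual_probability(p10):
    """Constant-hazard conversion of a 10-year probability to a 1-year one.

    ``p1 = 1 - (1 - p10) ** (1/10)``; exact round trip with ten annual
    Bernoulli trials at ``p1``.
    """
    p10 = np.asarray(p10, dtype=float)
    if np.any(p10 < 0) or np.any(p10 >= 1):
        raise ValueError("p10 must lie in [0, 1)")
    out = 1.0 - np.power(1.0 - p10, 0.1)
    return float(out) if out.ndim == 0 else out


def risk_arrays(params: FindriscParams):
    """Coefficient lookup arrays for vectorised scoring.

    Returns ``(intercept, age_coef[111], bmi_coef[3], waist_coef[3],
    bp_coef[2], glucose_coef[2])`` indexed by age and category codes.
    """
    age_coef = np.zeros(201)
    for lo, hi, label in AGE_BANDS:
        age_coef[lo : min(hi, 200) + 1] = params.coefficients["age_band"][label]
    bmi = np.array([0.0] + [params.coefficients["bmi_class"][c] for c in ["25to30", "gt30"]])
    waist = np.array([0.0] + [params.coefficients["waist_class"][c] for c in ["mid", "high"]])
    bp = np.array([0.0, params.coefficients["bp_medication"]["yes"]])
    glu = np.array([0.0, params.coefficients["high_glucose_history"]["yes"]])
    return params.intercept, age_coef, bmi, waist, bp, glu
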