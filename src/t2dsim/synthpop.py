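"""Baseline synthetic population construction.

Two stages mirror the intended workflow: a survey-like individual-level
sample is generated (or supplied by the user), then expanded to the
population marginals by weighted sampling with replacement of donors
within each age-group x sex x province stratum.  Education, income and
risk-factor states ride along with the sampled donor, so the sample's
correlation structure is embedded in the expanded population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .constants import (
    ADULT_AGE,
    ADULT_ONLY_VARIABLES,
    AGE_GROUPS,
    AGE_GROUP_LABELS,
    CATEGORY_ORDERS,
    INDIVIDUAL_COLUMNS,
    PROVINCE_REGION,
    age_group_of,
)

#: sampling order: each variable may only be conditioned on earlier ones
VARIABLE_ORDER = [
    "education",
    "income",
    "bmi_class",
    "waist_class",
    "bp_medication",
    "high_glucose_history",
    "t2d",
]


class InfeasibleCorrelationError(ValueError):
    """A configured odds multiplier cannot be realised for a margin cell."""


@dataclass
class MarginalSpec:
    """Population marginals: stratum counts plus per-age-group prevalences.

    Parameters
    ----------
    counts
        DataFrame with columns ``age_group, sex, province, count``.
    prevalence
        Mapping variable -> DataFrame with columns ``age_group, category, p``.
    year
        Baseline calendar year the marginals describe.
    """

    counts: pd.DataFrame
    prevalence: dict = field(default_factory=dict)
    year: int = 2018

    def __post_init__(self):
        if (self.counts["count"] <= 0).any():
            raise ValueError("stratum counts must be positive")
        for var, df in self.prevalence.items():
            sums = df.groupby("age_group")["p"].sum()
            if not np.allclose(sums.to_numpy(), 1.0, atol=1e-9):
                raise ValueError(f"prevalence vectors for {var!r} must sum to 1")

    def prevalence_vector(self, var: str, age_group: str) -> np.ndarray:
        df = self.prevalence[var]
        sub = df[df["age_group"] == age_group].set_index("category")["p"]
        return np.array([sub.get(c, 0.0) for c in CATEGORY_ORDERS[var]], dtype=float)

    # -- I/O: long-format CSV with a YAML comment header ------------------
    def to_csv(self, path) -> None:
        rows = [
            {
                "variable": "count",
                "age_group": r.age_group,
                "sex": r.sex,
                "province": r.province,
                "category": "",
                "value": r.count,
            }
            for r in self.counts.itertuples()
        ]
        for var, df in self.prevalence.items():
            for r in df.itertuples():
                rows.append(
                    {
                        "variable": var,
                        "age_group": r.age_group,
                        "sex": "all",
                        "province": "all",
                        "category": r.category,
                        "value": r.p,
                    }
                )
        header = "# " + yaml.safe_dump({"year": int(self.year)}).strip() + "\n"
        with open(path, "w") as fh:
            fh.write(header)
            pd.DataFrame(rows).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "MarginalSpec":
        with open(path) as fh:
            first = fh.readline()
            meta = {}
            if first.startswith("#"):
                meta = yaml.safe_load(first.lstrip("#"))
                df = pd.read_csv(fh)
            else:
                fh.seek(0)
                df = pd.read_csv(fh)
        counts = (
            df[df["variable"] == "count"]
            .rename(columns={"value": "count"})[["age_group", "sex", "province", "count"]]
            .reset_index(drop=True)
        )
        counts["count"] = counts["count"].astype(int)
        prevalence = {}
        for var, sub in df[df["variable"] != "count"].groupby("variable"):
            prevalence[var] = sub.rename(columns={"value": "p"})[
                ["age_group", "category", "p"]
            ].reset_index(drop=True)
        return cls(counts=counts, prevalence=prevalence, year=int(meta.get("year", 2018)))


def ipf_joint(p_row: np.ndarray, p_col: np.ndarray, odds: float, *, max_iter=500, tol=1e-12):
    """Joint distribution with the given margins and log-bilinear association.

    The seed matrix ``odds ** (s_i * t_j)`` (s, t: normalised ordinal scores)
    is proportionally fitted to the margins; iterative proportional fitting
    preserves the seed's cross-product ratios, so the extreme-cell odds
    ratio of the result equals ``odds`` while both margins are exact.
    """
    p_row = np.asarray(p_row, dtype=float)
    p_col = np.asarray(p_col, dtype=float)
    nr, nc = len(p_row), len(p_col)
    s = np.arange(nr) / max(nr - 1, 1)
    t = np.arange(nc) / max(nc - 1, 1)
    joint = np.power(odds, np.outer(s, t))
    joint *= np.outer(p_row, p_col)
    for _ in range(max_iter):
        row_sums = joint.sum(axis=1)
        joint *= np.where(row_sums > 0, p_row / np.where(row_sums > 0, row_sums, 1), 0)[:, None]
        col_sums = joint.sum(axis=0)
        joint *= np.where(col_sums > 0, p_col / np.where(col_sums > 0, col_sums, 1), 0)[None, :]
        if np.abs(joint.sum(axis=1) - p_row).max() < tol:
            break
    return joint


def _check_feasible(var_src, p_src, var_tgt, p_tgt, odds, age_group):
    if odds == 1.0:
        return
    for var, p in [(var_src, p_src), (var_tgt, p_tgt)]:
        near_one = np.isclose(p, 1.0)
        if near_one.any():
            cat = CATEGORY_ORDERS[var][int(np.argmax(near_one))]
            raise InfeasibleCorrelationError(
                f"odds multiplier {odds} for {var_src}->{var_tgt} cannot be realised: "
                f"cell ({var}={cat}, age_group={age_group}) has probability 1"
            )


def generate_survey_fixture(spec: MarginalSpec, correlation_config, n: int, seed) -> pd.DataFrame:
    """Generate a complete survey-like sample of ``n`` individuals.

    Strata (age group x sex x province) are drawn proportionally to the
    spec counts, exact ages uniformly within the age group, and the
    remaining categorical attributes sequentially in :data:`VARIABLE_ORDER`.
    Each ``correlation_config`` entry ``{source, target, odds}`` induces a
    monotone association by conditioning the target's draw on the realised
    source category through an IPF-fitted joint, which leaves the target's
    marginal distribution intact.

    Returns a DataFrame with the individual columns plus ``weight``.
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    rng = np.random.default_rng(seed)
    correlation_config = correlation_config or []
    for entry in correlation_config:
        si, ti = VARIABLE_ORDER.index(entry["source"]), VARIABLE_ORDER.index(entry["target"])
        if si >= ti:
            raise ValueError(
                f"correlation source {entry['source']!r} must precede target {entry['target']!r}"
            )

    counts = spec.counts
    probs = counts["count"].to_numpy(dtype=float)
    probs = probs / probs.sum()
    stratum_idx = rng.choice(len(counts), size=n, p=probs)
    age_group = counts["age_group"].to_numpy()[stratum_idx]
    sex = counts["sex"].to_numpy()[stratum_idx]
    province = counts["province"].to_numpy()[stratum_idx]
    region = np.array([PROVINCE_REGION[p] for p in province])

    bounds = dict(zip(AGE_GROUP_LABELS, AGE_GROUPS))
    age = np.empty(n, dtype=int)
    for lab, (lo, hi) in bounds.items():
        mask = age_group == lab
        age[mask] = rng.integers(lo, hi + 1, size=mask.sum())

    data = {
        "age": age,
        "sex": sex,
        "region": region,
        "province": province,
    }

    # pre-validate feasibility of every configured association per age group
    for entry in correlation_config:
        for lab in AGE_GROUP_LABELS:
            grp_min = bounds[lab][0]
            if grp_min < ADULT_AGE:
                continue  # minors are deterministic for adult-only variables
            _check_feasible(
                entry["source"],
                spec.prevalence_vector(entry["source"], lab),
                entry["target"],
                spec.prevalence_vector(entry["target"], lab),
                entry["odds"],
                lab,
            )

    drawn_codes: dict[str, np.ndarray] = {}
    for var in VARIABLE_ORDER:
        if var not in spec.prevalence:
            continue
        cats = CATEGORY_ORDERS[var]
        k = len(cats)
        codes = np.zeros(n, dtype=int)
        mods = [e for e in correlation_config if e["target"] == var]
        for lab in AGE_GROUP_LABELS:
            mask = age_group == lab
            if not mask.any():
                continue
            p_base = spec.prevalence_vector(var, lab)
            adult_group = bounds[lab][0] >= ADULT_AGE
            # conditional rows: start from the marginal, tilt by each source
            prob_rows = np.tile(p_base, (mask.sum(), 1))
            if adult_group:
                for entry in mods:
                    src = entry["source"]
                    if src not in drawn_codes:
                        continue
                    p_src = spec.prevalence_vector(src, lab)
                    joint = ipf_joint(p_src, p_base, entry["odds"])
                    with np.errstate(invalid="ignore", divide="ignore"):
                        cond = joint / joint.sum(axis=1, keepdims=True)
                    cond = np.nan_to_num(cond, nan=0.0)
                    src_codes = drawn_codes[src][mask]
                    # multiply in the likelihood ratio of this source's tilt
                    with np.errstate(invalid="ignore", divide="ignore"):
                        lr = np.where(p_base > 0, cond[src_codes] / p_base, 0.0)
                    prob_rows = prob_rows * lr
                row_sums = prob_rows.sum(axis=1, keepdims=True)
                prob_rows = np.where(row_sums > 0, prob_rows / row_sums, prob_rows)
            u = rng.random(mask.sum())
            codes[mask] = (prob_rows.cumsum(axis=1) < u[:, None]).sum(axis=1).clip(0, k - 1)
        if var in ADULT_ONLY_VARIABLES:
            codes[age < ADULT_AGE] = 0
        drawn_codes[var] = codes
        data[var] = np.array(cats, dtype=object)[codes]

    df = pd.DataFrame(data)
    df["t2d"] = df["t2d"] == "yes" if "t2d" in df.columns else False
    df["alive"] = True
    df["t2d_onset_year"] = np.where(df["t2d"], spec.year, np.nan)
    df["death_year"] = np.nan
    df["death_cause"] = pd.Series([pd.NA] * n, dtype=object)
    df["weight"] = 1.0
    df.insert(0, "id", np.arange(n))
    return df[INDIVIDUAL_COLUMNS + ["weight"]]


def expand_population(sample: pd.DataFrame, spec: MarginalSpec, seed) -> pd.DataFrame:
    """Expand a weighted survey sample to the spec's stratum counts.

    Donors are drawn with replacement, with probability proportional to
    their ``weight``, independently within each age-group x sex x province
    stratum until the target count is met exactly.  Ids are reassigned.
    """
    rng = np.random.default_rng(seed)
    sample = sample.copy()
    sample["_age_group"] = age_group_of(sample["age"].to_numpy())
    grouped = sample.groupby(["_age_group", "sex", "province"]).indices

    pieces = []
    for row in spec.counts.itertuples():
        key = (row.age_group, row.sex, row.province)
        idx = grouped.get(key)
        if idx is None or len(idx) == 0:
            raise ValueError(f"no donors in sample for stratum {key}")
        w = sample["weight"].to_numpy()[idx]
        pick = rng.choice(idx, size=int(row.count), replace=True, p=w / w.sum())
        pieces.append(sample.iloc[pick])
    pop = pd.concat(pieces, ignore_index=True).drop(columns=["_age_group", "weight"])
    pop["id"] = np.arange(len(pop))
    return pop[INDIVIDUAL_COLUMNS]


def population_summary(pop: pd.DataFrame, grouping, variables=None, weight_col=None) -> pd.DataFrame:
    """Weighted category fractions per stratum.

    Parameters
    ----------
    grouping
        Subset of ``{age_group, sex, region, province, education}``.
    variables
        Attribute columns to summarise; defaults to the categorical
        risk-factor and demographic variables present in ``pop``.

    Returns a tidy frame ``grouping + [variable, category, share]``; empty
    strata simply do not appear.  Shares per (stratum, variable) sum to 1.
    """
    allowed = {"age_group", "sex", "region", "province", "education"}
    grouping = list(grouping)
    unknown = set(grouping) - allowed
    if unknown:
        raise ValueError(f"unknown grouping variable(s): {sorted(unknown)}")

    pop = pop.copy()
    if "age_group" in grouping:
        pop["age_group"] = age_group_of(pop["age"].to_numpy())
    if variables is None:
        variables = [
            v
            for v in ["education", "income", "bmi_class", "waist_class",
                      "bp_medication", "high_glucose_history", "t2d"]
            if v in pop.columns and v not in grouping
        ]
    w = pop[weight_col].to_numpy(dtype=float) if weight_col else np.ones(len(pop))
    pop["_w"] = w

    out = []
    keys = grouping if grouping else [()]
    groups = pop.groupby(grouping) if grouping else [((), pop)]
    for key, sub in groups:
        if not isinstance(key, tuple):
            key = (key,)
        total = sub["_w"].sum()
        if total == 0:
            continue
        for var in variables:
            vals = sub[var]
            if vals.dtype == bool:
                vals = vals.map({True: "yes", False: "no"})
            shares = sub.assign(_v=vals).groupby("_v")["_w"].sum() / total
            for cat, share in shares.items():
                out.append(dict(zip(grouping, key)) | {"variable": var, "category": cat, "share": share})
    return pd.DataFrame(out)
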