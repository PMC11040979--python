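"""Category vocabularies and column schema shared across modules.

All categorical fields are stored as plain strings in DataFrames; modules
that need speed encode them to integer codes against the ordered lists
below.  Order matters for the ordinal variables (education, income,
bmi_class, waist_class): index 0 is always the lowest-risk / lowest state.
"""

from __future__ import annotations

SEXES = ["male", "female"]

REGIONS = ["Brussels", "Flanders", "Wallonia"]

#: 11 administrative units: Brussels-Capital plus 5 + 5 provinces.
PROVINCES = [
    "Brussels",
    "Antwerp",
    "East Flanders",
    "Flemish Brabant",
    "Limburg",
    "West Flanders",
    "Hainaut",
    "Liege",
    "Luxembourg",
    "Namur",
    "Walloon Brabant",
]

PROVINCE_REGION = {
    "Brussels": "Brussels",
    "Antwerp": "Flanders",
    "East Flanders": "Flanders",
    "Flemish Brabant": "Flanders",
    "Limburg": "Flanders",
    "West Flanders": "Flanders",
    "Hainaut": "Wallonia",
    "Liege": "Wallonia",
    "Luxembourg": "Wallonia",
    "Namur": "Wallonia",
    "Walloon Brabant": "Wallonia",
}

EDUCATION_LEVELS = ["low", "intermediate", "high"]
INCOME_QUINTILES = ["Q1", "Q2", "Q3", "Q4", "Q5"]

BMI_CLASSES = ["lt25", "25to30", "gt30"]
#: sex-specific cut meanings: M <94 / 94-102 / >=102 cm, F <80 / 80-88 / >=88 cm
WAIST_CLASSES = ["low", "mid", "high"]
BOOL_STATES = ["no", "yes"]

#: ordered state lists for every modifiable risk factor
RISK_FACTOR_STATES = {
    "bmi_class": BMI_CLASSES,
    "waist_class": WAIST_CLASSES,
    "bp_medication": BOOL_STATES,
    "high_glucose_history": BOOL_STATES,
}

#: variables carried on every individual, in canonical column order
INDIVIDUAL_COLUMNS = [
    "id",
    "age",
    "sex",
    "region",
    "province",
    "education",
    "income",
    "bmi_class",
    "waist_class",
    "bp_medication",
    "high_glucose_history",
    "t2d",
    "alive",
    "t2d_onset_year",
    "death_year",
    "death_cause",
]

#: default age-group partition of [0, 80]
AGE_GROUPS = [(0, 17), (18, 34), (35, 64), (65, 80)]
AGE_GROUP_LABELS = ["0-17", "18-34", "35-64", "65-80"]

ADULT_AGE = 18
MAX_AGE = 110

CATEGORY_ORDERS = {
    "sex": SEXES,
    "region": REGIONS,
    "province": PROVINCES,
    "education": EDUCATION_LEVELS,
    "income": INCOME_QUINTILES,
    "bmi_class": BMI_CLASSES,
    "waist_class": WAIST_CLASSES,
    "bp_medication": BOOL_STATES,
    "high_glucose_history": BOOL_STATES,
    "t2d": BOOL_STATES,
}

#: variables whose value is forced to the lowest-risk state below ADULT_AGE
ADULT_ONLY_VARIABLES = ["waist_class", "bp_medication", "high_glucose_history", "t2d"]


def age_group_label(age) -> str:
    """Map an exact age (scalar) to its age-group label."""
    for (lo, hi), lab in zip(AGE_GROUPS, AGE_GROUP_LABELS):
        if lo <= age <= hi:
            return lab
    return AGE_GROUP_LABELS[-1]


def age_group_of(ages):
    """Vectorised age -> age-group label (ages above the last group clamp)."""
    import numpy as np

    ages = np.asarray(ages)
    out = np.full(ages.shape, AGE_GROUP_LABELS[-1], dtype=object)
    for (lo, hi), lab in zip(AGE_GROUPS, AGE_GROUP_LABELS):
        out[(ages >= lo) & (ages <= hi)] = lab
    return out
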