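"""Shared microdata schema: column names, coded level sets, value ranges.

One row per survey respondent. All categorical variables are stored as
numeric codes (floats in memory so that NaN can mark a missing value);
``state`` is a free-text label.
"""

from __future__ import annotations

STATE = "state"
AGE = "age_category"
SEX = "sex"
RACE = "race_ethnicity"
EDUCATION = "education"
INCOME = "income_category"
N_ADULTS = "n_adults"
N_CHILDREN = "n_children"
BMI = "bmi"
PREGNANT = "pregnant"
WEIGHT = "survey_weight"

#: Canonical column order of the delimited-text microdata schema.
MICRODATA_COLUMNS = (
    STATE,
    AGE,
    SEX,
    RACE,
    EDUCATION,
    INCOME,
    N_ADULTS,
    N_CHILDREN,
    BMI,
    PREGNANT,
    WEIGHT,
)

#: Coded levels for each categorical variable.
AGE_LEVELS = (1, 2, 3, 4, 5)  # 18-24, 25-34, 35-44, 45-54, 55-64
SEX_LEVELS = (1, 2)  # 1 = male, 2 = female
RACE_LEVELS = (1, 2, 3, 4, 5, 6)
EDUCATION_LEVELS = (1, 2, 3, 4)
INCOME_LEVELS = (1, 2, 3, 4, 5, 6, 7, 8)

CATEGORICAL_LEVELS = {
    AGE: AGE_LEVELS,
    SEX: SEX_LEVELS,
    RACE: RACE_LEVELS,
    EDUCATION: EDUCATION_LEVELS,
    INCOME: INCOME_LEVELS,
}

#: Variables entering the statistical analysis (used by eligibility checks).
ANALYSIS_VARIABLES = (
    AGE,
    SEX,
    RACE,
    EDUCATION,
    INCOME,
    N_ADULTS,
    N_CHILDREN,
    BMI,
)

#: Income-group labels shared by both classification schemes.
GROUP_LOW = "low"
GROUP_MIDDLE = "middle"
GROUP_HIGH = "high"
GROUPS = (GROUP_LOW, GROUP_MIDDLE, GROUP_HIGH)

#: Scheme identifiers.
SCHEME_HWDI = "hwdi"
SCHEME_RHWDI = "rhwdi"
SCHEMES = (SCHEME_HWDI, SCHEME_RHWDI)

#: Derived columns appended by income classification.
ASSIGNED_INCOME = "assigned_income"
POVERTY_RATIO = "poverty_ratio"
HWDI_GROUP = "hwdi_group"
RHWDI_GROUP = "rhwdi_group"
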