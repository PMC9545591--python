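"""Column schema and category codings for matched case-control subject tables.

One row per participant.  Rows are grouped into matched sets (strata) of one
case plus one or more controls; matching attributes (country, sex, age, blood
draw date) are constant within a set and are absorbed by the conditional
likelihood, so they never enter a design matrix as covariates.
"""

from __future__ import annotations

#: Transsulfuration pathway metabolites, in reporting order.
METABOLITES: tuple[str, ...] = (
    "plp",
    "homocysteine",
    "serine",
    "cystathionine",
    "cysteine",
)

#: Additional circulating analytes used as adjustment covariates.
EXTRA_ANALYTES: tuple[str, ...] = ("folate", "sdma", "neopterin")

#: All analytes measured on each subject (concentrations, strictly positive).
ANALYTES: tuple[str, ...] = METABOLITES + EXTRA_ANALYTES

EDUCATION_LEVELS: tuple[str, ...] = (
    "primary_or_less",
    "secondary",
    "technical_professional",
    "university",
)
FASTING_LEVELS: tuple[str, ...] = ("not_fasting", "in_between", "fasting")
SMOKING_LEVELS: tuple[str, ...] = ("never", "former", "current")
SEX_LEVELS: tuple[str, ...] = ("male", "female")

CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "education": EDUCATION_LEVELS,
    "fasting": FASTING_LEVELS,
    "smoking": SMOKING_LEVELS,
    "sex": SEX_LEVELS,
}

#: Reference (first-listed) level used when dummy-coding each categorical.
REFERENCE_LEVELS: dict[str, str] = {
    "education": "primary_or_less",
    "fasting": "not_fasting",
    "smoking": "never",
    "sex": "male",
}

#: Set-constant matching attributes; requesting one as a model covariate is an
#: error (sex is allowed as an effect modifier through interaction terms only).
MATCHING_FACTORS: tuple[str, ...] = ("country", "sex", "age", "blood_draw_date")

#: Canonical column order of the subject CSV.
SUBJECT_COLUMNS: tuple[str, ...] = (
    "set_id",
    "subject_id",
    "is_case",
    *ANALYTES,
    "education",
    "fasting",
    "smoking",
    "bmi",
    "sex",
    "sbp",
    "dbp",
    "country",
    "age",
    "blood_draw_date",
)
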