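"""Baseline covariate definitions and reference-cell dummy coding.

The cohort carries ten baseline covariates measured at (or before) inclusion
at age 23: year of birth, parental education, parental income band, parental
disability history, mother's marital status, childhood chronic-disease
benefit, conscript IQ (stanine bands), conscript BMI band, military
eligibility and the continuous district unemployment rate; plus the binary
exposure (completion of upper secondary education) and the field of study
(general studies vs vocational tracks), which stratifies analyses and is not
itself a regression covariate.

Reference-cell coding with the designated reference levels gives 23 dummy /
continuous columns; adding the exposure indicator gives the 24-column design
used per transition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Categorical covariates: field -> ordered levels, reference level first.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "birth_year": ("1971", "1972", "1973", "1974", "1975", "1976"),
    "parental_education": ("upper_secondary", "lower_secondary", "university"),
    "parental_income_band": ("100_140", "lt60", "60_100", "gt140"),
    "parental_disability": ("no", "yes"),
    "mother_marital_status": ("married", "not_married", "separated", "other"),
    "childhood_chronic_disease": ("none", "basic", "attendance"),
    "iq_stanine_band": ("4_6", "1_3", "7_9"),
    "bmi_band": ("18.5_25", "lt18.5", "25_30", "30plus"),
    "military_eligibility": ("eligible", "issues"),
}

#: Continuous covariates passed through unchanged.
CONTINUOUS_COVARIATES: tuple[str, ...] = ("district_unemployment_rate",)

FIELD_LEVELS: tuple[str, ...] = ("general", "vocational")
EXPOSURE_LEVELS: tuple[str, ...] = ("non_completion", "completion")

#: Column order of the encoded covariate matrix (exposure excluded): 23 cols.
ENCODED_COLUMNS: tuple[str, ...] = tuple(
    f"{field}_{level}"
    for field, levels in CATEGORICAL_LEVELS.items()
    for level in levels[1:]
) + CONTINUOUS_COVARIATES

#: Encoded covariates plus exposure: the 24-column per-transition design.
DESIGN_COLUMNS: tuple[str, ...] = ("exposure",) + ENCODED_COLUMNS


def encode_covariates(cohort: pd.DataFrame, include_exposure: bool = True) -> pd.DataFrame:
    """Reference-cell dummy coding of the baseline covariates.

    Parameters
    ----------
    cohort
        One row per person, with the categorical covariate columns holding
        level labels, the continuous columns numeric, and (if
        ``include_exposure``) an ``exposure`` column with values in
        ``{'non_completion', 'completion'}`` or ``{0, 1}``.
    include_exposure
        Prepend the 0/1 exposure indicator (1 = completion).

    Returns
    -------
    DataFrame indexed like ``cohort`` with columns ``DESIGN_COLUMNS`` (or
    ``ENCODED_COLUMNS``), dtype float.
    """
    out: dict[str, np.ndarray] = {}
    if include_exposure:
        out["exposure"] = _encode_exposure(cohort["exposure"])
    for field, levels in CATEGORICAL_LEVELS.items():
        values = cohort[field].astype(str)
        bad = set(values.unique()) - set(levels)
        if bad:
            raise ValueError(f"unseen level(s) {sorted(bad)} in covariate '{field}'")
        for level in levels[1:]:
            out[f"{field}_{level}"] = (values == level).to_numpy(float)
    for col in CONTINUOUS_COVARIATES:
        out[col] = pd.to_numeric(cohort[col]).to_numpy(float)
    return pd.DataFrame(out, index=cohort.index)


def _encode_exposure(series: pd.Series) -> np.ndarray:
    if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
        bad = set(series.astype(str).unique()) - set(EXPOSURE_LEVELS)
        if bad:
            raise ValueError(f"unseen level(s) {sorted(bad)} in covariate 'exposure'")
        return (series.astype(str) == "completion").to_numpy(float)
    return series.to_numpy(float)


def encode_pattern(pattern: dict, include_exposure: bool = True) -> pd.Series:
    """Encode a single covariate pattern given as ``{covariate: level}``.

    Unspecified categoricals default to their reference level; unspecified
    continuous covariates default to 0 (i.e. the centering value when used
    with a centered fit).
    """
    row: dict[str, object] = {}
    for field, levels in CATEGORICAL_LEVELS.items():
        row[field] = pattern.get(field, levels[0])
    for col in CONTINUOUS_COVARIATES:
        row[col] = pattern.get(col, 0.0)
    if include_exposure:
        row["exposure"] = pattern.get("exposure", 0)
    frame = pd.DataFrame([row])
    return encode_covariates(frame, include_exposure=include_exposure).iloc[0]


#: Covariate pattern with adverse values on the strongest confounders.
UNFAVOURABLE_PATTERN: dict[str, str] = {
    "iq_stanine_band": "1_3",
    "parental_education": "lower_secondary",
    "parental_income_band": "lt60",
}

#: Mirror-image advantaged pattern.
FAVOURABLE_PATTERN: dict[str, str] = {
    "iq_stanine_band": "7_9",
    "parental_education": "university",
    "parental_income_band": "gt140",
}
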