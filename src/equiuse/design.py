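"""Design-matrix construction for the pipeline's regression models.

All designs use treatment (dummy) coding with the reference categories fixed
by the survey schema: male, age 15-35, occupation 'working', education
'insufficient', self-perceived health 'very_good', income quartile 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import schema
from .exceptions import ScoringError

AGE_DUMMIES = [f"age_{lvl}" for lvl in schema.AGE_LEVELS[1:]]
OCC_DUMMIES = [f"occ_{lvl}" for lvl in schema.OCCUPATION_LEVELS[1:]]
EDU_DUMMIES = [f"edu_{lvl}" for lvl in schema.EDUCATION_LEVELS[1:]]
SPH_DUMMIES = [f"sph_{lvl}" for lvl in schema.SPH_LEVELS[1:]]
QUARTILE_DUMMIES = ["q2", "q3", "q4"]

#: covariates of the per-wave ordered probit income model
INCOME_MODEL_TERMS = ["female"] + AGE_DUMMIES + OCC_DUMMIES + EDU_DUMMIES + ["household_size"]

#: covariates of the ownership and delayed-contact logistic models
HEALTH_MODEL_TERMS = ["female"] + AGE_DUMMIES + SPH_DUMMIES + ["chronic_count"]

#: nested covariate sets of the hurdle-model sequence (income only; + demographics;
#: + double cover and mental health)
MODEL_TERMS = {
    1: QUARTILE_DUMMIES,
    2: QUARTILE_DUMMIES + ["female"] + AGE_DUMMIES,
    3: QUARTILE_DUMMIES + ["female"] + AGE_DUMMIES + ["insurance", "ghq12"],
}


def _dummies(values: pd.Series, levels, prefix: str) -> pd.DataFrame:
    bad = ~values.isin(levels)
    if bad.any():
        raise ScoringError(
            f"column '{values.name}': unseen level {values[bad].iloc[0]!r}"
        )
    out = {}
    for lvl in levels[1:]:  # first level is the reference
        out[f"{prefix}_{lvl}"] = (values == lvl).astype(float)
    return pd.DataFrame(out, index=values.index)


def build_design(df: pd.DataFrame, terms, add_intercept: bool = True) -> pd.DataFrame:
    """Expand the requested terms into a numeric design matrix.

    ``terms`` is a list of column names from the vocabulary above; dummy names
    pull from the corresponding categorical schema column, plain names are
    taken as numeric columns of ``df``.
    """
    pieces = {}
    if add_intercept:
        pieces["intercept"] = pd.Series(1.0, index=df.index)
    cache = {}

    def group(prefix, col, levels):
        if prefix not in cache:
            cache[prefix] = _dummies(df[col], levels, prefix)
        return cache[prefix]

    for term in terms:
        if term == "female":
            pieces[term] = group("sex", "sex", schema.SEX_LEVELS)["sex_female"].rename(term)
        elif term.startswith("age_"):
            pieces[term] = group("age", "age_band", schema.AGE_LEVELS)[term]
        elif term.startswith("occ_"):
            pieces[term] = group("occ", "occupation", schema.OCCUPATION_LEVELS)[term]
        elif term.startswith("edu_"):
            pieces[term] = group("edu", "education", schema.EDUCATION_LEVELS)[term]
        elif term.startswith("sph_"):
            pieces[term] = group("sph", "sph", schema.SPH_LEVELS)[term]
        elif term in ("q2", "q3", "q4"):
            q = df["income_quartile"]
            pieces[term] = (q == int(term[1])).astype(float)
        else:
            if term not in df.columns:
                raise ScoringError(f"missing covariate column '{term}'")
            vals = pd.to_numeric(df[term])
            if vals.isna().any():
                raise ScoringError(f"missing values in covariate column '{term}'")
            pieces[term] = vals.astype(float)
    return pd.DataFrame(pieces, index=df.index)


def check_levels_observed(X: pd.DataFrame, add_intercept: bool = True) -> None:
    """Raise if any non-intercept design column is constant (empty category level
    or no variation), which would make the fit inestimable."""
    from .exceptions import FitError

    for col in X.columns:
        if col == "intercept":
            continue
        v = X[col].to_numpy()
        if np.all(v == v[0]):
            raise FitError(f"design column '{col}' has no variation "
                           f"(empty or exhaustive category level)")
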