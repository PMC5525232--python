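"""Survey microdata schema: column definitions, validation, delimited-text I/O.

One row per respondent.  Two income dialects are supported: wave 2006 uses
8 annual income bands, wave 2011 uses 10 monthly bands.  Recall windows are
4 weeks for primary/specialist care and 12 months for emergencies and
hospitalizations.  Missingness is encoded by an empty field; the ownership
flag of the last contact (and the delayed-contact indicator, where defined)
must be missing exactly when the corresponding raw count is zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import SchemaError

WAVES = (2006, 2011)

SEX_LEVELS = ("male", "female")  # male = reference
AGE_LEVELS = ("15-35", "36-45", "46-55", "56-65", "66-75", "75+")  # 15-35 = reference
OCCUPATION_LEVELS = (
    "working",  # reference
    "unemployed_lt1y",
    "unemployed_gt1y",
    "housework",
    "student",
    "retiree",
    "other",
)
EDUCATION_LEVELS = ("insufficient", "primary", "secondary", "university")  # insufficient = ref
SPH_LEVELS = ("very_good", "good", "fair", "bad", "very_bad")  # very_good = reference

SERVICES = ("primary", "specialist", "emergency", "hospital")
FOUR_WEEK_SERVICES = ("primary", "specialist")  # 4-week recall; others are 12-month

N_MEDICINE_ITEMS = 22
CONTRACEPTIVE_ITEM = 22  # 1-based index of the contraceptive item, excluded from the count
MEDICINE_COLS = tuple(f"med_{i:02d}" for i in range(1, N_MEDICINE_ITEMS + 1))

#: number of income bands per dialect
INCOME_BANDS = {2006: 8, 2011: 10}

CATEGORICAL_LEVELS = {
    "sex": SEX_LEVELS,
    "age_band": AGE_LEVELS,
    "occupation": OCCUPATION_LEVELS,
    "education": EDUCATION_LEVELS,
    "sph": SPH_LEVELS,
}

COUNT_COLS = tuple(f"{s}_count" for s in SERVICES)
PRIVATE_COLS = tuple(f"{s}_private" for s in SERVICES)
DELAYED_COLS = tuple(f"{s}_delayed" for s in FOUR_WEEK_SERVICES)

COLUMNS = (
    ("id", "wave", "sex", "age_band", "income_band", "occupation", "education",
     "household_size", "insurance", "ghq12", "sph", "chronic_count")
    + sum(
        (
            (f"{s}_count", f"{s}_private") + ((f"{s}_delayed",) if s in FOUR_WEEK_SERVICES else ())
            for s in SERVICES
        ),
        (),
    )
    + MEDICINE_COLS
    + ("group_id",)
)

# nullable integer columns: ownership/delay flags are missing by design when
# the count is zero; ghq12/chronic_count/insurance admit item nonresponse
_NULLABLE_INT = PRIVATE_COLS + DELAYED_COLS + ("ghq12", "chronic_count", "insurance")


def _fail(row, col, msg):
    raise SchemaError(f"row {row}, column '{col}': {msg}")


def validate_survey(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a survey table against the schema.

    Returns the frame with normalized dtypes.  Raises :class:`SchemaError`
    naming the offending row and column on the first violation found.
    """
    unknown = set(df.columns) - set(COLUMNS)
    if unknown:
        raise SchemaError(f"unknown column(s): {sorted(unknown)}")
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing column(s): {sorted(missing)}")

    df = df.copy()
    for col in _NULLABLE_INT:
        df[col] = df[col].astype("Int64")

    for col, levels in CATEGORICAL_LEVELS.items():
        bad = ~df[col].isin(levels)
        if col == "sph":  # item nonresponse allowed
            bad &= df[col].notna()
        if bad.any():
            row = int(df.index[bad][0])
            _fail(row, col, f"value {df[col].iloc[np.flatnonzero(bad.to_numpy())[0]]!r} "
                            f"not in {levels}")

    bad = ~df["wave"].isin(WAVES)
    if bad.any():
        _fail(int(df.index[bad][0]), "wave", f"must be one of {WAVES}")

    for wave, k in INCOME_BANDS.items():
        sub = df.loc[df["wave"] == wave, "income_band"]
        bad = ~sub.between(1, k)
        if bad.any():
            _fail(int(sub.index[bad][0]), "income_band", f"wave {wave} allows bands 1..{k}")

    bad = ~df["ghq12"].between(0, 12) & df["ghq12"].notna()
    if bad.any():
        _fail(int(df.index[bad][0]), "ghq12", "must be in [0, 12]")

    if (df["household_size"] < 1).any():
        _fail(int(df.index[df["household_size"] < 1][0]), "household_size", "must be >= 1")
    bad = (df["chronic_count"] < 0) & df["chronic_count"].notna()
    if bad.any():
        _fail(int(df.index[bad][0]), "chronic_count", "must be >= 0")

    bad = ~df["insurance"].isin((0, 1)) & df["insurance"].notna()
    if bad.any():
        _fail(int(df.index[bad][0]), "insurance", "must be binary 0/1")
    for col in MEDICINE_COLS:
        bad = ~df[col].isin((0, 1))
        if bad.any():
            _fail(int(df.index[bad][0]), col, "must be binary 0/1")

    for s in SERVICES:
        cnt, priv = df[f"{s}_count"], df[f"{s}_private"]
        if (cnt < 0).any():
            _fail(int(df.index[cnt < 0][0]), f"{s}_count", "must be >= 0")
        bad = (cnt == 0) & priv.notna()
        if bad.any():
            _fail(int(df.index[bad][0]), f"{s}_private",
                  "ownership flag set but count is 0")
        bad = (cnt > 0) & priv.isna()
        if bad.any():
            _fail(int(df.index[bad][0]), f"{s}_private",
                  "ownership flag missing for a respondent with contacts")
        set_priv = priv.dropna()
        if not set_priv.isin((0, 1)).all():
            bad_idx = set_priv.index[~set_priv.isin((0, 1))][0]
            _fail(int(bad_idx), f"{s}_private", "must be binary 0/1 when set")

    for s in FOUR_WEEK_SERVICES:
        cnt, dly = df[f"{s}_count"], df[f"{s}_delayed"]
        bad = (cnt == 0) & dly.notna()
        if bad.any():
            _fail(int(df.index[bad][0]), f"{s}_delayed",
                  "delay indicator set but count is 0")
    return df


def write_survey(df: pd.DataFrame, path) -> None:
    """Write survey records as UTF-8 CSV with header; missing values as empty fields."""
    validate_survey(df).to_csv(path, index=False)


def read_survey(path) -> pd.DataFrame:
    """Read and validate a survey CSV written by :func:`write_survey`."""
    df = pd.read_csv(
        path,
        dtype={c: "Int64" for c in _NULLABLE_INT},
        keep_default_na=True,
    )
    return validate_survey(df)
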