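"""Annual count construction from recall-window responses.

Primary and specialist care are asked with a 4-week recall window, so the
reported counts of respondents with at least one contact are multiplied by
12.  Zero reporters may simply have waited longer than 4 weeks between
perceiving a problem and the consultation: a logistic model of that delay
indicator, fitted on users, predicts for each zero reporter the probability
of a contact anyway, and a single annual contact is imputed when that
probability exceeds 0.5 (strictly).  Hospitalizations and emergencies are
already reported per year and pass through unchanged.  The medicine count is
the number of the 22 listed medicine items used, excluding contraceptives
(range 0-21).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import schema
from .design import HEALTH_MODEL_TERMS, build_design
from .exceptions import DataError
from .logit import LogitModel

__all__ = ["annualize", "fit_delay_model", "impute_zero_reporters",
           "count_medicines", "CountAnnualizer"]

ANNUALIZATION_FACTOR = 12


def annualize(records: pd.DataFrame, service: str,
              column: str | None = None) -> pd.Series:
    """Extrapolate a 4-week count column to a year (x12) for respondents with
    at least one contact; zero reporters stay 0 here (they are handled by
    :func:`impute_zero_reporters`).  12-month services pass through unchanged.
    """
    if service not in schema.SERVICES:
        raise DataError(f"unknown service '{service}'")
    column = column or f"{service}_count"
    counts = pd.to_numeric(records[column]).to_numpy()
    if np.any(counts < 0):
        raise DataError(f"negative count in column '{column}'")
    if service not in schema.FOUR_WEEK_SERVICES:
        annual = counts
    else:
        annual = np.where(counts >= 1, ANNUALIZATION_FACTOR * counts, 0)
    return pd.Series(annual.astype(np.int64), index=records.index)


def fit_delay_model(users: pd.DataFrame, service: str) -> LogitModel:
    """Fit the delayed-contact logistic model on users (count >= 1) of a
    4-week-recall service within one wave."""
    if service not in schema.FOUR_WEEK_SERVICES:
        raise DataError(f"delay model only applies to {schema.FOUR_WEEK_SERVICES}")
    waves = users["wave"].unique()
    if len(waves) != 1:
        raise DataError("fit_delay_model expects records from one wave")
    if (users[f"{service}_count"] < 1).any():
        raise DataError("delay model must be fitted on users only")
    y = users[f"{service}_delayed"]
    if y.isna().any():
        raise DataError(f"{service}: user without delay indicator")
    X = build_design(users, HEALTH_MODEL_TERMS)
    fit = LogitModel().fit(X, y.astype(float).to_numpy())
    fit.service_ = service
    fit.wave_ = int(waves[0])
    return fit


def impute_zero_reporters(fit: LogitModel, nonusers: pd.DataFrame) -> pd.Series:
    """Predict, for zero reporters, whether a contact happened anyway.

    Returns the imputed *annual* count: 1 if the predicted delay probability
    is strictly greater than 0.5, else 0.  The imputed contact is a single
    annual contact, not an extrapolated one.
    """
    X = build_design(nonusers, HEALTH_MODEL_TERMS)
    p_hat = fit.predict_proba(X)
    return pd.Series((p_hat > 0.5).astype(np.int64), index=nonusers.index)


def count_medicines(medicine_items,
                    contraceptive_item: int = schema.CONTRACEPTIVE_ITEM) -> pd.Series:
    """Number of distinct medicines used: sum of the 22 binary items minus the
    contraceptive item (range 0-21)."""
    if isinstance(medicine_items, pd.DataFrame):
        cols = [c for c in schema.MEDICINE_COLS if c in medicine_items.columns]
        if len(cols) != schema.N_MEDICINE_ITEMS:
            raise DataError(f"expected {schema.N_MEDICINE_ITEMS} medicine columns")
        arr = medicine_items[cols].to_numpy()
        index = medicine_items.index
    else:
        arr = np.atleast_2d(np.asarray(medicine_items))
        index = None
    if arr.shape[1] != schema.N_MEDICINE_ITEMS:
        raise DataError(f"expected {schema.N_MEDICINE_ITEMS} medicine items")
    if not np.isin(arr, (0, 1)).all():
        raise DataError("medicine items must be binary 0/1")
    keep = np.ones(arr.shape[1], dtype=bool)
    keep[contraceptive_item - 1] = False
    return pd.Series(arr[:, keep].sum(axis=1).astype(np.int64), index=index)


class CountAnnualizer(BaseEstimator, TransformerMixin):
    """Transformer producing annual total/public/private counts per service.

    Expects the raw split columns added by
    :class:`~equiuse.ownership.OwnershipImputer` and needs that fitted imputer
    to assign imputed single contacts to an ownership (same rounding rule as
    multi-visit splitting).  Adds ``{service}_year_{total,public,private}``
    and ``medicines`` columns.
    """

    def __init__(self, ownership=None):
        self.ownership = ownership

    def fit(self, X: pd.DataFrame, y=None):
        self.delay_fits_ = {}
        for wave in sorted(X["wave"].unique()):
            sub = X[X["wave"] == wave]
            for service in schema.FOUR_WEEK_SERVICES:
                users = sub[sub[f"{service}_count"] >= 1]
                self.delay_fits_[(service, int(wave))] = fit_delay_model(
                    users, service)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for service in schema.SERVICES:
            for part in ("total", "public", "private_n"):
                if f"{service}_{part}" not in out.columns:
                    raise DataError(
                        f"missing '{service}_{part}': run OwnershipImputer first")
        for service in schema.SERVICES:
            four_week = service in schema.FOUR_WEEK_SERVICES
            for part, src in (("total", "total"), ("public", "public"),
                              ("private", "private_n")):
                raw = out[f"{service}_{src}"].to_numpy(dtype=np.int64)
                out[f"{service}_year_{part}"] = (
                    np.where(out[f"{service}_count"].to_numpy() >= 1,
                             ANNUALIZATION_FACTOR * raw, 0)
                    if four_week else raw
                )
            if not four_week:
                continue
            for wave in sorted(out["wave"].unique()):
                zero = (out["wave"] == wave) & (out[f"{service}_count"] == 0)
                if not zero.any():
                    continue
                nonusers = out.loc[zero]
                imputed = impute_zero_reporters(
                    self.delay_fits_[(service, int(wave))], nonusers)
                hit = imputed == 1
                if not hit.any():
                    continue
                idx = nonusers.index[hit]
                own_fit = (self.ownership.fits_[(service, int(wave))]
                           if self.ownership is not None else None)
                if own_fit is not None:
                    p_priv = own_fit.predict_proba(
                        build_design(out.loc[idx], HEALTH_MODEL_TERMS))
                    priv = np.rint(p_priv).astype(np.int64)
                else:
                    priv = np.zeros(len(idx), dtype=np.int64)
                out.loc[idx, f"{service}_year_total"] = 1
                out.loc[idx, f"{service}_year_private"] = priv
                out.loc[idx, f"{service}_year_public"] = 1 - priv
        out["medicines"] = count_medicines(out[list(schema.MEDICINE_COLS)])
        return out
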