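"""Public/private split of service contacts.

The surveys record only the ownership of the *last* contact.  Respondents
with exactly one contact therefore reveal that contact's ownership directly;
a logistic regression fitted on those single-visit users (covariates: sex,
age band, self-perceived health, chronic-condition count) predicts the
probability that a contact was private, and multi-visit users' totals are
split as private = round(total x p-hat) with banker's rounding.  Public
contacts are the remainder, so public + private = total exactly.  Fits are
per service and per wave.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import schema
from .design import HEALTH_MODEL_TERMS, build_design
from .exceptions import DataError
from .logit import LogitModel

__all__ = ["fit_ownership_model", "split_counts", "OwnershipImputer"]


def fit_ownership_model(records: pd.DataFrame, service: str) -> LogitModel:
    """Fit the private-ownership logistic model on single-visit users of one
    service within one wave."""
    if service not in schema.SERVICES:
        raise DataError(f"unknown service '{service}'")
    waves = records["wave"].unique()
    if len(waves) != 1:
        raise DataError("fit_ownership_model expects records from one wave")
    single = records[records[f"{service}_count"] == 1]
    if single.empty:
        raise DataError(
            f"no single-visit users of '{service}' in wave {int(waves[0])}")
    X = build_design(single, HEALTH_MODEL_TERMS)
    y = single[f"{service}_private"].astype(float).to_numpy()
    fit = LogitModel().fit(X, y)
    fit.service_ = service
    fit.wave_ = int(waves[0])
    return fit


def split_counts(fit: LogitModel, records: pd.DataFrame,
                 service: str | None = None) -> pd.DataFrame:
    """Split each respondent's total contacts into private and public counts.

    Single-visit users keep their observed ownership; multi-visit users get
    private = round-half-to-even(total x p-hat); zero-visit users get zeros.
    Returns a frame with columns ``total``, ``public``, ``private``.
    """
    service = service or fit.service_
    total = records[f"{service}_count"].to_numpy(dtype=np.int64)
    private = np.zeros_like(total)

    single = total == 1
    if single.any():
        flags = records.loc[single, f"{service}_private"]
        if flags.isna().any():
            raise DataError(f"{service}: single-visit user without ownership flag")
        private[single] = flags.astype(int).to_numpy()

    multi = total > 1
    if multi.any():
        X = build_design(records.loc[multi], HEALTH_MODEL_TERMS)
        p_hat = fit.predict_proba(X)
        private[multi] = np.rint(total[multi] * p_hat).astype(np.int64)

    out = pd.DataFrame(
        {"total": total, "private": private, "public": total - private},
        index=records.index,
    )
    assert (out["public"] + out["private"] == out["total"]).all()
    return out


class OwnershipImputer(BaseEstimator, TransformerMixin):
    """Transformer fitting one ownership model per service x wave and adding
    ``{service}_total`` / ``{service}_public`` / ``{service}_private_n``
    raw-count columns (still on the recall-window scale)."""

    def __init__(self, services=schema.SERVICES):
        self.services = services

    def fit(self, X: pd.DataFrame, y=None):
        self.fits_ = {}
        for wave in sorted(X["wave"].unique()):
            sub = X[X["wave"] == wave]
            for service in self.services:
                self.fits_[(service, int(wave))] = fit_ownership_model(sub, service)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for service in self.services:
            for col in ("total", "public", "private_n"):
                out[f"{service}_{col}"] = 0
            for wave in sorted(X["wave"].unique()):
                mask = out["wave"] == wave
                split = split_counts(self.fits_[(service, int(wave))],
                                     out.loc[mask], service)
                out.loc[mask, f"{service}_total"] = split["total"].to_numpy()
                out.loc[mask, f"{service}_public"] = split["public"].to_numpy()
                out.loc[mask, f"{service}_private_n"] = split["private"].to_numpy()
        return out
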