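"""Thin maximum-likelihood logistic regression wrapper used by the ownership
and delayed-contact models (statsmodels behind an estimator surface)."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from .exceptions import DataError, FitError


class LogitModel(BaseEstimator):
    """Unpenalized logistic regression with coefficient standard errors.

    Raises :class:`FitError` on separation (a single-class response,
    non-convergence, or runaway coefficients) and :class:`DataError` on an
    empty sample.  Quasi-separation confined to a sparse dummy cell leaves a
    boundary estimate for that one coefficient; this is tolerated — the
    implied prediction (p-hat near 0 or 1 in that cell) is the cell's
    empirical rate, which is exactly what downstream imputation needs.
    """

    def __init__(self, *, max_iter=500, coef_bound=1e3):
        self.max_iter = max_iter
        self.coef_bound = coef_bound

    def fit(self, X, y):
        import statsmodels.api as sm

        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            names = [f"x{j}" for j in range(Xa.shape[1])]
        y = np.asarray(y, dtype=float)
        if y.size == 0:
            raise DataError("empty estimation sample")
        classes = np.unique(y)
        if not np.isin(classes, (0.0, 1.0)).all():
            raise DataError("response must be binary 0/1")
        if classes.size < 2:
            raise FitError(
                f"complete separation: all responses equal {int(classes[0])}")

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                # lbfgs: flat directions from sparse cells stall smoothly
                # instead of blowing up the Newton step
                res = sm.Logit(y, Xa).fit(method="lbfgs", disp=0,
                                          maxiter=self.max_iter)
            except Exception as exc:  # PerfectSeparationError and friends
                raise FitError(f"logistic fit failed: {exc}") from exc
        params = np.asarray(res.params)
        if (not res.mle_retvals.get("converged", False)
                or not np.all(np.isfinite(params))
                or np.max(np.abs(params)) > self.coef_bound):
            raise FitError("logistic fit did not converge (possible separation)")

        self.coef_ = pd.Series(params, index=names)
        # observed-information covariance (lbfgs does not retain one)
        H = res.model.hessian(params)
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(-H)
        self.se_ = pd.Series(np.sqrt(np.clip(np.diag(cov), 0, np.inf)),
                             index=names)
        self.cov_ = pd.DataFrame(cov, index=names, columns=names)
        self.loglik_ = float(res.llf)
        self.nobs_ = int(y.size)
        return self

    def predict_proba(self, X):
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        return expit(np.asarray(X, dtype=float) @ self.coef_.to_numpy())

    def predict(self, X, threshold=0.5):
        return (self.predict_proba(X) > threshold).astype(int)
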