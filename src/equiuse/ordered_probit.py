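"""Ordered probit regression for interval-censored income bands.

The latent income index is y* = X'gamma + eps with standard-normal eps;
band k is observed when c_{k-1} < y* <= c_k for strictly increasing cut
points.  The log-likelihood is sum_i log[Phi(c_k - X'gamma) -
Phi(c_{k-1} - X'gamma)].  Estimation is delegated to statsmodels'
``OrderedModel`` (probit link), which enforces threshold monotonicity by
reparameterization; this module adds schema-aware validation and a latent
index scorer.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import DataError, FitError


class OrderedProbit(BaseEstimator):
    """Ordered probit with K observed bands coded 1..K.

    Attributes after fit: ``coef_`` / ``coef_se_`` (slopes, pandas Series),
    ``thresholds_`` (K-1 increasing cut points), ``loglik_``, ``converged_``.
    """

    def __init__(self, *, n_bands=None, max_iter=200):
        self.n_bands = n_bands
        self.max_iter = max_iter

    def fit(self, X, y):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            names = [f"x{j}" for j in range(Xa.shape[1])]
        y = np.asarray(y, dtype=int)
        k = self.n_bands if self.n_bands is not None else int(y.max())
        if k < 2:
            raise DataError("need at least two income bands")
        counts = np.bincount(y, minlength=k + 1)[1:k + 1]
        empty = np.flatnonzero(counts == 0)
        if empty.size:
            raise FitError(f"income band {empty[0] + 1} has zero observations")

        # OrderedModel rejects a constant column: the intercept is absorbed
        # into the thresholds.
        if np.any(np.ptp(Xa, axis=0) == 0):
            j = int(np.flatnonzero(np.ptp(Xa, axis=0) == 0)[0])
            raise FitError(f"design column '{names[j]}' is constant; drop it "
                           "(thresholds absorb the intercept)")

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = OrderedModel(y, Xa, distr="probit")
            res = model.fit(method="lbfgs", maxiter=self.max_iter, disp=0)
        params = np.asarray(res.params)
        if not np.all(np.isfinite(params)):
            raise FitError("ordered probit estimates are not finite")
        p = Xa.shape[1]
        self.coef_ = pd.Series(params[:p], index=names)
        self.coef_se_ = pd.Series(np.asarray(res.bse)[:p], index=names)
        self.thresholds_ = np.asarray(
            model.transform_threshold_params(params)[1:-1])
        self.loglik_ = float(res.llf)
        self.converged_ = bool(res.mle_retvals.get("converged", True))
        self.n_bands_ = k
        self._names = names
        return self

    def decision_function(self, X):
        """Fitted latent income index X'gamma-hat."""
        if isinstance(X, pd.DataFrame):
            X = X[self._names].to_numpy(dtype=float)
        return np.asarray(X, dtype=float) @ self.coef_.to_numpy()

    def predict_proba(self, X):
        """Band probabilities Phi(c_k - eta) - Phi(c_{k-1} - eta)."""
        from scipy.special import ndtr

        eta = self.decision_function(X)
        cuts = np.r_[-np.inf, self.thresholds_, np.inf]
        cdf = ndtr(cuts[None, :] - eta[:, None])
        return np.diff(cdf, axis=1)

    def latent_conditional_mean(self, X, y):
        """E[y* | X, observed band]: the truncated-normal mean of the latent
        index within the observed band's interval.

        With y* = eta + eps, eps ~ N(0,1) truncated to (c_{k-1} - eta,
        c_k - eta), this is eta + (phi(a) - phi(b)) / (Phi(b) - Phi(a)).
        Strictly increasing in the observed band at fixed covariates and in
        eta at a fixed band.
        """
        from scipy.special import ndtr
        from scipy.stats import norm

        eta = self.decision_function(X)
        y = np.asarray(y, dtype=int)
        if np.any(y < 1) or np.any(y > self.n_bands_):
            raise DataError(f"observed band outside 1..{self.n_bands_}")
        cuts = np.r_[-np.inf, self.thresholds_, np.inf]
        a = cuts[y - 1] - eta
        b = cuts[y] - eta
        denom = np.clip(ndtr(b) - ndtr(a), 1e-300, None)
        return eta + (norm.pdf(a) - norm.pdf(b)) / denom
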