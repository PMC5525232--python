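"""Two-part hurdle count model: logistic hurdle × zero-truncated negative binomial.

The first part models the probability of any use in a year with a logistic
regression whose dispersion is fixed at one (a Bernoulli response identifies
only its mean).  The second part models the number of contacts among users
with a zero-truncated negative binomial whose dispersion follows the NB1
convention, psi = mu / phi, so that the untruncated variance is mu * (1 + phi).
The two parts enter the likelihood multiplicatively and are estimated jointly.

Unobserved heterogeneity is captured by a Gaussian random intercept shared by
both parts within a declared grouping (e.g. household), integrated out by
Gauss-Hermite quadrature; its standard deviation sigma_u carries an
exponential-tail penalty emulating a penalised-complexity prior, calibrated
through P(sigma_u > u) = alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.special import expit, gammaln, digamma, logsumexp
from sklearn.base import BaseEstimator

from .exceptions import DataError, ScoringError

__all__ = [
    "ztnb_logpmf",
    "ztnb_mean",
    "ztnb_rvs",
    "HurdleCountModel",
    "HurdleSpec",
    "fit_hurdle",
    "hurdle_loglik",
    "rate_ratio",
]


# ---------------------------------------------------------------------------
# zero-truncated negative binomial primitives
# ---------------------------------------------------------------------------

def _log_expm1(a):
    """log(exp(a) - 1), stable for both small and large a."""
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    small = a < 20.0
    out[small] = np.log(np.expm1(a[small]))
    out[~small] = a[~small] + np.log1p(-np.exp(-a[~small]))
    return out


def _lgamma_ratio(y, psi):
    """log Gamma(y + psi) - log Gamma(psi) for integer y >= 0.

    For very large psi the difference of two lgamma calls loses all precision,
    so the product form sum_{j<y} log(psi + j) is used there instead.
    """
    y = np.asarray(y)
    psi = np.asarray(psi, dtype=float)
    y_b, psi_b = np.broadcast_arrays(y, psi)
    out = np.empty(y_b.shape, dtype=float)
    big = psi_b > 1e6
    if np.any(~big):
        out[~big] = gammaln(y_b[~big] + psi_b[~big]) - gammaln(psi_b[~big])
    if np.any(big):
        yy = y_b[big].astype(int)
        pp = psi_b[big]
        acc = np.zeros(pp.shape)
        for j in range(int(yy.max()) if yy.size else 0):
            acc += np.where(j < yy, np.log(pp + j), 0.0)
        out[big] = acc
    return out


def ztnb_logpmf(y, mu, phi):
    """Log-pmf of the zero-truncated negative binomial with psi = mu / phi.

    ``f(y | y > 0) = [Gamma(y+psi) / (Gamma(psi) Gamma(y+1)) *
    (mu/(mu+psi))**y] / (((mu+psi)/psi)**psi - 1)``, equivalently the
    standard NB pmf renormalized by ``1 - P(0)``.  Vectorized; supports
    y >= 1 only.
    """
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(y < 1):
        raise ValueError("zero-truncated support requires y >= 1")
    if np.any(~np.equal(np.mod(y, 1), 0)):
        raise ValueError("y must be integer")
    if np.any(mu <= 0) or np.any(phi <= 0):
        raise ValueError("mu and phi must be positive")
    psi = mu / phi
    t = np.log1p(phi)
    # mu/(mu+psi) = phi/(1+phi), psi/(mu+psi) = 1/(1+phi)
    return (
        _lgamma_ratio(y, psi)
        - gammaln(np.asarray(y, dtype=float) + 1.0)
        + y * (np.log(phi) - t)
        - _log_expm1(psi * t)
    )


def ztnb_mean(mu, phi):
    """Mean of the zero-truncated negative binomial: mu / (1 - P0),
    with P0 = (1 + phi) ** (-mu/phi)."""
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    log_p0 = -(mu / phi) * np.log1p(phi)
    return mu / -np.expm1(log_p0)


def ztnb_rvs(mu, phi, rng, max_rounds=1000):
    """Draw zero-truncated NB variates by gamma-Poisson mixing with rejection
    of zeros.  ``mu`` may be an array; ``phi`` scalar or array."""
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    psi = mu / phi
    out = np.zeros(mu.shape, dtype=np.int64)
    todo = np.ones(mu.shape, dtype=bool)
    for _ in range(max_rounds):
        if not todo.any():
            break
        lam = rng.gamma(shape=psi[todo], scale=np.broadcast_to(phi, mu.shape)[todo])
        draw = rng.poisson(lam)
        out[todo] = draw
        todo = out == 0
    else:  # pragma: no cover - pathological parameters only
        raise RuntimeError("zero-truncated sampling did not terminate")
    return out


# ---------------------------------------------------------------------------
# joint likelihood
# ---------------------------------------------------------------------------

def _part1_logpmf(eta1, used):
    """Bernoulli log-likelihood terms, stable: log p for users, log(1-p) otherwise."""
    return np.where(used, -np.logaddexp(0.0, -eta1), -np.logaddexp(0.0, eta1))


def _nll_fixed(theta, X1, X2u, y_u, used, return_grad=False):
    """Negative log-likelihood (and gradient) without random effects.

    theta = [beta1 (p1), beta2 (p2), log phi]; X2u/y_u are the users' rows.
    """
    p1 = X1.shape[1]
    p2 = X2u.shape[1]
    b1 = theta[:p1]
    b2 = theta[p1:p1 + p2]
    log_phi = theta[p1 + p2]
    phi = np.exp(log_phi)

    eta1 = X1 @ b1
    ll = _part1_logpmf(eta1, used).sum()

    eta2 = X2u @ b2
    psi = np.exp(eta2 - log_phi)
    t = np.log1p(phi)
    a = psi * t
    ll += (
        _lgamma_ratio(y_u, psi)
        - gammaln(y_u + 1.0)
        + y_u * (log_phi - t)
        - _log_expm1(a)
    ).sum()

    if not return_grad:
        return -ll

    g = np.empty_like(theta)
    resid1 = used.astype(float) - expit(eta1)
    g[:p1] = -(X1.T @ resid1)

    r = 1.0 / -np.expm1(-a)  # d log(e^a - 1) / da
    dg = digamma(y_u + psi) - digamma(psi)
    d_psi = dg - t * r
    g[p1:p1 + p2] = -(X2u.T @ (d_psi * psi))
    d_logphi = (y_u / (1.0 + phi) - psi * dg + r * psi * (t - phi / (1.0 + phi))).sum()
    g[p1 + p2] = -d_logphi
    return -ll, g


def _nll_grouped(theta, X1, X2u, y_u, used, user_pos, group_starts,
                 gh_z, gh_logw, pc_lambda):
    """Penalized negative log-likelihood with a shared Gaussian random
    intercept per group, integrated by Gauss-Hermite quadrature.

    Rows must already be sorted by group; ``group_starts`` are the reduceat
    boundaries, ``user_pos`` the positions of users within the sorted order.
    """
    p1 = X1.shape[1]
    p2 = X2u.shape[1]
    b1 = theta[:p1]
    b2 = theta[p1:p1 + p2]
    log_phi = theta[p1 + p2]
    log_sigma = theta[p1 + p2 + 1]
    phi = np.exp(log_phi)
    sigma = np.exp(log_sigma)

    eta1 = X1 @ b1
    eta2 = X2u @ b2
    nodes = np.sqrt(2.0) * sigma * gh_z  # (K,)

    n = X1.shape[0]
    K = nodes.size
    ll_obs = np.empty((K, n))
    t = np.log1p(phi)
    for k, u in enumerate(nodes):
        ll_k = _part1_logpmf(eta1 + u, used)
        psi = np.exp(eta2 + u - log_phi)
        ll_k[user_pos] += (
            _lgamma_ratio(y_u, psi)
            - gammaln(y_u + 1.0)
            + y_u * (log_phi - t)
            - _log_expm1(psi * t)
        )
        ll_obs[k] = ll_k

    group_ll = np.add.reduceat(ll_obs, group_starts, axis=1)  # (K, G)
    ll = logsumexp(group_ll + gh_logw[:, None], axis=0).sum()
    return -ll + pc_lambda * sigma


class HurdleCountModel(BaseEstimator):
    """Jointly estimated logistic hurdle x zero-truncated NB count model.

    Parameters
    ----------
    random_effects : bool
        Include a Gaussian random intercept shared by both parts within the
        groups passed to :meth:`fit`.
    gh_points : int
        Gauss-Hermite nodes for integrating the random effect.
    pc_u, pc_alpha : float
        Calibration of the exponential penalty on sigma_u via
        P(sigma_u > pc_u) = pc_alpha (only with random effects).
    gtol, xtol, max_iter : float, float, int
        Optimizer tolerances: projected-gradient norm, parameter step, and
        iteration cap.

    Attributes (after fit)
    ----------------------
    coef_hurdle_ : pd.Series   part-1 coefficients beta_1 (log-odds of any use)
    coef_count_ : pd.Series    part-2 coefficients beta_2 (log rate among users)
    dispersion_ : float        phi > 0 (NB1 dispersion; psi_i = mu_i / phi)
    re_sd_ : float or None     sigma_u >= 0
    params_, se_, cov_ :       full parameter vector (log phi, log sigma scale),
                               delta-method-free internal parameterization
    loglik_ : float            maximized (penalized, if applicable) log-likelihood
    converged_ : bool
    """

    def __init__(self, *, random_effects=False, gh_points=25, pc_u=1.0,
                 pc_alpha=0.01, gtol=1e-6, xtol=1e-8, max_iter=500):
        self.random_effects = random_effects
        self.gh_points = gh_points
        self.pc_u = pc_u
        self.pc_alpha = pc_alpha
        self.gtol = gtol
        self.xtol = xtol
        self.max_iter = max_iter

    # -- helpers ---------------------------------------------------------

    @staticmethod
    def _asarray(X, default_prefix):
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), list(X.columns)
        X = np.asarray(X, dtype=float)
        return X, [f"{default_prefix}{j}" for j in range(X.shape[1])]

    def _validate_y(self, y):
        y = np.asarray(y)
        if np.any(y < 0) or np.any(~np.equal(np.mod(y, 1), 0)):
            raise DataError("responses must be non-negative integers")
        y = y.astype(np.int64)
        used = y > 0
        if used.all() or not used.any():
            raise DataError("both outcome classes (zero and positive) must be present")
        return y, used

    def _start_values(self, X1, X2u, y_u, used):
        import statsmodels.api as sm

        try:
            b1 = sm.Logit(used.astype(float), X1).fit(disp=0, maxiter=100).params
            b1 = np.asarray(b1)
            if not np.all(np.isfinite(b1)):
                raise ValueError
        except Exception:
            b1 = np.zeros(X1.shape[1])
        try:
            b2 = sm.GLM(y_u, X2u, family=sm.families.Poisson()).fit().params
            b2 = np.asarray(b2)
            if not np.all(np.isfinite(b2)):
                raise ValueError
        except Exception:
            b2 = np.zeros(X2u.shape[1])
            b2[0] = np.log(max(y_u.mean(), 1.0))
        mu = np.exp(np.clip(X2u @ b2, -30, 30))
        phi0 = max(np.mean((y_u - mu) ** 2 / np.maximum(mu, 1e-8)) - 1.0, 1e-3)
        return b1, b2, np.log(phi0)

    # -- estimation ------------------------------------------------------

    def fit(self, X, y, X2=None, groups=None):
        """Fit the joint model.

        ``X`` is the part-1 design (with intercept); ``X2`` the part-2 design
        (defaults to ``X``); both over all observations.  ``groups`` labels
        the random-effect grouping and is required iff ``random_effects``.
        """
        X1, names1 = self._asarray(X, "x")
        if X2 is None:
            X2_full, names2 = X1, list(names1)
        else:
            X2_full, names2 = self._asarray(X2, "z")
        if X2_full.shape[0] != X1.shape[0]:
            raise DataError("X and X2 must have the same number of rows")
        y, used = self._validate_y(y)

        if self.random_effects:
            if groups is None:
                raise DataError("random_effects=True requires groups")
            groups = np.asarray(groups)
            order = np.argsort(groups, kind="stable")
            X1 = X1[order]
            X2_full = X2_full[order]
            y = y[order]
            used = used[order]
            groups = groups[order]
            group_starts = np.flatnonzero(
                np.r_[True, groups[1:] != groups[:-1]])
        X2u = X2_full[used]
        y_u = y[used].astype(float)

        b1, b2, log_phi0 = self._start_values(X1, X2u, y_u, used)
        p1, p2 = X1.shape[1], X2u.shape[1]

        if not self.random_effects:
            theta0 = np.r_[b1, b2, log_phi0]
            res = optimize.minimize(
                _nll_fixed, theta0, args=(X1, X2u, y_u, used, True),
                jac=True, method="L-BFGS-B",
                options={"gtol": self.gtol, "ftol": self.xtol,
                         "maxiter": self.max_iter},
            )
            nll = lambda th: _nll_fixed(th, X1, X2u, y_u, used)  # noqa: E731
            extra_names = ["log_phi"]
        else:
            gh_z, gh_w = np.polynomial.hermite.hermgauss(self.gh_points)
            gh_logw = np.log(gh_w) - 0.5 * np.log(np.pi)
            pc_lambda = -np.log(self.pc_alpha) / self.pc_u
            user_pos = np.flatnonzero(used)
            args = (X1, X2u, y_u, used, user_pos, group_starts,
                    gh_z, gh_logw, pc_lambda)
            theta0 = np.r_[b1, b2, log_phi0, np.log(0.3)]
            res = optimize.minimize(
                _nll_grouped, theta0, args=args, method="L-BFGS-B",
                options={"gtol": self.gtol, "ftol": self.xtol,
                         "maxiter": self.max_iter},
            )
            nll = lambda th: _nll_grouped(th, *args)  # noqa: E731
            extra_names = ["log_phi", "log_sigma_u"]

        theta = res.x
        self.converged_ = bool(res.success)
        self.n_iter_ = int(res.nit)
        self.loglik_ = -float(res.fun)
        self.param_names_ = ([f"part1:{n}" for n in names1]
                             + [f"part2:{n}" for n in names2] + extra_names)

        from statsmodels.tools.numdiff import approx_hess

        H = approx_hess(theta, nll)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        self.params_ = pd.Series(theta, index=self.param_names_)
        self.cov_ = pd.DataFrame(cov, index=self.param_names_,
                                 columns=self.param_names_)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        self.se_ = pd.Series(se, index=self.param_names_)

        self.coef_hurdle_ = pd.Series(theta[:p1], index=names1)
        self.coef_count_ = pd.Series(theta[p1:p1 + p2], index=names2)
        self.dispersion_ = float(np.exp(theta[p1 + p2]))
        self.re_sd_ = (float(np.exp(theta[p1 + p2 + 1]))
                       if self.random_effects else None)
        self.nobs_ = int(len(y))
        self._p1, self._p2 = p1, p2
        if not self.converged_:
            self.diagnostics_ = {"message": str(res.message), "nit": res.nit}
        return self

    # -- prediction ------------------------------------------------------

    def predict_use_proba(self, X):
        """Part-1 probability of any use (population-averaged, u = 0)."""
        X1, _ = self._asarray(X, "x")
        return expit(X1 @ self.coef_hurdle_.to_numpy())

    def predict_rate(self, X2):
        """Part-2 conditional mean number of contacts among users."""
        Xa, _ = self._asarray(X2, "z")
        mu = np.exp(Xa @ self.coef_count_.to_numpy())
        return ztnb_mean(mu, self.dispersion_)

    def predict(self, X, X2=None):
        """Expected annual count: P(use) x E[count | use]."""
        return self.predict_use_proba(X) * self.predict_rate(X if X2 is None else X2)


# ---------------------------------------------------------------------------
# spec-level wrappers
# ---------------------------------------------------------------------------

@dataclass
class HurdleSpec:
    """Declarative description of one hurdle fit on a survey frame."""

    response: str
    x1_terms: list = field(default_factory=list)
    x2_terms: list | None = None  # None -> same as part 1
    group_col: str | None = None
    pc_u: float = 1.0
    pc_alpha: float = 0.01
    gh_points: int = 25
    max_iter: int = 500


def fit_hurdle(data: pd.DataFrame, spec: HurdleSpec) -> HurdleCountModel:
    """Fit the joint hurdle model described by ``spec`` on survey records."""
    from .design import build_design

    X1 = build_design(data, spec.x1_terms)
    X2 = X1 if spec.x2_terms is None else build_design(data, spec.x2_terms)
    y = pd.to_numeric(data[spec.response]).to_numpy()
    model = HurdleCountModel(
        random_effects=spec.group_col is not None,
        gh_points=spec.gh_points, pc_u=spec.pc_u, pc_alpha=spec.pc_alpha,
        max_iter=spec.max_iter,
    )
    groups = data[spec.group_col].to_numpy() if spec.group_col else None
    return model.fit(X1, y, X2=X2, groups=groups)


def hurdle_loglik(params: dict, data: pd.DataFrame, spec: HurdleSpec) -> float:
    """Evaluate the joint hurdle log-likelihood at fixed parameters.

    ``params`` maps 'beta1' and 'beta2' to coefficient arrays aligned with the
    spec's designs (intercept first) and 'phi' to the NB1 dispersion; with a
    grouped spec it also takes 'sigma_u', and the PC penalty is included.
    """
    from .design import build_design

    X1 = build_design(data, spec.x1_terms).to_numpy()
    X2 = (X1 if spec.x2_terms is None
          else build_design(data, spec.x2_terms).to_numpy())
    y = pd.to_numeric(data[spec.response]).to_numpy()
    if np.any(y < 0) or np.any(~np.equal(np.mod(y, 1), 0)):
        raise DataError("responses must be non-negative integers")
    y = y.astype(np.int64)
    used = y > 0
    b1 = np.asarray(params["beta1"], dtype=float)
    b2 = np.asarray(params["beta2"], dtype=float)
    phi = float(params["phi"])
    theta = np.r_[b1, b2, np.log(phi)]
    if spec.group_col is None:
        return -_nll_fixed(theta, X1, X2[used], y[used].astype(float), used)
    groups = np.asarray(data[spec.group_col])
    order = np.argsort(groups, kind="stable")
    X1, X2, y, used, groups = X1[order], X2[order], y[order], used[order], groups[order]
    group_starts = np.flatnonzero(np.r_[True, groups[1:] != groups[:-1]])
    gh_z, gh_w = np.polynomial.hermite.hermgauss(spec.gh_points)
    theta = np.r_[theta, np.log(float(params["sigma_u"]))]
    return -_nll_grouped(
        theta, X1, X2[used], y[used].astype(float), used,
        np.flatnonzero(used), group_starts, gh_z,
        np.log(gh_w) - 0.5 * np.log(np.pi),
        -np.log(spec.pc_alpha) / spec.pc_u,
    )


@dataclass
class RateRatio:
    ratio: float
    lower: float
    upper: float
    part: int
    scale: str  # 'odds' for part 1, 'rate' for part 2


def rate_ratio(fit: HurdleCountModel, contrast: dict, part: int = 1,
               level: float = 0.95) -> RateRatio:
    """Exponentiated contrast of fitted coefficients with a delta-method interval.

    ``contrast`` maps coefficient names of the requested part to weights; for
    part 1 the result is an odds ratio, for part 2 a rate ratio.
    """
    if part not in (1, 2):
        raise ValueError("part must be 1 or 2")
    coefs = fit.coef_hurdle_ if part == 1 else fit.coef_count_
    offset = 0 if part == 1 else fit._p1
    c_full = np.zeros(len(fit.params_))
    for name, w in contrast.items():
        if name not in coefs.index:
            raise ScoringError(f"unknown coefficient '{name}' in part {part}")
        c_full[offset + coefs.index.get_loc(name)] = w
    est = float(c_full @ fit.params_.to_numpy())
    se = float(np.sqrt(c_full @ fit.cov_.to_numpy() @ c_full))
    z = special.ndtri(0.5 + level / 2.0)
    return RateRatio(
        ratio=float(np.exp(est)),
        lower=float(np.exp(est - z * se)),
        upper=float(np.exp(est + z * se)),
        part=part,
        scale="odds" if part == 1 else "rate",
    )
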