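"""Hurdle-model primitives and joint estimation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import check_grad, minimize
from scipy.special import expit
from scipy.stats import nbinom

from equiuse.exceptions import DataError, ScoringError
from equiuse.hurdle import (HurdleCountModel, HurdleSpec, _nll_fixed,
                            fit_hurdle, hurdle_loglik, rate_ratio,
                            ztnb_logpmf, ztnb_mean, ztnb_rvs)


def test_ztnb_pmf_example_one_third():
    # mu=2, phi=1 -> psi=2; P(1 | >0) = 0.25 / (1 - 0.25) = 1/3
    assert np.exp(ztnb_logpmf(1, 2.0, 1.0)) == pytest.approx(1 / 3, abs=1e-14)


def test_ztnb_matches_renormalized_nb():
    rng = np.random.default_rng(1)
    for _ in range(50):
        mu = float(rng.uniform(0.05, 20))
        phi = float(rng.uniform(0.05, 20))
        y = int(rng.integers(1, 30))
        psi = mu / phi
        p = psi / (mu + psi)
        oracle = nbinom.pmf(y, psi, p) / (1 - nbinom.pmf(0, psi, p))
        assert np.exp(ztnb_logpmf(y, mu, phi)) == pytest.approx(oracle, abs=1e-12)


def test_ztnb_domain_errors():
    with pytest.raises(ValueError):
        ztnb_logpmf(0, 1.0, 1.0)
    with pytest.raises(ValueError):
        ztnb_logpmf(1, -1.0, 1.0)
    with pytest.raises(ValueError):
        ztnb_logpmf(1, 1.0, 0.0)


def test_ztnb_mean_equals_pmf_sum():
    for mu, phi in [(0.5, 0.3), (3.0, 1.5), (8.0, 0.1)]:
        ys = np.arange(1, 2000)
        m = (ys * np.exp(ztnb_logpmf(ys, mu, phi))).sum()
        assert ztnb_mean(mu, phi) == pytest.approx(m, rel=1e-10)


def _simulate(n, b1, b2, phi, seed):
    rng = np.random.default_rng(seed)
    X = np.c_[np.ones(n), rng.normal(size=n), rng.binomial(1, 0.4, n)]
    use = rng.random(n) < expit(X @ b1)
    y = np.zeros(n, dtype=int)
    if use.any():
        y[use] = ztnb_rvs(np.exp(X[use] @ b2), phi, rng)
    return X, y


def test_gradient_matches_finite_differences():
    X, y = _simulate(400, np.r_[0.2, 0.5, -0.3], np.r_[0.8, 0.3, 0.2], 0.7, 3)
    used = y > 0
    args = (X, X[used], y[used].astype(float), used)
    theta = np.r_[0.1, 0.4, -0.2, 0.9, 0.2, 0.1, np.log(0.5)]
    err = check_grad(lambda t: _nll_fixed(t, *args),
                     lambda t: _nll_fixed(t, *args, return_grad=True)[1], theta)
    assert err < 1e-3


def test_loglik_additivity_over_observations():
    df = pd.DataFrame({
        "y": [0, 2, 5],
        "x": [0.5, -1.0, 2.0],
        "wave": 2006,
    })
    spec = HurdleSpec(response="y", x1_terms=["x"], x2_terms=["x"])
    params = {"beta1": [0.2, 0.4], "beta2": [0.6, -0.1], "phi": 0.8}
    total = hurdle_loglik(params, df, spec)
    parts = [hurdle_loglik(params, df.iloc[[i]], spec) for i in range(3)]
    assert total == pytest.approx(sum(parts), rel=1e-12)


def test_loglik_all_zero_closed_form():
    df = pd.DataFrame({"y": [0] * 7, "x": 0.0, "wave": 2006})
    spec = HurdleSpec(response="y", x1_terms=["x"])
    b0 = -0.4
    val = hurdle_loglik({"beta1": [b0, 0.0], "beta2": [0.0, 0.0], "phi": 1.0},
                        df, spec)
    assert val == pytest.approx(7 * np.log(1 - expit(b0)), rel=1e-12)


def test_loglik_matches_bruteforce_gamma_arithmetic():
    """Six printed observations, fixed parameters: the likelihood equals a
    brute-force evaluation with direct Gamma-function arithmetic."""
    ys = [0, 0, 1, 2, 3, 7]
    xs = [0.0, 1.0, -0.5, 0.3, 1.2, 2.0]
    b1 = (0.1, 0.3)
    b2 = (0.5, 0.25)
    phi = 0.6

    expected = 0.0
    for y, x in zip(ys, xs):
        eta1 = b1[0] + b1[1] * x
        p1 = 1.0 / (1.0 + math.exp(-eta1))
        if y == 0:
            expected += math.log(1.0 - p1)
        else:
            mu = math.exp(b2[0] + b2[1] * x)
            psi = mu / phi
            nb = (math.gamma(y + psi) / (math.gamma(psi) * math.gamma(y + 1))
                  * (mu / (mu + psi)) ** y)
            denom = ((mu + psi) / psi) ** psi - 1.0
            expected += math.log(p1) + math.log(nb / denom)

    df = pd.DataFrame({"y": ys, "x": xs, "wave": 2006})
    spec = HurdleSpec(response="y", x1_terms=["x"], x2_terms=["x"])
    got = hurdle_loglik({"beta1": list(b1), "beta2": list(b2), "phi": phi},
                        df, spec)
    assert got == pytest.approx(expected, rel=1e-10)


def test_noninteger_response_rejected():
    df = pd.DataFrame({"y": [0.0, 1.5], "x": [0.0, 1.0], "wave": 2006})
    spec = HurdleSpec(response="y", x1_terms=["x"])
    with pytest.raises(DataError):
        hurdle_loglik({"beta1": [0, 0], "beta2": [0, 0], "phi": 1}, df, spec)
    with pytest.raises(DataError):
        HurdleCountModel().fit(np.c_[np.ones(2), [0., 1.]], [0.0, 1.5])


def test_single_class_rejected():
    X = np.ones((5, 1))
    with pytest.raises(DataError):
        HurdleCountModel().fit(X, [0, 0, 0, 0, 0])
    with pytest.raises(DataError):
        HurdleCountModel().fit(X, [1, 2, 3, 4, 5])


def test_joint_fit_separates_into_part_fits():
    """With disjoint parameter blocks and no random effects, the joint
    maximum coincides with the two independent maxima."""
    X, y = _simulate(1500, np.r_[0.3, 0.4, -0.3], np.r_[0.8, 0.25, 0.2], 0.8, 9)
    joint = HurdleCountModel().fit(X, y)

    import statsmodels.api as sm
    part1 = sm.Logit((y > 0).astype(float), X).fit(disp=0)
    assert np.allclose(joint.coef_hurdle_.to_numpy(), part1.params, atol=5e-4)

    used = y > 0
    ll2 = lambda t: -ztnb_logpmf(  # noqa: E731
        y[used], np.exp(X[used] @ t[:3]), np.exp(t[3])).sum()
    res2 = minimize(ll2, np.r_[joint.coef_count_.to_numpy() * 0.9, 0.0],
                    method="Nelder-Mead",
                    options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
    assert np.allclose(joint.coef_count_.to_numpy(), res2.x[:3], atol=1e-3)
    assert joint.dispersion_ == pytest.approx(np.exp(res2.x[3]), abs=1e-3)


def test_rate_ratio_contrasts():
    X, y = _simulate(1200, np.r_[0.3, 0.4, -0.3], np.r_[0.8, 0.25, 0.2], 0.8, 4)
    Xdf = pd.DataFrame(X, columns=["intercept", "x", "z"])
    fit = HurdleCountModel().fit(Xdf, y)

    rr = rate_ratio(fit, {"x": 0.0}, part=1)
    assert rr.ratio == 1.0 and rr.lower <= 1.0 <= rr.upper

    est = fit.coef_hurdle_.loc["x"]
    rr = rate_ratio(fit, {"x": 1.0}, part=1)
    assert rr.ratio == pytest.approx(np.exp(est), rel=1e-12)
    # interval width is exactly exp(2 * z * se) on the ratio scale
    se = np.sqrt(fit.cov_.loc["part1:x", "part1:x"])
    assert np.log(rr.upper / rr.lower) == pytest.approx(2 * 1.959964 * se,
                                                        rel=1e-4)
    with pytest.raises(ScoringError):
        rate_ratio(fit, {"nope": 1.0}, part=2)


def test_fit_hurdle_on_survey_frame(processed):
    out, _ = processed
    sub = out[out.wave == 2006]
    spec = HurdleSpec(response="emergency_year_total",
                      x1_terms=["q2", "q3", "q4"])
    fit = fit_hurdle(sub, spec)
    assert fit.converged_
    assert set(fit.coef_hurdle_.index) == {"intercept", "q2", "q3", "q4"}
    assert fit.dispersion_ > 0
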