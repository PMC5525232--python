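"""Ownership imputation: single-visit fits, count splitting, conservation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import logit

from equiuse import schema
from equiuse.design import HEALTH_MODEL_TERMS, build_design
from equiuse.exceptions import DataError, FitError
from equiuse.logit import LogitModel
from equiuse.ownership import fit_ownership_model, split_counts
from equiuse.synthetic import GeneratorConfig, generate_survey


def _dummy_fit(p):
    """LogitModel with a fixed intercept-only probability over the health
    design (all other coefficients zero)."""
    fit = LogitModel()
    cols = build_design(generate_survey(GeneratorConfig().scaled(5, seed=0))[0],
                        HEALTH_MODEL_TERMS).columns
    fit.coef_ = pd.Series(0.0, index=cols)
    fit.coef_.loc["intercept"] = logit(p)
    fit.service_ = "primary"
    return fit


@pytest.fixture(scope="module")
def tiny_records():
    records, _ = generate_survey(GeneratorConfig().scaled(60, seed=13))
    return records


def test_single_visit_flag_used_directly(tiny_records):
    rec = tiny_records.copy()
    rec["primary_count"] = 1
    rec["primary_private"] = pd.array([1] * len(rec), dtype="Int64")
    out = split_counts(_dummy_fit(0.01), rec, "primary")
    assert (out["private"] == 1).all() and (out["public"] == 0).all()


def test_round_half_to_even_split(tiny_records):
    rec = tiny_records.head(1).copy()
    rec["primary_count"] = 5
    rec["primary_private"] = pd.array([1], dtype="Int64")
    out = split_counts(_dummy_fit(0.4), rec, "primary")
    assert out["private"].iloc[0] == 2 and out["public"].iloc[0] == 3
    rec["primary_count"] = 2  # 2 * 0.25 = 0.5 rounds to 0 (half to even)
    out = split_counts(_dummy_fit(0.25), rec, "primary")
    assert out["private"].iloc[0] == 0


def test_zero_visits_zero_split(tiny_records):
    rec = tiny_records.copy()
    rec["primary_count"] = 0
    rec["primary_private"] = pd.array([pd.NA] * len(rec), dtype="Int64")
    out = split_counts(_dummy_fit(0.9), rec, "primary")
    assert (out[["total", "public", "private"]] == 0).all().all()


@given(st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.integers(2, 40))
def test_private_monotone_in_probability(p_low, p_high, total):
    if p_low > p_high:
        p_low, p_high = p_high, p_low
    low = np.rint(total * p_low)
    high = np.rint(total * p_high)
    assert low <= high <= total


def test_all_public_single_visits_is_separation(tiny_records):
    rec = tiny_records[tiny_records.wave == 2006].copy()
    rec["primary_count"] = 1
    rec["primary_private"] = pd.array([0] * len(rec), dtype="Int64")
    with pytest.raises(FitError, match="separation"):
        fit_ownership_model(rec, "primary")


def test_empty_single_visit_subsample_is_data_error(tiny_records):
    rec = tiny_records[tiny_records.wave == 2006].copy()
    rec["primary_count"] = 0
    rec["primary_private"] = pd.array([pd.NA] * len(rec), dtype="Int64")
    with pytest.raises(DataError, match="single-visit"):
        fit_ownership_model(rec, "primary")


def test_intercept_only_probability_recovery():
    """Intercept-only truth p = 0.3: the estimate covers logit(0.3) within
    3 SE in at least 95% of 200 replicates."""
    rng = np.random.default_rng(77)
    n, truth = 5000, logit(0.3)
    X = np.ones((n, 1))
    covered = 0
    for _ in range(200):
        y = (rng.random(n) < 0.3).astype(float)
        fit = LogitModel().fit(X, y)
        covered += abs(fit.coef_.iloc[0] - truth) <= 3 * fit.se_.iloc[0]
    assert covered / 200 >= 0.95


def test_null_slopes_within_3se():
    rng = np.random.default_rng(5)
    n = 4000
    X = np.c_[np.ones(n), rng.normal(size=n), rng.binomial(1, 0.3, n)]
    y = (rng.random(n) < 0.4).astype(float)
    fit = LogitModel().fit(X, y)
    assert (fit.coef_.iloc[1:].abs() <= 3 * fit.se_.iloc[1:]).all()


def test_conservation_everywhere(processed):
    out, _ = processed
    for s in schema.SERVICES:
        total = out[f"{s}_total"]
        assert (out[f"{s}_public"] + out[f"{s}_private_n"] == total).all()
        assert (out[[f"{s}_public", f"{s}_private_n"]] >= 0).all().all()
        assert (total == out[f"{s}_count"]).all()


def test_aggregate_private_share_recovered(survey):
    """On yearly-scale counts with known ownership of every contact, the
    aggregate private share recovered by split_counts stays within 3
    Monte-Carlo SEs of the true share.

    The Monte-Carlo SE combines (a) the binomial noise of the true per-contact
    ownership draws and (b) the sampling noise of the ownership model, which
    is fitted on the single-visit subsample only and therefore dominates;
    the latter is propagated by the delta method through the fitted
    coefficients.
    """
    records, truth = survey
    s = "primary"
    rec = records.copy()
    annual = truth[f"{s}_annual"].to_numpy()
    true_private = truth[f"{s}_annual_private"].to_numpy()
    rec[f"{s}_count"] = annual
    flag = pd.array([pd.NA] * len(rec), dtype="Int64")
    has = annual >= 1
    # single-contact users' flag IS the true ownership of their one contact;
    # multi-visit flags are never used by split_counts
    flag[has] = (true_private[has] > 0).astype(int)
    rec[f"{s}_private"] = flag

    est_total = np.zeros(len(rec), dtype=np.int64)
    est_private = np.zeros(len(rec), dtype=np.int64)
    var_fit = 0.0
    grand_total = 0.0
    for wave in (2006, 2011):
        sub = rec[rec.wave == wave]
        fit = fit_ownership_model(sub, s)
        split = split_counts(fit, sub, s)
        est_total[sub.index] = split["total"].to_numpy()
        est_private[sub.index] = split["private"].to_numpy()
        # delta-method variance of the multi-visit private total
        multi = sub[sub[f"{s}_count"] > 1]
        X = build_design(multi, HEALTH_MODEL_TERMS).to_numpy()
        t = multi[f"{s}_count"].to_numpy()
        p = fit.predict_proba(build_design(multi, HEALTH_MODEL_TERMS))
        g = (t * p * (1 - p)) @ X
        var_fit += float(g @ fit.cov_.to_numpy() @ g)
        grand_total += t.sum()

    true_share = true_private.sum() / annual.sum()
    est_share = est_private.sum() / est_total.sum()
    se_binom = np.sqrt(true_share * (1 - true_share) / annual.sum())
    se_fit = np.sqrt(var_fit) / est_total.sum()
    mc_se = np.sqrt(se_binom ** 2 + se_fit ** 2)
    assert abs(est_share - true_share) < 3 * mc_se
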