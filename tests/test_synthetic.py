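"""Generator and schema behaviour: determinism, dialects, invariants, I/O."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import nbinom

from equiuse import schema
from equiuse.exceptions import ConfigError, SchemaError
from equiuse.synthetic import (GeneratorConfig, discretize_income,
                               generate_population, generate_survey,
                               simulate_utilization)


def test_fixed_seed_is_deterministic(tmp_path):
    cfg = GeneratorConfig().scaled(100, seed=7)
    rec1, truth1 = generate_survey(cfg)
    rec2, truth2 = generate_survey(cfg)
    pd.testing.assert_frame_equal(rec1, rec2)
    pd.testing.assert_frame_equal(truth1, truth2)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    schema.write_survey(rec1, p1)
    schema.write_survey(rec2, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_distinct_seeds_differ():
    rec1, _ = generate_survey(GeneratorConfig().scaled(200, seed=1))
    rec2, _ = generate_survey(GeneratorConfig().scaled(200, seed=2))
    assert not rec1.drop(columns=["id"]).equals(rec2.drop(columns=["id"]))


def test_income_dialects_have_8_and_10_bands(survey):
    records, _ = survey
    bands06 = set(records.loc[records.wave == 2006, "income_band"])
    bands11 = set(records.loc[records.wave == 2011, "income_band"])
    assert bands06 == set(range(1, 9))
    assert bands11 == set(range(1, 11))


def test_cut_point_goes_to_upper_band():
    cfg = GeneratorConfig()
    cut = cfg.cuts_2006[2]
    assert discretize_income([cut - 1e-9, cut, cut + 1e-9], 2006, cfg).tolist() \
        == [3, 4, 4]
    mcut = 12.0 * cfg.cuts_2011_monthly[0]
    assert discretize_income([mcut, mcut - 1], 2011, cfg).tolist() == [2, 1]


def test_invalid_cut_points_rejected():
    cfg = GeneratorConfig()
    cfg.cuts_2006[3] = cfg.cuts_2006[2]  # not strictly increasing
    with pytest.raises(ConfigError):
        cfg.validate()


def test_degenerate_hurdle_gives_all_zero_counts():
    cfg = GeneratorConfig().scaled(300, seed=3)
    for params in cfg.services.values():
        params.beta1["intercept"] = -np.inf
    records, truth = generate_survey(cfg)
    for s in schema.SERVICES:
        assert (records[f"{s}_count"] == 0).all()
        assert (truth[f"{s}_annual"] == 0).all()
        assert records[f"{s}_private"].isna().all()


def test_truncated_count_mean_matches_closed_form():
    """With sigma_u = 0 and intercept-only parts, the mean generated count
    among users matches the truncated-NB mean computed by summing the
    renormalized NB pmf to machine tolerance."""
    mu, phi = 2.0, 0.5
    cfg = GeneratorConfig().scaled(20000, seed=11)
    cfg.n_2011 = 1  # one wave is enough
    cfg.sigma_u = 0.0
    cfg.services = {"primary": cfg.services["primary"]}
    cfg.services["primary"].beta1 = {"intercept": 0.5}
    cfg.services["primary"].beta2 = {"intercept": math.log(mu)}
    cfg.services["primary"].phi = phi
    cfg.ownership_coefs = {"primary": {"intercept": -2.0}}
    cfg.delay_coefs = {"primary": {"intercept": -1.0}}
    _, truth = generate_survey(cfg)
    counts = truth.loc[(truth.wave == 2006) & (truth.primary_annual > 0),
                       "primary_annual"].to_numpy()

    # oracle: renormalized NB pmf, summed until the tail is negligible
    psi = mu / phi
    p = psi / (mu + psi)
    ys = np.arange(1, 400)
    pmf = nbinom.pmf(ys, psi, p) / (1 - nbinom.pmf(0, psi, p))
    assert abs(pmf.sum() - 1) < 1e-12
    oracle_mean = float((ys * pmf).sum())

    mc_se = counts.std(ddof=1) / np.sqrt(counts.size)
    assert abs(counts.mean() - oracle_mean) < 3 * mc_se


def test_zero_fraction_matches_design_average(survey, survey_cfg):
    """The generated share of annual non-users converges to the average of
    1 - logit^-1(X'b1 + u) over the generated design."""
    records, truth = survey
    from equiuse.synthetic import _linear_predictor
    from scipy.special import expit

    work = records.copy()
    work["income_quartile"] = truth["true_quartile"].to_numpy()
    for s in ("primary", "emergency"):
        eta = _linear_predictor(work, survey_cfg.services[s].beta1) \
            + truth["u"].to_numpy()
        expected_zero = float(np.mean(1 - expit(eta)))
        observed_zero = float((truth[f"{s}_annual"] == 0).mean())
        mc_se = np.sqrt(expected_zero * (1 - expected_zero) / len(work))
        assert abs(observed_zero - expected_zero) < 4 * mc_se


def test_roundtrip_write_read(tmp_path):
    records, _ = generate_survey(GeneratorConfig().scaled(150, seed=9))
    path = tmp_path / "survey.csv"
    schema.write_survey(records, path)
    back = schema.read_survey(path)
    pd.testing.assert_frame_equal(
        back.reset_index(drop=True),
        schema.validate_survey(records).reset_index(drop=True),
        check_dtype=False,
    )


@pytest.mark.parametrize(
    "mutate, message",
    [
        (lambda df: df.__setitem__("ghq12", df["ghq12"].where(df.index != 3, 13)),
         "ghq12"),
        (lambda df: df.__setitem__(
            "primary_private",
            df["primary_private"].where(~((df["primary_count"] == 0)
                                          & (df.index == 0)), 1)),
         "primary_private"),
        (lambda df: df.__setitem__("sex", df["sex"].where(df.index != 1, "unknown")),
         "sex"),
    ],
)
def test_schema_violations_are_named(mutate, message):
    records, _ = generate_survey(GeneratorConfig().scaled(50, seed=4))
    bad = records.copy()
    mutate(bad)
    with pytest.raises(SchemaError, match=message):
        schema.validate_survey(bad)


def test_unknown_column_rejected():
    records, _ = generate_survey(GeneratorConfig().scaled(20, seed=4))
    bad = records.copy()
    bad["mystery"] = 1
    with pytest.raises(SchemaError, match="mystery"):
        schema.validate_survey(bad)


def test_config_from_flat_keys():
    cfg = GeneratorConfig.from_flat({
        "n_2006": 500, "services.emergency.beta1.q4": -0.9, "sigma_u": 0.2})
    assert cfg.n_2006 == 500
    assert cfg.services["emergency"].beta1["q4"] == -0.9
    with pytest.raises(ConfigError):
        GeneratorConfig.from_flat({"no_such_key": 1})


def test_missingness_rate_produces_missing_need_covariates():
    cfg = GeneratorConfig().scaled(400, seed=6)
    cfg.missing_rate = 0.1
    records, _ = generate_survey(cfg)
    assert records["ghq12"].isna().any()
    schema.validate_survey(records)  # nonresponse is schema-legal
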