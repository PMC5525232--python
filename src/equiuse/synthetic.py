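"""Seeded synthetic survey generator.

Generates two-wave cross-sectional microdata with the statistical structure
the pipeline assumes: interval-censored income in two dialects (8 annual
bands for wave 2006, 10 monthly bands for wave 2011, discretized from one
latent annual income), household random effects, and per-service utilization
from the same two-part process the estimator targets — a Bernoulli hurdle on
logit(X'b1 + u) and a zero-truncated NB1 count with mean exp(X'b2 + u) and
dispersion phi.  Annual counts for primary/specialist care are thinned into
the 4-week recall window contact-by-contact with probability 4/52, so the
x12 annualization rule is an approximate inverse of the recall truncation.

Every draw is deterministic given the config seed.  The generator returns
the observable records together with a ``truth`` frame (latent income, true
quartile, random effects, true annual and private counts) for recovery
tests; the truth frame is never written to survey files.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from . import schema
from .design import build_design
from .exceptions import ConfigError
from .hurdle import ztnb_rvs

__all__ = ["ServiceParams", "GeneratorConfig", "generate_population",
           "simulate_utilization", "generate_survey", "discretize_income",
           "write_survey", "read_survey"]

write_survey = schema.write_survey
read_survey = schema.read_survey


@dataclass
class ServiceParams:
    """True two-part parameters of one service's utilization process."""

    beta1: dict  # part-1 log-odds coefficients, key 'intercept' required
    beta2: dict  # part-2 log-rate coefficients
    phi: float   # NB1 dispersion (> 0)


def _default_services():
    # Signs of the income-quartile effects mirror the qualitative pattern the
    # analysis is designed to detect: emergencies and hospitalizations
    # pro-poor, specialist care pro-rich.
    return {
        "primary": ServiceParams(
            beta1={"intercept": 0.3, "q2": 0.0, "q3": 0.0, "q4": 0.0,
                   "female": 0.25, "age_66-75": 0.4, "age_75+": 0.6,
                   "insurance": -0.1, "ghq12": 0.06},
            beta2={"intercept": 1.5, "female": 0.1, "age_75+": 0.25,
                   "ghq12": 0.03},
            phi=1.2,
        ),
        "specialist": ServiceParams(
            beta1={"intercept": -0.5, "q2": 0.15, "q3": 0.35, "q4": 0.55,
                   "female": 0.15, "insurance": 0.3, "ghq12": 0.05},
            beta2={"intercept": 1.0, "q4": 0.2},
            phi=1.5,
        ),
        "emergency": ServiceParams(
            beta1={"intercept": -1.0, "q2": -0.40, "q3": -0.69, "q4": -0.76,
                   "ghq12": 0.05},
            beta2={"intercept": 0.4},
            phi=0.8,
        ),
        "hospital": ServiceParams(
            beta1={"intercept": -2.2, "q2": -0.33, "q3": -0.87, "q4": -0.92,
                   "age_75+": 0.5},
            beta2={"intercept": 0.25},
            phi=0.5,
        ),
    }


def _default_ownership():
    coefs = {"intercept": -2.0, "female": 0.1, "sph_good": -0.2,
             "sph_fair": -0.5, "sph_bad": -0.8, "sph_very_bad": -1.0,
             "chronic_count": -0.1}
    return {s: dict(coefs) for s in schema.SERVICES}


def _default_delay():
    coefs = {"intercept": -1.0, "female": 0.1, "sph_good": 0.2,
             "sph_fair": 0.45, "sph_bad": 0.7, "sph_very_bad": 0.9,
             "chronic_count": 0.1}
    return {s: dict(coefs) for s in schema.FOUR_WEEK_SERVICES}


@dataclass
class GeneratorConfig:
    """True parameters and sampling conditions of the synthetic survey.

    Sample sizes default to the two survey waves' respondent counts
    (29,712 and 19,935).  Use :meth:`scaled` for desk-scale runs and
    :meth:`null` for a generator with no income and no wave effects.
    """

    n_2006: int = 29712
    n_2011: int = 19935
    seed: int = 0
    sigma_u: float = 0.5       # household random-effect SD
    mean_extra_members: float = 1.5  # household size = 1 + Poisson(this)
    thin_prob: float = 4.0 / 52.0    # P(an annual contact falls in the 4-week window)
    missing_rate: float = 0.0        # MCAR missingness on need covariates

    female_share: dict = field(default_factory=lambda: {2006: 0.606, 2011: 0.539})
    age_probs: dict = field(default_factory=lambda: {
        2006: [0.244, 0.201, 0.161, 0.138, 0.136, 0.120],
        2011: [0.237, 0.193, 0.169, 0.111, 0.140, 0.150],
    })
    occupation_probs: dict = field(default_factory=lambda: {
        2006: [0.46, 0.04, 0.04, 0.12, 0.08, 0.22, 0.04],
        2011: [0.38, 0.07, 0.09, 0.11, 0.08, 0.23, 0.04],
    })
    education_probs: list = field(default_factory=lambda: [0.15, 0.30, 0.35, 0.20])

    income_intercept: dict = field(default_factory=lambda: {2006: 9.65, 2011: 9.60})
    income_coefs: dict = field(default_factory=lambda: {
        "female": -0.05,
        "age_36-45": 0.15, "age_46-55": 0.20, "age_56-65": 0.15,
        "age_66-75": 0.0, "age_75+": -0.10,
        "occ_unemployed_lt1y": -0.30, "occ_unemployed_gt1y": -0.45,
        "occ_housework": -0.25, "occ_student": -0.20,
        "occ_retiree": -0.15, "occ_other": -0.20,
        "edu_primary": 0.20, "edu_secondary": 0.45, "edu_university": 0.85,
        "household_size": 0.05,
    })
    income_sd: float = 0.70
    cuts_2006: list = field(default_factory=lambda: [
        4200.0, 7200.0, 10800.0, 14400.0, 21600.0, 43200.0, 72000.0])
    cuts_2011_monthly: list = field(default_factory=lambda: [
        550.0, 800.0, 1050.0, 1300.0, 1550.0, 1850.0, 2250.0, 2750.0, 3450.0])

    insurance_intercept: dict = field(default_factory=lambda: {2006: -2.3, 2011: -2.2})
    insurance_income_slope: float = 0.8

    services: dict = field(default_factory=_default_services)
    ownership_coefs: dict = field(default_factory=_default_ownership)
    delay_coefs: dict = field(default_factory=_default_delay)

    # -- validation / constructors --------------------------------------

    def validate(self):
        if self.n_2006 < 1 or self.n_2011 < 1:
            raise ConfigError("sample sizes must be positive")
        if self.sigma_u < 0:
            raise ConfigError("sigma_u must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        for name, cuts in (("cuts_2006", self.cuts_2006),
                           ("cuts_2011_monthly", self.cuts_2011_monthly)):
            arr = np.asarray(cuts, dtype=float)
            if np.any(np.diff(arr) <= 0):
                raise ConfigError(f"{name} must be strictly increasing")
        if len(self.cuts_2006) != schema.INCOME_BANDS[2006] - 1:
            raise ConfigError("cuts_2006 must have 7 cut points (8 bands)")
        if len(self.cuts_2011_monthly) != schema.INCOME_BANDS[2011] - 1:
            raise ConfigError("cuts_2011_monthly must have 9 cut points (10 bands)")
        for svc, params in self.services.items():
            if params.phi <= 0:
                raise ConfigError(f"service '{svc}': phi must be > 0")
        return self

    def copy(self) -> "GeneratorConfig":
        return copy.deepcopy(self)

    def scaled(self, n_per_wave: int, seed: int | None = None) -> "GeneratorConfig":
        """Same process at a smaller sample size."""
        cfg = self.copy()
        cfg.n_2006 = cfg.n_2011 = int(n_per_wave)
        if seed is not None:
            cfg.seed = int(seed)
        return cfg

    @classmethod
    def null(cls, n_per_wave: int = 2000, seed: int = 0) -> "GeneratorConfig":
        """Generator with no income-quartile effects and identical waves."""
        cfg = cls().scaled(n_per_wave, seed)
        for params in cfg.services.values():
            for key in ("q2", "q3", "q4"):
                params.beta1.pop(key, None)
                params.beta2.pop(key, None)
        for d in (cfg.female_share, cfg.age_probs, cfg.occupation_probs,
                  cfg.income_intercept, cfg.insurance_intercept):
            d[2011] = copy.deepcopy(d[2006])
        return cfg

    @classmethod
    def from_flat(cls, mapping: dict) -> "GeneratorConfig":
        """Build a config from flat dotted keys, e.g.
        ``services.emergency.beta1.q4: -0.8`` or ``n_2006: 5000``."""
        cfg = cls()
        for key, value in mapping.items():
            parts = str(key).split(".")
            obj = cfg
            for part in parts[:-1]:
                if isinstance(obj, dict):
                    obj = obj[int(part) if part.isdigit() else part]
                else:
                    obj = getattr(obj, part)
            leaf = parts[-1]
            if isinstance(obj, dict):
                obj[int(leaf) if leaf.isdigit() else leaf] = value
            else:
                if not hasattr(obj, leaf):
                    raise ConfigError(f"unknown config key '{key}'")
                setattr(obj, leaf, value)
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        import yaml

        with open(path) as fh:
            mapping = yaml.safe_load(fh) or {}
        return cls.from_flat(mapping)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def discretize_income(annual_income, wave: int, config: GeneratorConfig) -> np.ndarray:
    """Map latent annual income to the wave's band dialect (1-based).

    Wave 2006 uses annual cut points directly; wave 2011 stores monthly cut
    points, annualized by x12.  Half-open convention: income exactly at a cut
    point belongs to the upper band.
    """
    cuts = (np.asarray(config.cuts_2006, dtype=float) if wave == 2006
            else 12.0 * np.asarray(config.cuts_2011_monthly, dtype=float))
    return np.searchsorted(cuts, np.asarray(annual_income, dtype=float),
                           side="right") + 1


def _linear_predictor(df: pd.DataFrame, coefs: dict) -> np.ndarray:
    """X'b from a coefficient dict over the design vocabulary."""
    eta = np.full(len(df), float(coefs.get("intercept", 0.0)))
    terms = [k for k in coefs if k != "intercept"]
    if terms:
        X = build_design(df, terms, add_intercept=False)
        eta = eta + X.to_numpy() @ np.array([float(coefs[t]) for t in terms])
    return eta


def _household_groups(n, wave, cfg, rng):
    sizes = []
    total = 0
    while total < n:
        s = 1 + rng.poisson(cfg.mean_extra_members)
        sizes.append(s)
        total += s
    group_id = np.repeat(np.arange(len(sizes)), sizes)[:n]
    size = np.repeat(sizes, sizes)[:n]
    labels = np.array([f"h{wave}-{g}" for g in group_id])
    return labels, size


def generate_population(config: GeneratorConfig):
    """Draw covariates, latent income and income bands for both waves.

    Returns ``(records, truth)``: the observable covariate frame (service
    counts zeroed, flags missing) and the latent truth frame (log income,
    true within-wave quartile, household random effect).
    """
    cfg = config.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    frames, truths = [], []
    for wave, n in ((2006, cfg.n_2006), (2011, cfg.n_2011)):
        group, hh_size = _household_groups(n, wave, cfg, rng)
        df = pd.DataFrame({
            "id": [f"{wave}-{i}" for i in range(n)],
            "wave": wave,
            "sex": np.where(rng.random(n) < cfg.female_share[wave],
                            "female", "male"),
            "age_band": rng.choice(schema.AGE_LEVELS, size=n,
                                   p=np.asarray(cfg.age_probs[wave]) /
                                   np.sum(cfg.age_probs[wave])),
            "occupation": rng.choice(schema.OCCUPATION_LEVELS, size=n,
                                     p=np.asarray(cfg.occupation_probs[wave]) /
                                     np.sum(cfg.occupation_probs[wave])),
            "education": rng.choice(schema.EDUCATION_LEVELS, size=n,
                                    p=np.asarray(cfg.education_probs) /
                                    np.sum(cfg.education_probs)),
            "household_size": hh_size,
            "group_id": group,
        })
        age_idx = pd.Categorical(df["age_band"],
                                 categories=schema.AGE_LEVELS).codes
        df["chronic_count"] = rng.poisson(0.3 + 0.25 * age_idx)
        latent_h = (0.45 * age_idx + 0.5 * np.minimum(df["chronic_count"], 4)
                    + rng.normal(0, 1.0, n))
        df["sph"] = pd.cut(latent_h, [-np.inf, 1.0, 2.2, 3.2, 4.2, np.inf],
                           labels=schema.SPH_LEVELS).astype(str)
        g = rng.normal(0, 0.7, n)
        df["ghq12"] = rng.binomial(
            12, expit(-2.2 + 0.25 * (df["chronic_count"] > 0) + g))

        log_inc = (cfg.income_intercept[wave]
                   + _linear_predictor(df, cfg.income_coefs)
                   + rng.normal(0, cfg.income_sd, n))
        df["income_band"] = discretize_income(np.exp(log_inc), wave, cfg)

        z = ((log_inc - log_inc.mean()) / log_inc.std()
             if n > 1 and log_inc.std() > 0 else np.zeros(n))
        df["insurance"] = (rng.random(n) < expit(
            cfg.insurance_intercept[wave] + cfg.insurance_income_slope * z)
        ).astype(int)

        # true within-wave income quartile (continuous latent, no ties)
        q1, q2, q3 = np.quantile(log_inc, [0.25, 0.5, 0.75],
                                 method="inverted_cdf")
        quart = 1 + (log_inc > q1) + (log_inc > q2) + (log_inc > q3)

        groups_unique, first_pos = np.unique(group, return_index=True)
        u_by_group = dict(zip(
            groups_unique, rng.normal(0, cfg.sigma_u, groups_unique.size)))
        truth = pd.DataFrame({
            "id": df["id"],
            "wave": wave,
            "log_income": log_inc,
            "true_quartile": quart.astype(int),
            "u": df["group_id"].map(u_by_group).to_numpy(),
        })
        frames.append(df)
        truths.append(truth)

    records = pd.concat(frames, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)

    # placeholder utilization columns so the frame is schema-complete
    for s in schema.SERVICES:
        records[f"{s}_count"] = 0
        records[f"{s}_private"] = pd.array([pd.NA] * len(records),
                                           dtype="Int64")
    for s in schema.FOUR_WEEK_SERVICES:
        records[f"{s}_delayed"] = pd.array([pd.NA] * len(records),
                                           dtype="Int64")
    for col in schema.MEDICINE_COLS:
        records[col] = 0
    return records[list(schema.COLUMNS)], truth


def simulate_utilization(records: pd.DataFrame, truth: pd.DataFrame,
                         config: GeneratorConfig):
    """Fill utilization responses by inverting the analysis model.

    For each service: annual use from the Bernoulli hurdle, annual frequency
    from the zero-truncated NB1, both with the household random effect in the
    linear predictor; each contact's ownership i.i.d. from the ownership
    model (the last contact's ownership is what the survey records); annual
    counts of 4-week-recall services thinned into the window with probability
    ``thin_prob`` per contact; the delay indicator drawn for recorded users.
    """
    cfg = config.validate()
    rng = np.random.default_rng([cfg.seed, 2])
    records = records.copy()
    truth = truth.copy()
    n = len(records)
    work = records.copy()
    work["income_quartile"] = truth["true_quartile"].to_numpy()
    u = truth["u"].to_numpy()

    for service, params in cfg.services.items():
        eta1 = _linear_predictor(work, params.beta1) + u
        use = rng.random(n) < expit(eta1)
        annual = np.zeros(n, dtype=np.int64)
        if use.any():
            mu2 = np.exp(np.clip(
                _linear_predictor(work.loc[use], params.beta2) + u[use],
                -30, 30))
            annual[use] = ztnb_rvs(mu2, params.phi, rng)

        p_priv = expit(_linear_predictor(work, cfg.ownership_coefs[service]))
        private_annual = rng.binomial(annual, p_priv)
        last_private = rng.random(n) < p_priv  # ownership of the last contact

        if service in schema.FOUR_WEEK_SERVICES:
            recorded = rng.binomial(annual, cfg.thin_prob)
        else:
            recorded = annual
        records[f"{service}_count"] = recorded
        flag = pd.array([pd.NA] * n, dtype="Int64")
        has = recorded >= 1
        flag[has] = last_private[has].astype(int)
        records[f"{service}_private"] = flag

        if service in schema.FOUR_WEEK_SERVICES:
            p_delay = expit(_linear_predictor(work, cfg.delay_coefs[service]))
            delayed = pd.array([pd.NA] * n, dtype="Int64")
            delayed[has] = (rng.random(n)[has] < p_delay[has]).astype(int)
            records[f"{service}_delayed"] = delayed

        truth[f"{service}_annual"] = annual
        truth[f"{service}_annual_private"] = private_annual
        truth[f"{service}_p_private"] = p_priv

    # medicine items: 22 binary indicators; the contraceptive item only for
    # younger women
    chronic = np.minimum(records["chronic_count"].to_numpy(), 6)
    ghq = records["ghq12"].to_numpy(dtype=float)
    p_item = expit(-2.6 + 0.3 * chronic + 0.05 * ghq)
    for i, col in enumerate(schema.MEDICINE_COLS, start=1):
        if i == schema.CONTRACEPTIVE_ITEM:
            eligible = ((records["sex"] == "female")
                        & records["age_band"].isin(schema.AGE_LEVELS[:2]))
            p = np.where(eligible, 0.15, 0.005)
        else:
            p = p_item
        records[col] = (rng.random(n) < p).astype(int)

    if cfg.missing_rate > 0:
        for col in ("ghq12", "sph", "chronic_count", "insurance"):
            mask = rng.random(n) < cfg.missing_rate
            records.loc[mask, col] = (pd.NA if records[col].dtype == "Int64"
                                      else np.nan)
    return records, truth


def generate_survey(config: GeneratorConfig):
    """Convenience: :func:`generate_population` then
    :func:`simulate_utilization`."""
    records, truth = generate_population(config)
    return simulate_utilization(records, truth, config)
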