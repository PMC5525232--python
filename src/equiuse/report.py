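"""Descriptive and model-based inequality outputs.

Descriptive tables stratify annual utilization by within-wave income
quartile and compare waves cell by cell: Wilcoxon rank-sum (Mann-Whitney)
p-values for count/continuous variables, Fisher exact p-values for binary
ones, and the percent change of the mean.  No multiple-testing correction is
applied; raw p-values are reported.

The model sequence fits three nested hurdle models per service, ownership
and wave: Model 1 has income quartiles only, Model 2 adds gender and age,
Model 3 adds private insurance and GHQ-12 — so that the income effect can be
read before and after adjustment for need and double cover.  Quartile
effects are reported as odds ratios (part 1) and rate ratios (part 2)
against the poorest quartile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import schema
from .design import MODEL_TERMS
from .exceptions import DataError, FitError
from .hurdle import HurdleSpec, fit_hurdle, rate_ratio

__all__ = ["percent_change", "descriptive_table", "run_model_sequence",
           "run_pipeline", "ModelSequenceResult"]

#: variables summarized in the descriptive table: (name, kind)
_DESCRIPTIVE_VARS = (
    [(f"{s}_year_{own}", "count")
     for s in schema.SERVICES for own in ("total", "public", "private")]
    + [("medicines", "count"), ("insurance", "binary")]
)


def percent_change(mean_pre: float, mean_post: float) -> float:
    """Signed percent change between wave means; NaN when the baseline is 0."""
    if mean_pre == 0:
        return float("nan")
    return (mean_post - mean_pre) / mean_pre * 100.0


def _wave_test(pre: np.ndarray, post: np.ndarray, kind: str):
    if len(pre) == 0 or len(post) == 0:
        return np.nan, "none"
    if kind == "binary":
        table = [[int((pre == 1).sum()), int((pre == 0).sum())],
                 [int((post == 1).sum()), int((post == 0).sum())]]
        return float(stats.fisher_exact(table)[1]), "fisher"
    if np.ptp(np.r_[pre, post]) == 0:
        return 1.0, "wilcoxon"
    return float(stats.mannwhitneyu(pre, post, alternative="two-sided")[1]), "wilcoxon"


def descriptive_table(records: pd.DataFrame, variables=None) -> pd.DataFrame:
    """Quartile x wave summary with wave-comparison tests.

    One row per variable x quartile (quartile 0 = all respondents): n, mean
    and SD per wave, percent change of the mean, test p-value and test name.
    Empty cells are kept and flagged, never dropped silently.
    """
    if set(records["wave"].unique()) != set(schema.WAVES):
        raise DataError("descriptive_table needs both waves")
    if "income_quartile" not in records.columns:
        raise DataError("assign income quartiles first")
    variables = variables or _DESCRIPTIVE_VARS
    rows = []
    for var, kind in variables:
        values = pd.to_numeric(records[var])
        for quartile in (0, 1, 2, 3, 4):
            mask = (records["income_quartile"] == quartile
                    if quartile else np.ones(len(records), dtype=bool))
            cell = {}
            for wave in schema.WAVES:
                v = values[mask & (records["wave"] == wave)].dropna().to_numpy()
                cell[wave] = v
            p, test = _wave_test(cell[2006], cell[2011], kind)
            empty = any(len(cell[w]) == 0 for w in schema.WAVES)
            rows.append({
                "variable": var,
                "quartile": quartile,
                "n_2006": len(cell[2006]),
                "mean_2006": cell[2006].mean() if len(cell[2006]) else np.nan,
                "sd_2006": cell[2006].std(ddof=1) if len(cell[2006]) > 1 else np.nan,
                "n_2011": len(cell[2011]),
                "mean_2011": cell[2011].mean() if len(cell[2011]) else np.nan,
                "sd_2011": cell[2011].std(ddof=1) if len(cell[2011]) > 1 else np.nan,
                "pct_change": (percent_change(cell[2006].mean(), cell[2011].mean())
                               if not empty else np.nan),
                "p_value": p,
                "test": test,
                "empty": empty,
            })
    return pd.DataFrame(rows)


def format_descriptive_table(table: pd.DataFrame) -> pd.DataFrame:
    """Printed rounding: 3 decimals for means/SDs, 1 for percent changes,
    3 for p-values."""
    out = table.copy()
    for col in ("mean_2006", "sd_2006", "mean_2011", "sd_2011", "p_value"):
        out[col] = out[col].round(3)
    out["pct_change"] = out["pct_change"].round(1)
    return out


@dataclass
class ModelSequenceResult:
    """Model 1-3 fits for one service x ownership x wave."""

    service: str
    ownership: str
    wave: int
    fits: dict = field(default_factory=dict)       # model number -> HurdleCountModel
    ratios: pd.DataFrame | None = None             # quartile effects vs Q1
    errors: dict = field(default_factory=dict)     # model number -> message


def _quartile_ratios(fits: dict) -> pd.DataFrame:
    rows = []
    for model, fit in fits.items():
        for part in (1, 2):
            coefs = fit.coef_hurdle_ if part == 1 else fit.coef_count_
            for q in ("q2", "q3", "q4"):
                if q not in coefs.index:
                    continue
                rr = rate_ratio(fit, {q: 1.0}, part=part)
                rows.append({"model": model, "part": part, "quartile": q,
                             "ratio": rr.ratio, "lower": rr.lower,
                             "upper": rr.upper, "scale": rr.scale})
    return pd.DataFrame(rows)


def run_model_sequence(records: pd.DataFrame, service: str,
                       ownership: str = "total", group_col: str | None = None,
                       models=(1, 2, 3)) -> dict:
    """Fit the nested Model 1-3 hurdle sequence per wave.

    ``service`` is one of the four services or ``'medicines'`` (total only).
    Returns ``{wave: ModelSequenceResult}``; per-model fit failures are
    recorded as structured errors, not raised, so a degenerate cell (e.g. no
    private users in a wave) leaves the rest of the table intact.
    """
    if service == "medicines":
        if ownership != "total":
            raise DataError("drug consumption is analyzed as total only")
        response = "medicines"
    else:
        if service not in schema.SERVICES:
            raise DataError(f"unknown service '{service}'")
        if ownership not in ("total", "public", "private"):
            raise DataError(f"unknown ownership '{ownership}'")
        response = f"{service}_year_{ownership}"
    out = {}
    for wave in sorted(records["wave"].unique()):
        sub = records[records["wave"] == wave]
        result = ModelSequenceResult(service=service, ownership=ownership,
                                     wave=int(wave))
        for model in models:
            spec = HurdleSpec(response=response, x1_terms=list(MODEL_TERMS[model]),
                              group_col=group_col)
            try:
                result.fits[model] = fit_hurdle(sub, spec)
            except (DataError, FitError) as exc:
                result.errors[model] = (
                    f"{service}/{ownership}/wave {wave}/model {model}: {exc}")
        result.ratios = _quartile_ratios(result.fits)
        out[int(wave)] = result
    return out


def run_pipeline(records: pd.DataFrame):
    """Standardize income, split ownership, annualize counts.

    Returns ``(processed, stages)`` where ``processed`` carries
    ``income_score``/``income_quartile``, raw splits and
    ``{service}_year_{total,public,private}`` plus ``medicines`` columns, and
    ``stages`` holds the fitted transformers.
    """
    from .counts import CountAnnualizer
    from .income import IncomeStandardizer
    from .ownership import OwnershipImputer

    stages = {}
    stages["income"] = IncomeStandardizer().fit(records)
    out = stages["income"].transform(records)
    stages["ownership"] = OwnershipImputer().fit(out)
    out = stages["ownership"].transform(out)
    stages["annualizer"] = CountAnnualizer(ownership=stages["ownership"]).fit(out)
    out = stages["annualizer"].transform(out)
    return out, stages
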