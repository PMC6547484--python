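"""Between-survey comparison tests and survey-weighted logistic regression.

Two concentration indices from independent surveys are compared with a
normal two-sample statistic ``|CI_a - CI_b| / sqrt(SE_a^2 + SE_b^2)``.
Institutional delivery is modelled with weighted binary logistic regression
(one single-covariate model per covariate for the unadjusted odds ratios,
all covariates jointly for the adjusted ones), and the rich-poor odds
ratios of two surveys are compared on the odds-ratio scale with a one-sided
normal test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .concentration import ConcentrationEstimate

__all__ = [
    "ComparisonTest",
    "LogisticFit",
    "ci_difference_test",
    "fit_delivery_model",
    "or_equality_test",
    "wald_interval",
    "DELIVERY_COVARIATES",
    "REFERENCE_LEVELS",
]

#: covariates of the institutional-delivery model, in table order
DELIVERY_COVARIATES = [
    "wealth_quintile",
    "education",
    "occupation",
    "residence",
    "ethnicity",
    "religion",
    "age_band",
    "n_children",
]

#: reference level of each categorical covariate (odds ratio fixed at 1)
REFERENCE_LEVELS = {
    "wealth_quintile": "poorest",
    "education": "none",
    "occupation": "no",
    "residence": "urban",
    "ethnicity": "group_A",
    "religion": "christianity",
    "age_band": "15-19",
}


@dataclass(frozen=True)
class ComparisonTest:
    """A two-group normal test: statistic, p-value, sidedness, inputs."""

    statistic: float
    p_value: float
    sided: Literal["one", "two"]
    inputs: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _normal_test(a: float, se_a: float, b: float, se_b: float,
                 sided: Literal["one", "two"]) -> ComparisonTest:
    denom = float(np.hypot(se_a, se_b))
    if denom == 0.0:
        raise ValueError("both standard errors are zero; test undefined")
    z = abs(a - b) / denom
    p = float(norm.sf(z)) if sided == "one" else float(2.0 * norm.sf(z))
    return ComparisonTest(statistic=float(z), p_value=min(p, 1.0), sided=sided,
                          inputs=((a, se_a), (b, se_b)))


def ci_difference_test(
    est_a: ConcentrationEstimate,
    est_b: ConcentrationEstimate,
    sided: Literal["one", "two"] = "two",
) -> ComparisonTest:
    """Normal test for the difference of two concentration indices.

    Both estimates must carry standard errors (i.e. come from the convenient
    regression, not the area method).
    """
    for est in (est_a, est_b):
        if est.standard_error is None:
            raise ValueError(f"estimate from the {est.method} method carries no "
                             "standard error; use the regression estimator")
    return _normal_test(est_a.estimate, est_a.standard_error,
                        est_b.estimate, est_b.standard_error, sided)


def or_equality_test(
    or_a: float,
    se_a: float,
    or_b: float,
    se_b: float,
    sided: Literal["one", "two"] = "one",
    scale: Literal["or", "log"] = "or",
) -> ComparisonTest:
    """Test equality of two odds ratios.

    By default the comparison is on the raw odds-ratio scale with the
    standard errors given on that same scale, and the p-value is the
    one-sided upper-tail normal probability.  ``scale='log'`` converts the
    inputs to log-odds via the delta method (SE_log = SE / OR) and tests on
    the log scale instead.
    """
    if or_a <= 0 or or_b <= 0:
        raise ValueError("odds ratios must be positive")
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be non-negative")
    if scale == "log":
        return _normal_test(np.log(or_a), se_a / or_a, np.log(or_b), se_b / or_b, sided)
    return _normal_test(or_a, se_a, or_b, se_b, sided)


def wald_interval(estimate: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation confidence bounds ``estimate ± z * SE``."""
    z = float(norm.ppf(0.5 + level / 2.0))
    return estimate - z * se, estimate + z * se


@dataclass(frozen=True)
class LogisticFit:
    """Odds-ratio table from a weighted binary logistic regression.

    ``table`` has one row per non-reference covariate level (plus the
    reference rows with OR fixed at 1) with columns ``covariate``, ``level``,
    ``odds_ratio``, ``or_se``, ``ci_low``, ``ci_high``, ``p_value``.
    """

    table: pd.DataFrame
    adjusted: bool
    reference_levels: dict

    def odds_ratio(self, covariate: str, level: str) -> pd.Series:
        mask = (self.table["covariate"] == covariate) & (self.table["level"] == level)
        if not mask.any():
            raise KeyError(f"{covariate}={level} not in the fitted table")
        return self.table.loc[mask].iloc[0]


def _categorical_design(records: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        if cov not in REFERENCE_LEVELS:  # continuous term (n_children, wealth_rank, ...)
            cols[cov] = records[cov].astype(float)
            continue
        ref = REFERENCE_LEVELS[cov]
        col = records[cov]
        if isinstance(col.dtype, pd.CategoricalDtype):
            ordered = [str(c) for c in col.cat.categories]
        else:
            ordered = sorted(pd.unique(col.astype(str)))
        values = col.astype(str)
        levels = [lv for lv in ordered if lv != ref and (values == lv).any()]
        for lv in levels:
            cols[f"{cov}[{lv}]"] = (values == lv).astype(float)
    return pd.DataFrame(cols, index=records.index)


def _fit_weighted_logit(y: np.ndarray, X: pd.DataFrame, w: np.ndarray,
                        robust: bool):
    X = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w)
    try:
        fit = model.fit(cov_type="HC1" if robust else "nonrobust")
    except Exception as exc:  # pragma: no cover - perfect-separation paths
        raise ValueError(f"logistic fit failed (possible separation): {exc}") from exc
    if not np.all(np.isfinite(fit.bse)) or np.any(fit.bse > 1e3):
        bad = [c for c, s in fit.bse.items() if not np.isfinite(s) or s > 1e3]
        raise ValueError(f"separation or degenerate fit for term(s) {bad}")
    return fit


def fit_delivery_model(
    records: pd.DataFrame,
    weights,
    adjusted: bool,
    outcome: str = "delivered_in_facility",
    covariates: Sequence[str] = tuple(DELIVERY_COVARIATES),
    robust: bool = False,
) -> LogisticFit:
    """Weighted logistic regression of institutional delivery.

    ``adjusted=True`` fits all covariates jointly; ``adjusted=False`` fits one
    single-covariate model per covariate.  Survey weights are applied as
    frequency-style weights normalized to sum to the number of records, so
    the variance carries no design effect; ``robust=True`` switches to
    sandwich (HC1) standard errors.
    """
    y = records[outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"{outcome} must be binary 0/1")
    if y.min() == y.max():
        raise ValueError(f"{outcome} is constant; logistic model undefined")
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("all weights must be positive")
    w = w * (len(w) / w.sum())

    rows = []
    blocks = ([covariates] if adjusted else [[c] for c in covariates])
    for block in blocks:
        X = _categorical_design(records, block)
        fit = _fit_weighted_logit(y, X, w, robust)
        for cov in block:
            if cov in REFERENCE_LEVELS:
                ref = REFERENCE_LEVELS[cov]
                rows.append(dict(covariate=cov, level=ref, odds_ratio=1.0,
                                 or_se=0.0, ci_low=1.0, ci_high=1.0,
                                 p_value=np.nan))
            for name in X.columns:
                if cov not in REFERENCE_LEVELS:
                    if name != cov:
                        continue
                    level = cov
                elif name.startswith(f"{cov}["):
                    level = name[len(cov) + 1:-1]
                else:
                    continue
                beta = float(fit.params[name])
                se_beta = float(fit.bse[name])
                orr = float(np.exp(beta))
                lo, hi = np.exp(wald_interval(beta, se_beta))
                # Wald p for the coefficient (two-sided normal)
                p = float(2.0 * norm.sf(abs(beta) / se_beta)) if se_beta > 0 else np.nan
                rows.append(dict(covariate=cov, level=level, odds_ratio=orr,
                                 or_se=orr * se_beta, ci_low=float(lo),
                                 ci_high=float(hi), p_value=p))
    table = pd.DataFrame(rows)
    return LogisticFit(table=table, adjusted=adjusted,
                       reference_levels=dict(REFERENCE_LEVELS))
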