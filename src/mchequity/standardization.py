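"""Covariate-standardized (adjusted) concentration index.

The adjusted CI isolates the wealth gradient in a health variable from
confounding demographics: a weighted prediction model regresses the outcome
on wealth terms plus control covariates, each record is then re-predicted
with its own wealth terms but every control frozen at its weighted mean, and
the CI of those adjusted values is reported.

The standard error comes from a second weighted regression of the
(untransformed) adjusted outcome on the transformed living-standard
regressor ``RWealth_i = (mu / (2 var_w(r))) * r_i``: rescaling the rank by
the inverse of the convenient-regression outcome transform makes the slope
of that regression equal the CI itself, so its slope standard error serves
directly as the CI standard error.  The rank variance depends only on the
weights and is treated as a constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .concentration import (
    ConcentrationEstimate,
    RankedOutcome,
    _wls_slope,
    weighted_rank_variance,
)

__all__ = ["PredictionModel", "fit_prediction_model", "predict_at_means", "ci_adjusted"]

Link = Literal["identity", "logit", "log"]

_FAMILIES = {
    "identity": lambda: sm.families.Gaussian(sm.families.links.Identity()),
    "logit": lambda: sm.families.Binomial(sm.families.links.Logit()),
    "log": lambda: sm.families.Poisson(sm.families.links.Log()),
}


@dataclass(frozen=True)
class PredictionModel:
    """A fitted weighted prediction model for the health variable.

    Holds the intercept, the coefficients for the wealth terms and for the
    control covariates, the link, and the weighted means of the controls
    (computed with the same weights as the fit).
    """

    intercept: float
    wealth_coef: pd.Series
    control_coef: pd.Series
    control_means: pd.Series
    link: Link

    def __post_init__(self) -> None:
        if not self.control_coef.index.equals(self.control_means.index):
            raise ValueError("control coefficients and means must share an index")


def _design(frame: pd.DataFrame) -> pd.DataFrame:
    """Expand categorical columns into treatment-coded indicators."""
    if frame.shape[1] == 0:
        return frame.astype(float)
    out = pd.get_dummies(frame, drop_first=True, dtype=float)
    return out


def fit_prediction_model(
    h,
    wealth_terms: pd.DataFrame,
    controls: pd.DataFrame,
    weights,
    link: Link = "identity",
) -> PredictionModel:
    """Weighted fit of the outcome on wealth terms plus control covariates.

    ``wealth_terms`` is a DataFrame of the living-standard regressors
    (quintile indicators by default upstream; a continuous score or the
    fractional rank work equally).  Categorical columns in either block are
    expanded to treatment-coded indicators.  ``link`` selects a Gaussian
    (identity), binomial (logit) or Poisson (log) weighted fit.
    """
    h = np.asarray(h, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("all weights must be positive")
    Xw = _design(wealth_terms.reset_index(drop=True))
    Xc = _design(controls.reset_index(drop=True))
    X = pd.concat([Xw, Xc], axis=1)
    X.insert(0, "const", 1.0)
    rank = np.linalg.matrix_rank(X.to_numpy() * np.sqrt(w)[:, None])
    if rank < X.shape[1]:
        # name the offending columns for the caller
        bad = [c for c in X.columns[1:]
               if np.isclose(X[c].to_numpy().std(), 0.0)]
        raise ValueError(
            "rank-deficient design"
            + (f": zero-variance column(s) {bad}" if bad else ": collinear columns")
        )
    if link == "identity":
        fit = sm.WLS(h, X, weights=w).fit()
    else:
        fit = sm.GLM(h, X, family=_FAMILIES[link](), freq_weights=w).fit()
    params = fit.params
    wn = w / w.sum()
    control_means = pd.Series(
        {c: float(np.sum(wn * Xc[c].to_numpy())) for c in Xc.columns}, dtype=float
    )
    return PredictionModel(
        intercept=float(params["const"]),
        wealth_coef=params[list(Xw.columns)].astype(float),
        control_coef=params[list(Xc.columns)].astype(float),
        control_means=control_means,
        link=link,
    )


def _inverse_link(eta: np.ndarray, link: Link) -> np.ndarray:
    if link == "identity":
        return eta
    if link == "logit":
        return 1.0 / (1.0 + np.exp(-eta))
    return np.exp(eta)


def predict_at_means(model: PredictionModel, wealth_terms: pd.DataFrame) -> np.ndarray:
    """Per-record predictions with controls replaced by their weighted means.

    Each record keeps its own wealth terms; every control enters at the
    weighted mean stored in the model.  Identity-link predictions may be
    negative; they are reported as-is, not clipped.
    """
    Xw = _design(wealth_terms.reset_index(drop=True))
    missing = set(model.wealth_coef.index) - set(Xw.columns)
    if missing:
        raise ValueError(f"wealth terms missing columns {sorted(missing)}")
    eta = (
        model.intercept
        + Xw[list(model.wealth_coef.index)].to_numpy() @ model.wealth_coef.to_numpy()
        + float(model.control_coef @ model.control_means)
    )
    return _inverse_link(np.asarray(eta, dtype=float), model.link)


def ci_adjusted(
    ranked: RankedOutcome,
    adjusted_h: np.ndarray,
    robust: bool = False,
    mode: Literal["direct", "indirect"] = "direct",
    controls: Sequence[str] = (),
) -> ConcentrationEstimate:
    """Adjusted CI of the standardized outcome values, with standard error.

    Parameters
    ----------
    ranked : the ranked outcome object carrying weights and fractional ranks
        (its ``h`` is the raw outcome; only ``w`` and ``r`` are reused here).
    adjusted_h : the ``predict_at_means`` values, aligned with ``ranked``.
    mode : ``direct`` takes the CI of the adjusted values themselves;
        ``indirect`` takes the CI of ``h - h_hat + hbar`` (the classical
        indirectly standardized outcome), using ``ranked.h`` as the raw h.
    """
    y = np.asarray(adjusted_h, dtype=float)
    if y.shape != ranked.w.shape:
        raise ValueError("adjusted values must align with the ranked outcome")
    if mode == "indirect":
        y = ranked.h - y + float(np.sum(ranked.w * y))
    mu = float(np.sum(ranked.w * y))
    if mu <= 0:
        raise ValueError("adjusted CI undefined: weighted mean of adjusted values "
                         f"is not positive ({mu:.6g})")
    var_r = weighted_rank_variance(ranked)
    if var_r <= 0:
        raise ValueError("degenerate rank variance")
    rwealth = (mu / (2.0 * var_r)) * ranked.r
    slope, se = _wls_slope(y, rwealth, ranked.w, robust=robust)
    # point estimate via the covariance formula (identical to the slope up to
    # float round-off; asserted in the property suite)
    rbar = float(np.sum(ranked.w * ranked.r))
    est = 2.0 / mu * float(np.sum(ranked.w * y * (ranked.r - rbar)))
    return ConcentrationEstimate(
        estimate=est,
        standard_error=se,
        method="regression",
        adjusted=True,
        n=ranked.n,
        controls=tuple(controls),
    )
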