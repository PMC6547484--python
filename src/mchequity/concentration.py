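"""Concentration curves and concentration indices for weighted survey data.

The concentration index (CI) measures wealth-rank-related inequality in a
health variable h: it is twice the weighted covariance between h and the
fractional wealth rank r, divided by the mean of h, and equivalently twice
the area between the concentration curve and the 45-degree line of equality.
Positive values indicate concentration among the rich (the curve lies below
the line of equality).

Three mutually checking estimators are provided:

``ci_covariance``
    the covariance formula ``(2/mu) * sum_i w_i h_i (r_i - rbar)`` — no
    standard error, used as the algebraic oracle;
``ci_regression``
    the "convenient regression": weighted least squares of the transformed
    outcome ``2 * var_w(r) * h_i / mu`` on ``r_i``, whose slope equals the
    covariance formula exactly and whose slope standard error provides
    inference;
``ci_area``
    one minus twice the trapezoid area under the concentration curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

__all__ = [
    "RankedOutcome",
    "ConcentrationCurve",
    "ConcentrationEstimate",
    "fractional_rank",
    "rank_outcome",
    "weighted_rank_variance",
    "curve_points",
    "ci_area",
    "ci_regression",
    "ci_covariance",
    "dominance",
]

_WEIGHT_SUM_TOL = 1e-8


@dataclass(frozen=True)
class RankedOutcome:
    """An outcome vector aligned with normalized weights and fractional
    wealth ranks, in ascending wealth order, ready for CI estimation.

    Attributes
    ----------
    h : outcome values (non-negative).
    w : normalized sampling weights, summing to one.
    r : fractional wealth ranks in (0, 1); tied wealth scores share the
        average mid-rank of their block.
    mu : weighted mean of ``h`` (must be positive for a defined CI).
    """

    h: np.ndarray
    w: np.ndarray
    r: np.ndarray
    mu: float

    def __post_init__(self) -> None:
        for name in ("h", "w", "r"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.h.shape == self.w.shape == self.r.shape):
            raise ValueError("h, w and r must have identical shapes")
        if abs(self.w.sum() - 1.0) > _WEIGHT_SUM_TOL:
            raise ValueError(f"weights must sum to 1 (got {self.w.sum():.12g})")
        if np.any(self.w <= 0):
            raise ValueError("all weights must be positive")
        if np.any((self.r <= 0) | (self.r >= 1)):
            raise ValueError("fractional ranks must lie strictly inside (0, 1)")

    @property
    def n(self) -> int:
        return self.h.size


@dataclass(frozen=True)
class ConcentrationCurve:
    """Ordered (cumulative population share, cumulative outcome share) points.

    Starts at (0, 0) and ends at (1, 1); both coordinates are non-decreasing.
    """

    p: np.ndarray
    L: np.ndarray
    grouping: Literal["individual", "quintile"] = "individual"

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        L = np.asarray(self.L, dtype=float)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "L", L)
        if p.shape != L.shape or p.ndim != 1 or p.size < 2:
            raise ValueError("curve needs matched 1-d p and L with >= 2 points")
        if not (np.isclose(p[0], 0) and np.isclose(L[0], 0)
                and np.isclose(p[-1], 1) and np.isclose(L[-1], 1)):
            raise ValueError("curve must run from (0,0) to (1,1)")
        if np.any(np.diff(p) < -1e-12) or np.any(np.diff(L) < -1e-12):
            raise ValueError("curve coordinates must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"population_share": self.p, "outcome_share": self.L})


@dataclass(frozen=True)
class ConcentrationEstimate:
    """A concentration-index point estimate with optional standard error."""

    estimate: float
    standard_error: Optional[float]
    method: Literal["area", "regression", "covariance"]
    adjusted: bool = False
    n: int = 0
    controls: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if abs(self.estimate) > 1 + 1e-9:
            raise ValueError(f"|CI| must be <= 1 (got {self.estimate})")
        if self.standard_error is not None and self.standard_error < 0:
            raise ValueError("standard error must be non-negative")

    def confidence_interval(self, level: float = 0.95) -> tuple[float, float]:
        """Normal-approximation confidence bounds ``estimate ± z * SE``."""
        from scipy.stats import norm

        if self.standard_error is None:
            raise ValueError(f"the {self.method} estimator carries no standard error")
        z = norm.ppf(0.5 + level / 2.0)
        return (self.estimate - z * self.standard_error,
                self.estimate + z * self.standard_error)


def fractional_rank(sorted_weights: np.ndarray) -> np.ndarray:
    """Weighted mid-ranks ``r_i = sum_{j<i} w_j + w_i / 2``.

    Parameters
    ----------
    sorted_weights : normalized weights given in ascending wealth order,
        summing to one.
    """
    w = np.asarray(sorted_weights, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValueError("weights must be a non-empty 1-d array")
    if np.any(w <= 0):
        raise ValueError("all weights must be positive")
    if abs(w.sum() - 1.0) > _WEIGHT_SUM_TOL:
        raise ValueError(f"weights must sum to 1 (got {w.sum():.12g})")
    return np.cumsum(w) - w / 2.0


def rank_outcome(h, wealth, weights) -> RankedOutcome:
    """Sort records by wealth, normalize weights, and compute fractional ranks.

    Tied wealth scores receive the average mid-rank of their tied block, so
    the result is invariant to the input ordering of tied records.
    """
    h = np.asarray(h, dtype=float)
    wealth = np.asarray(wealth, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (h.shape == wealth.shape == w.shape) or h.ndim != 1:
        raise ValueError("h, wealth and weights must be matched 1-d arrays")
    if np.any(w <= 0):
        raise ValueError("all weights must be positive")
    if np.any(h < 0):
        raise ValueError("outcome values must be non-negative")
    order = np.argsort(wealth, kind="stable")
    h, wealth, w = h[order], wealth[order], w[order]
    w = w / w.sum()
    r = fractional_rank(w)
    # average mid-ranks over blocks of tied wealth scores
    if wealth.size > 1:
        block_start = np.flatnonzero(np.r_[True, np.diff(wealth) != 0])
        block_id = np.cumsum(np.r_[1, np.diff(wealth) != 0]) - 1
        if block_start.size < wealth.size:
            wsum = np.bincount(block_id, weights=w)
            wrsum = np.bincount(block_id, weights=w * r)
            r = (wrsum / wsum)[block_id]
    mu = float(np.sum(w * h))
    return RankedOutcome(h=h, w=w, r=r, mu=mu)


def weighted_rank_variance(ranked: RankedOutcome) -> float:
    """Weighted variance of the fractional rank, ``sum_i w_i (r_i - rbar)^2``."""
    rbar = float(np.sum(ranked.w * ranked.r))
    return float(np.sum(ranked.w * (ranked.r - rbar) ** 2))


def curve_points(
    ranked: RankedOutcome,
    grouping: Literal["individual", "quintile"] = "individual",
) -> ConcentrationCurve:
    """Concentration-curve points from a ranked outcome.

    ``individual`` grouping accumulates record by record; ``quintile``
    accumulates over five weighted wealth quintiles (six curve points),
    matching the curve one would draw from a quintile table.
    """
    if ranked.mu <= 0:
        raise ValueError("concentration curve undefined: weighted mean of h is not positive")
    cum_w = np.cumsum(ranked.w)
    cum_hw = np.cumsum(ranked.w * ranked.h) / ranked.mu
    if grouping == "individual":
        p = np.r_[0.0, cum_w]
        L = np.r_[0.0, cum_hw]
    elif grouping == "quintile":
        # cumulative shares at the quintile boundaries, by linear interpolation
        # on the individual-level curve
        p = np.r_[0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
        L = np.interp(p, np.r_[0.0, cum_w], np.r_[0.0, cum_hw])
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    p[-1], L[-1] = 1.0, 1.0  # clamp float round-off at the endpoint
    return ConcentrationCurve(p=p, L=L, grouping=grouping)


def ci_area(curve: ConcentrationCurve) -> ConcentrationEstimate:
    """CI as one minus twice the trapezoid area under the concentration curve.

    Carries no standard error; positive when the curve lies below the line of
    equality (pro-rich concentration).
    """
    area = float(np.trapezoid(curve.L, curve.p))
    return ConcentrationEstimate(
        estimate=1.0 - 2.0 * area,
        standard_error=None,
        method="area",
        n=curve.p.size - 1,
    )


def ci_covariance(ranked: RankedOutcome) -> ConcentrationEstimate:
    """Covariance-formula CI: ``(2/mu) * sum_i w_i h_i (r_i - rbar)``."""
    if ranked.mu <= 0:
        raise ValueError("CI undefined: weighted mean of h is not positive")
    rbar = float(np.sum(ranked.w * ranked.r))
    est = 2.0 / ranked.mu * float(np.sum(ranked.w * ranked.h * (ranked.r - rbar)))
    return ConcentrationEstimate(estimate=est, standard_error=None,
                                 method="covariance", n=ranked.n)


def ci_regression(ranked: RankedOutcome, robust: bool = False) -> ConcentrationEstimate:
    """Convenient-regression CI with a standard error.

    Weighted least squares of ``y_i = 2 var_w(r) h_i / mu`` on ``r_i`` with
    weights ``w_i``; the slope equals the covariance-formula CI exactly.  The
    default standard error is the conventional WLS slope error; ``robust``
    switches to the HC0 heteroskedasticity-robust sandwich.
    """
    if ranked.mu <= 0:
        raise ValueError("CI undefined: weighted mean of h is not positive")
    var_r = weighted_rank_variance(ranked)
    if var_r <= 0:
        raise ValueError("degenerate rank variance: all records share one rank")
    y = 2.0 * var_r * ranked.h / ranked.mu
    est, se = _wls_slope(y, ranked.r, ranked.w, robust=robust)
    return ConcentrationEstimate(estimate=est, standard_error=se,
                                 method="regression", n=ranked.n)


def _wls_slope(y: np.ndarray, x: np.ndarray, w: np.ndarray,
               robust: bool = False) -> tuple[float, float]:
    """Slope and slope standard error of a weighted simple regression.

    Closed form: with weighted means removed, slope = S_xy / S_xx.  The
    conventional error uses sigma^2 = (sum w e^2) / (n - 2) in the weighted
    metric; HC0 uses the sandwich sum w^2 e^2 x~^2 / S_xx^2.
    """
    w = w / w.sum()
    xbar = float(np.sum(w * x))
    ybar = float(np.sum(w * y))
    xc = x - xbar
    yc = y - ybar
    sxx = float(np.sum(w * xc * xc))
    if sxx <= 0:
        raise ValueError("degenerate regressor: zero weighted variance")
    slope = float(np.sum(w * xc * yc)) / sxx
    resid = yc - slope * xc
    n = y.size
    if robust:
        se2 = float(np.sum((w * xc * resid) ** 2)) / sxx**2
    else:
        dof = max(n - 2, 1)
        sigma2 = float(np.sum(w * resid * resid)) * n / dof
        se2 = sigma2 / (n * sxx)
    return slope, float(np.sqrt(se2))


def dominance(
    curve_a: ConcentrationCurve,
    curve_b: ConcentrationCurve,
    tol: float = 1e-9,
) -> str:
    """Classify the relation between two concentration curves.

    Returns one of ``a_dominates`` (curve a weakly above b everywhere,
    strictly somewhere — a closer to the line of equality from below),
    ``b_dominates``, ``cross`` (the sign of the ordinate difference changes
    beyond ``tol``), or ``coincide``.  Curves are linearly interpolated onto
    the union of their abscissae before comparison.
    """
    grid = np.union1d(curve_a.p, curve_b.p)
    La = np.interp(grid, curve_a.p, curve_a.L)
    Lb = np.interp(grid, curve_b.p, curve_b.L)
    diff = La - Lb
    above = bool(np.any(diff > tol))
    below = bool(np.any(diff < -tol))
    if above and below:
        return "cross"
    if above:
        return "a_dominates"
    if below:
        return "b_dominates"
    return "coincide"
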