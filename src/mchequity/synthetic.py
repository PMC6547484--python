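"""DHS-like synthetic survey generator with configurable wealth gradients.

Emulates a two-stage cluster design: enumeration areas (EAs) are drawn with
probability proportional to their listed household count within urban/rural
strata, then a fixed number of households is sampled per EA; one woman with
a recent birth is interviewed per sampled household.  Sampling weights are
the product of the two inverse selection probabilities, normalized to mean
one.

A continuous wealth index is drawn log-normally with an additive urban
location shift, and the three outcomes are generated from generalized
linear models whose linear predictors carry a configurable wealth-rank
gradient plus fixed covariate effects: antenatal visit counts are Poisson
(log link), the four postnatal review components and facility delivery are
Bernoulli (logit link).  A bisection calibrator maps a target concentration
index to the gradient that produces it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .concentration import rank_outcome, ci_covariance

__all__ = [
    "PopulationConfig",
    "generate_population",
    "calibrate_gradient_to_ci",
    "write_records",
    "read_records",
    "write_config",
    "read_config",
]

Outcome = Literal["anc", "pnc", "delivery"]

#: covariate level proportions mimicking a West-African DHS profile
#: (mostly rural, low formal education, large Muslim majority)
DEFAULT_PREVALENCES: dict[str, dict[str, float]] = {
    "education": {"none": 0.70, "primary": 0.13, "secondary": 0.15, "higher": 0.02},
    "occupation": {"yes": 0.74, "no": 0.26},
    "ethnicity": {"group_A": 0.44, "group_B": 0.40, "other": 0.16},
    "religion": {"christianity": 0.19, "islam": 0.80, "other": 0.01},
    "age_band": {"15-19": 0.09, "20-24": 0.20, "25-29": 0.26, "30-34": 0.18,
                 "35-39": 0.16, "40-44": 0.07, "45-49": 0.04},
    "siblings": {"none": 0.22, "one_to_four": 0.53, "more_than_four": 0.25},
}

#: fixed covariate effects on each outcome's linear predictor (log / logit
#: scale); education and urban residence push utilization up
DEFAULT_COVARIATE_EFFECTS: dict[str, dict[str, float]] = {
    "anc": {"education_secondary_plus": 0.10, "rural": -0.08},
    "pnc": {"education_secondary_plus": 0.20, "rural": -0.15},
    "delivery": {"education_secondary_plus": 0.70, "rural": -0.70},
}

DEFAULT_BASELINE_RATES: dict[str, float] = {
    # mean ANC visit count at mid-rank for the reference profile
    "anc": 4.2,
    # per-component postnatal review probability; completeness is the
    # product of four such draws
    "pnc": 0.55,
    # facility-delivery probability at mid-rank
    "delivery": 0.27,
}


@dataclass(frozen=True)
class PopulationConfig:
    """Configuration of one synthetic survey round.

    The default design mirrors a national DHS round: 353 EAs of about 85
    listed households each with 22 sampled, a rural majority, and covariate
    prevalences resembling the survey's background-characteristics table.
    Wealth gradients are the synthetic ground truth: log-scale effect of the
    (centered) fractional wealth rank for the ANC count and the PNC review
    components, log-odds scale for facility delivery.
    """

    n_clusters: int = 353
    households_per_cluster: int = 22
    listed_households: int = 85
    urban_fraction: float = 0.30
    urban_wealth_shift: float = 1.5
    covariate_prevalences: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PREVALENCES.items()})
    covariate_effects: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_EFFECTS.items()})
    baseline_rates: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_RATES))
    wealth_gradient_anc: float = 0.0
    wealth_gradient_pnc: float = 0.0
    wealth_gradient_delivery: float = 0.0
    survey_year: int = 2008
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_clusters", "households_per_cluster", "listed_households"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer (got {v!r})")
        if self.households_per_cluster > self.listed_households:
            raise ValueError("households_per_cluster cannot exceed listed_households")
        for name in ("urban_fraction",):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1] (got {v!r})")
        for name in ("urban_wealth_shift", "wealth_gradient_anc",
                     "wealth_gradient_pnc", "wealth_gradient_delivery"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for cov, levels in self.covariate_prevalences.items():
            probs = np.array(list(levels.values()), dtype=float)
            if np.any(~np.isfinite(probs)) or np.any(probs < 0) or np.any(probs > 1):
                raise ValueError(f"covariate_prevalences[{cov!r}] has proportions "
                                 "outside [0, 1]")
            if abs(probs.sum() - 1.0) > 1e-6:
                raise ValueError(f"covariate_prevalences[{cov!r}] proportions must "
                                 f"sum to 1 (got {probs.sum():.6g})")
        for name, v in self.baseline_rates.items():
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"baseline_rates[{name!r}] must be positive and finite")
        for name in ("pnc", "delivery"):
            if self.baseline_rates[name] >= 1.0:
                raise ValueError(f"baseline_rates[{name!r}] is a probability; must be < 1")

    def replace(self, **changes) -> "PopulationConfig":
        return dataclasses.replace(self, **changes)

    @property
    def n_records(self) -> int:
        return self.n_clusters * self.households_per_cluster


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _draw_categorical(rng: np.random.Generator, levels: dict[str, float],
                      n: int) -> np.ndarray:
    names = list(levels.keys())
    probs = np.array([levels[k] for k in names], dtype=float)
    probs = probs / probs.sum()
    return np.array(names, dtype=object)[rng.choice(len(names), size=n, p=probs)]


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Generate one synthetic survey round as a record table.

    Returns one row per interviewed woman with the design columns
    (``record_id``, ``cluster_id``, ``survey_year``, ``sampling_weight``),
    the wealth score, the demographic covariates, and the raw outcomes
    (``anc_visits``, the four ``pnc_*`` component flags,
    ``delivered_in_facility``).  Identical config (including seed) yields an
    identical table.
    """
    root = np.random.SeedSequence(config.seed)
    cluster_seeds = root.spawn(config.n_clusters)
    outcome_rng = np.random.default_rng(root.spawn(1)[0])

    m = config.households_per_cluster
    urban_flags = np.empty(config.n_clusters, dtype=bool)
    weights_c = np.empty(config.n_clusters)
    wealth_parts = []
    covariate_parts: dict[str, list[np.ndarray]] = {
        cov: [] for cov in config.covariate_prevalences}
    for c, ss in enumerate(cluster_seeds):
        rng = np.random.default_rng(ss)
        urban = rng.random() < config.urban_fraction
        # listed household count varies around the nominal EA size; the EA is
        # drawn PPS within its stratum and urban strata are oversampled, so
        # the inverse-probability weight varies across EAs
        listed = int(rng.integers(max(config.listed_households - 25, m),
                                  config.listed_households + 26))
        stratum_rate = 1.6 if urban else 1.0
        p_ea = stratum_rate * listed / config.listed_households
        p_hh = m / listed
        urban_flags[c] = urban
        weights_c[c] = 1.0 / (p_ea * p_hh)
        cluster_effect = rng.normal(0.0, 0.3)
        z = rng.normal(0.0, 1.0, size=m)
        wealth_parts.append(
            np.exp(z + cluster_effect)
            + (config.urban_wealth_shift if urban else 0.0))
        for cov, levels in config.covariate_prevalences.items():
            covariate_parts[cov].append(_draw_categorical(rng, levels, m))
    n = config.n_clusters * m
    df = pd.DataFrame({
        "record_id": np.arange(n),
        "cluster_id": np.repeat(np.arange(config.n_clusters), m),
        "survey_year": config.survey_year,
        "residence": np.where(np.repeat(urban_flags, m), "urban", "rural"),
        "sampling_weight": np.repeat(weights_c / weights_c.mean(), m),
        "wealth_score": np.concatenate(wealth_parts),
    })
    for cov, parts in covariate_parts.items():
        df[cov] = np.concatenate(parts)

    # number of children from the sibling-group draw
    sib = df.pop("siblings").to_numpy()
    n_children = np.ones(len(df), dtype=int)
    mask = sib == "one_to_four"
    n_children[mask] = outcome_rng.integers(2, 6, size=int(mask.sum()))
    mask = sib == "more_than_four"
    n_children[mask] = outcome_rng.integers(6, 10, size=int(mask.sum()))
    df["n_children"] = n_children

    # weighted fractional wealth rank drives the outcome gradients
    ranked_order = np.argsort(df["wealth_score"].to_numpy(), kind="stable")
    w_sorted = df["sampling_weight"].to_numpy()[ranked_order]
    w_sorted = w_sorted / w_sorted.sum()
    r_sorted = np.cumsum(w_sorted) - w_sorted / 2.0
    r = np.empty(len(df))
    r[ranked_order] = r_sorted
    df["wealth_rank"] = r
    rc = r - 0.5

    edu_plus = df["education"].isin(["secondary", "higher"]).to_numpy(dtype=float)
    rural = (df["residence"] == "rural").to_numpy(dtype=float)

    def _covariate_term(outcome: str) -> np.ndarray:
        eff = config.covariate_effects.get(outcome, {})
        return (eff.get("education_secondary_plus", 0.0) * edu_plus
                + eff.get("rural", 0.0) * rural)

    eta_anc = (np.log(config.baseline_rates["anc"])
               + config.wealth_gradient_anc * rc + _covariate_term("anc"))
    df["anc_visits"] = outcome_rng.poisson(np.exp(eta_anc))

    eta_pnc = (_logit(config.baseline_rates["pnc"])
               + config.wealth_gradient_pnc * rc + _covariate_term("pnc"))
    p_pnc = _expit(eta_pnc)
    from .recode import PNC_COMPONENT_COLUMNS
    for col in PNC_COMPONENT_COLUMNS:
        df[col] = (outcome_rng.random(len(df)) < p_pnc).astype(int)

    eta_del = (_logit(config.baseline_rates["delivery"])
               + config.wealth_gradient_delivery * rc + _covariate_term("delivery"))
    df["delivered_in_facility"] = (
        outcome_rng.random(len(df)) < _expit(eta_del)).astype(int)
    return df


_OUTCOME_COLUMNS = {"anc": "anc_visits", "pnc": "pnc_complete",
                    "delivery": "delivered_in_facility"}
_GRADIENT_FIELDS = {"anc": "wealth_gradient_anc", "pnc": "wealth_gradient_pnc",
                    "delivery": "wealth_gradient_delivery"}


def population_ci(config: PopulationConfig, outcome: Outcome) -> float:
    """Covariance-formula CI of one outcome on a freshly generated round."""
    from .recode import recode_pnc, PNC_COMPONENT_COLUMNS

    df = generate_population(config)
    if outcome == "pnc":
        h = (recode_pnc(df[PNC_COMPONENT_COLUMNS]).codes == 1).astype(float)
    else:
        h = df[_OUTCOME_COLUMNS[outcome]].to_numpy(dtype=float)
    ranked = rank_outcome(h, df["wealth_score"].to_numpy(),
                          df["sampling_weight"].to_numpy())
    return ci_covariance(ranked).estimate


def calibrate_gradient_to_ci(
    target_ci: float,
    config: PopulationConfig,
    outcome: Outcome = "anc",
    tol: float = 0.002,
    bounds: tuple[float, float] = (-6.0, 6.0),
    max_iter: int = 40,
) -> float:
    """Find the wealth gradient whose generated population attains a target CI.

    Monotone bisection over the gradient, evaluating the covariance-formula
    CI on a population generated from ``config`` (same seed every
    evaluation, so the objective is deterministic).  Raises if the target
    lies outside the CI range achievable at the gradient bounds.
    """
    if not abs(target_ci) < 1:
        raise ValueError("target CI must lie strictly inside (-1, 1)")
    if outcome not in _GRADIENT_FIELDS:
        raise ValueError(f"unknown outcome {outcome!r}")

    def f(g: float) -> float:
        return population_ci(config.replace(**{_GRADIENT_FIELDS[outcome]: g}),
                             outcome) - target_ci

    lo, hi = bounds
    f_lo, f_hi = f(lo), f(hi)
    if f_lo > 0 or f_hi < 0:
        raise ValueError(
            f"target CI {target_ci} unreachable for outcome {outcome!r}: "
            f"achievable range is [{f_lo + target_ci:.4f}, {f_hi + target_ci:.4f}]")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if abs(f_mid) < tol:
            return mid
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# flat-file round-trip

def write_records(records: pd.DataFrame, path) -> None:
    """Write the record table as a delimited flat file with a header row."""
    records.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_config(config: PopulationConfig, path) -> None:
    """Write the generator config as YAML; round-trips losslessly."""
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def read_config(path) -> PopulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PopulationConfig(**raw)
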