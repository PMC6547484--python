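"""End-to-end orchestration: simulate/load -> recode -> estimate -> compare.

``run_survey_analysis`` takes one survey round (a simulation config or a
flat file of records), recodes it, and produces concentration curves,
unadjusted and adjusted concentration-index estimates for the ANC and PNC
outcomes, and the logistic odds-ratio table for institutional delivery.
``compare_surveys`` places two such bundles side by side: difference-in-CI
tests, curve dominance, and the rich–poor odds-ratio equality test.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .concentration import (
    ConcentrationCurve,
    ConcentrationEstimate,
    ci_area,
    ci_covariance,
    ci_regression,
    curve_points,
    dominance,
    rank_outcome,
)
from .inference import (
    LogisticFit,
    ci_difference_test,
    fit_delivery_model,
    or_equality_test,
)
from .recode import recode_records
from .standardization import ci_adjusted, fit_prediction_model, predict_at_means
from .synthetic import PopulationConfig, generate_population, read_records

logger = logging.getLogger("mchequity")

__all__ = ["RunConfig", "SurveyBundle", "run_survey_analysis", "compare_surveys"]

#: default control covariates for the adjusted (standardized) CI
DEFAULT_CONTROLS = ["education", "occupation", "residence", "ethnicity",
                    "religion", "age_band", "n_children"]

_OUTCOME_COLUMNS = {"anc": "anc_visits", "pnc": "pnc_complete",
                    "delivery": "delivered_in_facility"}


@dataclass(frozen=True)
class RunConfig:
    """One survey-analysis run: where records come from and what to estimate."""

    simulation: Optional[PopulationConfig] = None
    input_path: Optional[str] = None
    outcomes: tuple[str, ...] = ("anc", "pnc")
    grouping: Literal["individual", "quintile"] = "individual"
    controls: tuple[str, ...] = tuple(DEFAULT_CONTROLS)
    wealth_terms: Literal["quintile", "score", "rank"] = "quintile"
    sided: Literal["one", "two"] = "two"
    anc_four_in_upper: bool = False
    fit_delivery: bool = True
    out_dir: Optional[str] = None
    seed: Optional[int] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_path is None):
            raise ValueError("provide exactly one of simulation config or input_path")
        unknown = set(self.outcomes) - set(_OUTCOME_COLUMNS)
        if unknown:
            raise ValueError(f"unrecognized outcome name(s): {sorted(unknown)}")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise ValueError(f"input file not found: {self.input_path}")


@dataclass
class SurveyBundle:
    """All artifacts of one analysed survey round."""

    records: pd.DataFrame
    estimates: pd.DataFrame
    curves: dict[str, ConcentrationCurve]
    estimate_objects: dict[tuple[str, bool], ConcentrationEstimate]
    delivery_fits: dict[str, LogisticFit]
    manifest: dict


def _wealth_terms_frame(records: pd.DataFrame,
                        kind: Literal["quintile", "score", "rank"]) -> pd.DataFrame:
    if kind == "quintile":
        return pd.DataFrame({"wealth_quintile": records["wealth_quintile"].astype(str)})
    if kind == "score":
        return pd.DataFrame({"wealth_score": records["wealth_score"].astype(float)})
    return pd.DataFrame({"wealth_rank": records["wealth_rank"].astype(float)})


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def run_survey_analysis(config: RunConfig) -> SurveyBundle:
    """Run the full single-survey analysis and (optionally) write its outputs."""
    logging.basicConfig(level=config.log_level)
    warnings_log: list[str] = []

    with _stage("load"):
        if config.simulation is not None:
            sim = config.simulation
            if config.seed is not None:
                sim = sim.replace(seed=config.seed)
            records = generate_population(sim)
        else:
            records = read_records(config.input_path)
        if len(records) == 0:
            raise ValueError("no input records")

    with _stage("recode"):
        records = recode_records(records, anc_four_in_upper=config.anc_four_in_upper)
        if "wealth_rank" not in records.columns:
            ranked_all = rank_outcome(np.ones(len(records)),
                                      records["wealth_score"].to_numpy(),
                                      records["sampling_weight"].to_numpy())
            order = np.argsort(records["wealth_score"].to_numpy(), kind="stable")
            r = np.empty(len(records))
            r[order] = ranked_all.r
            records["wealth_rank"] = r

    weights = records["sampling_weight"].to_numpy()
    wealth = records["wealth_score"].to_numpy()

    curves: dict[str, ConcentrationCurve] = {}
    estimate_objects: dict[tuple[str, bool], ConcentrationEstimate] = {}
    rows = []
    with _stage("estimate"):
        for outcome in config.outcomes:
            h = records[_OUTCOME_COLUMNS[outcome]].to_numpy(dtype=float)
            ranked = rank_outcome(h, wealth, weights)
            curves[outcome] = curve_points(ranked, grouping=config.grouping)

            unadj = ci_regression(ranked)
            estimate_objects[(outcome, False)] = unadj
            for est in (unadj, ci_covariance(ranked), ci_area(curves[outcome])):
                rows.append(dict(outcome=outcome, method=est.method, adjusted=False,
                                 estimate=est.estimate,
                                 standard_error=est.standard_error, n=ranked.n))

            if config.controls:
                wterms = _wealth_terms_frame(records, config.wealth_terms)
                controls = records[list(config.controls)].copy()
                model = fit_prediction_model(h, wterms, controls, weights,
                                             link="identity")
                order = np.argsort(wealth, kind="stable")
                adjusted_h = predict_at_means(model, wterms.iloc[order])
                adj = ci_adjusted(ranked, adjusted_h, controls=config.controls)
                estimate_objects[(outcome, True)] = adj
                rows.append(dict(outcome=outcome, method=adj.method, adjusted=True,
                                 estimate=adj.estimate,
                                 standard_error=adj.standard_error, n=adj.n))

    delivery_fits: dict[str, LogisticFit] = {}
    if config.fit_delivery:
        with _stage("delivery_model"):
            for adjusted in (False, True):
                fit = fit_delivery_model(records, weights, adjusted=adjusted)
                delivery_fits["adjusted" if adjusted else "unadjusted"] = fit

    estimates = pd.DataFrame(rows)
    manifest = {
        "package_version": __version__,
        "config": _config_dict(config),
        "n_records": int(len(records)),
        "outcomes": list(config.outcomes),
        "warnings": warnings_log,
    }
    bundle = SurveyBundle(records=records, estimates=estimates, curves=curves,
                          estimate_objects=estimate_objects,
                          delivery_fits=delivery_fits, manifest=manifest)
    if config.out_dir is not None:
        _write_bundle(bundle, Path(config.out_dir))
    return bundle


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.simulation is not None:
        d["simulation"] = dataclasses.asdict(config.simulation)
    return d


def _write_bundle(bundle: SurveyBundle, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    bundle.estimates.to_csv(out / "estimates.csv", index=False)
    for outcome, curve in bundle.curves.items():
        curve.to_frame().to_csv(out / f"curve_{outcome}.csv", index=False)
    for name, fit in bundle.delivery_fits.items():
        fit.table.to_csv(out / f"delivery_or_{name}.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, default=str)


def compare_surveys(bundle_a: SurveyBundle, bundle_b: SurveyBundle,
                    sided: Literal["one", "two"] = "two") -> dict[str, pd.DataFrame]:
    """Compare two analysed survey rounds.

    Returns a ``ci_tests`` table (per outcome × adjustment: estimates, SEs,
    test statistic, p-value), a ``dominance`` table, and — when both bundles
    carry delivery fits — an ``or_equality`` table comparing the richest-vs-
    poorest odds ratios on the odds-ratio scale.
    """
    outcomes_a = set(bundle_a.curves)
    outcomes_b = set(bundle_b.curves)
    if outcomes_a != outcomes_b:
        raise ValueError("bundles analyse different outcome sets: "
                         f"{sorted(outcomes_a ^ outcomes_b)} differ")

    ci_rows = []
    for (outcome, adjusted), est_a in sorted(bundle_a.estimate_objects.items()):
        key = (outcome, adjusted)
        if key not in bundle_b.estimate_objects:
            continue
        est_b = bundle_b.estimate_objects[key]
        test = ci_difference_test(est_a, est_b, sided=sided)
        ci_rows.append(dict(outcome=outcome, adjusted=adjusted,
                            estimate_a=est_a.estimate, se_a=est_a.standard_error,
                            estimate_b=est_b.estimate, se_b=est_b.standard_error,
                            statistic=test.statistic, p_value=test.p_value,
                            sided=test.sided))
    dom_rows = [dict(outcome=o, relation=dominance(bundle_a.curves[o],
                                                   bundle_b.curves[o]))
                for o in sorted(outcomes_a)]

    out = {"ci_tests": pd.DataFrame(ci_rows), "dominance": pd.DataFrame(dom_rows)}

    if bundle_a.delivery_fits and bundle_b.delivery_fits:
        or_rows = []
        for name in ("unadjusted", "adjusted"):
            row_a = bundle_a.delivery_fits[name].odds_ratio("wealth_quintile", "richest")
            row_b = bundle_b.delivery_fits[name].odds_ratio("wealth_quintile", "richest")
            test = or_equality_test(row_a["odds_ratio"], row_a["or_se"],
                                    row_b["odds_ratio"], row_b["or_se"])
            or_rows.append(dict(model=name,
                                or_a=row_a["odds_ratio"], se_a=row_a["or_se"],
                                or_b=row_b["odds_ratio"], se_b=row_b["or_se"],
                                statistic=test.statistic, p_value=test.p_value,
                                sided=test.sided))
        out["or_equality"] = pd.DataFrame(or_rows)
    return out
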