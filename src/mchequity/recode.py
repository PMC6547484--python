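"""Recoding of raw survey records into the analysis variables.

Antenatal-care visit counts collapse to three categories, the four postnatal
review components collapse to a complete/incomplete composite, and the
continuous wealth score is cut into five weighted quintiles.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "ANC_LEVELS",
    "PNC_LEVELS",
    "QUINTILE_LEVELS",
    "PNC_COMPONENT_COLUMNS",
    "recode_anc",
    "recode_pnc",
    "assign_quintiles",
    "most_recent_birth",
    "recode_records",
]

ANC_LEVELS = ["none", "up_to_four", "more_than_four"]
PNC_LEVELS = ["incomplete", "complete"]
QUINTILE_LEVELS = ["poorest", "poorer", "middle", "richer", "richest"]

#: the four recommended postnatal reviews, in chronological order
PNC_COMPONENT_COLUMNS = [
    "pnc_post_delivery",
    "pnc_pre_discharge",
    "pnc_week_after",
    "pnc_six_weeks",
]


def recode_anc(anc_visits, anc_four_in_upper: bool = False) -> pd.Categorical:
    """Collapse ANC visit counts into none / up_to_four / more_than_four.

    Zero visits map to ``none``.  By default exactly four visits fall in
    ``up_to_four`` (a literal reading of "more than four"); setting
    ``anc_four_in_upper`` moves the four-visit boundary case into the upper
    category, matching the WHO "four or more" adequacy convention.
    """
    v = np.asarray(anc_visits)
    if not np.issubdtype(v.dtype, np.number):
        raise ValueError("anc_visits must be numeric")
    if np.any(v < 0):
        raise ValueError("anc_visits must be non-negative")
    cut = 4 if anc_four_in_upper else 5
    codes = np.where(v == 0, 0, np.where(v < cut, 1, 2))
    return pd.Categorical.from_codes(codes, categories=ANC_LEVELS)


def recode_pnc(pnc_components) -> pd.Categorical:
    """Complete iff all four postnatal review components were attended.

    ``pnc_components`` is an (n, 4) array-like of 0/1 flags (or a DataFrame
    holding the four component columns).
    """
    if isinstance(pnc_components, pd.DataFrame):
        pnc_components = pnc_components.to_numpy()
    flags = np.atleast_2d(np.asarray(pnc_components))
    if flags.shape[1] != 4:
        raise ValueError(f"expected exactly 4 PNC component flags, got {flags.shape[1]}")
    if not np.isin(flags, (0, 1)).all():
        raise ValueError("PNC component flags must be binary (0/1)")
    codes = flags.all(axis=1).astype(int)
    return pd.Categorical.from_codes(codes, categories=PNC_LEVELS)


def assign_quintiles(wealth_score, sampling_weight) -> pd.Categorical:
    """Weighted wealth quintiles: poorest, poorer, middle, richer, richest.

    Records are sorted by wealth score and cut at cumulative normalized
    weight 0.2, 0.4, 0.6, 0.8.  A tied block of scores is assigned as one
    unit to the quintile containing the midpoint of its cumulative-weight
    span, so the assignment is invariant to the ordering of tied records and
    to any strictly monotone transform of the score.
    """
    score = np.asarray(wealth_score, dtype=float)
    w = np.asarray(sampling_weight, dtype=float)
    if score.shape != w.shape or score.ndim != 1:
        raise ValueError("wealth_score and sampling_weight must be matched 1-d arrays")
    if np.any(w <= 0):
        raise ValueError("all sampling weights must be positive")
    if score.size < 5:
        raise ValueError("need at least 5 records to form quintiles")
    if np.all(score == score[0]):
        warnings.warn("all wealth scores identical: degenerate single-quintile output",
                      stacklevel=2)
        return pd.Categorical.from_codes(np.zeros(score.size, dtype=int),
                                         categories=QUINTILE_LEVELS)
    order = np.argsort(score, kind="stable")
    w_sorted = w[order] / w.sum()
    # midpoint of each record's cumulative-weight span == its weighted mid-rank;
    # tied blocks share the weighted average of their mid-ranks
    r = np.cumsum(w_sorted) - w_sorted / 2.0
    s_sorted = score[order]
    block_id = np.cumsum(np.r_[1, np.diff(s_sorted) != 0]) - 1
    wsum = np.bincount(block_id, weights=w_sorted)
    wrsum = np.bincount(block_id, weights=w_sorted * r)
    r = (wrsum / wsum)[block_id]
    codes_sorted = np.minimum((r / 0.2).astype(int), 4)
    codes = np.empty(score.size, dtype=int)
    codes[order] = codes_sorted
    return pd.Categorical.from_codes(codes, categories=QUINTILE_LEVELS)


def most_recent_birth(records: pd.DataFrame,
                      woman_col: str = "woman_id",
                      date_col: str = "birth_date") -> pd.DataFrame:
    """Keep one row per woman: the birth with the maximum birth date."""
    for col in (woman_col, date_col):
        if col not in records.columns:
            raise KeyError(f"column {col!r} not found")
    idx = records.groupby(woman_col, sort=False)[date_col].idxmax()
    return records.loc[idx].reset_index(drop=True)


def recode_records(records: pd.DataFrame, anc_four_in_upper: bool = False) -> pd.DataFrame:
    """Append the recoded analysis columns to a raw record table.

    Adds ``anc_category``, ``pnc_status``, ``pnc_complete`` (0/1) and
    ``wealth_quintile``; original columns are preserved.
    """
    out = records.copy()
    out["anc_category"] = recode_anc(records["anc_visits"].to_numpy(),
                                     anc_four_in_upper=anc_four_in_upper)
    pnc = recode_pnc(records[PNC_COMPONENT_COLUMNS])
    out["pnc_status"] = pnc
    out["pnc_complete"] = (np.asarray(pnc.codes) == PNC_LEVELS.index("complete")).astype(int)
    out["wealth_quintile"] = assign_quintiles(records["wealth_score"].to_numpy(),
                                              records["sampling_weight"].to_numpy())
    return out
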