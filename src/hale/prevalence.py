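"""Dichotomization of the two SF-36 items and age-specific prevalence.

The general-health item ("How do you rate your general health?", five
levels) is dichotomized as excellent/very good/good = good versus
fair/poor = poor.  The walking item ("Are you limited to walk a few hundred
meters due to your health condition?", three levels) assigns limitation to
both "very much limited" and "a little bit limited".  Missing answers stay
missing and are excluded from both numerator and denominator.

Prevalence is tabulated on the same age grid as the life table, indexed by
age at the survey date; empty cells can borrow the nearest non-empty
younger cell's value (flagged), so that a sparse survey can still meet the
life-table grid row for row.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._dates import years_between_vec
from .persontime import AgeGrid

log = logging.getLogger(__name__)

__all__ = [
    "dichotomize_general_health",
    "dichotomize_walking",
    "prevalence_by_age",
]

_GH_MAP = {
    "excellent": "good",
    "very_good": "good",
    "good": "good",
    "fair": "poor",
    "poor": "poor",
    "missing": "missing",
}
_WALK_MAP = {
    "very_limited": "limited",
    "little_limited": "limited",
    "not_limited": "not_limited",
    "missing": "missing",
}

OUTCOME_COLUMNS = {"poor_health": "general_health_item", "disability": "walking_item"}
_ADVERSE = {"poor_health": "poor", "disability": "limited"}


def dichotomize_general_health(level: str) -> str:
    """5-level general health -> {good, poor, missing}."""
    try:
        return _GH_MAP[level]
    except KeyError:
        raise ValueError(f"unknown general-health token {level!r}") from None


def dichotomize_walking(level: str) -> str:
    """3-level walking limitation -> {limited, not_limited, missing}."""
    try:
        return _WALK_MAP[level]
    except KeyError:
        raise ValueError(f"unknown walking token {level!r}") from None


def _dichotomize_series(series: pd.Series, outcome: str) -> pd.Series:
    mapping = _GH_MAP if outcome == "poor_health" else _WALK_MAP
    vals = series.map(mapping)
    if vals.isna().any():
        bad = sorted(set(series[vals.isna()]))
        raise ValueError(f"unknown item token(s) {bad}")
    return vals


def join_survey(survey: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Inner-join survey records to their person records; error on orphans."""
    missing = ~survey["person_id"].isin(cohort["person_id"])
    if missing.any():
        ids = survey.loc[missing, "person_id"].tolist()[:10]
        raise ValueError(f"survey person_id(s) without a cohort record: {ids}")
    return survey.merge(cohort, on="person_id", how="left", validate="many_to_one")


def prevalence_by_age(
    survey: pd.DataFrame,
    cohort: pd.DataFrame,
    grid: AgeGrid,
    outcome: str = "poor_health",
    borrow: bool = True,
) -> pd.DataFrame:
    """Age-specific prevalence of the adverse state among respondents.

    Respondents are assigned to the grid interval containing their age at
    the survey date; those below the grid floor are excluded (the analysis
    is restricted to ages the life table covers).  Missing outcomes are
    dropped from numerator and denominator alike.  Returns a DataFrame
    aligned with the grid: age_group, n, k, pi, se, borrowed.

    With ``borrow=True`` an empty cell takes the value of the nearest
    non-empty younger cell (or, if there is none, the nearest older one),
    including its n for downstream variance, and is flagged ``borrowed``.
    """
    if outcome not in OUTCOME_COLUMNS:
        raise ValueError(f"unknown outcome {outcome!r}")
    joined = join_survey(survey, cohort)
    age = years_between_vec(joined["birth_date"], joined["survey_date"])
    state = _dichotomize_series(joined[OUTCOME_COLUMNS[outcome]], outcome)
    usable = (state != "missing").to_numpy() & (age >= grid.lowers[0])
    age, state = age[usable], state[usable]

    idx = grid.locate_entry(age)
    adverse = (state == _ADVERSE[outcome]).to_numpy()
    n_cells = len(grid.lowers)
    n = np.bincount(idx, minlength=n_cells).astype(float)
    k = np.bincount(idx, weights=adverse.astype(float), minlength=n_cells)

    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n > 0, k / np.where(n > 0, n, 1.0), np.nan)
        se = np.where(
            n > 0,
            np.sqrt(np.clip(pi * (1 - pi), 0, None) / np.where(n > 0, n, 1.0)),
            np.nan,
        )
    borrowed = np.zeros(n_cells, dtype=bool)
    if borrow and np.isnan(pi).any():
        filled = np.flatnonzero(~np.isnan(pi))
        if len(filled) == 0:
            raise ValueError("no respondents in any age group")
        for i in np.flatnonzero(np.isnan(pi)):
            younger = filled[filled < i]
            donor = younger.max() if len(younger) else filled[filled > i].min()
            # n and k stay 0: the cell truly has no respondents; the donor's
            # estimate and its uncertainty stand in for the missing cell
            pi[i], se[i] = pi[donor], se[donor]
            borrowed[i] = True
        log.warning("borrowed prevalence into %d empty age group(s)", int(borrowed.sum()))

    return pd.DataFrame(
        {
            "age": grid.lowers,
            "age_group": grid.labels,
            "n": n.astype(int),
            "k": k.astype(int),
            "pi": pi,
            "se": se,
            "borrowed": borrowed,
        }
    )
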