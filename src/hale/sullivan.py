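"""Sullivan-method health expectancies.

The Sullivan method partitions the remaining life years of a period life
table by a health state observed cross-sectionally: person-years lived in
each age interval are weighted by the proportion of that age group in good
health,

    HLE_x = sum_{y >= x} (1 - pi_y) * L_y / l_x ,

and analogously for disability-free life expectancy (DFLE) with the
prevalence of walking limitation.  The standard error keeps the prevalence
(binomial) component of the Sullivan variance,

    Var(HLE_x) = sum_{y >= x} L_y^2 * pi_y (1 - pi_y) / N_y  /  l_x^2 ,

the mortality component being negligible when prevalence uncertainty
dominates (a Chiang-style mortality term can be added via
``mortality_variance=True``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortFilter, assign_followup_class
from .lifetable import build_life_table, death_rates, life_expectancy
from .persontime import AgeGrid, aggregate_exposure
from .prevalence import join_survey, prevalence_by_age

log = logging.getLogger(__name__)

__all__ = [
    "sullivan_expectancy",
    "proportion_in_state",
    "health_expectancy_table",
    "stratified_sullivan",
]

#: strata whose unknown / excluded levels are dropped from stratified tables
_STRATUM_DROP = {
    "stage": {"unknown"},
    "ses": {"institutionalized", "unknown"},
    "comorbidity": {"unknown"},
}


def _check_alignment(lt: pd.DataFrame, prev: pd.DataFrame) -> None:
    if len(lt) != len(prev) or not np.allclose(
        lt["age"].to_numpy(dtype=float), prev["age"].to_numpy(dtype=float)
    ):
        raise ValueError("life table and prevalence table are on different age grids")


def sullivan_expectancy(
    lt: pd.DataFrame,
    prev: pd.DataFrame,
    age: float,
    mortality_variance: bool = False,
) -> dict:
    """Health expectancy at *age* from a life table and a prevalence table.

    Returns a dict with LE, HLE (years in the non-adverse state), the
    percent of remaining life in that state, the prevalence-based standard
    error and the 95% Wald interval.
    """
    _check_alignment(lt, prev)
    pi = prev["pi"].to_numpy(dtype=float)
    if np.isnan(pi).any():
        raise ValueError(
            "prevalence missing in some age group(s); enable borrowing or "
            "supply a complete table"
        )
    ages = lt["age"].to_numpy(dtype=float)
    hit = np.flatnonzero(np.isclose(ages, float(age)))
    if len(hit) == 0:
        raise ValueError(f"age {age} is not a boundary of the table's grid")
    i = hit[0]

    L = lt["L"].to_numpy(dtype=float)
    l = lt["l"].to_numpy(dtype=float)
    if not l[i] > 0:
        # nobody survives to this age in the (possibly sparse) stratum
        log.warning("zero survivorship at age %s; expectancies undefined", age)
        return {
            "age": float(age), "LE": np.nan, "HLE": np.nan, "prop": np.nan,
            "se": np.nan, "ci_low": np.nan, "ci_high": np.nan,
        }
    healthy_L = (1.0 - pi) * L
    le = float(lt["T"].iloc[i] / l[i])
    hle = float(healthy_L[i:].sum() / l[i])

    se_pi = np.nan_to_num(prev["se"].to_numpy(dtype=float), nan=0.0)
    var = float((L[i:] ** 2 * se_pi[i:] ** 2).sum() / l[i] ** 2)
    if mortality_variance:
        var += _chiang_mortality_variance(lt, pi, i)
    se = float(np.sqrt(var))
    prop = proportion_in_state(hle, le, rounded=False) if le > 0 else np.nan
    return {
        "age": float(age),
        "LE": le,
        "HLE": hle,
        "prop": prop,
        "se": se,
        "ci_low": hle - 1.96 * se,
        "ci_high": hle + 1.96 * se,
    }


def _chiang_mortality_variance(lt: pd.DataFrame, pi: np.ndarray, i: int) -> float:
    """Chiang-style mortality component of the Sullivan variance.

    Uses the sample variance of q_x, Var(q) ~ q^2 (1-q) / D_x, propagated
    through the survivorship weights; requires a ``deaths`` column merged
    into the life table (set to zero contribution otherwise).
    """
    if "deaths" not in lt.columns:
        log.warning("mortality variance requested but no deaths column; omitted")
        return 0.0
    q = lt["q"].to_numpy(dtype=float)
    d = lt["deaths"].to_numpy(dtype=float)
    l = lt["l"].to_numpy(dtype=float)
    e = lt["e"].to_numpy(dtype=float)
    n = lt["n"].to_numpy(dtype=float)
    a = np.nan_to_num(lt["a"].to_numpy(dtype=float), nan=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_q = np.where(d > 0, q**2 * (1.0 - q) / np.where(d > 0, d, 1.0), 0.0)
    healthy_tail = np.append(e[1:] * (1.0 - pi[1:]), 0.0)
    weights = l**2 * ((1.0 - a / n) * n + healthy_tail) ** 2
    contrib = weights[:-1] * var_q[:-1]
    return float(contrib[i:].sum() / l[i] ** 2)


def proportion_in_state(hle: float, le: float, rounded: bool = True):
    """Percent of remaining life spent in the given state, 100*hle/le.

    Computed from unrounded years and then (by default) rounded to the
    integer percent used in reporting.
    """
    if le <= 0:
        raise ValueError("life expectancy must be positive")
    if not 0.0 <= hle <= le + 1e-12:
        raise ValueError("state expectancy must lie in [0, LE]")
    pct = 100.0 * hle / le
    return int(round(pct)) if rounded else float(pct)


def health_expectancy_table(
    lt: pd.DataFrame,
    prev_health: pd.DataFrame,
    prev_disability: pd.DataFrame,
    ages=(50, 65, 80),
) -> pd.DataFrame:
    """LE / HLE / DFLE (years and percent of LE) at the reporting ages."""
    def rounded_pct(hle, le):
        if not (np.isfinite(le) and np.isfinite(hle)) or le <= 0:
            return np.nan
        return proportion_in_state(min(hle, le), le)

    rows = []
    for age in ages:
        h = sullivan_expectancy(lt, prev_health, age)
        d = sullivan_expectancy(lt, prev_disability, age)
        rows.append(
            {
                "age": age,
                "LE": h["LE"],
                "HLE": h["HLE"],
                "prop_HLE": rounded_pct(h["HLE"], h["LE"]),
                "se_HLE": h["se"],
                "HLE_ci_low": h["ci_low"],
                "HLE_ci_high": h["ci_high"],
                "DFLE": d["HLE"],
                "prop_DFLE": rounded_pct(d["HLE"], d["LE"]),
                "se_DFLE": d["se"],
                "DFLE_ci_low": d["ci_low"],
                "DFLE_ci_high": d["ci_high"],
            }
        )
    return pd.DataFrame(rows)


def _stratum_frame(cohort: pd.DataFrame, filt: CohortFilter, name: str) -> pd.Series:
    if name == "followup_class":
        return assign_followup_class(cohort, filt)
    if name not in cohort.columns:
        raise ValueError(f"unknown stratum {name!r}")
    return cohort[name]


def stratified_sullivan(
    cohort: pd.DataFrame,
    survey: pd.DataFrame,
    filt: CohortFilter,
    grid: AgeGrid,
    strata=(),
    ages=(50, 65, 80),
    min_deaths: int = 10,
) -> pd.DataFrame:
    """Run person-time -> life table -> prevalence -> Sullivan per stratum.

    ``strata`` names at most one grouping variable per run level; each
    variable is analysed marginally (as in stratified reporting tables:
    sex, socioeconomic class, follow-up class, stage, comorbidity).  Levels
    with fewer than ``min_deaths`` deaths are computed but flagged
    ``sparse``; a level with no deaths at all raises, naming the stratum.
    """
    results = []
    specs = [(None, None)] if not strata else [
        (s, lv)
        for s in strata
        for lv in _ordered_levels(_stratum_frame(cohort, filt, s), s)
    ]
    for stratum, level in specs:
        if stratum is None:
            sub = cohort
            label = ("overall", "all")
        else:
            values = _stratum_frame(cohort, filt, stratum)
            sub = cohort.loc[(values == level).to_numpy()]
            label = (stratum, level)
        exposure = aggregate_exposure(sub, filt, grid)
        total_deaths = int(exposure["deaths"].sum())
        if total_deaths == 0:
            raise ValueError(f"stratum {label[0]}={label[1]} has zero deaths in every age group")
        m = death_rates(exposure)
        if m[-1] <= 0:
            # close the open interval with the pooled rate of the oldest
            # non-empty groups so sparse strata still produce a table
            m = death_rates(exposure, zero_cell="pool")
            if m[-1] <= 0:
                nz = np.flatnonzero(m > 0)
                m[-1] = m[nz.max()]
            log.warning("stratum %s=%s: open-interval rate borrowed", *label)
        lt = build_life_table(m, grid)
        sub_survey = survey.loc[survey["person_id"].isin(sub["person_id"]).to_numpy()]
        prev_h = prevalence_by_age(sub_survey, sub, grid, "poor_health")
        prev_d = prevalence_by_age(sub_survey, sub, grid, "disability")
        block = health_expectancy_table(lt, prev_h, prev_d, ages)
        block.insert(0, "level", label[1])
        block.insert(0, "stratum", label[0])
        block["deaths"] = total_deaths
        block["respondents"] = int(prev_h["n"].to_numpy()[~prev_h["borrowed"].to_numpy()].sum())
        block["sparse"] = total_deaths < min_deaths
        results.append(block)
    return pd.concat(results, ignore_index=True)


def _ordered_levels(values: pd.Series, stratum: str) -> list:
    preferred = {
        "sex": ["male", "female"],
        "ses": ["high", "middle", "low"],
        "followup_class": ["short", "long"],
        "stage": ["I", "II", "III", "IV"],
        "comorbidity": ["0", "1plus"],
    }
    present = list(pd.unique(values))
    drop = _STRATUM_DROP.get(stratum, set())
    if stratum in preferred:
        return [lv for lv in preferred[stratum] if lv in present]
    return [lv for lv in present if lv not in drop]
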