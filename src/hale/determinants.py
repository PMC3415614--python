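"""Multivariate logistic models for poor health and functional disability.

The outcome is the dichotomized survey item; covariates are sex, age group
at survey, socioeconomic class, tumour site, follow-up class, stage,
comorbidity and treatment, dummy-coded against fixed reference levels
(male, youngest age band, high SES, colon, short follow-up, stage I, no
comorbidity, surgery only).  ``unknown`` levels are kept as explicit
categories rather than dropped, mirroring how registry covariates with
incomplete ascertainment are usually reported.

The fit is the ordinary maximum-likelihood logistic regression (Newton
scoring, i.e. iteratively reweighted least squares) with Wald standard
errors from the observed information; adjusted odds ratios are
``exp(beta)`` with 95% Wald intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._dates import years_between_vec
from .cohort import CohortFilter, assign_followup_class
from .prevalence import OUTCOME_COLUMNS, _ADVERSE, _dichotomize_series, join_survey

log = logging.getLogger(__name__)

__all__ = [
    "SeparationError",
    "build_design",
    "fit_logistic",
    "crude_odds_ratio",
    "determinants_table",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = (
    "sex", "age_group", "ses", "site", "followup_class", "stage",
    "comorbidity", "treatment",
)

_REFERENCES = {
    "sex": "male",
    "ses": "high",
    "site": "colon",
    "followup_class": "short",
    "stage": "I",
    "comorbidity": "0",
    "treatment": "surgery_only",
}

_LEVEL_ORDER = {
    "sex": ["male", "female"],
    "ses": ["high", "middle", "low", "institutionalized", "unknown"],
    "site": ["colon", "rectum"],
    "followup_class": ["short", "long"],
    "stage": ["I", "II", "III", "IV", "unknown"],
    "comorbidity": ["0", "1plus", "unknown"],
    "treatment": ["surgery_only", "surgery_chemo", "surgery_radio_chemo", "other"],
}


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


def _levels_for(cov: str, values: pd.Series) -> list:
    if isinstance(values.dtype, pd.CategoricalDtype):
        return list(values.cat.categories)
    return _LEVEL_ORDER.get(cov) or list(pd.unique(values))


def _age_bands(age: np.ndarray, scheme: str) -> pd.Categorical:
    if scheme == "5yr":
        edges = list(range(50, 90, 5))  # 50-54 ... 80-84, 85+
        labels = [f"{a}-{a + 4}" for a in edges[:-1]] + ["85+"]
        idx = np.clip(np.searchsorted(edges, age, side="right") - 1, 0, len(labels) - 1)
    elif scheme == "broad":
        edges = [50, 65, 80]
        labels = ["50-64", "65-79", "80+"]
        idx = np.clip(np.searchsorted(edges, age, side="right") - 1, 0, 2)
    else:
        raise ValueError(f"unknown age-band scheme {scheme!r}")
    return pd.Categorical.from_codes(idx, categories=labels)


def build_design(
    survey: pd.DataFrame,
    cohort: pd.DataFrame,
    filt: CohortFilter,
    outcome: str = "poor_health",
    covariates=DEFAULT_COVARIATES,
    age_bands: str = "5yr",
):
    """Assemble (y, X, info) for the logistic fit.

    Rows with a missing outcome are dropped.  Each categorical covariate is
    dummy-coded against its reference level; a level absent from the data is
    simply not represented (logged as a dropped term).  Returns the binary
    outcome vector, the design matrix (with ``const``), and a dict with the
    term -> (covariate, level) map and the rows used.
    """
    joined = join_survey(survey, cohort)
    state = _dichotomize_series(joined[OUTCOME_COLUMNS[outcome]], outcome)
    usable = (state != "missing").to_numpy()
    if not usable.any():
        raise ValueError("outcome is missing for every respondent")
    joined = joined.loc[usable].reset_index(drop=True)
    y = (state[usable] == _ADVERSE[outcome]).to_numpy(dtype=float)

    work = pd.DataFrame(index=joined.index)
    age = years_between_vec(joined["birth_date"], joined["survey_date"])
    for cov in covariates:
        if cov == "age_group":
            work[cov] = _age_bands(age, age_bands)
        elif cov == "followup_class":
            work[cov] = assign_followup_class(joined, filt).to_numpy()
        elif cov in joined.columns:
            work[cov] = joined[cov].to_numpy()
        else:
            raise ValueError(f"unknown covariate {cov!r}")

    X = pd.DataFrame({"const": np.ones(len(work))})
    terms = {"const": ("const", None)}
    for cov in covariates:
        order = _levels_for(cov, work[cov])
        present = [lv for lv in order if (work[cov] == lv).any()]
        ref = _REFERENCES.get(cov, present[0] if present else None)
        if ref not in present:
            ref = present[0]
        dropped = [lv for lv in order if lv not in present]
        if dropped:
            log.warning("covariate %s: level(s) %s absent, term dropped", cov, dropped)
        for lv in present:
            if lv == ref:
                continue
            name = f"{cov}[{lv}]"
            X[name] = (work[cov] == lv).to_numpy(dtype=float)
            terms[name] = (cov, lv)
    info = {"terms": terms, "references": {c: _REFERENCES.get(c) for c in covariates},
            "n_used": len(X), "data": work.assign(_outcome=y)}
    return y, X, info


def fit_logistic(X: pd.DataFrame, y, maxiter: int = 50) -> pd.DataFrame:
    """Maximum-likelihood logistic fit with Wald odds-ratio intervals.

    Raises :class:`SeparationError` when any fitted probability is within
    1e-8 of 0 or 1 together with a diverging coefficient, and a rank error
    for a rank-deficient design.  Returns a tidy per-term frame: term, beta,
    se, OR, ci_low, ci_high, p, plus n and convergence info as attrs.
    """
    Xm = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        raise ValueError(f"design matrix is rank deficient (rank {rank} < {Xm.shape[1]} columns)")
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, Xm, family=sm.families.Binomial())
            res = model.fit(maxiter=maxiter, tol=1e-10)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(
            f"separation or singular information during the fit: {exc}"
        ) from exc
    fitted = res.predict(Xm)
    if ((fitted < 1e-8) | (fitted > 1 - 1e-8)).any() and np.abs(res.params).max() > 15:
        raise SeparationError(
            "complete or quasi-complete separation detected: fitted "
            "probabilities at the 0/1 boundary with diverging coefficients"
        )
    beta = res.params
    se = res.bse
    out = pd.DataFrame(
        {
            "term": list(X.columns),
            "beta": beta,
            "se": se,
            "OR": np.exp(beta),
            "ci_low": np.exp(beta - 1.96 * se),
            "ci_high": np.exp(beta + 1.96 * se),
            "p": res.pvalues,
        }
    )
    out.attrs["n_used"] = int(len(y))
    out.attrs["converged"] = bool(getattr(res, "converged", True))
    out.attrs["iterations"] = int(res.fit_history.get("iteration", -1))
    return out


def crude_odds_ratio(a: int, b: int, c: int, d: int, correction: str | None = None):
    """2x2 odds ratio ad/bc with the Woolf log-interval.

    Cells are (exposed & case, exposed & control, unexposed & case,
    unexposed & control).  A zero cell is an error unless
    ``correction='haldane'`` adds 0.5 to every cell.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be nonnegative")
    if np.any(cells == 0):
        if correction is None:
            raise ValueError(
                "zero cell in the 2x2 table; pass correction='haldane' to "
                "add 0.5 to every cell"
            )
        if correction != "haldane":
            raise ValueError(f"unknown correction {correction!r}")
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se_log = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    return {
        "OR": float(or_),
        "ci_low": float(np.exp(np.log(or_) - 1.96 * se_log)),
        "ci_high": float(np.exp(np.log(or_) + 1.96 * se_log)),
    }


def determinants_table(
    survey: pd.DataFrame,
    cohort: pd.DataFrame,
    filt: CohortFilter,
    outcome: str = "poor_health",
    covariates=DEFAULT_COVARIATES,
    age_bands: str = "5yr",
    collapse_age: bool = False,
) -> pd.DataFrame:
    """Adjusted odds-ratio table in stratified-report layout.

    One row per covariate level (references carry OR = 1 and empty
    intervals), with counts of respondents per outcome state and a
    significance flag at p < 0.05.  ``collapse_age=True`` refits with broad
    age bands (50-64 / 65-79 / 80+) for display.
    """
    scheme = "broad" if collapse_age else age_bands
    y, X, info = build_design(survey, cohort, filt, outcome, covariates, scheme)
    fit = fit_logistic(X, y)
    fit_by_term = fit.set_index("term")
    data = info["data"]

    rows = []
    for cov in covariates:
        order = [lv for lv in _levels_for(cov, data[cov]) if (data[cov] == lv).any()]
        ref = info["references"].get(cov)
        if ref not in order:
            ref = order[0]
        for lv in order:
            n_adverse = int(((data[cov] == lv) & (data["_outcome"] == 1)).sum())
            n_ok = int(((data[cov] == lv) & (data["_outcome"] == 0)).sum())
            term = f"{cov}[{lv}]"
            if lv == ref:
                rows.append((cov, lv, n_ok, n_adverse, 1.0, np.nan, np.nan, np.nan, False))
            else:
                r = fit_by_term.loc[term]
                rows.append(
                    (cov, lv, n_ok, n_adverse, r["OR"], r["ci_low"], r["ci_high"],
                     r["p"], bool(r["p"] < 0.05))
                )
    out = pd.DataFrame(
        rows,
        columns=["covariate", "level", "n_good", "n_adverse", "OR",
                 "ci_low", "ci_high", "p", "significant"],
    )
    out.attrs.update(fit.attrs)
    return out
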