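"""Synthetic registry cohorts and survey subsamples with known ground truth.

The generator emulates a population-based colorectal-cancer survivor registry
(the Eindhoven Cancer Registry style of data): person-level records with
diagnosis dates spread over decades, stage at diagnosis, treatment,
comorbidity and socioeconomic class, plus a cross-sectional postal
quality-of-life survey of the survivors alive at a survey date.

Mortality follows an additive-excess model: the all-cause hazard at attained
age ``a`` for a survivor with stage ``s`` is

    mu(a) = alpha * exp(beta * a) + excess[s]

i.e. a Gompertz background schedule plus a constant stage-specific excess from
diagnosis onward.  Both pieces have closed-form cumulative hazards, so death
times are sampled exactly by inversion (the minimum of the two independent
event times), and remaining life expectancy has a quadrature oracle
(:func:`analytic_life_expectancy`) against which the whole downstream
pipeline can be validated.

Self-rated health and walking disability are Bernoulli draws from logistic
models in age, stage and comorbidity, so the prevalence structure seen by the
Sullivan stage is known exactly.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from ._dates import add_years_vec, as_date, years_between_vec

__all__ = [
    "GompertzHazard",
    "LogisticModel",
    "ResponseModel",
    "SimulationParams",
    "generate_cohort",
    "generate_survey",
    "validation_cohort",
    "analytic_life_expectancy",
    "VALIDATION_WINDOW",
]

STAGES = ("I", "II", "III", "IV")

#: fraction of questionnaire items left blank by responders
ITEM_MISSING_HEALTH = 0.05
ITEM_MISSING_WALKING = 0.08


class ParamError(ValueError):
    """A simulation parameter failed validation; the message names the field."""


@dataclass(frozen=True)
class GompertzHazard:
    """Gompertz schedule mu(a) = alpha * exp(beta * a).

    ``alpha`` is the rate per year at age 0 of the schedule; ``beta`` the
    log-slope per year of age.  ``beta == 0`` degenerates to a constant
    hazard ``alpha``.
    """

    alpha: float
    beta: float

    def rate(self, age):
        return self.alpha * np.exp(self.beta * np.asarray(age, dtype=float))

    def cumulative(self, age0, t):
        """Integrated hazard over [age0, age0 + t]."""
        age0 = np.asarray(age0, dtype=float)
        t = np.asarray(t, dtype=float)
        if self.beta == 0.0:
            return self.alpha * t
        return (self.alpha / self.beta) * np.exp(self.beta * age0) * (
            np.expm1(self.beta * t)
        )

    def invert(self, age0, cumhaz):
        """Time t at which the cumulative hazard from age0 reaches *cumhaz*."""
        age0 = np.asarray(age0, dtype=float)
        cumhaz = np.asarray(cumhaz, dtype=float)
        if self.alpha == 0.0:
            return np.full(np.broadcast(age0, cumhaz).shape, np.inf)
        if self.beta == 0.0:
            return cumhaz / self.alpha
        return np.log1p(cumhaz * self.beta / (self.alpha * np.exp(self.beta * age0))) / self.beta


@dataclass(frozen=True)
class LogisticModel:
    """Logistic model logit(p) = intercept + age_slope*(age-50) + stage + comorbidity.

    ``stage_offsets`` are log-odds offsets per stage I-IV (reference scale is
    whatever the intercept encodes; conventionally offset[0] == 0 so stage I
    is the reference).  Age is centred at 50 so the intercept is the
    log-odds for a 50-year-old in the reference category.
    """

    intercept: float
    age_slope: float = 0.0
    stage_offsets: tuple = (0.0, 0.0, 0.0, 0.0)
    comorbidity_offset: float = 0.0

    def linpred(self, age, stage_idx, comorbid):
        lp = (
            self.intercept
            + self.age_slope * (np.asarray(age, dtype=float) - 50.0)
            + np.asarray(self.stage_offsets)[np.asarray(stage_idx)]
            + self.comorbidity_offset * np.asarray(comorbid, dtype=float)
        )
        return lp

    def prob(self, age, stage_idx, comorbid):
        return 1.0 / (1.0 + np.exp(-self.linpred(age, stage_idx, comorbid)))


@dataclass(frozen=True)
class ResponseModel:
    """Logistic response model: logit P(respond) = intercept + poor_health_offset * 1{poor}.

    A negative ``poor_health_offset`` encodes health-dependent nonresponse
    (the magnitude is not identified by any published figure; the default is
    a mild selection effect and is documented as arbitrary).
    """

    intercept: float = 1.8
    poor_health_offset: float = -0.6

    def prob(self, poor):
        return 1.0 / (1.0 + np.exp(-(self.intercept + self.poor_health_offset * np.asarray(poor, dtype=float))))


def _default_poor_health() -> LogisticModel:
    return LogisticModel(
        intercept=-2.1, age_slope=0.02,
        stage_offsets=(0.0, -0.1, 0.1, 1.75), comorbidity_offset=0.9,
    )


def _default_disability() -> LogisticModel:
    return LogisticModel(
        intercept=-2.6, age_slope=0.055,
        stage_offsets=(0.0, 0.18, 0.48, 1.4), comorbidity_offset=0.75,
    )


@dataclass(frozen=True)
class SimulationParams:
    """All knobs of the synthetic registry.

    Defaults describe a cohort of the scale and structure of a regional
    Dutch colorectal-cancer registry observed over a five-year window:
    roughly 53% male, stage mix ~26/36/25/13% (I-IV), a strong stage
    gradient in survival, and ~63% with at least one comorbidity at
    diagnosis.  ``n_persons`` counts generated survivors; after the
    alive-in-window / age-50 selection roughly 15,000 remain (the scale of
    the registry cohort being emulated), with ~1,300 survey respondents.
    """

    n_persons: int = 22_500
    seed: int = 0
    window_start: object = "2005-01-01"
    window_end: object = "2009-12-31"
    background_hazard: GompertzHazard = GompertzHazard(alpha=3e-5, beta=0.095)
    stage_probs: tuple = (0.26, 0.36, 0.25, 0.13)
    stage_excess_hazard: tuple = (0.01, 0.02, 0.05, 0.45)
    sex_ratio: float = 0.53
    poor_health_model: LogisticModel = field(default_factory=_default_poor_health)
    disability_model: LogisticModel = field(default_factory=_default_disability)
    survey_fraction: float = 0.15
    response_model: ResponseModel = ResponseModel()
    comorbidity_prob: float = 0.63
    ses_probs: tuple = (0.32, 0.40, 0.28)
    survey_date: object = None  # default: window_end
    diagnosis_lookback: float = 20.0  # years before window_end
    age_at_diagnosis_dist: str = "normal"  # or "uniform"
    age_at_diagnosis_mean: float = 69.0
    age_at_diagnosis_sd: float = 11.0
    age_at_diagnosis_min: float = 30.0
    age_at_diagnosis_max: float = 95.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.n_persons, (int, np.integer)) or self.n_persons < 0:
            raise ParamError("n_persons must be a nonnegative integer")
        for name in ("sex_ratio", "survey_fraction", "comorbidity_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParamError(f"{name} must lie in [0, 1], got {v}")
        for name, k in (("stage_probs", 4), ("ses_probs", 3)):
            v = getattr(self, name)
            if len(v) != k:
                raise ParamError(f"{name} must have {k} entries")
            if any(p < 0 or p > 1 for p in v):
                raise ParamError(f"{name} entries must lie in [0, 1]")
            if abs(sum(v) - 1.0) > 1e-9:
                raise ParamError(f"{name} must sum to 1 (got {sum(v)})")
        if self.background_hazard.alpha < 0:
            raise ParamError("background_hazard.alpha must be >= 0")
        if any(h < 0 for h in self.stage_excess_hazard):
            raise ParamError("stage_excess_hazard rates must be >= 0")
        if as_date(self.window_start) >= as_date(self.window_end):
            raise ParamError("window_start must precede window_end")
        if self.age_at_diagnosis_dist not in ("normal", "uniform"):
            raise ParamError("age_at_diagnosis_dist must be 'normal' or 'uniform'")
        if self.age_at_diagnosis_min >= self.age_at_diagnosis_max:
            raise ParamError("age_at_diagnosis_min must precede age_at_diagnosis_max")

    def replace(self, **kw) -> "SimulationParams":
        return dataclasses.replace(self, **kw)


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _sample_death_times(rng, age_dx, stage_idx, params: SimulationParams):
    """Exact inversion sampling of time from diagnosis to death.

    The total hazard is background(age) + excess(stage); the death time is
    the minimum of two independent event times, one per additive component.
    """
    n = len(age_dx)
    bg = params.background_hazard
    e_bg = rng.exponential(size=n)
    t_bg = bg.invert(age_dx, e_bg)
    excess = np.asarray(params.stage_excess_hazard, dtype=float)[stage_idx]
    e_ex = rng.exponential(size=n)
    with np.errstate(divide="ignore"):
        t_ex = np.where(excess > 0, e_ex / np.where(excess > 0, excess, 1.0), np.inf)
    return np.minimum(t_bg, t_ex)


_TREATMENT_LEVELS = ("surgery_only", "surgery_chemo", "surgery_radio_chemo", "other")
# stage-conditional treatment mix: descriptive only, no effect on survival
_TREATMENT_BY_STAGE = np.array(
    [
        [0.88, 0.02, 0.04, 0.06],  # I
        [0.72, 0.14, 0.06, 0.08],  # II
        [0.26, 0.42, 0.26, 0.06],  # III
        [0.44, 0.26, 0.14, 0.16],  # IV
    ]
)


def generate_cohort(params: SimulationParams) -> pd.DataFrame:
    """Generate ``params.n_persons`` survivor records.

    Returns a DataFrame with columns person_id, sex, birth_date,
    diagnosis_date, site, stage, treatment, comorbidity, ses, vital_status,
    exit_date.  Persons who die before the observation window are emitted
    anyway; selecting the alive-in-window subcohort is the pipeline's job.
    Deterministic given ``params.seed``.
    """
    params.validate()
    n = int(params.n_persons)
    cols = [
        "person_id", "sex", "birth_date", "diagnosis_date", "site", "stage",
        "treatment", "comorbidity", "ses", "vital_status", "exit_date",
    ]
    if n == 0:
        return pd.DataFrame(columns=cols)

    (r_attr, r_diag, r_death) = _streams(int(params.seed), 3)

    w_start = as_date(params.window_start)
    w_end = as_date(params.window_end)

    sex = np.where(r_attr.random(n) < params.sex_ratio, "male", "female")
    stage_idx = r_attr.choice(4, size=n, p=np.asarray(params.stage_probs, dtype=float))
    site = np.where(r_attr.random(n) < 0.65, "colon", "rectum")
    comorbid = r_attr.random(n) < params.comorbidity_prob
    ses = np.asarray(["high", "middle", "low"])[
        r_attr.choice(3, size=n, p=np.asarray(params.ses_probs, dtype=float))
    ]
    treat_u = r_attr.random(n)
    cum = np.cumsum(_TREATMENT_BY_STAGE, axis=1)
    treatment_idx = (treat_u[:, None] > cum[stage_idx]).sum(axis=1)
    treatment = np.asarray(_TREATMENT_LEVELS)[treatment_idx]

    lookback = float(params.diagnosis_lookback)
    diag_offset_years = r_diag.random(n) * lookback  # years before window_end
    diagnosis_date = add_years_vec(np.repeat(np.datetime64(w_end, "D"), n), -diag_offset_years)
    if params.age_at_diagnosis_dist == "uniform":
        age_dx = r_diag.uniform(params.age_at_diagnosis_min, params.age_at_diagnosis_max, size=n)
    else:
        age_dx = r_diag.normal(params.age_at_diagnosis_mean, params.age_at_diagnosis_sd, size=n)
        age_dx = np.clip(age_dx, params.age_at_diagnosis_min, params.age_at_diagnosis_max)
    birth_date = add_years_vec(diagnosis_date, -age_dx)
    # recompute exact diagnosis age from the (day-rounded) dates
    age_dx = years_between_vec(birth_date, diagnosis_date)

    t_death = _sample_death_times(r_death, age_dx, stage_idx, params)
    death_date = add_years_vec(diagnosis_date, t_death)
    dead = death_date <= w_end
    exit_date = pd.DatetimeIndex(np.where(dead, death_date, np.datetime64(w_end, "D")))

    frame = pd.DataFrame(
        {
            "person_id": [f"p{i:06d}" for i in range(n)],
            "sex": sex,
            "birth_date": pd.DatetimeIndex(birth_date).astype("datetime64[ns]"),
            "diagnosis_date": pd.DatetimeIndex(diagnosis_date).astype("datetime64[ns]"),
            "site": site,
            "stage": np.asarray(STAGES)[stage_idx],
            "treatment": treatment,
            "comorbidity": np.where(comorbid, "1plus", "0"),
            "ses": ses,
            "vital_status": np.where(dead, "dead", "censored"),
            "exit_date": exit_date.astype("datetime64[ns]"),
        }
    )
    return frame[cols]


def generate_survey(cohort: pd.DataFrame, params: SimulationParams) -> pd.DataFrame:
    """Draw the cross-sectional survey among survivors alive at the survey date.

    Persons alive at ``params.survey_date`` (default: the window end) are
    sampled with probability ``survey_fraction``; sampled persons respond per
    the response model, which may depend on their (latent) poor-health state.
    The 5-level general-health item is generated so that P(fair or poor)
    equals the poor-health logistic model exactly, the "good" mass being
    spread uniformly over excellent/very_good/good; likewise for the 3-level
    walking item and the disability model.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    params.validate()
    survey_date = as_date(params.survey_date if params.survey_date is not None else params.window_end)

    (r_sample, r_items) = _streams(int(params.seed) + 7_654_321, 2)

    alive = ~(
        (cohort["vital_status"].to_numpy() == "dead")
        & (pd.to_datetime(cohort["exit_date"]) <= survey_date).to_numpy()
    )
    eligible = alive & (pd.to_datetime(cohort["diagnosis_date"]) <= survey_date).to_numpy()
    pool = cohort.loc[eligible]
    take = r_sample.random(len(pool)) < params.survey_fraction
    pool = pool.loc[take]
    if len(pool) == 0:
        return pd.DataFrame(columns=["person_id", "survey_date", "general_health_item", "walking_item"])

    age = years_between_vec(pool["birth_date"], np.repeat(np.datetime64(survey_date, "D"), len(pool)))
    stage_idx = pd.Categorical(pool["stage"], categories=list(STAGES)).codes
    stage_idx = np.where(stage_idx < 0, 0, stage_idx)  # unknown stage -> reference risk
    comorbid = (pool["comorbidity"].to_numpy() == "1plus").astype(float)

    p_poor = params.poor_health_model.prob(age, stage_idx, comorbid)
    p_dis = params.disability_model.prob(age, stage_idx, comorbid)
    poor = r_items.random(len(pool)) < p_poor
    disabled = r_items.random(len(pool)) < p_dis

    responds = r_items.random(len(pool)) < params.response_model.prob(poor)
    pool = pool.loc[responds]
    poor, disabled = poor[responds], disabled[responds]
    m = len(pool)

    u = r_items.random(m)
    gh = np.where(
        poor,
        np.where(u < 0.5, "fair", "poor"),
        np.asarray(["excellent", "very_good", "good"])[(u * 3).astype(int).clip(0, 2)],
    )
    v = r_items.random(m)
    walk = np.where(
        disabled,
        np.where(v < 0.5, "very_limited", "little_limited"),
        "not_limited",
    )
    gh = np.where(r_items.random(m) < ITEM_MISSING_HEALTH, "missing", gh)
    walk = np.where(r_items.random(m) < ITEM_MISSING_WALKING, "missing", walk)

    return pd.DataFrame(
        {
            "person_id": pool["person_id"].to_numpy(),
            "survey_date": pd.Timestamp(survey_date).as_unit("ns"),
            "general_health_item": gh,
            "walking_item": walk,
        }
    )


#: observation window of the dense-exposure validation scenario
VALIDATION_WINDOW = ("1975-01-01", "2014-12-31")


def validation_cohort(
    n_persons: int,
    seed: int,
    background_hazard: GompertzHazard | None = None,
    excess: float = 0.0,
    **param_overrides,
):
    """Cohort designed for parameter-recovery checks against the quadrature oracle.

    Period life-table estimates of remaining life expectancy at 50 are only
    as precise as the thinnest age cell, and a registry-style cohort
    (diagnosed old, short window) leaves the youngest and oldest cells
    sparse.  This constructor instead unions two equally sized subcohorts
    over a long window (1975-2014, diagnoses uniform across it): one
    diagnosed at ages 40-50, which passes through every age with exposure
    proportional to survivorship, and one diagnosed at ages 45-85, which
    populates the oldest cells directly.  Every age group is then densely
    observed and the Monte-Carlo error of e50 approaches the complete-data
    limit.

    The same stage-independent excess ``excess`` is applied to all stages,
    so the true hazard is exactly Gompertz + constant and
    :func:`analytic_life_expectancy` is the ground truth.

    Returns ``(cohort, params)`` where ``params`` carries the shared
    settings (window, models) for :func:`generate_survey`.
    """
    if background_hazard is None:
        background_hazard = SimulationParams().background_hazard
    base = dict(
        window_start=VALIDATION_WINDOW[0],
        window_end=VALIDATION_WINDOW[1],
        diagnosis_lookback=40.0,
        age_at_diagnosis_dist="uniform",
        background_hazard=background_hazard,
        stage_excess_hazard=(excess,) * 4,
        **param_overrides,
    )
    young = SimulationParams(
        n_persons=n_persons // 2, seed=int(seed),
        age_at_diagnosis_min=40.0, age_at_diagnosis_max=50.0, **base,
    )
    spread = SimulationParams(
        n_persons=n_persons - n_persons // 2, seed=int(seed) + 1_000_000,
        age_at_diagnosis_min=45.0, age_at_diagnosis_max=85.0, **base,
    )
    a = generate_cohort(young)
    b = generate_cohort(spread)
    b = b.assign(person_id="b" + b["person_id"])
    cohort = pd.concat([a, b], ignore_index=True)
    return cohort, spread


def analytic_life_expectancy(
    hazard: GompertzHazard, age: float, excess: float = 0.0
) -> float:
    """Remaining life expectancy at *age* under Gompertz + constant excess.

    Computes ``int_0^inf exp(-H(t)) dt`` with ``H(t)`` the cumulative hazard
    from *age*, by adaptive quadrature truncated where survivorship drops
    below 1e-12.  This is the ground-truth oracle for parameter-recovery
    tests of the life-table pipeline.
    """
    if hazard.alpha < 0 or excess < 0:
        raise ValueError("hazard components must be nonnegative")

    def cumhaz(t):
        return hazard.cumulative(age, t) + excess * t

    total0 = hazard.rate(age) + excess
    if total0 <= 0 and hazard.alpha == 0:
        raise ValueError("zero hazard: life expectancy diverges")
    # find truncation point where survivorship < 1e-12
    target = -math.log(1e-12)
    hi = 1.0
    while cumhaz(hi) < target and hi < 1e6:
        hi *= 2.0
    if cumhaz(hi) < target:
        raise ArithmeticError("could not bracket the survivorship tail")
    upper = optimize.brentq(lambda t: cumhaz(t) - target, 0.0, hi)

    val, err = integrate.quad(lambda t: math.exp(-cumhaz(t)), 0.0, upper, limit=200)
    if not math.isfinite(val) or err > 1e-6 * max(val, 1.0):
        raise ArithmeticError(f"quadrature did not converge (err={err})")
    return float(val)
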