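"""Generator: determinism, validity, and agreement with closed forms."""

import numpy as np
import pandas as pd
import pytest

from hale import (
    CohortFilter,
    GompertzHazard,
    LogisticModel,
    SimulationParams,
    analytic_life_expectancy,
    generate_cohort,
    generate_survey,
)
from hale.simulate import ParamError, ResponseModel, validation_cohort
from hale._dates import years_between_vec


def test_empty_cohort():
    cohort = generate_cohort(SimulationParams(n_persons=0, seed=1))
    assert len(cohort) == 0
    assert "person_id" in cohort.columns


def test_determinism_same_seed():
    p = SimulationParams(n_persons=2000, seed=42)
    c1, c2 = generate_cohort(p), generate_cohort(p)
    pd.testing.assert_frame_equal(c1, c2)
    s1, s2 = generate_survey(c1, p), generate_survey(c2, p)
    pd.testing.assert_frame_equal(s1, s2)
    c3 = generate_cohort(SimulationParams(n_persons=2000, seed=43))
    assert not c3.equals(c1)


@pytest.mark.parametrize(
    "field,value",
    [
        ("sex_ratio", 1.5),
        ("stage_probs", (0.5, 0.5, 0.2, -0.2)),
        ("stage_probs", (0.3, 0.3, 0.3, 0.3)),
        ("ses_probs", (0.5, 0.5, 0.5)),
        ("stage_excess_hazard", (0.1, -0.1, 0.1, 0.1)),
        ("n_persons", -3),
    ],
)
def test_invalid_params_name_the_field(field, value):
    with pytest.raises(ParamError, match=field.split("_")[0]):
        SimulationParams(**{field: value})


def test_dates_are_ordered():
    cohort = generate_cohort(SimulationParams(n_persons=3000, seed=7))
    assert (cohort["diagnosis_date"] >= cohort["birth_date"]).all()
    assert (cohort["exit_date"] >= cohort["diagnosis_date"]).all()
    assert set(cohort["stage"]) <= {"I", "II", "III", "IV", "unknown"}
    assert set(cohort["vital_status"]) <= {"dead", "censored"}


def test_survival_from_60_matches_gompertz_closed_form():
    """Kaplan-Meier 10-year survival from age 60 vs exp(-integral of the hazard)."""
    from lifelines import KaplanMeierFitter

    h = GompertzHazard(alpha=1e-5, beta=0.1)
    # long window so deaths are fully observed; entry before 60
    p = SimulationParams(
        n_persons=10_000, seed=11,
        window_start="1975-01-01", window_end="2069-12-31",
        diagnosis_lookback=90.0, background_hazard=h,
        stage_excess_hazard=(0.0,) * 4,
        age_at_diagnosis_dist="uniform",
        age_at_diagnosis_min=40.0, age_at_diagnosis_max=55.0,
    )
    cohort = generate_cohort(p)
    age_exit = years_between_vec(cohort["birth_date"], cohort["exit_date"])
    alive_at_60 = age_exit > 60.0
    durations = age_exit[alive_at_60] - 60.0
    events = (cohort["vital_status"].to_numpy() == "dead")[alive_at_60]
    km = KaplanMeierFitter().fit(durations, events)
    s10 = float(km.survival_function_at_times(10.0).iloc[0])
    expected = np.exp(-h.cumulative(60.0, 10.0))
    assert s10 == pytest.approx(expected, abs=0.02)


def test_survey_degenerate_intercepts():
    p = SimulationParams(
        n_persons=2000, seed=5, survey_fraction=0.5,
        poor_health_model=LogisticModel(intercept=-30.0),
        disability_model=LogisticModel(intercept=-30.0),
    )
    cohort = generate_cohort(p)
    survey = generate_survey(cohort, p)
    assert len(survey) > 0
    assert not survey["general_health_item"].isin(["fair", "poor"]).any()
    assert not survey["walking_item"].isin(["very_limited", "little_limited"]).any()

    empty = generate_survey(cohort, p.replace(survey_fraction=0.0))
    assert len(empty) == 0


def test_survey_intercept_only_prevalence_is_binomial():
    """logit^-1(0) = 0.5 of respondents report fair-or-poor, +/- Monte-Carlo error."""
    p = SimulationParams(
        n_persons=12_000, seed=9, survey_fraction=1.0,
        response_model=ResponseModel(intercept=8.0, poor_health_offset=0.0),
        poor_health_model=LogisticModel(intercept=0.0),
    )
    cohort = generate_cohort(p)
    survey = generate_survey(cohort, p)
    answered = survey.loc[survey["general_health_item"] != "missing"]
    assert len(answered) >= 5000
    frac = answered["general_health_item"].isin(["fair", "poor"]).mean()
    assert frac == pytest.approx(0.5, abs=0.02)


def test_survey_requires_cohort_and_respects_survey_date():
    p = SimulationParams(n_persons=500, seed=3, survey_fraction=1.0)
    cohort = generate_cohort(p)
    survey = generate_survey(cohort, p)
    merged = survey.merge(cohort, on="person_id", validate="one_to_one")
    died_before = (merged["vital_status"] == "dead") & (
        merged["exit_date"] < merged["survey_date"]
    )
    assert not died_before.any()
    with pytest.raises(ValueError):
        generate_survey(cohort.iloc[:0], p)


def test_stage_independent_of_survival_without_excess():
    """With zero excess for every stage, stage carries no survival information."""
    from scipy.stats import chi2_contingency

    p = SimulationParams(n_persons=8000, seed=13, stage_excess_hazard=(0.0,) * 4)
    cohort = generate_cohort(p)
    dead = cohort.loc[cohort["vital_status"] == "dead"]
    t = years_between_vec(dead["diagnosis_date"], dead["exit_date"])
    quartile = pd.qcut(t, 4, labels=False)
    table = pd.crosstab(dead["stage"], quartile)
    _, pval, _, _ = chi2_contingency(table)
    assert pval > 0.001


def test_analytic_life_expectancy_constant_hazard():
    assert analytic_life_expectancy(GompertzHazard(0.1, 0.0), 50.0) == pytest.approx(10.0, rel=1e-6)
    assert analytic_life_expectancy(GompertzHazard(0.05, 0.0), 30.0) == pytest.approx(20.0, rel=1e-6)
    # beta=0 with excess folded either way
    assert analytic_life_expectancy(
        GompertzHazard(0.04, 0.0), 50.0, excess=0.06
    ) == pytest.approx(10.0, rel=1e-6)


def test_analytic_life_expectancy_vs_riemann_oracle():
    h = GompertzHazard(alpha=1e-4, beta=0.09)
    quad = analytic_life_expectancy(h, 50.0)
    t = np.arange(0.0, 120.0, 0.01)
    surv = np.exp(-h.cumulative(50.0, t))
    riemann = float((surv[:-1] + surv[1:]).sum() / 2 * 0.01)
    assert quad == pytest.approx(riemann, rel=1e-4)


def test_validation_cohort_is_deterministic_and_well_formed():
    c1, params = validation_cohort(2000, seed=1, excess=0.1)
    c2, _ = validation_cohort(2000, seed=1, excess=0.1)
    pd.testing.assert_frame_equal(c1, c2)
    assert len(c1) == 2000
    assert c1["person_id"].is_unique
    assert params.stage_excess_hazard == (0.1,) * 4
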