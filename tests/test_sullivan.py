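"""Sullivan weighting: exact limits, linearity, variance and stratification."""

import numpy as np
import pandas as pd
import pytest

from hale import (
    AgeGrid,
    CohortFilter,
    SimulationParams,
    build_life_table,
    generate_cohort,
    generate_survey,
    health_expectancy_table,
    proportion_in_state,
    select_alive_in_window,
    stratified_sullivan,
    sullivan_expectancy,
)

GRID = AgeGrid((50, 55, 60, 65, 70, 75, 80, 85))


@pytest.fixture(scope="module")
def life_table():
    m = [0.02, 0.03, 0.045, 0.06, 0.08, 0.11, 0.15, 0.25]
    return build_life_table(m, GRID)


def prev_table(pi, n=200):
    pi = np.broadcast_to(pi, len(GRID.lowers)).astype(float)
    return pd.DataFrame(
        {
            "age": GRID.lowers,
            "age_group": GRID.labels,
            "n": n,
            "k": (pi * n).astype(int),
            "pi": pi,
            "se": np.sqrt(pi * (1 - pi) / n),
            "borrowed": False,
        }
    )


def test_zero_prevalence_gives_hle_equal_le(life_table):
    for age in (50, 65, 80):
        r = sullivan_expectancy(life_table, prev_table(0.0), age)
        assert r["HLE"] == pytest.approx(r["LE"], abs=1e-12)


def test_full_prevalence_gives_zero_hle(life_table):
    r = sullivan_expectancy(life_table, prev_table(1.0), 50)
    assert r["HLE"] == pytest.approx(0.0, abs=1e-12)


def test_constant_prevalence_scales_le_exactly(life_table):
    r = sullivan_expectancy(life_table, prev_table(0.25), 50)
    assert r["HLE"] == pytest.approx(0.75 * r["LE"], abs=1e-12)


def test_sullivan_is_monotone_in_prevalence_scale(life_table):
    hles = [
        sullivan_expectancy(life_table, prev_table(alpha * 0.4), 50)["HLE"]
        for alpha in np.linspace(0, 1, 6)
    ]
    assert all(a > b for a, b in zip(hles, hles[1:]))


def test_standard_error_shrinks_with_survey_size(life_table):
    small = sullivan_expectancy(life_table, prev_table(0.3, n=50), 50)
    large = sullivan_expectancy(life_table, prev_table(0.3, n=50_000), 50)
    assert large["se"] < small["se"] / 10
    assert small["ci_low"] < small["HLE"] < small["ci_high"]


def test_grid_mismatch_is_an_error(life_table):
    other = prev_table(0.2).iloc[:5]
    with pytest.raises(ValueError, match="grid"):
        sullivan_expectancy(life_table, other, 50)


def test_missing_prevalence_cell_is_an_error(life_table):
    prev = prev_table(0.2)
    prev.loc[3, "pi"] = np.nan
    with pytest.raises(ValueError, match="missing"):
        sullivan_expectancy(life_table, prev, 50)


@pytest.mark.parametrize(
    "hle,le,expected",
    [(9.5, 12.3, 77), (9.9, 13.3, 74), (16.0, 19.2, 83), (3.8, 5.5, 69), (6.0, 9.3, 65)],
)
def test_published_year_pairs_round_to_printed_percent(hle, le, expected):
    assert proportion_in_state(hle, le) == expected


def test_proportion_edge_cases():
    assert proportion_in_state(5.0, 5.0) == 100
    with pytest.raises(ValueError):
        proportion_in_state(1.0, 0.0)
    with pytest.raises(ValueError):
        proportion_in_state(6.0, 5.0)


def test_hle_and_dfle_bounded_by_le(life_table):
    tab = health_expectancy_table(life_table, prev_table(0.3), prev_table(0.45))
    assert (tab["HLE"] <= tab["LE"] + 1e-9).all()
    assert (tab["DFLE"] <= tab["LE"] + 1e-9).all()
    assert (tab["prop_DFLE"] <= tab["prop_HLE"]).all()


@pytest.fixture(scope="module")
def synthetic_run():
    filt = CohortFilter()
    params = SimulationParams(n_persons=12_000, seed=31, survey_fraction=0.6)
    cohort = generate_cohort(params)
    survey = generate_survey(cohort, params)
    selected = select_alive_in_window(cohort, filt)
    survey = survey.loc[survey["person_id"].isin(selected["person_id"]).to_numpy()]
    return selected, survey, filt


def test_sex_symmetric_generator_gives_similar_hle(synthetic_run):
    """The generator treats the sexes identically, so HLE must agree to MC error."""
    selected, survey, filt = synthetic_run
    tab = stratified_sullivan(selected, survey, filt, GRID, strata=("sex",), ages=(50,))
    by = tab.set_index("level")
    assert abs(by.loc["male", "HLE"] - by.loc["female", "HLE"]) < 1.5


def test_stage_gradient_orders_life_expectancy(synthetic_run):
    selected, survey, filt = synthetic_run
    tab = stratified_sullivan(selected, survey, filt, GRID, strata=("stage",), ages=(50,))
    by = tab.set_index("level")
    assert by.loc["IV", "LE"] < by.loc["I", "LE"]
    assert (tab["HLE"] <= tab["LE"] + 1e-9).all()


def test_no_strata_equals_direct_computation(synthetic_run):
    from hale import aggregate_exposure, death_rates, prevalence_by_age

    selected, survey, filt = synthetic_run
    tab = stratified_sullivan(selected, survey, filt, GRID, strata=(), ages=(50, 65))
    lt = build_life_table(death_rates(aggregate_exposure(selected, filt, GRID)), GRID)
    prev = prevalence_by_age(survey, selected, GRID, "poor_health")
    direct = sullivan_expectancy(lt, prev, 50)
    row = tab.loc[tab["age"] == 50].iloc[0]
    assert row["stratum"] == "overall"
    assert row["HLE"] == pytest.approx(direct["HLE"], rel=1e-12)
    assert row["LE"] == pytest.approx(direct["LE"], rel=1e-12)


def test_zero_death_stratum_raises():
    filt = CohortFilter()
    params = SimulationParams(n_persons=400, seed=33)
    cohort = generate_cohort(params)
    selected = select_alive_in_window(cohort, filt).copy()
    # make 'male' a stratum level in which nobody dies
    selected["sex"] = np.where(
        selected["vital_status"].to_numpy() == "dead", "female", "male"
    )
    survey = generate_survey(cohort, params)
    survey = survey.loc[survey["person_id"].isin(selected["person_id"]).to_numpy()]
    with pytest.raises(ValueError, match="male.*zero deaths"):
        stratified_sullivan(selected, survey, filt, GRID, strata=("sex",), ages=(50,))
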