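"""Lexis splitting: exact overlap arithmetic against day-by-day counting."""

import numpy as np
import pandas as pd
import pytest

from hale import AgeGrid, CohortFilter, aggregate_exposure, split_person_time
from hale._dates import DAYS_PER_YEAR, add_years, as_date, years_between_vec
from conftest import brute_force_exposure, frame_of, person_aged, random_persons

WINDOW = CohortFilter(window_start="2005-01-01", window_end="2010-01-01")
GRID = AgeGrid()
DAY = 1.0 / DAYS_PER_YEAR


def test_grid_spec_parsing_and_validation():
    g = AgeGrid.from_spec("50:85:5")
    assert list(g.lowers) == [50, 55, 60, 65, 70, 75, 80, 85]
    assert g.labels[-1] == "85+"
    assert np.isinf(g.uppers[-1])
    with pytest.raises(ValueError):
        AgeGrid((60, 55))


def test_single_interval_full_window():
    person = person_aged(60.0, WINDOW, years_in_window=4.99)
    segs = split_person_time(person, WINDOW, GRID)
    assert len(segs) == 1
    label, py, died = segs[0]
    assert label == "60-64"
    assert py == pytest.approx(4.99, abs=2 * DAY)
    assert not died


def test_split_across_boundary():
    person = person_aged(63.0, WINDOW)
    segs = dict((lab, py) for lab, py, _ in split_person_time(person, WINDOW, GRID))
    assert segs["60-64"] == pytest.approx(2.0, abs=2 * DAY)
    assert segs["65-69"] == pytest.approx(3.0, abs=2 * DAY)


def test_death_attributed_to_interval_of_last_exposure():
    person = person_aged(57.5, WINDOW, years_in_window=2.4997, dies=True)
    segs = split_person_time(person, WINDOW, GRID)
    assert len(segs) == 1
    label, py, died = segs[0]
    assert label == "55-59"
    assert py == pytest.approx(2.5, abs=2 * DAY)
    assert died


def test_zero_eligible_time_is_empty():
    person = person_aged(40.0, WINDOW)  # never reaches 50 in window
    assert split_person_time(person, WINDOW, GRID) == []


def test_toy_aggregation_matches_hand_sums():
    cohort = frame_of(
        person_aged(63.0, WINDOW, person_id="a"),
        person_aged(57.5, WINDOW, years_in_window=2.4997, dies=True, person_id="b"),
    )
    exposure = aggregate_exposure(cohort, WINDOW, GRID)
    by = exposure.set_index("age_group")
    assert by.loc["55-59", "deaths"] == 1
    assert by.loc["55-59", "person_years"] == pytest.approx(2.5, abs=2 * DAY)
    assert by.loc["60-64", "person_years"] == pytest.approx(2.0, abs=2 * DAY)
    assert by.loc["65-69", "person_years"] == pytest.approx(3.0, abs=2 * DAY)
    assert by["deaths"].sum() == 1


def test_empty_cohort_gives_zero_table():
    exposure = aggregate_exposure(frame_of().reindex(columns=["person_id"]), WINDOW, GRID)
    assert list(exposure["age_group"]) == GRID.labels
    assert exposure["deaths"].sum() == 0
    assert exposure["person_years"].sum() == 0


def test_person_years_conservation_and_death_count():
    """Total exposure equals summed eligible spans; deaths equal in-window deaths."""
    filt = WINDOW
    cohort = random_persons(1000, seed=21, filt=filt)
    exposure = aggregate_exposure(cohort, filt, GRID)

    w_start, w_end = as_date(filt.window_start), as_date(filt.window_end)
    birth = pd.to_datetime(cohort["birth_date"])
    start = pd.to_datetime(cohort["diagnosis_date"]).clip(lower=w_start)
    floor_date = pd.DatetimeIndex(
        [add_years(b, max(filt.min_age_in_window, GRID.lowers[0])) for b in birth]
    )
    start = pd.DatetimeIndex(np.maximum(start.to_numpy(), floor_date.to_numpy()))
    end = pd.to_datetime(cohort["exit_date"]).clip(upper=w_end)
    spans = np.clip(years_between_vec(start, pd.DatetimeIndex(end)), 0.0, None)
    assert exposure["person_years"].sum() == pytest.approx(spans.sum(), abs=1000 * DAY)

    in_window_death = (
        (cohort["vital_status"] == "dead")
        & (pd.to_datetime(cohort["exit_date"]) <= w_end)
        & (spans > 0)
    )
    assert exposure["deaths"].sum() == int(in_window_death.sum())


def test_agreement_with_day_by_day_oracle():
    filt = WINDOW
    cohort = random_persons(300, seed=22, filt=filt)
    fast = aggregate_exposure(cohort, filt, GRID)
    slow = brute_force_exposure(cohort, filt, GRID)
    diff = (fast["person_years"] - slow["person_years"]).abs()
    assert (diff <= len(cohort) * DAY).all()
    assert fast["deaths"].tolist() == slow["deaths"].tolist()


def test_refine_then_coarsen_is_exact():
    filt = WINDOW
    cohort = random_persons(400, seed=23, filt=filt)
    coarse = aggregate_exposure(cohort, filt, GRID)
    fine = aggregate_exposure(cohort, filt, AgeGrid.from_spec("50:85:1"))
    fine_groups = np.clip((fine["age_group"].str.extract(r"^(\d+)")[0].astype(int) - 50) // 5, 0, 7)
    recoarse = fine.groupby(fine_groups).agg({"deaths": "sum", "person_years": "sum"})
    np.testing.assert_allclose(
        recoarse["person_years"].to_numpy(), coarse["person_years"].to_numpy(), rtol=0, atol=1e-9
    )
    assert recoarse["deaths"].tolist() == coarse["deaths"].tolist()


def test_stratified_exposure_partitions_totals():
    from hale import SimulationParams, generate_cohort, select_alive_in_window

    filt = CohortFilter()
    cohort = select_alive_in_window(
        generate_cohort(SimulationParams(n_persons=3000, seed=6)), filt
    )
    overall = aggregate_exposure(cohort, filt, GRID)
    by_sex = aggregate_exposure(cohort, filt, GRID, strata=("sex",))
    merged = by_sex.groupby("age_group", sort=False).sum(numeric_only=True)
    assert merged["deaths"].sum() == overall["deaths"].sum()
    assert merged["person_years"].sum() == pytest.approx(
        overall["person_years"].sum(), rel=1e-12
    )


def test_dynamic_followup_class_preserves_totals():
    from hale import SimulationParams, generate_cohort, select_alive_in_window

    filt = CohortFilter(followup_update="dynamic")
    cohort = select_alive_in_window(
        generate_cohort(SimulationParams(n_persons=2000, seed=9)), filt
    )
    overall = aggregate_exposure(cohort, filt, GRID)
    dyn = aggregate_exposure(cohort, filt, GRID, strata=("followup_class",))
    assert dyn["deaths"].sum() == overall["deaths"].sum()
    assert dyn["person_years"].sum() == pytest.approx(
        overall["person_years"].sum(), rel=1e-12
    )
    frozen = aggregate_exposure(
        cohort, filt.replace(followup_update="entry"), GRID, strata=("followup_class",)
    )
    short_dyn = dyn.loc[dyn["followup_class"] == "short", "person_years"].sum()
    short_frozen = frozen.loc[frozen["followup_class"] == "short", "person_years"].sum()
    assert short_dyn <= short_frozen + 1e-9
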