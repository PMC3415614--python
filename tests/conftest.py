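"""Shared fixtures: toy person rows, random cohorts, brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hale._dates import DAYS_PER_YEAR, add_years, as_date
from hale.cohort import CohortFilter
from hale.persontime import AgeGrid


def make_person(
    person_id="p1",
    sex="male",
    birth_date="1940-01-01",
    diagnosis_date="2000-01-01",
    site="colon",
    stage="II",
    treatment="surgery_only",
    comorbidity="0",
    ses="middle",
    vital_status="censored",
    exit_date="2009-12-31",
):
    return {
        "person_id": person_id,
        "sex": sex,
        "birth_date": as_date(birth_date),
        "diagnosis_date": as_date(diagnosis_date),
        "site": site,
        "stage": stage,
        "treatment": treatment,
        "comorbidity": comorbidity,
        "ses": ses,
        "vital_status": vital_status,
        "exit_date": as_date(exit_date),
    }


def person_aged(age_at_window_start, filt, years_in_window=None, dies=False, **kw):
    """Person whose age at the window start is (to day resolution) *age_at_window_start*."""
    w_start = as_date(filt.window_start)
    birth = add_years(w_start, -age_at_window_start)
    if years_in_window is None:
        exit_date = as_date(filt.window_end)
    else:
        exit_date = add_years(w_start, years_in_window)
    return make_person(
        birth_date=birth,
        diagnosis_date=kw.pop("diagnosis_date", add_years(w_start, -1.0)),
        vital_status="dead" if dies else "censored",
        exit_date=exit_date,
        **kw,
    )


def frame_of(*persons) -> pd.DataFrame:
    return pd.DataFrame(list(persons))


def brute_force_exposure(cohort: pd.DataFrame, filt: CohortFilter, grid: AgeGrid):
    """Day-by-day accumulation of person-time, the slow independent oracle.

    Walks every calendar day of each person's eligible span, computes the
    exact age that day, and drops one day of exposure into the containing
    age group.  Accurate to one day per person-segment boundary.
    """
    w_start = as_date(filt.window_start)
    w_end = as_date(filt.window_end)
    floor = max(filt.min_age_in_window, grid.lowers[0])
    py_days = np.zeros(len(grid.lowers))
    deaths = np.zeros(len(grid.lowers), dtype=int)
    for _, person in cohort.iterrows():
        birth = person["birth_date"]
        start = max(w_start, person["diagnosis_date"])
        end = min(person["exit_date"], w_end)
        if end <= start:
            continue
        days = np.arange(
            np.datetime64(start, "D"), np.datetime64(end, "D"), dtype="datetime64[D]"
        )
        ages = (days - np.datetime64(birth, "D")).astype(float) / DAYS_PER_YEAR
        ok = ages >= floor
        idx = np.searchsorted(grid.lowers, ages[ok], side="right") - 1
        np.add.at(py_days, idx, 1.0)
        if person["vital_status"] == "dead" and person["exit_date"] <= w_end:
            age_death = ((np.datetime64(end, "D") - np.datetime64(birth, "D")).astype(float) - 0.5) / DAYS_PER_YEAR
            if age_death >= floor:
                deaths[np.searchsorted(grid.lowers, age_death, side="right") - 1] += 1
    return pd.DataFrame(
        {
            "age_group": grid.labels,
            "deaths": deaths,
            "person_years": py_days / DAYS_PER_YEAR,
        }
    )


def random_persons(n, seed, filt):
    """Messy random persons around the observation window for conservation tests."""
    rng = np.random.default_rng(seed)
    w_start = as_date(filt.window_start)
    rows = []
    for i in range(n):
        age_w = rng.uniform(30.0, 100.0)
        birth = add_years(w_start, -age_w)
        diag = add_years(w_start, rng.uniform(-15.0, 4.0))
        if diag < birth:
            diag = birth
        dies = rng.random() < 0.5
        exit_date = add_years(diag, rng.uniform(0.0, 20.0))
        rows.append(
            make_person(
                person_id=f"r{i}",
                birth_date=birth,
                diagnosis_date=diag,
                vital_status="dead" if dies else "censored",
                exit_date=exit_date,
            )
        )
    return frame_of(*rows)


@pytest.fixture
def default_filter():
    return CohortFilter()


@pytest.fixture
def default_grid():
    return AgeGrid()
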