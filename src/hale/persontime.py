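"""Lexis-style splitting of follow-up into age-group exposure.

Each selected person contributes person-time from
``max(window_start, diagnosis_date, 50th-birthday-equivalent)`` until
``min(exit_date, window_end)``.  That span, expressed in exact real-valued
age (365.2425-day years), is cut at every age-group boundary; a death inside
the window is attributed to the age group containing the final instant of
exposure (a death falling exactly on a boundary belongs to the interval
below it, the one that received the person's last exposure).

Age intervals are half-open ``[lower, upper)``: a person moves into 65-69 at
the instant of the 65th birthday.  The final interval is open-ended.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._dates import years_between_vec
from .cohort import CohortFilter, assign_followup_class, followup_years_at_entry

__all__ = ["AgeGrid", "split_person_time", "aggregate_exposure"]


@dataclass(frozen=True)
class AgeGrid:
    """Lower bounds of age intervals; the last interval is open-ended.

    The default grid is 5-year groups from 50 to 85 with an open 85+ group.
    """

    lower_bounds: tuple = (50, 55, 60, 65, 70, 75, 80, 85)

    def __post_init__(self):
        lb = np.asarray(self.lower_bounds, dtype=float)
        if len(lb) < 1 or np.any(np.diff(lb) <= 0):
            raise ValueError("lower_bounds must be strictly increasing")

    @classmethod
    def from_spec(cls, spec: str) -> "AgeGrid":
        """Parse 'start:last:step', e.g. '50:85:5' -> 50,55,...,85+."""
        start, last, step = (float(x) for x in spec.split(":"))
        return cls(tuple(np.arange(start, last + step / 2, step)))

    @property
    def lowers(self) -> np.ndarray:
        return np.asarray(self.lower_bounds, dtype=float)

    @property
    def uppers(self) -> np.ndarray:
        return np.append(self.lowers[1:], np.inf)

    @property
    def widths(self) -> np.ndarray:
        return self.uppers - self.lowers

    @property
    def labels(self) -> list:
        labs = [
            f"{int(lo)}-{int(hi) - 1}" for lo, hi in zip(self.lowers[:-1], self.lowers[1:])
        ]
        labs.append(f"{int(self.lowers[-1])}+")
        return labs

    def locate(self, age) -> np.ndarray:
        """Index of the interval containing each age; -1 below the grid floor.

        An age exactly on a boundary belongs to the interval *below* when
        used for death attribution (see module docstring); use
        ``side='right'`` semantics via :meth:`locate_entry` for exposure
        starts.
        """
        idx = np.searchsorted(self.lowers, np.asarray(age, dtype=float), side="left") - 1
        return idx

    def locate_entry(self, age) -> np.ndarray:
        """Interval receiving exposure that starts at *age* (half-open rule)."""
        idx = np.searchsorted(self.lowers, np.asarray(age, dtype=float), side="right") - 1
        return idx


def _eligible_age_span(cohort: pd.DataFrame, filt: CohortFilter, floor: float):
    """(age_entry, age_exit, died_in_window) per person, in exact years."""
    w_start, w_end = pd.Timestamp(filt.window_start), pd.Timestamp(filt.window_end)
    birth = pd.to_datetime(cohort["birth_date"])
    diag = pd.to_datetime(cohort["diagnosis_date"])
    exit_ = pd.to_datetime(cohort["exit_date"])

    start_date = diag.where(diag > w_start, w_start)
    end_date = exit_.where(exit_ < w_end, w_end)
    a_start = np.maximum(years_between_vec(birth, start_date), max(filt.min_age_in_window, floor))
    a_end = years_between_vec(birth, end_date)
    died = (cohort["vital_status"].to_numpy() == "dead") & (exit_ <= w_end).to_numpy()
    return a_start, a_end, died


def split_person_time(person, filt: CohortFilter, grid: AgeGrid) -> list:
    """Split one person's eligible time; returns [(age_label, years, died)].

    *person* is a mapping/Series with the cohort columns.  A person with no
    eligible time returns an empty list.
    """
    frame = pd.DataFrame([dict(person)])
    a0, a1, died = _eligible_age_span(frame, filt, grid.lowers[0])
    a0, a1, died = float(a0[0]), float(a1[0]), bool(died[0])
    if a1 <= a0:
        return []
    lo, hi = grid.lowers, grid.uppers
    overlap = np.clip(np.minimum(a1, hi) - np.maximum(a0, lo), 0.0, None)
    death_idx = grid.locate(a1) if died else -99
    out = []
    for i, labs in enumerate(grid.labels):
        if overlap[i] > 0 or i == death_idx:
            out.append((labs, float(overlap[i]), i == death_idx))
    return out


def aggregate_exposure(
    cohort: pd.DataFrame,
    filt: CohortFilter,
    grid: AgeGrid,
    strata: tuple = (),
) -> pd.DataFrame:
    """Deaths and person-years per age group (per stratum level if requested).

    Vectorized over persons; exact interval-overlap arithmetic, so total
    person-years equal the summed eligible spans to floating-point
    resolution.  ``strata`` may name cohort columns (sex, stage, ses,
    comorbidity, site, treatment) or the derived ``followup_class``; with
    ``filt.followup_update == 'dynamic'`` the follow-up class flips mid
    window, and exposure is re-cut at the flip age.

    Returns a DataFrame with columns ``strata... , age_group, deaths,
    person_years``.
    """
    base_cols = ["age_group", "deaths", "person_years"]
    if len(cohort) == 0:
        empty = pd.DataFrame({"age_group": grid.labels, "deaths": 0, "person_years": 0.0})
        return empty[base_cols]

    work = cohort
    dynamic_fu = "followup_class" in strata and filt.followup_update == "dynamic"
    if "followup_class" in strata and "followup_class" not in work.columns:
        work = work.assign(followup_class=assign_followup_class(work, filt))

    a0, a1, died = _eligible_age_span(work, filt, grid.lowers[0])
    keep = a1 > a0
    work, a0, a1, died = work.loc[keep], a0[keep], a1[keep], died[keep]
    if dynamic_fu:
        # age at which completed follow-up years exceed the cut
        diag = pd.to_datetime(work["diagnosis_date"])
        age_dx = years_between_vec(work["birth_date"], diag)
        flip_age = age_dx + filt.followup_class_cut + 1.0
        pieces = []
        for cls, lo_a, hi_a in (
            ("short", a0, np.minimum(a1, flip_age)),
            ("long", np.maximum(a0, flip_age), a1),
        ):
            sel = hi_a > lo_a
            sub = work.loc[sel].assign(followup_class=cls)
            # death belongs to the piece containing the exit instant
            sub_died = died[sel] & (np.abs(hi_a[sel] - a1[sel]) < 1e-12)
            pieces.append((sub, lo_a[sel], hi_a[sel], sub_died))
        return pd.concat(
            [_tabulate(sub, lo_a, hi_a, dd, grid, strata) for sub, lo_a, hi_a, dd in pieces],
            ignore_index=True,
        ).groupby(list(strata) + ["age_group"], sort=False, as_index=False, observed=True).sum()

    return _tabulate(work, a0, a1, died, grid, strata)


def _tabulate(work, a0, a1, died, grid: AgeGrid, strata) -> pd.DataFrame:
    lo, hi = grid.lowers, grid.uppers
    overlap = np.clip(
        np.minimum(a1[:, None], hi[None, :]) - np.maximum(a0[:, None], lo[None, :]),
        0.0, None,
    )  # persons x intervals
    death_idx = np.where(died, grid.locate(a1), -1)

    if not strata:
        deaths = np.bincount(death_idx[death_idx >= 0], minlength=len(lo))
        out = pd.DataFrame(
            {
                "age_group": grid.labels,
                "deaths": deaths.astype(int),
                "person_years": overlap.sum(axis=0),
            }
        )
        return out

    keys = pd.MultiIndex.from_frame(work[list(strata)].reset_index(drop=True))
    levels, codes = np.unique(keys.to_numpy(), return_inverse=True)
    rows = []
    for g, level in enumerate(levels):
        sel = codes == g
        deaths = np.bincount(
            death_idx[sel][death_idx[sel] >= 0], minlength=len(lo)
        )
        block = pd.DataFrame(
            {
                "age_group": grid.labels,
                "deaths": deaths.astype(int),
                "person_years": overlap[sel].sum(axis=0),
            }
        )
        lev = level if isinstance(level, tuple) else (level,)
        for name, val in zip(strata, lev):
            block.insert(0, name, val)
        rows.append(block)
    return pd.concat(rows, ignore_index=True)
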