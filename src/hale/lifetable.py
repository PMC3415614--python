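"""Abridged period life tables from age-grouped deaths and person-years.

Standard demographic construction: central death rates m_x = D_x / P_x are
converted to death probabilities with the actuarial identity

    q_x = n_x * m_x / (1 + (n_x - a_x) * m_x)

where a_x is the average number of years lived within the interval by those
dying in it (default n_x / 2), the survivorship column l_x descends from a
radix of 100,000, person-years lived are L_x = n_x * l_{x+n} + a_x * d_x,
and the open-ended final interval is closed exponentially with
L = l / m (equivalently e = 1/m at its start).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .persontime import AgeGrid

log = logging.getLogger(__name__)

__all__ = ["death_rates", "build_life_table", "life_expectancy", "RADIX"]

RADIX = 100_000.0

#: exposure below which a rate is flagged as unstable in the log
SMALL_CELL_PERSON_YEARS = 50.0


def death_rates(exposure: pd.DataFrame, zero_cell: str = "zero") -> np.ndarray:
    """Central death rates m_x = deaths / person_years per age group.

    ``zero_cell`` controls cells with no exposure and no deaths:
    ``"zero"`` (default) sets m_x = 0; ``"pool"`` borrows the pooled rate of
    the adjacent non-empty cells.  A cell with deaths but no person-years is
    a hard error (infinite rate).
    """
    d = exposure["deaths"].to_numpy(dtype=float)
    p = exposure["person_years"].to_numpy(dtype=float)
    if np.any((p <= 0) & (d > 0)):
        bad = exposure.loc[(p <= 0) & (d > 0), "age_group"].tolist()
        raise ValueError(f"deaths with zero person-years in age group(s) {bad}")
    small = (p > 0) & (p < SMALL_CELL_PERSON_YEARS)
    if small.any():
        log.warning("unstable rates: person-years < %g in %d age group(s)",
                    SMALL_CELL_PERSON_YEARS, int(small.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(p > 0, d / np.where(p > 0, p, 1.0), 0.0)
    empty = p <= 0
    if empty.any() and zero_cell == "pool":
        for i in np.flatnonzero(empty):
            neighbours = [j for j in (i - 1, i + 1) if 0 <= j < len(p) and p[j] > 0]
            if neighbours:
                m[i] = sum(d[j] for j in neighbours) / sum(p[j] for j in neighbours)
    elif zero_cell not in ("zero", "pool"):
        raise ValueError(f"unknown zero_cell rule {zero_cell!r}")
    return m


def build_life_table(m, grid: AgeGrid, a_convention: str = "half") -> pd.DataFrame:
    """Abridged life table from central death rates on *grid*.

    Returns a DataFrame with columns age, n, m, a, q, l, d, L, T, e.  The
    final (open) interval must have a positive rate so the table can be
    closed with L = l / m.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("negative death rate")
    if len(m) != len(grid.lowers):
        raise ValueError("rate vector length does not match the age grid")
    if m[-1] <= 0:
        raise ValueError(
            "zero death rate in the open-ended interval: the table cannot be "
            "closed; supply a positive rate (e.g. pool older age groups)"
        )
    n = grid.widths.copy()
    if a_convention == "half":
        a = n / 2.0
        a[-1] = np.nan  # not used in the open interval
    else:
        raise ValueError(f"unknown a_convention {a_convention!r}")

    q = np.empty_like(m)
    closed = slice(0, len(m) - 1)
    q[closed] = (n[closed] * m[closed]) / (1.0 + (n[closed] - a[closed]) * m[closed])
    q = np.clip(q, 0.0, 1.0)
    q[-1] = 1.0

    l = np.empty_like(m)
    l[0] = RADIX
    for i in range(len(m) - 1):
        l[i + 1] = l[i] * (1.0 - q[i])
    d = np.empty_like(m)
    d[:-1] = l[:-1] - l[1:]
    d[-1] = l[-1]

    L = np.empty_like(m)
    L[:-1] = n[:-1] * l[1:] + a[:-1] * d[:-1]
    L[-1] = l[-1] / m[-1]

    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(l > 0, T / np.where(l > 0, l, 1.0), 0.0)

    return pd.DataFrame(
        {
            "age": grid.lowers,
            "age_group": grid.labels,
            "n": n,
            "m": m,
            "a": a,
            "q": q,
            "l": l,
            "d": d,
            "L": L,
            "T": T,
            "e": e,
        }
    )


def life_expectancy(lt: pd.DataFrame, age: float) -> float:
    """Remaining life expectancy e_x at a grid boundary *age*.

    The age must be one of the table's interval lower bounds; no
    interpolation is attempted.
    """
    ages = lt["age"].to_numpy(dtype=float)
    hit = np.flatnonzero(np.isclose(ages, float(age)))
    if len(hit) == 0:
        below = ages[ages < age]
        above = ages[ages > age]
        hint = []
        if len(below):
            hint.append(str(below.max()))
        if len(above):
            hint.append(str(above.min()))
        raise ValueError(
            f"age {age} is not a grid boundary; nearest boundaries: {', '.join(hint)}"
        )
    return float(lt["e"].iloc[hit[0]])
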