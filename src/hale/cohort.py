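"""Reading, validating and filtering registry and survey tables.

The registry table is person-level: one row per survivor with dates, tumour
attributes and covariates.  The inclusion rules implemented here mirror a
period life-table analysis of prevalent cancer survivors: keep persons alive
at some instant inside a calendar observation window, attaining a minimum
age (default 50) while alive in the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._dates import years_between_vec

log = logging.getLogger(__name__)

__all__ = [
    "CohortFilter",
    "SchemaError",
    "RowError",
    "read_cohort",
    "read_survey",
    "write_cohort",
    "select_alive_in_window",
    "assign_followup_class",
]

COHORT_COLUMNS = [
    "person_id", "sex", "birth_date", "diagnosis_date", "site", "stage",
    "treatment", "comorbidity", "ses", "vital_status", "exit_date",
]
SURVEY_COLUMNS = ["person_id", "survey_date", "general_health_item", "walking_item"]

# Closed vocabularies.  Fields with an `unknown` level absorb unrecognized
# tokens (with a warning); the others reject them.
VOCAB = {
    "sex": ({"male", "female"}, None),
    "site": ({"colon", "rectum"}, None),
    "stage": ({"I", "II", "III", "IV", "unknown"}, "unknown"),
    "treatment": ({"surgery_only", "surgery_chemo", "surgery_radio_chemo", "other"}, "other"),
    "comorbidity": ({"0", "1plus", "unknown"}, "unknown"),
    "ses": ({"high", "middle", "low", "institutionalized", "unknown"}, "unknown"),
    "vital_status": ({"dead", "censored"}, None),
}

# Documented alias table: common alternative encodings accepted on read.
ALIASES = {
    "sex": {"m": "male", "f": "female", "1": "male", "2": "female"},
    "stage": {
        "1": "I", "2": "II", "3": "III", "4": "IV",
        "i": "I", "ii": "II", "iii": "III", "iv": "IV",
        "x": "unknown", "": "unknown", "na": "unknown", "nan": "unknown",
    },
    "comorbidity": {"none": "0", "1+": "1plus", "1 or more": "1plus", "": "unknown", "nan": "unknown"},
    "ses": {"institution": "institutionalized", "": "unknown", "nan": "unknown", "missing": "unknown"},
    "site": {"c18": "colon", "c19": "rectum", "c20": "rectum"},
    "vital_status": {"deceased": "dead", "alive": "censored", "0": "censored", "1": "dead"},
    "treatment": {"surgery": "surgery_only", "s": "surgery_only"},
}


class SchemaError(ValueError):
    """The file-level schema (header, required columns) is wrong."""


class RowError(ValueError):
    """One or more rows failed validation; message lists row indices."""


@dataclass(frozen=True)
class CohortFilter:
    """Cohort inclusion rules for the observation window.

    ``alive_at='any'`` keeps persons alive at any instant inside the window
    (the default reading of "alive between" the window years);
    ``alive_at='start'`` requires being a diagnosed survivor already alive at
    ``window_start``.  ``followup_class_cut`` dichotomizes completed years
    since diagnosis into short (<= cut) versus long follow-up.
    """

    window_start: object = "2005-01-01"
    window_end: object = "2009-12-31"
    min_age_in_window: float = 50.0
    followup_class_cut: float = 5.0
    strata: tuple = ()
    alive_at: str = "any"
    followup_update: str = "entry"  # or "dynamic"

    def __post_init__(self):
        if pd.Timestamp(self.window_start) >= pd.Timestamp(self.window_end):
            raise ValueError("window_start must precede window_end")
        if self.min_age_in_window < 0:
            raise ValueError("min_age_in_window must be >= 0")
        if self.alive_at not in ("any", "start"):
            raise ValueError("alive_at must be 'any' or 'start'")
        if self.followup_update not in ("entry", "dynamic"):
            raise ValueError("followup_update must be 'entry' or 'dynamic'")

    def replace(self, **kw) -> "CohortFilter":
        return replace(self, **kw)


def _map_tokens(series: pd.Series, column: str, errors: list) -> pd.Series:
    vocab, fallback = VOCAB[column]
    aliases = ALIASES.get(column, {})
    raw = series.astype(str).str.strip()
    lowered = raw.str.lower()
    mapped = lowered.map(lambda t: aliases.get(t, t))
    # canonical stage tokens are upper-case Roman numerals
    if column == "stage":
        mapped = mapped.map(lambda t: t.upper() if t.upper() in vocab else t)
    bad = ~mapped.isin(vocab)
    if bad.any():
        if fallback is not None:
            log.warning(
                "%d unrecognized %s token(s) mapped to %r: %s",
                int(bad.sum()), column, fallback,
                sorted(set(raw[bad]))[:5],
            )
            mapped = mapped.where(~bad, fallback)
        else:
            errors.extend(
                f"row {i}: unrecognized {column} token {t!r}"
                for i, t in raw[bad].items()
            )
    return mapped


def _parse_dates(series: pd.Series, column: str, errors: list) -> pd.Series:
    parsed = pd.to_datetime(series, errors="coerce", format="ISO8601")
    bad = parsed.isna() & series.notna()
    errors.extend(f"row {i}: unparseable {column} {series[i]!r}" for i in series.index[bad])
    missing = series.isna()
    errors.extend(f"row {i}: missing {column}" for i in series.index[missing])
    return parsed


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a registry CSV; returns a typed DataFrame.

    Raises :class:`SchemaError` if required columns are missing and
    :class:`RowError` (listing row indices) if any row violates the schema
    or the date-ordering invariants.
    """
    df = pd.read_csv(path, dtype=str, comment="#")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    errors: list = []
    out = pd.DataFrame(index=df.index)
    out["person_id"] = df["person_id"].astype(str)
    for col in ("birth_date", "diagnosis_date", "exit_date"):
        out[col] = _parse_dates(df[col], col, errors)
    for col in VOCAB:
        out[col] = _map_tokens(df[col], col, errors)
    ok = out[["birth_date", "diagnosis_date", "exit_date"]].notna().all(axis=1)
    bad_order = ok & (out["diagnosis_date"] < out["birth_date"])
    errors.extend(f"row {i}: diagnosis_date precedes birth_date" for i in out.index[bad_order])
    bad_exit = ok & (out["exit_date"] < out["diagnosis_date"])
    errors.extend(f"row {i}: exit_date precedes diagnosis_date" for i in out.index[bad_exit])
    if errors:
        raise RowError(f"{len(errors)} invalid row value(s):\n" + "\n".join(errors[:20]))
    log.info("read %d cohort records from %s", len(out), path)
    return out[COHORT_COLUMNS]


def read_survey(path) -> pd.DataFrame:
    """Read and validate a survey CSV (person_id, survey_date, the two items)."""
    df = pd.read_csv(path, dtype=str, comment="#")
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    errors: list = []
    out = pd.DataFrame(index=df.index)
    out["person_id"] = df["person_id"].astype(str)
    out["survey_date"] = _parse_dates(df["survey_date"], "survey_date", errors)
    gh_vocab = {"excellent", "very_good", "good", "fair", "poor", "missing"}
    wk_vocab = {"very_limited", "little_limited", "not_limited", "missing"}
    for col, vocab in (("general_health_item", gh_vocab), ("walking_item", wk_vocab)):
        vals = df[col].fillna("missing").astype(str).str.strip().str.lower()
        bad = ~vals.isin(vocab)
        errors.extend(f"row {i}: unrecognized {col} token {t!r}" for i, t in vals[bad].items())
        out[col] = vals
    if errors:
        raise RowError(f"{len(errors)} invalid row value(s):\n" + "\n".join(errors[:20]))
    return out[SURVEY_COLUMNS]


def write_cohort(frame: pd.DataFrame, path, header_lines=()) -> None:
    """Write a cohort/survey table as CSV with ISO dates and optional
    ``#``-prefixed provenance header lines."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False, date_format="%Y-%m-%d")


def select_alive_in_window(cohort: pd.DataFrame, filt: CohortFilter) -> pd.DataFrame:
    """Apply the inclusion rules; idempotent.

    Keeps persons with ``exit_date >= window_start``, diagnosed by
    ``window_end``, whose attained age reaches ``min_age_in_window`` at some
    instant while alive inside the window (i.e. age at
    ``min(exit_date, window_end)`` is at least the minimum age).
    """
    w_start, w_end = pd.Timestamp(filt.window_start), pd.Timestamp(filt.window_end)
    exit_ = pd.to_datetime(cohort["exit_date"])
    diag = pd.to_datetime(cohort["diagnosis_date"])
    keep = (exit_ >= w_start) & (diag <= w_end)
    if filt.alive_at == "start":
        keep &= diag <= w_start
    last_alive = exit_.where(exit_ < w_end, w_end)
    age_last = years_between_vec(cohort["birth_date"], last_alive)
    keep &= age_last >= filt.min_age_in_window
    out = cohort.loc[keep.to_numpy()]
    log.info("select_alive_in_window: kept %d of %d", len(out), len(cohort))
    if len(out) == 0:
        log.warning("selection produced an empty cohort")
    return out


def followup_years_at_entry(cohort: pd.DataFrame, filt: CohortFilter) -> np.ndarray:
    """Exact years from diagnosis to each person's entry into the window."""
    w_start = pd.Timestamp(filt.window_start)
    diag = pd.to_datetime(cohort["diagnosis_date"])
    entry = diag.where(diag > w_start, w_start)
    return years_between_vec(diag, entry)


def completed_years(start: pd.Series, end) -> np.ndarray:
    """Whole calendar years from *start* to *end* (anniversary arithmetic).

    The anniversary day itself counts as completed, so exactly five years
    after diagnosis is five completed years.
    """
    start = pd.to_datetime(start)
    end = pd.to_datetime(end)
    if np.ndim(end) == 0:
        end = pd.Series(pd.Timestamp(end), index=start.index)
    years = end.dt.year.to_numpy() - start.dt.year.to_numpy()
    before_anniv = (end.dt.month.to_numpy() * 100 + end.dt.day.to_numpy()) < (
        start.dt.month.to_numpy() * 100 + start.dt.day.to_numpy()
    )
    return np.maximum(years - before_anniv.astype(int), 0)


def assign_followup_class(cohort: pd.DataFrame, filt: CohortFilter) -> pd.Series:
    """Short versus long follow-up at window entry.

    Completed calendar years from diagnosis to window entry; ``short`` when
    the completed years are <= ``followup_class_cut`` (so exactly 5.0 years,
    and anything under 6 completed years, is short with the default cut of
    5; 6 or more completed years is long).
    """
    w_start = pd.Timestamp(filt.window_start)
    diag = pd.to_datetime(cohort["diagnosis_date"])
    entry = diag.where(diag > w_start, w_start)
    completed = completed_years(diag, entry)
    cls = np.where(completed <= filt.followup_class_cut, "short", "long")
    return pd.Series(cls, index=cohort.index, name="followup_class")
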