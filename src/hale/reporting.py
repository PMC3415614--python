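"""End-to-end orchestration, cohort summaries and survival reporting.

Runs the whole pipeline from one config: simulate (or read) the registry
and survey tables, apply the inclusion rules, build the abridged life
table, the prevalence tables, the Sullivan health expectancies per stratum
and the logistic determinants tables, and write everything with a
provenance header.

Also houses the aggregate-count utilities: a cohort characteristics summary
(counts and column percentages by sex), and a loader for published
aggregate count tables so that in-print worked examples can be checked
without person-level microdata.  The packaged reference counts and LE/HLE
pairs come from the published description of colorectal-cancer survivors in
the Eindhoven Cancer Registry area, 2005-2009.
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._dates import years_between_vec
from .cohort import CohortFilter, read_cohort, read_survey, select_alive_in_window
from .determinants import determinants_table
from .persontime import AgeGrid, aggregate_exposure
from .lifetable import build_life_table, death_rates
from .prevalence import prevalence_by_age
from .simulate import GompertzHazard, LogisticModel, ResponseModel, SimulationParams, generate_cohort, generate_survey
from .sullivan import stratified_sullivan

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "cohort_summary",
    "derived_shares",
    "load_reference_counts",
    "load_reference_expectancies",
    "km_survival",
    "run_pipeline",
]

_AGE_BANDS = [(0, 50, "<50"), (50, 65, "50-64"), (65, 80, "65-79"), (80, np.inf, "80+")]


def _band(ages: np.ndarray, include_under50: bool) -> pd.Series:
    bands = _AGE_BANDS if include_under50 else _AGE_BANDS[1:]
    labels = np.full(len(ages), "", dtype=object)
    for lo, hi, lab in bands:
        labels[(ages >= lo) & (ages < hi)] = lab
    return pd.Series(labels)


def cohort_summary(cohort: pd.DataFrame, filt: CohortFilter) -> pd.DataFrame:
    """Counts and column percentages by sex for the descriptive table.

    Variables: age at diagnosis, attained age at window entry, SES, site,
    stage, treatment, comorbidity, plus a ``total`` row.  Percentages are
    per sex column and rounded to integers for display alongside exact
    counts.
    """
    variables = {}
    if len(cohort):
        w_start = pd.Timestamp(filt.window_start)
        diag = pd.to_datetime(cohort["diagnosis_date"])
        age_dx = years_between_vec(cohort["birth_date"], diag)
        entry = diag.where(diag > w_start, w_start)
        age_entry = years_between_vec(cohort["birth_date"], entry)
        variables["age_at_diagnosis"] = _band(age_dx, include_under50=True)
        variables["age_in_window"] = _band(age_entry, include_under50=False)
        for col in ("ses", "site", "stage", "treatment", "comorbidity"):
            variables[col] = cohort[col].reset_index(drop=True)
        sex = cohort["sex"].reset_index(drop=True)
    else:
        sex = pd.Series([], dtype=object)

    rows = []
    n_male = int((sex == "male").sum())
    n_female = int((sex == "female").sum())
    for var, values in variables.items():
        for level in pd.unique(values):
            m = int(((values == level) & (sex == "male")).sum())
            f = int(((values == level) & (sex == "female")).sum())
            rows.append((var, level, m, f))
    rows.append(("total", "all", n_male, n_female))
    out = pd.DataFrame(rows, columns=["variable", "level", "male", "female"])
    out["male_pct"] = np.where(n_male > 0, 100.0 * out["male"] / max(n_male, 1), 0.0)
    out["female_pct"] = np.where(n_female > 0, 100.0 * out["female"] / max(n_female, 1), 0.0)
    out.loc[out["variable"] == "total", ["male_pct", "female_pct"]] = np.nan
    return out


def derived_shares(summary: pd.DataFrame) -> dict:
    """Headline shares computed from a summary-count table.

    percent_male — share of men among all survivors; percent_65plus_at_dx —
    share aged 65 or older at diagnosis; percent_comorbid_known — share with
    at least one comorbidity among those with known comorbidity status.
    All returned as unrounded percentages.
    """
    totals = summary.loc[summary["variable"] == "total"]
    n_male = float(totals["male"].sum())
    n_female = float(totals["female"].sum())
    n_all = n_male + n_female

    age_dx = summary.loc[summary["variable"] == "age_at_diagnosis"]
    older = age_dx.loc[age_dx["level"].isin(["65-79", "80+"])]
    n_older = float(older["male"].sum() + older["female"].sum())

    com = summary.loc[summary["variable"] == "comorbidity"]
    known = com.loc[com["level"].isin(["0", "1plus"])]
    n_known = float(known["male"].sum() + known["female"].sum())
    plus = com.loc[com["level"] == "1plus"]
    n_plus = float(plus["male"].sum() + plus["female"].sum())

    return {
        "percent_male": 100.0 * n_male / n_all,
        "percent_65plus_at_dx": 100.0 * n_older / n_all,
        "percent_comorbid_known": 100.0 * n_plus / n_known,
    }


def _read_package_csv(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("hale").joinpath("data", name)
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")


def load_reference_counts() -> pd.DataFrame:
    """Published survivor-cohort characteristic counts (by sex), tidy form.

    Same layout as :func:`cohort_summary` minus the percentage columns, so
    the derived shares can be computed from print-published aggregates.
    """
    return _read_package_csv("reference_cohort_counts.csv")


def load_reference_expectancies() -> pd.DataFrame:
    """Published LE / HLE pairs (years) with their printed percent in good health."""
    return _read_package_csv("reference_expectancy_pairs.csv")


def km_survival(
    cohort: pd.DataFrame,
    by: str = "stage",
    horizons=tuple(range(0, 11)),
    window: tuple | None = None,
    filt: CohortFilter | None = None,
) -> pd.DataFrame:
    """Product-limit survival from diagnosis, per group, at yearly horizons.

    Optionally restricted to persons alive in *window* (the survival figure
    may use a wider window than the life table).  Right censoring at end of
    follow-up.  Groups with neither events nor censoring are flagged
    degenerate.
    """
    from lifelines import KaplanMeierFitter

    sub = cohort
    if window is not None:
        wf = (filt or CohortFilter()).replace(window_start=window[0], window_end=window[1])
        sub = select_alive_in_window(cohort, wf)
    durations = years_between_vec(sub["diagnosis_date"], sub["exit_date"])
    events = (sub["vital_status"] == "dead").to_numpy()
    rows = []
    for level in pd.unique(sub[by]):
        sel = (sub[by] == level).to_numpy()
        if sel.sum() == 0:
            continue
        km = KaplanMeierFitter()
        km.fit(durations[sel], events[sel])
        surv = km.survival_function_at_times(list(horizons)).to_numpy()
        for h, s in zip(horizons, surv):
            rows.append((level, float(h), float(s)))
    out = pd.DataFrame(rows, columns=[by, "years_since_diagnosis", "survival"])
    out.attrs["degenerate"] = bool(len(sub) and not events.any() and (durations > 0).all())
    return out


# ---------------------------------------------------------------------------
# pipeline config and runner


@dataclass
class RunConfig:
    """One config object driving the whole pipeline.

    Either a ``simulate`` parameter block or both input paths must be
    given.  ``grid`` is a 'start:last:step' spec; reporting ages must be
    grid boundaries.
    """

    output_dir: str = "hale_output"
    cohort_path: str | None = None
    survey_path: str | None = None
    simulate: dict | None = None
    seed: int = 0
    window_start: str = "2005-01-01"
    window_end: str = "2009-12-31"
    min_age: float = 50.0
    followup_class_cut: float = 5.0
    followup_update: str = "entry"
    alive_at: str = "any"
    grid: str = "50:85:5"
    ages: tuple = (50, 65, 80)
    strata: tuple = ("sex",)
    write_figures: bool = False

    def __post_init__(self):
        if self.simulate is None and (self.cohort_path is None or self.survey_path is None):
            raise ValueError(
                "config must provide either a 'simulate' block or both "
                "cohort_path and survey_path"
            )
        boundaries = AgeGrid.from_spec(self.grid).lowers
        bad = [a for a in self.ages if not np.isclose(boundaries, float(a)).any()]
        if bad:
            raise ValueError(f"reporting age(s) {bad} are not boundaries of grid {self.grid}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("ages", "strata"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_filter(self) -> CohortFilter:
        return CohortFilter(
            window_start=self.window_start,
            window_end=self.window_end,
            min_age_in_window=self.min_age,
            followup_class_cut=self.followup_class_cut,
            followup_update=self.followup_update,
            alive_at=self.alive_at,
            strata=tuple(self.strata),
        )

    def to_simulation_params(self) -> SimulationParams:
        block = dict(self.simulate or {})
        if "background_hazard" in block:
            block["background_hazard"] = GompertzHazard(**block["background_hazard"])
        for key in ("poor_health_model", "disability_model"):
            if key in block:
                mk = dict(block[key])
                if "stage_offsets" in mk:
                    mk["stage_offsets"] = tuple(mk["stage_offsets"])
                block[key] = LogisticModel(**mk)
        if "response_model" in block:
            block["response_model"] = ResponseModel(**block["response_model"])
        for key in ("stage_probs", "stage_excess_hazard", "ses_probs"):
            if key in block:
                block[key] = tuple(block[key])
        block.setdefault("seed", self.seed)
        block.setdefault("window_start", self.window_start)
        block.setdefault("window_end", self.window_end)
        return SimulationParams(**block)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(config: RunConfig) -> list:
    from . import __version__

    return [
        f"hale {__version__}",
        f"config_hash {config.config_hash()}",
        f"generated {datetime.now(timezone.utc).isoformat(timespec='seconds')}",
    ]


def _write_csv(frame: pd.DataFrame, path: Path, header_lines) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate/read -> select -> life table -> Sullivan -> determinants.

    Returns the result bundle as a dict of DataFrames (and the selected
    cohort); writes CSV outputs plus a ``run.json`` provenance record under
    ``config.output_dir``.  Deterministic given the seed.
    """
    filt = config.to_filter()
    grid = AgeGrid.from_spec(config.grid)
    header = _provenance(config)

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    if config.simulate is not None:
        params = config.to_simulation_params()
        cohort = stage("simulate_cohort", generate_cohort, params)
        survey = stage("simulate_survey", generate_survey, cohort, params)
    else:
        cohort = stage("read_cohort", read_cohort, config.cohort_path)
        survey = stage("read_survey", read_survey, config.survey_path)
    log.info("pipeline: %d cohort rows, %d survey rows in", len(cohort), len(survey))

    selected = stage("select", select_alive_in_window, cohort, filt)
    survey = survey.loc[survey["person_id"].isin(selected["person_id"]).to_numpy()]
    log.info("pipeline: %d selected, %d survey rows retained", len(selected), len(survey))

    summary = stage("summary", cohort_summary, selected, filt)
    exposure = stage("persontime", aggregate_exposure, selected, filt, grid)
    lt = stage("lifetable", lambda: build_life_table(death_rates(exposure), grid))
    prev_h = stage("prevalence_health", prevalence_by_age, survey, selected, grid, "poor_health")
    prev_d = stage("prevalence_disability", prevalence_by_age, survey, selected, grid, "disability")
    hle = stage(
        "sullivan", stratified_sullivan, selected, survey, filt, grid,
        tuple(config.strata), tuple(config.ages),
    )
    det_h = stage("determinants_health", determinants_table, survey, selected, filt, "poor_health")
    det_d = stage("determinants_disability", determinants_table, survey, selected, filt, "disability")
    km = stage("km", km_survival, selected)

    bundle = {
        "cohort": selected,
        "summary": summary,
        "exposure": exposure,
        "life_table": lt,
        "prevalence_poor_health": prev_h,
        "prevalence_disability": prev_d,
        "health_expectancy": hle,
        "determinants_poor_health": det_h,
        "determinants_disability": det_d,
        "km_survival": km,
    }

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, frame in bundle.items():
        if name == "cohort":
            continue
        _write_csv(frame, outdir / f"{name}.csv", header)
    shares = derived_shares(summary)
    record = {
        "provenance": header,
        "n_input": int(len(cohort)),
        "n_selected": int(len(selected)),
        "n_survey": int(len(survey)),
        "derived_shares": shares,
        "deaths": int(exposure["deaths"].sum()),
        "person_years": float(exposure["person_years"].sum()),
    }
    (outdir / "run.json").write_text(json.dumps(record, indent=2))
    bundle["run"] = record
    return bundle
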