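# Methods

This note documents the models, conventions and numerical choices behind
`hale`, and what the validation suite does and does not establish.

## Cohort model and inclusion rules

The unit of analysis is a cancer survivor: a person with a diagnosis date,
followed until death or the end of registry follow-up.  The observation
window (default 2005-01-01 to 2009-12-31) defines a period analysis: a
person is included when they are alive at some instant inside the window,
were diagnosed by its end, and attain the minimum age (default 50) at some
instant while alive inside it — so a person aged 49 at the window start who
turns 50 before dying or being censored is included, while one who dies at
49.9 is not.  A stricter reading ("alive at the window start") is available
as `CohortFilter(alive_at="start")`.

Time since diagnosis is dichotomized into short versus long follow-up at 5
completed calendar years (anniversary arithmetic, so exactly five years is
still "short"; six or more completed years is "long").  The class is frozen
at each person's entry into the window by default; with
`followup_update="dynamic"` the exposure is instead re-cut at the age where
the class flips, so one person can contribute person-time to both classes.

All other age and duration arithmetic uses exact real-valued year fractions
with a 365.2425-day year; calendar dates are stored at day resolution, so
any duration is exact to one day.

## Person-time splitting

Each included person contributes exposure from
`max(window_start, diagnosis_date, date of attaining the grid floor)` to
`min(exit_date, window_end)`.  That span, expressed in age, is intersected
with half-open age intervals `[lower, upper)` — a person enters 65-69 at
the instant of the 65th birthday.  A death inside the window is attributed
to the interval containing the last instant of exposure; a death falling
exactly on a boundary therefore belongs to the interval below it, which
keeps the invariant "no deaths in an interval without person-time".
Exposure sums are exact interval-overlap arithmetic (not day counting), so
aggregate person-years equal the summed individual spans to floating-point
precision; the test suite additionally checks agreement with a day-by-day
counting oracle to one day per person.

Late entry is deliberate: survivors diagnosed inside the window contribute
exposure only from diagnosis, because the target population is survivors,
not the general population.  The calendar dimension is collapsed — one
period, no age-by-period Lexis triangles.

## Life table

Abridged period life table on 5-year groups 50-85+ by default (any grid via
`AgeGrid.from_spec("start:last:step")`).  Conventions:

* `m_x = D_x / P_x`; a cell with deaths but no exposure is an error.
* A cell with neither deaths nor exposure has `m_x = 0` by default
  (transparency over smoothing; a warning flags person-years below 50).
  The alternative `zero_cell="pool"` borrows the pooled rate of adjacent
  non-empty cells, which is what sparse strata and fine grids need.
* `a_x = n_x / 2` for closed intervals (the standard abridged-table default
  for adult ages; exposed as `a_convention`, currently the only option).
* `q_x = n_x m_x / (1 + (n_x - a_x) m_x)`, capped at 1.  At very high
  mortality (5-year intervals with m around 0.5/yr, as in distant-stage
  strata) the cap binds and survivorship hits zero; expectancies at older
  reporting ages are then undefined and reported as NaN with a warning,
  never silently extrapolated.
* Open interval: `q = 1`, `L = l / m` (exponential closure), so `e` at its
  start equals `1/m`.  A zero rate in the open interval is an error
  instructing the caller to pool older groups.
* Radix 100,000; `e_x = T_x / l_x` at grid boundaries only (no
  interpolation).

## Prevalence and dichotomization

The general-health item maps excellent/very good/good to `good` and
fair/poor to `poor`; the walking item maps both "very much" and "a little"
limited to `limited`.  Missing answers are excluded from numerator and
denominator.  Respondents are indexed by age at the survey date (not at
diagnosis) and assigned to the same grid as the life table; respondents
below the grid floor are excluded.

Empty cells (typically the open 85+ group in small strata) borrow the
nearest non-empty younger cell's estimate and its standard error, keep
`n = 0`, and are flagged `borrowed` with a logged warning.  Borrowing keeps
the Sullivan sum computable without modelling; the alternative of
logistic-on-age smoothing was considered and rejected as harder to audit in
stratified runs.

## Sullivan health expectancies

`HLE_x = sum_{y>=x} (1 - pi_y) L_y / l_x`, prevalence applied to the L of
the same age interval with no within-interval age weighting.  The standard
error keeps the prevalence (binomial) component,
`Var = sum L_y^2 se(pi_y)^2 / l_x^2`; the mortality component is omitted by
default because prevalence uncertainty dominates when the survey is one or
two orders of magnitude smaller than the registry, and a Chiang-style
mortality term is available (`mortality_variance=True`) for single-source
settings.  Reporting ages default to 50, 65 and 80.  Percentages of
remaining life in a state are computed from unrounded years and then
rounded to integer percent; this convention reproduces the printed
percentages of the published LE/HLE pairs shipped with the package.

Stratified runs repeat person-time → life table → prevalence → Sullivan
within each level of one grouping variable at a time (sex, SES, follow-up
class, stage, comorbidity).  Records with unknown stage are excluded from
stage-stratified runs but retained in overall runs; institutionalized and
unknown SES are retained in the regression but excluded from SES-stratified
expectancy tables (both groups are too small to support stable life
tables).  Strata with fewer than 10 deaths are flagged `sparse`, and a
stratum with no deaths at all is an error naming the stratum.

## Determinants regression

Poor health and disability are modelled by maximum-likelihood logistic
regression (IRLS via a binomial GLM) on sex, 5-year age group at survey,
SES, tumour site, follow-up class, stage, comorbidity and treatment, dummy
coded against male / youngest band / high / colon / short / I / none /
surgery-only.  `unknown` levels are kept as explicit categories.  Wald 95%
intervals on `exp(beta)`; display tables can collapse age to broad bands
(50-64/65-79/80+) by refitting.  The design is rank-checked before the
fit, and complete or quasi-complete separation (fitted probabilities within
1e-8 of 0/1 with coefficients beyond 15 in absolute value) raises an
explicit error rather than returning garbage — sparse strata such as
distant-stage respondents in small cohorts genuinely trigger this.
No multiple-testing adjustment is applied; significance at p < 0.05 is a
display flag only.

## Synthetic registry generator

Mortality: all-cause hazard `mu(a) = alpha * exp(beta * a) + excess(stage)`
— a Gompertz background schedule (default alpha = 3e-5/yr at age 0,
beta = 0.095/yr, roughly a Western European adult schedule) plus a constant
stage-specific excess from diagnosis (default 0.01, 0.02, 0.05, 0.45/yr for
stages I-IV).  Constant additive excess is the simplest form with a
closed-form oracle; the stage-IV value is chosen so that distant-stage
survivors live about two years, matching the published registry gradient,
at the cost of understating the front-loading of real stage-IV mortality.
Death times are sampled exactly as the minimum of the two component event
times (Gompertz part by closed-form inversion, excess part exponential).

Cohort structure: diagnoses uniform over a 20-year lookback before the
window end; age at diagnosis truncated-normal (mean 69, sd 11, bounds
30-95), matching the published age mix; 53% male; stage mix 26/36/25/13%;
63% with comorbidity; SES 32/40/28% high/middle/low; treatment assigned
descriptively by stage with no effect on survival.  With the default
22,500 generated persons, about 14,800 survive selection — the scale of
the registry cohort being emulated — with roughly 1,350 survey
respondents.

Survey: persons alive at the survey date (default: window end) are sampled
with probability `survey_fraction`; sampled persons respond with
probability `logit^-1(1.8 - 0.6 * poor)`, a mild health-dependent
nonresponse whose magnitude is not identified by any published figure and
is documented as arbitrary.  True poor-health and disability states are
Bernoulli draws from logistic models in age, stage and comorbidity whose
defaults reproduce the published prevalence levels and odds-ratio
directions (overall poor health about 26%, disability about 32%, stage-IV
and comorbidity odds ratios the strongest).  Item levels are generated so
the dichotomies match the models exactly: the "good" mass is spread
uniformly over excellent/very good/good, the "poor" mass over fair/poor.
Around 5% (health) and 8% (walking) of answers are blanked as item
nonresponse.  One integer seed drives everything through deterministic
substreams.

What the generator does **not** emulate: time-varying excess hazard,
treatment effects on survival or health, stoma status and symptom scales,
response-shift in self-rating, and correlation between health state and
dropout beyond the single response coefficient.  Passing recovery tests
therefore validates the estimator machinery, not these aspects of real
registry data.

## Validation design and problem sizes

Parameter-recovery checks compare the full pipeline against
`analytic_life_expectancy`, an adaptive-quadrature evaluation of
`int exp(-H(t)) dt` truncated where survivorship falls below 1e-12 (itself
cross-checked against a 0.01-year Riemann sum).

The precision of a period life-table e50 is limited by its thinnest age
cell, and a realistic registry cohort (diagnosed old, five-year window)
leaves young and very old cells sparse.  Recovery runs therefore use a
dense-exposure design (`validation_cohort`): a 40-year window with
diagnoses uniform across it, half the cohort diagnosed at ages 40-50
(so exposure tracks survivorship through every age) and half at 45-85 (so
the oldest cells are populated directly), on a 1-year grid 50-90+ with
pooled zero cells.  With 20,000 persons and a uniform excess of 0.15/yr the
Monte-Carlo standard deviation of e50 is about 0.11 years; at 40,000
persons with a constant 0.1/yr hazard it is about 0.07 years.  The
healthy-fraction check (constant 30% prevalence through an intercept-only
model, full survey, no response selection) uses the registry-style window,
where respondent coverage across ages is good; its Monte-Carlo sd is about
0.7 percentage points.  Logistic recovery refits the generator's linear
predictor (continuous age, stage dummies, comorbidity) on 20 independent
4,000-person cohorts and checks that all coefficients fall within 3 Wald
SE of truth in at least 18.

These sizes keep the whole suite under ten seconds while leaving each
stochastic tolerance at roughly three standard deviations.

## Known limitations

* Exponential closure of the open interval biases e upward when the true
  hazard keeps rising beyond the last boundary; with the default 85+ group
  and registry-level mortality the effect on e50 is below 0.1 years.
* The abridged q-from-m conversion with midpoint a_x degrades for 5-year
  intervals at hazards above ~0.4/yr (distant-stage strata); the package
  reports NaN beyond the age where survivorship collapses rather than
  refining a_x, and a 1-year grid is the recommended remedy.
* Borrowed prevalence cells understate between-age heterogeneity at the
  oldest ages when the survey is sparse there.
* The published headline life expectancies of the emulated registry cohort
  are not reproducible without its microdata; the in-package reference
  files carry only printed aggregate counts and LE/HLE pairs, used for
  arithmetic consistency checks.
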