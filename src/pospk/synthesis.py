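"""Synthetic study data with the structure the analysis assumes.

Two generators live here:

* :func:`generate_virtual_population` draws (age, weight) pairs from a
  parametric pediatric growth stand-in: ages uniform within each group band
  and weight lognormal around a piecewise-linear median-growth curve,
  truncated to the group's observed range. Defaults are calibrated to the
  analysis population (median 16 kg at 2 to <7 years, 45.4 kg at 7 to 17
  years) and, for the adolescent tablet population, to a survey-like
  distribution in which fewer than 5% of adolescents weigh under 40 kg.

* :func:`generate_study_dataset` emulates the phase 1b dose-escalation
  design: three weight-based dose cohorts (3.5 / 4.5 / 6 mg/kg, 300-mg cap),
  IV BID on day 1, IV QD through day 10, and for a subset of subjects an
  oral-suspension switch QD through day 28, with sparse/intensive sampling
  schedules and an assay LLOQ of 5.00 ng/mL.

Data-preparation rules (BLQ and missing-value exclusion, pre-first-dose
exclusion, duplicate handling, covariate imputation) are applied by
:func:`apply_preparation_rules` and :func:`impute_covariates`.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    DEFAULT_INFUSION_HOURS,
    DEFAULT_LLOQ,
    FOOD_CATEGORIES,
    ROUTE_IV,
    ROUTE_PFS,
    DoseEvent,
    Observation,
    StudyDataset,
    Subject,
    concentration_profile,
    dose_for_weight,
    individual_from_population,
)
from .params import PopulationParameters


# ---------------------------------------------------------------------------
# virtual populations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgeGroup:
    """One age band of a virtual population."""

    label: str
    age_min: float  # years, inclusive
    age_max: float  # years, exclusive
    n: int
    median_anchors: tuple  # ((age, kg), ...) piecewise-linear median curve
    weight_log_sd: float  # lognormal spread around the median curve
    weight_range: tuple  # (lo, hi) kg truncation

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"age group {self.label!r} must have n >= 1, got {self.n}")
        if not 0 < self.weight_range[0] < self.weight_range[1]:
            raise ValueError("weight truncation bounds must be positive and ordered")


@dataclass(frozen=True)
class VirtualPopulationSpec:
    groups: tuple
    seed: int | None = None


def study_population_spec(n_young: int = 1000, n_old: int = 1000) -> VirtualPopulationSpec:
    """Age-weight stand-in calibrated to the analysis population.

    Group medians and truncation ranges follow the observed baseline
    characteristics: 16 kg (10.2-41.7) at 2 to <7 years and 45.4 kg
    (18.2-102) at 7 to 17 years.
    """
    young = AgeGroup(
        label="2 to <7 years",
        age_min=2.0,
        age_max=7.0,
        n=n_young,
        median_anchors=((2.0, 10.5), (4.5, 16.0), (7.0, 21.5)),
        weight_log_sd=0.21,
        weight_range=(10.2, 41.7),
    )
    old = AgeGroup(
        label="7 to 17 years",
        age_min=7.0,
        age_max=18.0,
        n=n_old,
        median_anchors=((7.0, 21.5), (12.5, 45.4), (18.0, 69.3)),
        weight_log_sd=0.25,
        weight_range=(18.2, 102.0),
    )
    return VirtualPopulationSpec(groups=(young, old))


def adolescent_population_spec(n: int = 1000) -> VirtualPopulationSpec:
    """Adolescent (12-17 y) stand-in for the fixed-dose tablet assessment.

    Calibrated so that fewer than 5% of draws fall below 40 kg, the printed
    feature of the survey-derived virtual population used for bridging.
    """
    grp = AgeGroup(
        label="adolescents 12 to 17 years",
        age_min=12.0,
        age_max=18.0,
        n=n,
        median_anchors=((12.0, 52.6), (18.0, 69.4)),
        weight_log_sd=0.17,
        weight_range=(30.0, 110.0),
    )
    return VirtualPopulationSpec(groups=(grp,))


def _median_weight(anchors, age):
    xs = np.array([a for a, _ in anchors])
    ys = np.array([w for _, w in anchors])
    return np.interp(age, xs, ys)


def generate_virtual_population(
    spec: VirtualPopulationSpec, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Sample (age, weight) pairs; returns columns age, weight, group.

    Ages are uniform within each band; weights are truncated-lognormal draws
    around the band's median growth curve, sampled by inverse CDF so the
    truncation never distorts the within-range shape.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(spec.seed if rng is None else rng)
    frames = []
    for g in spec.groups:
        if g.n < 1:
            raise ValueError(f"group {g.label!r} must have at least one subject")
        age = rng.uniform(g.age_min, g.age_max, size=g.n)
        med = _median_weight(g.median_anchors, age)
        lo, hi = g.weight_range
        if not (0 < lo < hi):
            raise ValueError("weight truncation bounds must be positive and ordered")
        a = np.log(lo / med) / g.weight_log_sd
        b = np.log(hi / med) / g.weight_log_sd
        u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b))
        weight = med * np.exp(g.weight_log_sd * stats.norm.ppf(u))
        frames.append(pd.DataFrame({"age": age, "weight": weight, "group": g.label}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# study design emulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyDesign:
    """Phase 1b dose-escalation design parameters."""

    cohort_levels: tuple = (3.5, 4.5, 6.0)  # mg/kg
    cohort_sizes: tuple = (35, 31, 48)
    iv_days: int = 10  # IV QD through this day (BID on day 1)
    pfs_days: int = 28  # oral suspension QD through this day for switchers
    switch_fraction: float = 60.0 / 114.0
    dose_cap: float = 300.0  # mg
    infusion_duration: float = DEFAULT_INFUSION_HOURS
    lloq: float = DEFAULT_LLOQ
    frac_young: float = 48.0 / 114.0  # share of subjects aged 2 to <7 years
    # sampling schedules (nominal hours relative to the anchor dose)
    iv_trough_day: int = 6
    iv_intensive_days: tuple = (7, 8, 9, 10)
    iv_sample_offsets: tuple = (-0.1, DEFAULT_INFUSION_HOURS, 4.0, 6.0, 12.0, 24.0)
    pfs_sampling_days: tuple = (25, 26, 27, 28)
    pfs_inpatient_offsets: tuple = (-0.1, 2.0, 4.0, 6.0, 8.0, 24.0)
    pfs_outpatient_offsets: tuple = (-0.1, 2.0, 4.0)
    inpatient_fraction: float = 0.6
    # covariate generation
    male_fraction: float = 0.59
    white_fraction: float = 0.83
    not_hispanic_fraction: float = 0.87
    egfr_median: float = 146.0
    egfr_log_sd: float = 0.35
    egfr_range: tuple = (12.0, 400.0)
    egfr_missing_fraction: float = 2.0 / 114.0
    food_frequencies: tuple = (0.25, 0.25, 0.25, 0.25)  # none/light/moderate/heavy
    #: multiplicative shift applied to the F1 logit for fed oral doses
    #: (0 = the no-food-effect truth)
    food_logit_shift: float = 0.0
    # data artifacts exercised by the preparation rules
    missing_time_fraction: float = 0.0
    duplicate_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.cohort_levels) != len(self.cohort_sizes):
            raise ValueError("cohort_levels and cohort_sizes must align")
        if any(n < 1 for n in self.cohort_sizes):
            raise ValueError("cohort sizes must be >= 1")
        if self.lloq <= 0:
            raise ValueError("lloq must be positive")
        for sched in (self.iv_sample_offsets, self.pfs_inpatient_offsets, self.pfs_outpatient_offsets):
            if list(sched) != sorted(sched):
                raise ValueError("sampling schedules must be increasing")


def dose_times_qd(first_day: int, last_day: int) -> list[float]:
    """Dose times (h) for QD dosing on days first_day..last_day (day 1 == t 0)."""
    return [24.0 * (d - 1) for d in range(first_day, last_day + 1)]


def build_dose_schedule(
    level: float,
    weight: float,
    design: StudyDesign,
    switch_to_pfs: bool,
    food_categories: list[str] | None = None,
) -> list[DoseEvent]:
    """IV BID day 1, IV QD days 2..iv_days, optional PFS QD to pfs_days."""
    amount = dose_for_weight(weight, level, design.dose_cap)
    doses = [
        DoseEvent(0.0, amount, ROUTE_IV, design.infusion_duration),
        DoseEvent(12.0, amount, ROUTE_IV, design.infusion_duration),
    ]
    for t in dose_times_qd(2, design.iv_days):
        doses.append(DoseEvent(t, amount, ROUTE_IV, design.infusion_duration))
    if switch_to_pfs:
        oral_times = dose_times_qd(design.iv_days + 1, design.pfs_days)
        cats = food_categories or ["none"] * len(oral_times)
        for t, cat in zip(oral_times, cats):
            doses.append(DoseEvent(t, amount, ROUTE_PFS, food_category=cat))
    return doses


def _sample_covariates(design: StudyDesign, rng: np.random.Generator) -> dict:
    sex = "M" if rng.random() < design.male_fraction else "F"
    race = "White" if rng.random() < design.white_fraction else "Other"
    eth = "Not Hispanic" if rng.random() < design.not_hispanic_fraction else "Hispanic"
    lo, hi = design.egfr_range
    a = math.log(lo / design.egfr_median) / design.egfr_log_sd
    b = math.log(hi / design.egfr_median) / design.egfr_log_sd
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b))
    egfr = design.egfr_median * math.exp(design.egfr_log_sd * stats.norm.ppf(u))
    if rng.random() < design.egfr_missing_fraction:
        egfr = None
    return {"sex": sex, "race": race, "ethnicity": eth, "egfr": egfr}


def _sample_times(design: StudyDesign, switch: bool, inpatient: bool, rng) -> list[float]:
    times = [24.0 * (design.iv_trough_day - 1) - 0.1]  # day-6 pre-dose trough
    iv_day = int(rng.choice(design.iv_intensive_days))
    anchor = 24.0 * (iv_day - 1)
    times += [anchor + off for off in design.iv_sample_offsets]
    if switch:
        pfs_day = int(rng.choice(design.pfs_sampling_days))
        anchor = 24.0 * (pfs_day - 1)
        offsets = design.pfs_inpatient_offsets if inpatient else design.pfs_outpatient_offsets
        times += [anchor + off for off in offsets]
    return sorted(times)


def generate_study_dataset(
    design: StudyDesign,
    truth: PopulationParameters,
    seed: int | None = None,
) -> StudyDataset:
    """Simulate one study at ``design`` from the ``truth`` parameters.

    Random effects are multivariate normal with the truth covariance;
    residual error is lognormal on concentrations, exp(eps) with
    eps ~ N(0, sigma_log^2). BLQ flags are set against the design LLOQ.
    Reproducible under ``seed`` (falls back to ``design.seed``).
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    omega = truth.omega_matrix()
    # factor only the positive-variance block so zero variances yield eta = 0 exactly
    chol = np.zeros((3, 3))
    active = np.diag(omega) > 0
    if active.any():
        idx = np.ix_(active, active)
        chol[idx] = np.linalg.cholesky(omega[idx])
    pop_spec = study_population_spec()

    subjects: list[Subject] = []
    sid = 0
    for level, size in zip(design.cohort_levels, design.cohort_sizes):
        for _ in range(size):
            sid += 1
            young = rng.random() < design.frac_young
            g = pop_spec.groups[0] if young else pop_spec.groups[1]
            draw = generate_virtual_population(
                VirtualPopulationSpec(groups=(replace(g, n=1),)), rng
            )
            age = float(draw.age.iloc[0])
            weight = float(draw.weight.iloc[0])
            switch = rng.random() < design.switch_fraction
            inpatient = rng.random() < design.inpatient_fraction

            n_oral = max(design.pfs_days - design.iv_days, 0)
            cats = [
                FOOD_CATEGORIES[int(c)]
                for c in rng.choice(len(FOOD_CATEGORIES), size=n_oral, p=design.food_frequencies)
            ]
            doses = build_dose_schedule(level, weight, design, switch, cats)

            eta = chol @ rng.standard_normal(3)
            ind = individual_from_population(truth, weight, tuple(eta))
            times = _sample_times(design, switch, inpatient, rng)
            conc_true = _true_concentrations(ind, doses, times, design.food_logit_shift)
            eps = rng.normal(0.0, truth.sigma_log, size=len(times))
            obs_conc = conc_true * np.exp(eps)

            observations = []
            for t, c in zip(times, obs_conc):
                t_obs: float = t
                missing = False
                if design.missing_time_fraction and rng.random() < design.missing_time_fraction:
                    t_obs, missing = math.nan, True
                observations.append(
                    Observation(
                        time=t_obs,
                        concentration=float(c),
                        blq_flag=bool(c < design.lloq),
                        missing_flag=missing,
                    )
                )
                if design.duplicate_fraction and rng.random() < design.duplicate_fraction:
                    c2 = float(c * math.exp(rng.normal(0.0, 0.05)))
                    observations.append(
                        Observation(time=t_obs, concentration=c2, blq_flag=bool(c2 < design.lloq))
                    )

            cov = _sample_covariates(design, rng)
            subjects.append(
                Subject(
                    id=sid,
                    weight=weight,
                    age=age,
                    doses=doses,
                    observations=observations,
                    eta=tuple(eta),
                    **cov,
                )
            )
    meta = {"design": "P097-emulation", "cohort_levels": list(design.cohort_levels)}
    return StudyDataset(subjects=subjects, lloq=design.lloq, meta=meta)


def _true_concentrations(ind, doses, times, food_logit_shift):
    """Model concentrations, applying any generating food effect per oral dose."""
    if not food_logit_shift:
        return concentration_profile(ind, doses, times)
    from .params import expit, logit

    base_logit = logit(ind.f1_i)
    plain, fed = [], []
    for d in doses:
        (fed if (d.is_oral and d.fed) else plain).append(d)
    total = np.zeros(len(times))
    if plain:
        total += concentration_profile(ind, plain, times)
    if fed:
        f_fed = expit(base_logit + food_logit_shift)
        scaled = replace(ind, f1_i=f_fed)
        total += concentration_profile(scaled, fed, times)
    return total


# ---------------------------------------------------------------------------
# data-preparation rules
# ---------------------------------------------------------------------------


def apply_preparation_rules(raw: StudyDataset) -> tuple[StudyDataset, dict]:
    """Exclude unusable observations; return the clean set and a count report.

    Categories (disjoint, applied in this precedence):
    ``missing`` (lost sampling time or missing value), ``pre_first_dose``
    (pre-treatment samples above the LLOQ), ``blq`` (below the LLOQ), and
    ``duplicate_time`` (same time within a subject; the first record is kept).
    """
    report = {"missing": 0, "pre_first_dose": 0, "blq": 0, "duplicate_time": 0}
    clean_subjects = []
    for s in raw.subjects:
        kept: list[Observation] = []
        seen_times: set[float] = set()
        t_first = s.first_dose_time()
        for o in s.observations:
            if o.missing_flag or math.isnan(o.time) or math.isnan(o.concentration):
                report["missing"] += 1
            elif o.time < t_first and o.concentration >= raw.lloq:
                report["pre_first_dose"] += 1
            elif o.concentration < raw.lloq:
                report["blq"] += 1
            elif o.time in seen_times:
                report["duplicate_time"] += 1
            else:
                seen_times.add(o.time)
                kept.append(o)
        clean_subjects.append(replace_observations(s, kept))
    clean = StudyDataset(subjects=clean_subjects, lloq=raw.lloq, meta=dict(raw.meta))
    if clean.n_observations == 0:
        import warnings

        warnings.warn("all observations excluded by preparation rules")
    return clean, report


def replace_observations(s: Subject, observations: list[Observation]) -> Subject:
    out = copy.copy(s)
    out.observations = list(observations)
    return out


#: covariates eligible for imputation and the stepwise search
CONTINUOUS_COVARIATES = ("egfr",)
CATEGORICAL_COVARIATES = ("sex", "race", "ethnicity")
MAX_MISSING_FRACTION = 0.30


def impute_covariates(ds: StudyDataset) -> StudyDataset:
    """Impute missing covariates; flag covariates missing in >30% of subjects.

    Continuous covariates are imputed with the median of the remaining values
    within the subject's age group (2 to <7 vs 7 to 17 years); categorical
    covariates with the most frequent category. Unusable covariates are
    recorded in ``meta['unusable_covariates']`` and never imputed.
    """
    n = len(ds.subjects)
    unusable = []
    subjects = [copy.copy(s) for s in ds.subjects]

    for cov in CONTINUOUS_COVARIATES:
        missing = [s for s in subjects if getattr(s, cov) is None]
        if not missing:
            continue
        if len(missing) / n > MAX_MISSING_FRACTION:
            unusable.append(cov)
            continue
        for grp_test in (lambda a: a < 7.0, lambda a: a >= 7.0):
            vals = [
                getattr(s, cov)
                for s in subjects
                if grp_test(s.age) and getattr(s, cov) is not None
            ]
            fill = float(np.median(vals)) if vals else None
            if fill is None:  # fall back to the overall median
                allv = [getattr(s, cov) for s in subjects if getattr(s, cov) is not None]
                fill = float(np.median(allv))
            for s in subjects:
                if grp_test(s.age) and getattr(s, cov) is None:
                    setattr(s, cov, fill)

    for cov in CATEGORICAL_COVARIATES:
        missing = [s for s in subjects if getattr(s, cov) in (None, "")]
        if not missing:
            continue
        if len(missing) / n > MAX_MISSING_FRACTION:
            unusable.append(cov)
            continue
        vals = [getattr(s, cov) for s in subjects if getattr(s, cov) not in (None, "")]
        mode = pd.Series(vals).mode().iloc[0]
        for s in missing:
            setattr(s, cov, mode)

    meta = dict(ds.meta)
    meta["unusable_covariates"] = unusable
    return StudyDataset(subjects=subjects, lloq=ds.lloq, meta=meta)
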