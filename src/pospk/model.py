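"""Structural PK model: dosing records, subjects, profiles and exposures.

One-compartment disposition with first-order absorption, parameterized by
clearance CL (L/h) and central volume Vc (L); IV infusions enter the central
compartment directly and oral doses through a first-order depot with rate ka.
Individual parameters derive from the population typical values through
allometric weight scaling, covariate multipliers and random effects:

    CL_i = CL_typ (WT/WT_ref)^alpha_CL e^{eta_CL}
    Vc_i = Vc_typ (WT/WT_ref)^alpha_Vc e^{eta_Vc}
    F1_i = expit(logit(F1_typ) + eta_F1)

Steady-state exposure metrics Cavg (AUC_tau / tau) and Cmin (trough at the
end of the interval) are computed from the analytic antiderivative of the
superposed exponential solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._kernel import DoseGrid, conc_at, cum_auc_at
from .params import IndividualParameters, PopulationParameters, expit, logit

DEFAULT_LLOQ = 5.00  # ng/mL, assay lower limit of quantification
DEFAULT_INFUSION_HOURS = 1.5

ROUTE_IV = "iv"
ROUTE_PFS = "pfs"
ROUTE_TABLET = "tablet"

#: relative bioavailability of the oral suspension vs the tablet; individual
#: tablet bioavailability is F1_i divided by this ratio
PFS_TO_TABLET_RATIO = 1.2

FOOD_CATEGORIES = ("none", "light", "moderate", "heavy")


@dataclass(frozen=True)
class DoseEvent:
    """A single administration. ``time`` is hours since the first dose."""

    time: float
    amount: float  # mg
    route: str = ROUTE_IV
    infusion_duration: float = DEFAULT_INFUSION_HOURS  # h, IV only
    food_category: str = "none"  # meal category attached to oral doses

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError(f"dose amount must be positive, got {self.amount}")
        if self.time < 0:
            raise ValueError(f"dose time must be non-negative, got {self.time}")
        if self.route not in (ROUTE_IV, ROUTE_PFS, ROUTE_TABLET):
            raise ValueError(f"unknown route {self.route!r}")
        if self.route == ROUTE_IV and self.infusion_duration <= 0:
            raise ValueError("IV doses need a positive infusion duration")
        if self.food_category not in FOOD_CATEGORIES:
            raise ValueError(f"unknown food category {self.food_category!r}")

    @property
    def is_oral(self) -> bool:
        return self.route != ROUTE_IV

    @property
    def fed(self) -> bool:
        """Meal (any size) within the pre/post-dose food-assessment window."""
        return self.food_category != "none"


@dataclass(frozen=True)
class Observation:
    """A plasma concentration sample."""

    time: float  # h; NaN when the sampling time was lost
    concentration: float  # ng/mL
    blq_flag: bool = False
    missing_flag: bool = False

    @property
    def usable(self) -> bool:
        return not (self.blq_flag or self.missing_flag or math.isnan(self.time))


@dataclass
class Subject:
    """One trial participant: covariates, dosing history and observations."""

    id: int
    weight: float  # kg
    age: float  # years
    sex: str = "M"
    race: str = "White"
    ethnicity: str = "Not Hispanic"
    egfr: float | None = None  # mL/min/1.73 m^2
    doses: list[DoseEvent] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)
    eta: tuple[float, float, float] | None = None  # simulation truth, if known

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"weight must be positive, got {self.weight}")

    @property
    def has_oral_doses(self) -> bool:
        return any(d.is_oral for d in self.doses)

    def first_dose_time(self) -> float:
        return min(d.time for d in self.doses) if self.doses else math.inf


@dataclass
class StudyDataset:
    """A cohort of subjects plus dataset-level metadata."""

    subjects: list[Subject]
    lloq: float = DEFAULT_LLOQ
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)

    @property
    def n_usable_observations(self) -> int:
        return sum(sum(o.usable for o in s.observations) for s in self.subjects)


@dataclass(frozen=True)
class ExposureMetrics:
    """Steady-state exposure over one dosing interval."""

    cavg: float  # ng/mL, AUC over the interval divided by tau
    cmin: float  # ng/mL, concentration at the interval end (trough)
    interval_start: float
    interval_end: float

    @property
    def tau(self) -> float:
        return self.interval_end - self.interval_start


def individual_from_population(
    pop: PopulationParameters,
    weight: float,
    eta: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> IndividualParameters:
    """Realize subject-level parameters from typical values and random effects."""
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight}")
    wr = weight / pop.wt_ref
    cl_i = pop.cl_typ * wr**pop.alpha_cl * math.exp(eta[0])
    vc_i = pop.vc_typ * wr**pop.alpha_vc * math.exp(eta[1])
    # keep f1 strictly inside (0, 1) even where expit saturates in floats
    f1_i = min(max(expit(logit(pop.f1_typ) + eta[2]), 1e-15), 1.0 - 1e-15)
    return IndividualParameters(cl_i=cl_i, vc_i=vc_i, ka_i=pop.ka, f1_i=f1_i, eta=tuple(eta))


def _dose_grid(doses: list[DoseEvent]) -> DoseGrid:
    rows = [
        (
            d.time,
            d.amount,
            d.infusion_duration if not d.is_oral else 1.0,
            d.is_oral,
            1.0 / PFS_TO_TABLET_RATIO if d.route == ROUTE_TABLET else 1.0,
        )
        for d in doses
    ]
    return DoseGrid.from_lists([rows])


def concentration_profile(
    ind: IndividualParameters, doses: list[DoseEvent], times
) -> np.ndarray:
    """Concentration (ng/mL) at ``times`` under the superposed closed form.

    The solution is linear in dose amounts; tablet doses carry an implicit
    bioavailability divisor of ``PFS_TO_TABLET_RATIO``.
    """
    times = np.asarray(times, dtype=float)
    if times.size and times.min() < 0:
        raise ValueError("observation times must be non-negative")
    if not doses:
        return np.zeros_like(times)
    grid = _dose_grid(doses)
    sidx = np.zeros(times.shape, dtype=int)
    return conc_at(
        times,
        sidx,
        grid,
        np.array([ind.cl_i]),
        np.array([ind.vc_i]),
        np.array([ind.ka_i]),
        np.array([ind.f1_i]),
    )


def exposure_metrics(
    ind: IndividualParameters,
    doses: list[DoseEvent],
    interval_start: float,
    tau: float = 24.0,
) -> ExposureMetrics:
    """Cavg and Cmin over ``[interval_start, interval_start + tau]``.

    Cavg uses the analytic antiderivative of the superposed exponentials;
    Cmin is the model concentration exactly at the interval end.
    """
    if not doses:
        raise ValueError("exposure metrics require at least one dose")
    t0 = min(d.time for d in doses)
    if interval_start < t0:
        raise ValueError("interval extends before the first dose")
    grid = _dose_grid(doses)
    cl = np.array([ind.cl_i])
    vc = np.array([ind.vc_i])
    ka = np.array([ind.ka_i])
    f1 = np.array([ind.f1_i])
    ends = np.array([interval_start, interval_start + tau])
    sidx = np.zeros(2, dtype=int)
    aucs = cum_auc_at(ends, sidx, grid, cl, vc, ka, f1)
    cavg = float(aucs[1] - aucs[0]) / tau
    cmin = float(conc_at(ends[1:], sidx[:1], grid, cl, vc, ka, f1)[0])
    return ExposureMetrics(
        cavg=cavg, cmin=cmin, interval_start=interval_start, interval_end=interval_start + tau
    )


def dose_for_weight(weight: float, level: float, cap: float = 300.0) -> float:
    """Weight-based dose (mg) at ``level`` mg/kg, limited to an absolute cap."""
    if weight <= 0 or level <= 0:
        raise ValueError("weight and dose level must be positive")
    return min(weight * level, cap)


def f1_population_interval(
    f1_typ: float, sd_logit: float, coverage: float = 0.95
) -> tuple[float, float]:
    """Central population interval of individual bioavailability.

    With logit-normal IIV, the central ``coverage`` interval of F1 is the
    inverse logit of logit(f1_typ) +/- z * sd_logit.
    """
    if not 0.0 < f1_typ < 1.0:
        raise ValueError("f1_typ must be in (0, 1)")
    if sd_logit < 0:
        raise ValueError("sd_logit must be non-negative")
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    z = stats.norm.ppf(0.5 + coverage / 2.0)
    mu = logit(f1_typ)
    return expit(mu - z * sd_logit), expit(mu + z * sd_logit)
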