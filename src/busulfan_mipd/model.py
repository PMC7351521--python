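"""One-compartment IV-infusion population PK model for busulfan.

The structural model is a linear one-compartment model with zero-order
infusion input and first-order elimination.  Clearance carries the
"second-generation" covariate structure: allometric scaling on fat-free
mass (FFM), a Hill maturation function on postnatal age, and a
multiplicative conditioning-regimen factor.  Volume scales allometrically
on FFM.  Between-subject variability is log-normal on CL and V
(2x2 covariance ``omega``); optional between-day (inter-occasion)
variability acts on CL; residual error is proportional-exponential with an
optional additive component.

All quantities use mg, L, hours and mg·h/L.  Time is measured in hours
from the start of the first infusion of the course.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "BusulfanError",
    "InvalidCovariateError",
    "InvalidInputError",
    "ConfigurationError",
    "EstimationError",
    "TerminalFitError",
    "PatientCovariates",
    "PopulationModel",
    "DoseEvent",
    "Regimen",
    "IndividualParameters",
    "ConcObservation",
    "compute_ffm",
    "maturation_factor",
    "typical_parameters",
    "predict_concentration",
    "analytic_course_auc",
    "simulate_observations",
    "build_regimen",
    "default_model",
    "first_generation_model",
    "round_to_step",
    "HOURS_PER_DAY",
    "INFUSION_DURATION",
]

HOURS_PER_DAY = 24.0

#: default infusion duration (h) by dosing interval (h)
INFUSION_DURATION = {6.0: 2.0, 12.0: 2.0, 24.0: 3.0}


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class BusulfanError(ValueError):
    """Base class for domain errors raised by this package."""


class InvalidCovariateError(BusulfanError):
    """Patient covariates violate their physical constraints."""


class InvalidInputError(BusulfanError):
    """An operation received data violating its preconditions."""


class ConfigurationError(BusulfanError):
    """Model or pipeline configuration is inconsistent."""


class EstimationError(BusulfanError):
    """Individual (MAP) estimation failed."""


class TerminalFitError(BusulfanError):
    """Terminal-phase log-linear regression failed (e.g. rising tail)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientCovariates:
    """Demographic and clinical covariates entering the covariate model.

    ``height`` may be None, in which case FFM falls back to a fixed
    fraction of body weight.  ``disease_class`` drives the predefined
    exposure target, not the PK model itself.
    """

    patient_id: str
    age: float                      # years
    weight: float                   # kg
    sex: str                        # "male" | "female"
    height: float | None = None     # cm
    disease_class: str = "malignant"
    regimen_label: str = "bu_flu"

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise InvalidCovariateError(f"weight must be > 0, got {self.weight}")
        if self.age < 0:
            raise InvalidCovariateError(f"age must be >= 0, got {self.age}")
        if self.height is not None and self.height <= 0:
            raise InvalidCovariateError(f"height must be > 0, got {self.height}")
        if self.sex not in ("male", "female"):
            raise InvalidCovariateError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.disease_class not in ("malignant", "nonmalignant"):
            raise InvalidCovariateError(
                f"disease_class must be 'malignant' or 'nonmalignant', got {self.disease_class!r}"
            )


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects, covariate parameters and variance components.

    This is the engine's prior.  ``theta_cl`` is the typical clearance of a
    patient at the reference fat-free mass ``ffm_ref``, fully matured, on
    the reference conditioning regimen; ``theta_v`` the typical volume at
    ``ffm_ref``.  ``omega`` is the 2x2 covariance of (eta_CL, eta_V) on the
    log scale; ``omega_iov_cl`` the per-day (occasion) variance of log CL.

    The residual model is y = f·exp(eps_prop) + eps_add.  Both sigmas may
    be zero, which makes simulation deterministic; MAP estimation requires
    a positive residual variance and raises otherwise.
    """

    theta_cl: float                         # L/h at reference
    theta_v: float                          # L at reference
    ffm_ref: float = 13.0                   # kg
    allo_cl: float = 0.75
    allo_v: float = 1.0
    tm50: float = 0.3                       # years, half-maximal maturation age
    hill: float = 2.0
    regimen_factors: Mapping[str, float] = field(
        default_factory=lambda: {"bu_flu": 1.0, "bu_cy": 1.05, "bu_mel": 0.9}
    )
    reference_regimen: str = "bu_flu"
    omega: np.ndarray = field(
        default_factory=lambda: np.array([[0.0484, 0.0120], [0.0120, 0.0400]])
    )
    omega_iov_cl: float = 0.0               # variance of per-day log-CL shift
    sigma_prop: float = 0.10                # proportional residual CV
    sigma_add: float = 0.0                  # additive residual SD, mg/L
    ffm_fallback_fraction: float = 0.85     # FFM = fraction*weight when no height
    size_descriptor: str = "ffm"            # "ffm" or "weight" (first-gen style)

    def __post_init__(self) -> None:
        for name in ("theta_cl", "theta_v", "ffm_ref", "tm50", "hill"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise ConfigurationError("residual sigmas must be >= 0")
        if self.omega_iov_cl < 0:
            raise ConfigurationError("omega_iov_cl must be >= 0")
        om = np.asarray(self.omega, dtype=float)
        if om.shape != (2, 2) or not np.allclose(om, om.T):
            raise ConfigurationError("omega must be a symmetric 2x2 matrix")
        if np.any(np.linalg.eigvalsh(om) < -1e-12):
            raise ConfigurationError("omega must be positive semidefinite")
        object.__setattr__(self, "omega", om)
        if self.size_descriptor not in ("ffm", "weight"):
            raise ConfigurationError("size_descriptor must be 'ffm' or 'weight'")
        ref = self.regimen_factors.get(self.reference_regimen)
        if ref != 1.0:
            raise ConfigurationError(
                f"reference regimen {self.reference_regimen!r} must carry factor 1.0"
            )

    def regimen_factor(self, label: str) -> float:
        try:
            return float(self.regimen_factors[label])
        except KeyError:
            raise ConfigurationError(f"unknown regimen label {label!r}") from None


@dataclass(frozen=True)
class DoseEvent:
    """A single intravenous infusion: ``amount`` mg over ``duration`` h."""

    start_time: float   # hours from course start
    amount: float       # mg
    duration: float     # hours

    def __post_init__(self) -> None:
        if self.start_time < 0:
            raise InvalidInputError("dose start_time must be >= 0")
        if self.amount <= 0:
            raise InvalidInputError("dose amount must be > 0")
        if self.duration <= 0:
            raise InvalidInputError("infusion duration must be > 0")

    @property
    def day(self) -> int:
        """1-based treatment day containing the infusion start."""
        return int(self.start_time // HOURS_PER_DAY) + 1


@dataclass(frozen=True)
class Regimen:
    """An ordered multi-day course of infusions at a fixed dose interval."""

    doses: tuple[DoseEvent, ...]
    interval: float     # hours: 6, 12 or 24
    n_days: int

    def __post_init__(self) -> None:
        if self.interval not in (6.0, 12.0, 24.0, 6, 12, 24):
            raise InvalidInputError(f"interval must be 6, 12 or 24 h, got {self.interval}")
        if self.n_days not in (2, 3, 4):
            raise InvalidInputError(f"n_days must be 2, 3 or 4, got {self.n_days}")
        doses = tuple(self.doses)
        starts = [d.start_time for d in doses]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise InvalidInputError("dose start times must be strictly increasing")
        for a, b in zip(doses, doses[1:]):
            if b.start_time < a.start_time + a.duration:
                raise InvalidInputError("infusion windows must not overlap")
        object.__setattr__(self, "doses", doses)

    @property
    def total_amount(self) -> float:
        return sum(d.amount for d in self.doses)

    def doses_on_day(self, day: int) -> tuple[DoseEvent, ...]:
        return tuple(d for d in self.doses if d.day == day)

    @property
    def doses_per_day(self) -> int:
        return int(round(HOURS_PER_DAY / float(self.interval)))


@dataclass(frozen=True)
class IndividualParameters:
    """Individual CL and V plus the random effects that produced them.

    ``cl`` and ``v`` include inter-individual variability
    (cl = CL_typ·exp(eta_CL)); per-day occasion shifts, when present,
    multiply CL on the corresponding day and are stored separately in
    ``occasion_etas`` (index 0 = day 1).
    """

    cl: float
    v: float
    eta: np.ndarray = field(default_factory=lambda: np.zeros(2))
    occasion_etas: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.cl <= 0 or self.v <= 0:
            raise InvalidInputError("cl and v must be > 0")
        object.__setattr__(self, "eta", np.asarray(self.eta, dtype=float))

    def cl_on_day(self, day: int) -> float:
        """Clearance effective on 1-based treatment ``day``."""
        if not self.occasion_etas:
            return self.cl
        idx = min(max(day - 1, 0), len(self.occasion_etas) - 1)
        return self.cl * math.exp(self.occasion_etas[idx])


@dataclass(frozen=True)
class ConcObservation:
    """A (possibly simulated) TDM plasma concentration sample."""

    time: float             # hours from course start
    concentration: float    # mg/L
    below_lloq: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise InvalidInputError("observation time must be >= 0")
        if self.concentration < 0:
            raise InvalidInputError("concentration must be >= 0")


# ---------------------------------------------------------------------------
# covariate model
# ---------------------------------------------------------------------------

def compute_ffm(cov: PatientCovariates, fallback_fraction: float = 0.85) -> float:
    """Fat-free mass (kg) from weight, height and sex.

    Uses the Janmahasatian sex-specific equation
    ``FFM = 9270·WT / (6680 + 216·BMI)`` (male) and
    ``FFM = 9270·WT / (8780 + 244·BMI)`` (female), with BMI in kg/m².
    When height is missing, FFM falls back to ``fallback_fraction·weight``.
    The result is capped at total body weight.
    """
    if cov.height is None:
        return min(fallback_fraction * cov.weight, cov.weight)
    bmi = cov.weight / (cov.height / 100.0) ** 2
    if cov.sex == "male":
        ffm = 9270.0 * cov.weight / (6680.0 + 216.0 * bmi)
    else:
        ffm = 9270.0 * cov.weight / (8780.0 + 244.0 * bmi)
    return min(ffm, cov.weight)


def maturation_factor(age: float, model: PopulationModel) -> float:
    """Fraction of adult clearance attained at postnatal ``age`` (years).

    Hill sigmoid ``age^h / (age^h + tm50^h)``: 0 at birth, 0.5 at ``tm50``,
    approaching 1 with maturity; strictly increasing in age.
    """
    if age < 0:
        raise InvalidCovariateError(f"age must be >= 0, got {age}")
    a = age ** model.hill
    return a / (a + model.tm50 ** model.hill)


def typical_parameters(model: PopulationModel, cov: PatientCovariates) -> IndividualParameters:
    """Population-typical CL and V for a covariate vector (eta = 0).

    CL_typ = theta_cl · (FFM/FFM_ref)^allo_cl · maturation(age) · regimen factor;
    V_typ  = theta_v · (FFM/FFM_ref)^allo_v.
    """
    if model.size_descriptor == "weight":
        size = cov.weight
    else:
        size = compute_ffm(cov, model.ffm_fallback_fraction)
    size_cl = (size / model.ffm_ref) ** model.allo_cl
    size_v = (size / model.ffm_ref) ** model.allo_v
    cl = model.theta_cl * size_cl * maturation_factor(cov.age, model) * model.regimen_factor(cov.regimen_label)
    v = model.theta_v * size_v
    return IndividualParameters(cl=cl, v=v, eta=np.zeros(2))


def individual_from_eta(
    model: PopulationModel,
    cov: PatientCovariates,
    eta: Sequence[float],
    occasion_etas: Sequence[float] | None = None,
) -> IndividualParameters:
    """Individual parameters from the typical values and a log-scale eta."""
    typ = typical_parameters(model, cov)
    eta = np.asarray(eta, dtype=float)
    return IndividualParameters(
        cl=typ.cl * math.exp(eta[0]),
        v=typ.v * math.exp(eta[1]),
        eta=eta,
        occasion_etas=tuple(occasion_etas) if occasion_etas is not None else None,
    )


# ---------------------------------------------------------------------------
# structural model: concentrations and AUC
# ---------------------------------------------------------------------------

def _dose_concentration(dose: DoseEvent, cl: float, v: float, t: np.ndarray) -> np.ndarray:
    """Concentration contribution of one infusion at absolute times ``t``."""
    ke = cl / v
    r0 = dose.amount / dose.duration
    tau = t - dose.start_time
    c = np.zeros_like(tau)
    during = (tau > 0) & (tau <= dose.duration)
    after = tau > dose.duration
    c[during] = (r0 / cl) * (1.0 - np.exp(-ke * tau[during]))
    c_end = (r0 / cl) * (1.0 - math.exp(-ke * dose.duration))
    c[after] = c_end * np.exp(-ke * (tau[after] - dose.duration))
    return c


def predict_concentration(
    ip: IndividualParameters, reg: Regimen, t: float | Sequence[float]
) -> float | np.ndarray:
    """Plasma concentration (mg/L) at time(s) ``t`` by superposition.

    Each dose contributes the standard one-compartment zero-order-infusion
    solution; doses that have not started contribute zero.  With
    inter-occasion variability, a dose's kinetics use the clearance of the
    day on which it starts.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise InvalidInputError("prediction times must be >= 0")
    c = np.zeros_like(t_arr)
    for dose in reg.doses:
        cl_d = ip.cl_on_day(dose.day)
        c += _dose_concentration(dose, cl_d, ip.v, t_arr)
    return float(c[0]) if np.isscalar(t) or np.ndim(t) == 0 else c


def _dose_cumulative_auc(dose: DoseEvent, cl: float, v: float, t: float) -> float:
    """AUC contribution of one infusion from its start to absolute time t."""
    tau = t - dose.start_time
    if tau <= 0:
        return 0.0
    ke = cl / v
    r0 = dose.amount / dose.duration
    if tau <= dose.duration:
        return (r0 / cl) * (tau + (math.exp(-ke * tau) - 1.0) / ke)
    inf_part = (r0 / cl) * (dose.duration + (math.exp(-ke * dose.duration) - 1.0) / ke)
    c_end = (r0 / cl) * (1.0 - math.exp(-ke * dose.duration))
    post = (c_end / ke) * (1.0 - math.exp(-ke * (tau - dose.duration)))
    return inf_part + post


def analytic_course_auc(
    ip: IndividualParameters,
    reg: Regimen,
    window: tuple[float, float] | None = None,
) -> float:
    """Closed-form AUC (mg·h/L) of the course.

    Without a window, the AUC over [0, inf): total dose / CL when there is
    no inter-occasion variability, or the sum of per-day dose/CL_day with
    it.  With ``window=(t1, t2)`` the exact piecewise integral of the
    superposed concentration curve over [t1, t2].
    """
    if window is None:
        return sum(d.amount / ip.cl_on_day(d.day) for d in reg.doses)
    t1, t2 = window
    if t2 < t1 or t1 < 0:
        raise InvalidInputError("window must satisfy 0 <= t1 <= t2")
    total = 0.0
    for dose in reg.doses:
        cl_d = ip.cl_on_day(dose.day)
        total += _dose_cumulative_auc(dose, cl_d, ip.v, t2) - _dose_cumulative_auc(
            dose, cl_d, ip.v, t1
        )
    return total


def simulate_observations(
    ip: IndividualParameters,
    reg: Regimen,
    times: Iterable[float],
    model: PopulationModel,
    seed: int | np.random.Generator,
) -> list[ConcObservation]:
    """Draw noisy TDM samples: y = f·exp(eps_prop) + eps_add.

    Proportional noise is log-normal (eps_prop ~ N(0, sigma_prop²));
    additive noise is Gaussian and may push a draw negative, in which case
    the value is truncated at zero and flagged ``below_lloq``.
    Deterministic under a fixed seed.
    """
    times = list(times)
    if not times:
        raise InvalidInputError("times must be nonempty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f = np.atleast_1d(predict_concentration(ip, reg, times))
    eps_p = rng.normal(0.0, model.sigma_prop, size=len(times)) if model.sigma_prop > 0 else np.zeros(len(times))
    eps_a = rng.normal(0.0, model.sigma_add, size=len(times)) if model.sigma_add > 0 else np.zeros(len(times))
    y = f * np.exp(eps_p) + eps_a
    out = []
    for t, yi in zip(times, y):
        if yi <= 0:
            out.append(ConcObservation(time=float(t), concentration=0.0, below_lloq=True))
        else:
            out.append(ConcObservation(time=float(t), concentration=float(yi)))
    return out


# ---------------------------------------------------------------------------
# construction helpers & defaults
# ---------------------------------------------------------------------------

def build_regimen(
    per_dose_amount: float,
    interval: float,
    n_days: int,
    infusion_duration: float | None = None,
    start_day: int = 1,
    base: Regimen | None = None,
) -> Regimen:
    """Uniform regimen of ``per_dose_amount`` mg every ``interval`` h.

    With ``base`` given, doses of days < ``start_day`` are taken from
    ``base`` and days >= ``start_day`` are replaced — the TDM dose-update
    primitive.
    """
    if per_dose_amount <= 0:
        raise InvalidInputError("per-dose amount must be > 0")
    interval = float(interval)
    if infusion_duration is None:
        infusion_duration = INFUSION_DURATION[interval]
    per_day = int(round(HOURS_PER_DAY / interval))
    doses: list[DoseEvent] = []
    if base is not None:
        doses.extend(d for d in base.doses if d.day < start_day)
    for day in range(start_day, n_days + 1):
        day_start = (day - 1) * HOURS_PER_DAY
        for k in range(per_day):
            doses.append(
                DoseEvent(
                    start_time=day_start + k * interval,
                    amount=per_dose_amount,
                    duration=infusion_duration,
                )
            )
    return Regimen(doses=tuple(doses), interval=interval, n_days=n_days)


def round_to_step(x: float, step: float = 0.1) -> float:
    """Round to the nearest multiple of ``step``; ties round half up."""
    if step <= 0:
        raise InvalidInputError("step must be > 0")
    return round(math.floor(x / step + 0.5) * step, 10)


def default_model(**overrides) -> PopulationModel:
    """The illustrative second-generation busulfan model used throughout.

    Parameter values are documented defaults producing pediatric-plausible
    exposures — typical CL 4.4 L/h at 13 kg FFM (≈ 0.25 L/h per kg body
    weight, in line with reported pediatric busulfan clearance of roughly
    3.5-4 mL/min/kg), V 10.5 L (≈ 0.65 L/kg).  They are configuration,
    not published estimates.
    """
    params = dict(theta_cl=4.4, theta_v=10.5)
    params.update(overrides)
    return PopulationModel(**params)


def first_generation_model(**overrides) -> PopulationModel:
    """An illustrative "first-generation" model: total-body-weight allometry
    with no maturation or FFM terms.

    Maturation is disabled (tm50 tiny) and size is total body weight
    referenced to 16 kg.  Used only for cohort-B initial dosing; its
    deliberate misspecification relative to the second-generation model
    reproduces that strategy's initial-dose bias.
    """
    params = dict(
        theta_cl=4.1,
        theta_v=11.0,
        ffm_ref=16.0,
        tm50=1e-6,
        hill=2.0,
        size_descriptor="weight",
    )
    params.update(overrides)
    return PopulationModel(**params)


def strip_height(cov: PatientCovariates) -> PatientCovariates:
    """Covariates with height removed (forces the FFM fallback path)."""
    return replace(cov, height=None)
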