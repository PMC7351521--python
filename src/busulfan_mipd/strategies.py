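"""The three initial-dosing + TDM strategies, run end-to-end in silico.

Strategy A — "conventional": weight-tier label dosing (1.1 mg/kg per q6
dose at or below 12 kg, 0.8 mg/kg above), NCA (trapezoid + lambda-z)
estimation of the per-dose AUC at each TDM day, and proportional dose
scaling for the remaining days.

Strategy B — "first-generation model": initial dose from a weight-allometry
population model (no maturation, no fat-free mass), then the same NCA-based
TDM loop as A.

Strategy C — "model-informed precision dosing": initial dose from the
second-generation covariate model, MAP-Bayesian estimation after each TDM
day, and grid search for the remaining-dose amount whose predicted
cumulative AUC is closest to the patient's predefined target.

TDM occurs once daily on days 1-3; day 4 is never sampled, so its exposure
is extrapolated from the final estimate (EBE clearance for C, the implied
clearance of the last NCA assessment for A/B).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nca as _nca
from .bayes import (
    DoseGrid,
    ExposureTarget,
    IndividualEstimate,
    estimate_course_cauc,
    map_estimate,
    recommend_remaining_doses,
)
from .cohort import VirtualPatient
from .model import (
    ConcObservation,
    ConfigurationError,
    EstimationError,
    HOURS_PER_DAY,
    INFUSION_DURATION,
    InvalidCovariateError,
    InvalidInputError,
    PatientCovariates,
    PopulationModel,
    Regimen,
    TerminalFitError,
    analytic_course_auc,
    build_regimen,
    round_to_step,
    simulate_observations,
    typical_parameters,
)

__all__ = [
    "StrategyModels",
    "Assessment",
    "CourseRecord",
    "conventional_initial_dose",
    "model_based_initial_dose",
    "sampling_schedule",
    "run_course",
]

#: default within-day sampling template: hours after end of infusion
DEFAULT_SAMPLING_OFFSETS = (0.25, 1.0, 3.5)

#: weight cutoff (kg) and rates (mg/kg per q6 dose) of the conventional nomogram
NOMOGRAM_CUTOFF_KG = 12.0
NOMOGRAM_RATE_LOW = 1.1
NOMOGRAM_RATE_HIGH = 0.8


@dataclass(frozen=True)
class StrategyModels:
    """The model set a course run may need.

    ``truth`` generates the simulated patient's concentrations (residual
    error); ``second_gen`` is strategy C's prior/estimator; ``first_gen``
    drives strategy B's initial dose.
    """

    truth: PopulationModel
    second_gen: PopulationModel
    first_gen: PopulationModel | None = None


@dataclass(frozen=True)
class Assessment:
    """One TDM cycle: the day's AUC estimate and the resulting dose."""

    day: int
    method: str                     # "nca" | "map"
    auc_per_dose: float | None      # estimated AUC of one dosing interval, mg·h/L
    cl_estimate: float | None       # L/h (MAP only)
    new_per_dose_amount: float
    failed: bool = False
    saturated: bool = False
    message: str = ""


@dataclass
class CourseRecord:
    """Complete log of one simulated treatment course."""

    patient_id: str
    strategy: str
    interval: float
    n_days: int
    target: ExposureTarget
    regimen: Regimen
    observations: list[ConcObservation]
    assessments: list[Assessment]
    dose_by_day: list[float]                    # per-dose amount each day, mg
    pk1_auc_est: float | None                   # estimated first-assessment AUC/dose
    pk1_ratio: float | None                     # % of the per-dose target
    final_estimated_cauc: float
    final_true_cauc: float | None               # simulation truth (None for real data)
    estimated_ratio: float                      # % of the cAUC target
    true_ratio: float | None
    saturated: bool = False
    failed_days: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        """JSON-serializable summary (course log record)."""
        return {
            "patient_id": self.patient_id,
            "strategy": self.strategy,
            "interval": self.interval,
            "n_days": self.n_days,
            "cauc_target": self.target.cauc_target,
            "dose_by_day": self.dose_by_day,
            "doses": [
                {"time": d.start_time, "amount": d.amount, "duration": d.duration}
                for d in self.regimen.doses
            ],
            "observations": [
                {"time": o.time, "conc": o.concentration, "below_lloq": o.below_lloq}
                for o in self.observations
            ],
            "assessments": [
                {
                    "day": a.day, "method": a.method, "auc_per_dose": a.auc_per_dose,
                    "cl_estimate": a.cl_estimate, "new_per_dose_amount": a.new_per_dose_amount,
                    "failed": a.failed, "saturated": a.saturated, "message": a.message,
                }
                for a in self.assessments
            ],
            "pk1_auc_est": self.pk1_auc_est,
            "pk1_ratio": self.pk1_ratio,
            "final_estimated_cauc": self.final_estimated_cauc,
            "final_true_cauc": self.final_true_cauc,
            "estimated_ratio": self.estimated_ratio,
            "true_ratio": self.true_ratio,
            "saturated": self.saturated,
            "failed_days": self.failed_days,
        }


# ---------------------------------------------------------------------------
# initial-dose rules
# ---------------------------------------------------------------------------

def conventional_initial_dose(weight: float, interval: float = 6.0) -> float:
    """Label nomogram dose (mg): 1.1 mg/kg at or below 12 kg, 0.8 above.

    The rates are per q6 dose; q12 and q24 equivalents scale the q6 dose
    by 2x and 4x.
    """
    if weight <= 0:
        raise InvalidCovariateError(f"weight must be > 0, got {weight}")
    rate = NOMOGRAM_RATE_LOW if weight <= NOMOGRAM_CUTOFF_KG else NOMOGRAM_RATE_HIGH
    scale = float(interval) / 6.0
    if interval not in (6, 12, 24, 6.0, 12.0, 24.0):
        raise InvalidInputError(f"interval must be 6, 12 or 24 h, got {interval}")
    return rate * weight * scale


def model_based_initial_dose(
    model: PopulationModel,
    cov: PatientCovariates,
    target: ExposureTarget,
    interval: float,
    n_days: int = 4,
    granularity: float = 0.1,
) -> float:
    """Per-dose amount hitting the target exactly for a typical patient.

    amount = (cAUC target / planned doses) x CL_typ, rounded to the dose
    granularity.
    """
    per_day = int(round(HOURS_PER_DAY / float(interval)))
    n_doses = per_day * n_days
    cl_typ = typical_parameters(model, cov).cl
    raw = target.per_dose_target(n_doses) * cl_typ
    return max(round_to_step(raw, granularity), granularity)


# ---------------------------------------------------------------------------
# sampling schedule
# ---------------------------------------------------------------------------

def sampling_schedule(
    interval: float,
    day: int,
    anchor: str = "dose1",
    offsets: Sequence[float] = DEFAULT_SAMPLING_OFFSETS,
    infusion_duration: float | None = None,
) -> list[float]:
    """Within-day sampling times (hours from the day's start).

    The template draws samples at ``infusion end + offset`` for each
    offset, anchored at the day's first dose by default.  ``anchor="dose3"``
    (q6/q12 first-day convention) anchors at the third dose instead, i.e.
    two intervals into the day.
    """
    interval = float(interval)
    if interval not in (6.0, 12.0, 24.0):
        raise ConfigurationError(f"unsupported dose interval {interval}")
    if day < 1:
        raise InvalidInputError("day must be >= 1")
    if infusion_duration is None:
        infusion_duration = INFUSION_DURATION[interval]
    if anchor == "dose1":
        anchor_time = 0.0
    elif anchor == "dose3":
        if interval == 24.0:
            raise ConfigurationError("dose-3 anchoring applies to q6/q12 dosing only")
        anchor_time = 2.0 * interval
    else:
        raise ConfigurationError(f"unknown anchor {anchor!r}")
    return [anchor_time + infusion_duration + off for off in offsets]


# ---------------------------------------------------------------------------
# course simulation (the TDM loop)
# ---------------------------------------------------------------------------

def _nca_assessment(
    obs_day: list[ConcObservation],
    anchor_start: float,
    n_terminal: int = 3,
) -> float:
    """Per-dose AUC (mg·h/L) by trapezoid + lambda-z extrapolation.

    A zero-concentration anchor at the infusion start closes the
    trapezoid on the left (single-dose convention of clinical busulfan
    NCA).
    """
    lz = _nca.fit_lambda_z(obs_day, n_points=min(n_terminal, len(obs_day)))
    anchored = [ConcObservation(time=anchor_start, concentration=0.0)] + list(obs_day)
    return _nca.auc_to_infinity(anchored, lz).auc_total


def run_course(
    strategy: str,
    patient: VirtualPatient,
    models: StrategyModels,
    seed: int,
    n_days: int = 4,
    tdm_days: Sequence[int] = (1, 2, 3),
    pk1_anchor: str = "dose1",
    sampling_offsets: Sequence[float] = DEFAULT_SAMPLING_OFFSETS,
    granularity: float = 0.1,
    grid_lo_factor: float = 0.5,
    grid_hi_factor: float = 2.0,
) -> CourseRecord:
    """Simulate one patient's full course under a dosing strategy.

    Day loop: administer the current per-dose amount, draw the day's TDM
    samples from the generative (truth) model, estimate exposure (NCA for
    A/B, MAP for C), and update the remaining days' doses (proportional
    scaling for A/B, predicted-cAUC grid search for C).  Estimation
    failures leave the dose unchanged and are flagged.  Fully reproducible
    under the seed.
    """
    if strategy not in ("A", "B", "C"):
        raise ConfigurationError(f"unknown strategy {strategy!r}")
    if strategy == "B" and models.first_gen is None:
        raise ConfigurationError("strategy B requires a first-generation model")

    cov = patient.covariates
    target = patient.target
    interval = float(patient.interval)
    per_day = int(round(HOURS_PER_DAY / interval))
    n_total_doses = per_day * n_days
    per_dose_target = target.per_dose_target(n_total_doses)
    duration = INFUSION_DURATION[interval]

    if strategy == "A":
        dose = max(round_to_step(conventional_initial_dose(cov.weight, interval), granularity),
                   granularity)
    elif strategy == "B":
        dose = model_based_initial_dose(models.first_gen, cov, target, interval, n_days,
                                        granularity)
    else:
        dose = model_based_initial_dose(models.second_gen, cov, target, interval, n_days,
                                        granularity)

    regimen = build_regimen(dose, interval, n_days, duration)
    rng = np.random.default_rng(seed)

    observations: list[ConcObservation] = []
    assessments: list[Assessment] = []
    dose_by_day = [dose] * n_days
    failed_days: list[int] = []
    saturated_any = False
    pk1_auc = None
    last_est: IndividualEstimate | None = None
    last_nca_auc: float | None = None
    last_nca_dose: float | None = None

    for day in sorted(tdm_days):
        if day > n_days:
            continue
        anchor = pk1_anchor if (day == 1 and interval in (6.0, 12.0)) else "dose1"
        rel_times = sampling_schedule(interval, day, anchor=anchor,
                                      offsets=sampling_offsets,
                                      infusion_duration=duration)
        day_start = (day - 1) * HOURS_PER_DAY
        times = [day_start + t for t in rel_times]
        obs_day = simulate_observations(patient.true_params, regimen, times,
                                        models.truth, rng)
        observations.extend(obs_day)
        anchor_start = day_start + (0.0 if anchor == "dose1" else 2.0 * interval)

        new_dose = dose_by_day[day - 1]
        if strategy in ("A", "B"):
            try:
                auc_obs = _nca_assessment(obs_day, anchor_start)
                new_dose = max(
                    _nca.adjust_dose(dose_by_day[day - 1], auc_obs, per_dose_target,
                                     granularity),
                    granularity,
                )
                last_nca_auc, last_nca_dose = auc_obs, dose_by_day[day - 1]
                if day == 1:
                    pk1_auc = auc_obs
                assessments.append(Assessment(day=day, method="nca", auc_per_dose=auc_obs,
                                              cl_estimate=None,
                                              new_per_dose_amount=new_dose))
            except (TerminalFitError, InvalidInputError) as exc:
                failed_days.append(day)
                assessments.append(Assessment(day=day, method="nca", auc_per_dose=None,
                                              cl_estimate=None,
                                              new_per_dose_amount=new_dose,
                                              failed=True, message=str(exc)))
            if day < n_days:
                regimen = build_regimen(new_dose, interval, n_days, duration,
                                        start_day=day + 1, base=regimen)
                for d in range(day, n_days):
                    dose_by_day[d] = new_dose
        else:
            try:
                est = map_estimate(models.second_gen, cov, regimen, observations)
                last_est = est
                if day == 1:
                    first_dose = regimen.doses[0]
                    pk1_auc = first_dose.amount / est.ip.cl
                if day < n_days:
                    cutoff = day * HOURS_PER_DAY
                    given = tuple(d for d in regimen.doses if d.start_time < cutoff)
                    reg_so_far = Regimen(doses=given, interval=interval, n_days=n_days)
                    slots = [(d.start_time, d.duration) for d in regimen.doses
                             if d.start_time >= cutoff]
                    grid = DoseGrid.around(dose_by_day[day - 1], grid_lo_factor,
                                           grid_hi_factor, granularity)
                    rec = recommend_remaining_doses(models.second_gen, est, target,
                                                    reg_so_far, slots, grid)
                    regimen = rec.regimen
                    new_dose = rec.per_dose_amount
                    saturated_any = saturated_any or rec.saturated
                    for d in range(day, n_days):
                        dose_by_day[d] = new_dose
                assessments.append(Assessment(day=day, method="map",
                                              auc_per_dose=None,
                                              cl_estimate=est.ip.cl,
                                              new_per_dose_amount=new_dose,
                                              saturated=saturated_any))
            except (EstimationError, InvalidInputError) as exc:
                failed_days.append(day)
                assessments.append(Assessment(day=day, method="map", auc_per_dose=None,
                                              cl_estimate=None,
                                              new_per_dose_amount=new_dose,
                                              failed=True, message=str(exc)))

    # final course-level estimate
    if strategy == "C":
        if last_est is None:
            last_est = map_estimate(models.second_gen, cov, regimen, [])
        est_cauc = estimate_course_cauc(last_est, regimen,
                                        observed_days=set(tdm_days))
    else:
        est_cauc = _nca_course_cauc(regimen, assessments, n_days)

    true_cauc = analytic_course_auc(patient.true_params, regimen)
    pk1_ratio = 100.0 * pk1_auc / per_dose_target if pk1_auc is not None else None
    return CourseRecord(
        patient_id=cov.patient_id,
        strategy=strategy,
        interval=interval,
        n_days=n_days,
        target=target,
        regimen=regimen,
        observations=observations,
        assessments=assessments,
        dose_by_day=dose_by_day,
        pk1_auc_est=pk1_auc,
        pk1_ratio=pk1_ratio,
        final_estimated_cauc=est_cauc,
        final_true_cauc=true_cauc,
        estimated_ratio=100.0 * est_cauc / target.cauc_target,
        true_ratio=100.0 * true_cauc / target.cauc_target,
        saturated=saturated_any,
        failed_days=failed_days,
    )


def _nca_course_cauc(regimen: Regimen, assessments: list[Assessment], n_days: int) -> float:
    """NCA-scaled course cAUC for strategies A/B.

    Days with a successful assessment contribute (per-dose AUC x doses
    that day); unsampled or failed days borrow the implied clearance
    (dose / per-dose AUC) of the nearest earlier assessment, falling back
    to the nearest later one for leading days.
    """
    by_day = {a.day: a for a in assessments if not a.failed and a.auc_per_dose}
    if not by_day:
        return float("nan")
    total = 0.0
    for day in range(1, n_days + 1):
        day_doses = regimen.doses_on_day(day)
        if not day_doses:
            continue
        day_amount = sum(d.amount for d in day_doses)
        earlier = [d for d in by_day if d <= day]
        ref = by_day[max(earlier) if earlier else min(by_day)]
        implied_cl = _dose_at_assessment(regimen, ref.day) / ref.auc_per_dose
        total += day_amount / implied_cl
    return total


def _dose_at_assessment(regimen: Regimen, day: int) -> float:
    doses = regimen.doses_on_day(day)
    if not doses:
        raise InvalidInputError(f"no doses on day {day}")
    return doses[0].amount
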