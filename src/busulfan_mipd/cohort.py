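"""Virtual-patient cohort generator.

Emulates the demographic structure of the three clinical dosing-era
cohorts: per disease class (malignant / non-malignant), the median and
range of body weight, age, the male:female ratio, and the predefined
cumulative-AUC target, plus the dosing-interval structure (6/12/24 h with
2-3 h infusions over 4 days).

Sampling laws: age and the exposure target are truncated log-normals
matched by median, with the log-scale SD set so the stated range is
approximately the central 99% interval.  Weight is generated conditionally
on age through a monotone piecewise-linear median weight-for-age growth
curve, anchored so that the class's median age maps to the class's median
weight, with log-normal scatter truncated to the class range.  Height is
imputed deterministically from age by a companion height-for-age curve.
True individual PK parameters draw eta from the model's omega (plus
optional per-day occasion shifts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .bayes import ExposureTarget
from .model import (
    ConfigurationError,
    IndividualParameters,
    PatientCovariates,
    PopulationModel,
    individual_from_eta,
)

__all__ = [
    "ClassSpec",
    "CohortSpec",
    "VirtualPatient",
    "sample_patient",
    "generate_cohort",
    "builtin_cohort_specs",
]

# central 99% interval half-width in SD units, used to map a stated
# (lo, hi) range onto a log-normal scale parameter
_Z99 = 2.576

# median weight-for-age (years -> kg), piecewise linear, sex-pooled
_WEIGHT_FOR_AGE = (
    (0.0, 3.4), (0.25, 5.6), (0.5, 7.5), (1.0, 9.5), (2.0, 12.2),
    (3.0, 14.3), (5.0, 18.0), (7.0, 23.0), (10.0, 32.0), (13.0, 46.0),
    (16.0, 61.0), (18.0, 68.0), (25.0, 72.0), (40.0, 75.0),
)

# median height-for-age (years -> cm), piecewise linear, sex-pooled
_HEIGHT_FOR_AGE = (
    (0.0, 50.0), (0.25, 60.0), (0.5, 66.0), (1.0, 75.0), (2.0, 87.0),
    (3.0, 95.0), (5.0, 109.0), (7.0, 122.0), (10.0, 138.0), (13.0, 156.0),
    (16.0, 169.0), (18.0, 172.0), (25.0, 172.0), (40.0, 172.0),
)

#: log-scale SD of weight scatter around the growth curve
_WEIGHT_SCATTER_SD = 0.18


def _curve(points: tuple[tuple[float, float], ...], x: float) -> float:
    xs, ys = zip(*points)
    return float(np.interp(x, xs, ys))


def median_weight_for_age(age: float) -> float:
    """Monotone median weight (kg) at postnatal ``age`` (years)."""
    return _curve(_WEIGHT_FOR_AGE, age)


def median_height_for_age(age: float) -> float:
    """Monotone median height (cm) at postnatal ``age`` (years)."""
    return _curve(_HEIGHT_FOR_AGE, age)


@dataclass(frozen=True)
class ClassSpec:
    """Per-disease-class demographics: median (lo, hi) for each covariate."""

    weight_median: float
    weight_range: tuple[float, float]
    age_median: float
    age_range: tuple[float, float]
    male_fraction: float
    target_median: float
    target_range: tuple[float, float]

    def __post_init__(self) -> None:
        for name in ("weight", "age", "target"):
            med = getattr(self, f"{name}_median")
            lo, hi = getattr(self, f"{name}_range")
            if not (lo <= med <= hi):
                raise ConfigurationError(
                    f"{name} median {med} outside its range ({lo}, {hi})"
                )
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigurationError("male_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition: class mix plus per-class demographic specs."""

    n_patients: int
    frac_malignant: float
    malignant: ClassSpec
    nonmalignant: ClassSpec
    n_days: int = 4
    interval_mix: Mapping[float, float] | None = None   # optional {6|12|24: fraction}
    infant_age_cutoff: float = 2.0      # years; below -> q24 default for nonmalignant

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not 0.0 <= self.frac_malignant <= 1.0:
            raise ConfigurationError("frac_malignant must lie in [0, 1]")
        if self.interval_mix is not None:
            fracs = list(self.interval_mix.values())
            if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
                raise ConfigurationError("interval_mix fractions must be >= 0 and sum to 1")
            if any(k not in (6, 12, 24, 6.0, 12.0, 24.0) for k in self.interval_mix):
                raise ConfigurationError("interval_mix keys must be 6, 12 or 24")

    def class_spec(self, disease_class: str) -> ClassSpec:
        return self.malignant if disease_class == "malignant" else self.nonmalignant


@dataclass(frozen=True)
class VirtualPatient:
    """A simulated subject: covariates, true PK parameters, target, interval."""

    covariates: PatientCovariates
    true_params: IndividualParameters
    target: ExposureTarget
    interval: float


def _range_sigma(median: float, lo: float, hi: float) -> float:
    """Log-normal scale so (lo, hi) is roughly the central 99% interval."""
    up = math.log(hi / median) if hi > median else 0.0
    down = math.log(median / lo) if lo < median else 0.0
    return max(up, down, 1e-6) / _Z99


def _truncated_lognormal(
    rng: np.random.Generator, median: float, lo: float, hi: float, max_tries: int = 1000
) -> float:
    """Median-matched log-normal draw, rejected into [lo, hi]."""
    sigma = _range_sigma(median, lo, hi)
    mu = math.log(median)
    for _ in range(max_tries):
        x = math.exp(rng.normal(mu, sigma))
        if lo <= x <= hi:
            return x
    return median


def sample_patient(
    spec: CohortSpec,
    model: PopulationModel,
    seed: int | np.random.Generator,
    patient_id: str = "sim-001",
    disease_class: str | None = None,
) -> VirtualPatient:
    """Draw one virtual patient; deterministic under a fixed seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if disease_class is None:
        disease_class = "malignant" if rng.random() < spec.frac_malignant else "nonmalignant"
    cs = spec.class_spec(disease_class)

    age = _truncated_lognormal(rng, cs.age_median, *cs.age_range)
    # weight conditional on age: growth curve anchored at the class medians
    anchor = cs.weight_median / median_weight_for_age(cs.age_median)
    w_lo, w_hi = cs.weight_range
    weight = None
    for _ in range(1000):
        w = anchor * median_weight_for_age(age) * math.exp(rng.normal(0.0, _WEIGHT_SCATTER_SD))
        if w_lo <= w <= w_hi:
            weight = w
            break
    if weight is None:
        weight = min(max(anchor * median_weight_for_age(age), w_lo), w_hi)
    height = median_height_for_age(age)
    sex = "male" if rng.random() < cs.male_fraction else "female"
    target = _truncated_lognormal(rng, cs.target_median, *cs.target_range)

    cov = PatientCovariates(
        patient_id=patient_id,
        age=age,
        weight=weight,
        height=height,
        sex=sex,
        disease_class=disease_class,
        regimen_label=model.reference_regimen,
    )

    omega = np.asarray(model.omega, dtype=float)
    chol = np.linalg.cholesky(omega + 1e-12 * np.eye(2))
    eta = chol @ rng.standard_normal(2)
    occ = None
    if model.omega_iov_cl > 0:
        occ = tuple(rng.normal(0.0, math.sqrt(model.omega_iov_cl), size=spec.n_days))
    true_params = individual_from_eta(model, cov, eta, occasion_etas=occ)

    if spec.interval_mix is not None:
        intervals = [float(k) for k in spec.interval_mix]
        probs = [spec.interval_mix[k] for k in spec.interval_mix]
        interval = float(rng.choice(intervals, p=probs))
    else:
        infant = age < spec.infant_age_cutoff
        interval = 24.0 if (disease_class == "nonmalignant" and infant) else 6.0

    return VirtualPatient(covariates=cov, true_params=true_params,
                          target=ExposureTarget(target), interval=interval)


def generate_cohort(
    spec: CohortSpec,
    model: PopulationModel,
    seed: int,
    id_prefix: str = "sim",
) -> list[VirtualPatient]:
    """Generate ``spec.n_patients`` independent virtual patients.

    Disease-class counts match the configured mix up to rounding (the
    first ``round(n·frac_malignant)`` patients are malignant).  Each
    patient consumes an independent child RNG stream, so the cohort is
    reproducible as a whole and per patient.
    """
    n = spec.n_patients
    n_mal = int(round(n * spec.frac_malignant))
    streams = np.random.SeedSequence(seed).spawn(n)
    patients = []
    for i in range(n):
        disease = "malignant" if i < n_mal else "nonmalignant"
        rng = np.random.default_rng(streams[i])
        patients.append(
            sample_patient(spec, model, rng, patient_id=f"{id_prefix}-{i + 1:04d}",
                           disease_class=disease)
        )
    return patients


def builtin_cohort_specs() -> dict[str, CohortSpec]:
    """Demographic specs of the three dosing-era cohorts (median and range
    of weight, age and predefined cAUC target per disease class)."""
    return {
        "A": CohortSpec(
            n_patients=53,
            frac_malignant=25 / 53,
            malignant=ClassSpec(
                weight_median=33.0, weight_range=(7.0, 101.0),
                age_median=8.8, age_range=(0.21, 29.0),
                male_fraction=14 / 25,
                target_median=86.0, target_range=(58.0, 86.0),
            ),
            nonmalignant=ClassSpec(
                weight_median=18.0, weight_range=(3.0, 61.0),
                age_median=4.9, age_range=(0.1, 21.0),
                male_fraction=17 / 28,
                target_median=58.0, target_range=(58.0, 86.0),
            ),
        ),
        "B": CohortSpec(
            n_patients=76,
            frac_malignant=40 / 76,
            malignant=ClassSpec(
                weight_median=24.0, weight_range=(8.0, 98.0),
                age_median=6.2, age_range=(0.9, 24.0),
                male_fraction=28 / 40,
                target_median=82.0, target_range=(62.0, 90.0),
            ),
            nonmalignant=ClassSpec(
                weight_median=10.1, weight_range=(4.9, 62.0),
                age_median=1.2, age_range=(0.24, 19.0),
                male_fraction=19 / 36,
                target_median=62.0, target_range=(29.0, 82.0),
            ),
        ),
        "C": CohortSpec(
            n_patients=59,
            frac_malignant=42 / 59,
            malignant=ClassSpec(
                weight_median=17.8, weight_range=(8.1, 150.0),
                age_median=5.9, age_range=(0.9, 20.0),
                male_fraction=28 / 42,
                target_median=83.0, target_range=(60.0, 90.0),
            ),
            nonmalignant=ClassSpec(
                weight_median=10.2, weight_range=(5.8, 79.0),
                age_median=1.4, age_range=(0.2, 17.0),
                male_fraction=13 / 17,
                target_median=60.0, target_range=(17.0, 85.0),
            ),
        ),
    }
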