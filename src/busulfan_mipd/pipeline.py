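"""End-to-end pipeline: cohorts -> courses -> attainment report.

All randomness flows from a single user-supplied seed: cohort generation
and each patient's course consume independent child streams spawned from
it, so identical config + seed reproduce every artifact byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .attainment import CohortResult, ComparisonReport, build_report, report_frame
from .cohort import CohortSpec, VirtualPatient, builtin_cohort_specs, generate_cohort
from .io import covariates_frame, write_dataset
from .model import ConfigurationError, PopulationModel, default_model, first_generation_model
from .strategies import CourseRecord, StrategyModels, run_course

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "simulate_strategy_cohort",
    "run_pipeline",
    "load_pipeline_config",
]

_STRATEGIES = ("A", "B", "C")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration.

    ``strategies`` selects which dosing-era protocols to simulate; each
    runs on its corresponding built-in cohort spec unless ``n_patients``
    overrides the cohort size (smoke runs).
    """

    strategies: tuple[str, ...] = ("A", "B", "C")
    n_patients: int | None = None           # None -> each cohort's built-in n
    iov_cl: float = 0.0                     # between-day variance of log CL
    truth_model: PopulationModel = field(default_factory=default_model)
    second_gen: PopulationModel = field(default_factory=default_model)
    first_gen: PopulationModel = field(default_factory=first_generation_model)

    def __post_init__(self) -> None:
        bad = [s for s in self.strategies if s not in _STRATEGIES]
        if bad:
            raise ConfigurationError(f"unknown strategy keys: {bad}")
        if not self.strategies:
            raise ConfigurationError("at least one strategy required")
        if self.n_patients is not None and self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        known = {"strategies", "n_patients", "iov_cl"}
        unknown = set(cfg) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        if "strategies" in cfg:
            kwargs["strategies"] = tuple(str(s) for s in cfg["strategies"])
        if "n_patients" in cfg and cfg["n_patients"] is not None:
            kwargs["n_patients"] = int(cfg["n_patients"])
        if "iov_cl" in cfg:
            kwargs["iov_cl"] = float(cfg["iov_cl"])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """Everything one pipeline run produced."""

    cohorts: dict[str, list[VirtualPatient]]
    courses: list[CourseRecord]
    results: list[CohortResult]
    comparisons: dict[str, ComparisonReport]
    seed: int


def _derive_seed(base: int, tag: str) -> int:
    """Stable child seed < 2^31 from a base seed and a text tag."""
    h = hashlib.sha256(f"{base}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def simulate_strategy_cohort(
    strategy: str,
    spec: CohortSpec,
    models: StrategyModels,
    seed: int,
    n_patients: int | None = None,
) -> tuple[list[VirtualPatient], list[CourseRecord]]:
    """Generate a cohort from ``spec`` and run every patient's course.

    The generative truth is ``models.truth`` (etas drawn from its omega,
    occasion shifts from its ``omega_iov_cl``); the strategy's estimator
    and dose logic come from the same model set.
    """
    if n_patients is not None:
        spec = CohortSpec(
            n_patients=n_patients,
            frac_malignant=spec.frac_malignant,
            malignant=spec.malignant,
            nonmalignant=spec.nonmalignant,
            n_days=spec.n_days,
            interval_mix=spec.interval_mix,
            infant_age_cutoff=spec.infant_age_cutoff,
        )
    cohort_seed = _derive_seed(seed, f"cohort-{strategy}")
    patients = generate_cohort(spec, models.truth, cohort_seed,
                               id_prefix=f"{strategy.lower()}")
    courses = []
    for i, patient in enumerate(patients):
        course_seed = _derive_seed(seed, f"course-{strategy}-{i}")
        courses.append(run_course(strategy, patient, models, course_seed,
                                  n_days=spec.n_days))
    return patients, courses


def run_pipeline(
    config: PipelineConfig,
    seed: int,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the configured strategies end to end and (optionally) write
    artifacts: per-cohort covariate and event CSVs, a JSON-lines course
    log, the attainment report CSV, a JSON summary, and a manifest with
    the config hash and seed."""
    truth = replace(config.truth_model, omega_iov_cl=config.iov_cl)
    models = StrategyModels(truth=truth, second_gen=config.second_gen,
                            first_gen=config.first_gen)
    specs = builtin_cohort_specs()

    cohorts: dict[str, list[VirtualPatient]] = {}
    courses: list[CourseRecord] = []
    for strat in config.strategies:
        patients, strat_courses = simulate_strategy_cohort(
            strat, specs[strat], models, seed, config.n_patients
        )
        cohorts[strat] = patients
        courses.extend(strat_courses)

    results, comparisons = build_report(courses)
    out = PipelineResult(cohorts=cohorts, courses=courses, results=results,
                         comparisons=comparisons, seed=seed)
    if out_dir is not None:
        _write_artifacts(out, config, Path(out_dir))
    return out


def _config_digest(config: PipelineConfig) -> str:
    payload = {
        "strategies": list(config.strategies),
        "n_patients": config.n_patients,
        "iov_cl": config.iov_cl,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _comparison_dict(rep: ComparisonReport) -> dict:
    return {
        "kind": rep.kind,
        "f_statistic": rep.f_statistic,
        "p_value": rep.p_value,
        "significant": rep.significant,
        "pairwise_bonferroni_p": {f"{a}-{b}": p for (a, b), p in rep.pairwise.items()},
    }


def _write_artifacts(result: PipelineResult, config: PipelineConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts = []
    course_by_strategy: dict[str, list[CourseRecord]] = {}
    for c in result.courses:
        course_by_strategy.setdefault(c.strategy, []).append(c)
    for strat, patients in result.cohorts.items():
        cov_path = out_dir / f"cohort_{strat}_covariates.csv"
        covariates_frame(patients).to_csv(cov_path, index=False)
        artifacts.append(cov_path.name)
        ev_path = out_dir / f"cohort_{strat}_events.csv"
        write_dataset(ev_path, patients, course_by_strategy.get(strat, []))
        artifacts.append(ev_path.name)

    log_path = out_dir / "courses.jsonl"
    with log_path.open("w") as fh:
        for c in result.courses:
            fh.write(json.dumps(c.to_dict(), sort_keys=True) + "\n")
    artifacts.append(log_path.name)

    report_path = out_dir / "attainment_report.csv"
    report_frame(result.results).to_csv(report_path, index=False)
    artifacts.append(report_path.name)

    summary = {
        "seed": result.seed,
        "cohorts": {
            f"{r.cohort}:{r.kind}": {
                "n": r.n,
                "median_ratio": r.median / 100.0,
                "cv_percent": r.cv_percent,
                "n_below": r.n_below,
                "n_within": r.n_within,
                "n_above": r.n_above,
                "pct_within": 100.0 * r.n_within / r.n,
            }
            for r in result.results
        },
        "comparisons": {k: _comparison_dict(v) for k, v in result.comparisons.items()},
    }
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    artifacts.append(summary_path.name)

    manifest = {
        "seed": result.seed,
        "config_sha256": _config_digest(config),
        "strategies": list(config.strategies),
        "n_patients": config.n_patients,
        "iov_cl": config.iov_cl,
        "artifacts": sorted(artifacts),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read and validate a pipeline config from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"pipeline config {path} is not a mapping")
    return PipelineConfig.from_dict(cfg)
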