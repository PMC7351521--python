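"""Dataset and configuration I/O.

The event-record CSV is a NONMEM-style long format: one row per dose or
observation, with covariates repeated on every row.

Columns (header required, missing-value token "."):

    ID      patient identifier (string)
    TIME    hours from course start (float, >= 0)
    EVID    1 = dose row, 0 = observation row
    AMT     dose amount, mg (dose rows only)
    DUR     infusion duration, h (dose rows only)
    DV      observed concentration, mg/L (observation rows only)
    BLQ     1 if the observation is below the LLOQ, else 0
    AGE     years;  WT kg;  HT cm (may be ".");  SEX male|female
    DISEASE malignant|nonmalignant;  REGIMEN conditioning-regimen label
    INTERVAL  dose interval, h (6/12/24)

Model configuration is a YAML/JSON mapping with one block per parameter
group (structural, covariate, variability, error); see
:func:`model_to_dict` for the layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import VirtualPatient
from .model import (
    ConcObservation,
    ConfigurationError,
    DoseEvent,
    InvalidInputError,
    PatientCovariates,
    PopulationModel,
    Regimen,
)

__all__ = [
    "COLUMNS",
    "MISSING",
    "PatientRecord",
    "read_dataset",
    "write_dataset",
    "patients_to_frame",
    "covariates_frame",
    "model_to_dict",
    "model_from_dict",
    "load_model",
    "save_model",
]

COLUMNS = ["ID", "TIME", "EVID", "AMT", "DUR", "DV", "BLQ", "AGE", "WT", "HT",
           "SEX", "DISEASE", "REGIMEN", "INTERVAL"]
MISSING = "."


@dataclass
class PatientRecord:
    """One patient's parsed dataset: covariates, doses, observations."""

    covariates: PatientCovariates
    doses: list[DoseEvent] = field(default_factory=list)
    observations: list[ConcObservation] = field(default_factory=list)
    interval: float = 6.0

    def regimen(self, n_days: int = 4) -> Regimen:
        return Regimen(doses=tuple(self.doses), interval=self.interval, n_days=n_days)


# ---------------------------------------------------------------------------
# event-record CSV
# ---------------------------------------------------------------------------

def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == MISSING:
        return None
    return float(value)


def patients_to_frame(patients: Sequence[VirtualPatient],
                      courses: Sequence | None = None) -> pd.DataFrame:
    """Event-record frame for a cohort.

    With matching course records, administered doses and TDM samples are
    written; without them a patient has no event rows yet and is omitted
    (the pipeline writes a separate covariate table for that purpose).
    Within a patient, rows are time-sorted with doses before observations
    at ties.
    """
    rows = []
    course_by_id = {}
    if courses is not None:
        course_by_id = {c.patient_id: c for c in courses}
    for p in patients:
        cov = p.covariates
        base = {
            "ID": cov.patient_id, "AGE": round(cov.age, 4), "WT": round(cov.weight, 3),
            "HT": round(cov.height, 2) if cov.height is not None else MISSING,
            "SEX": cov.sex, "DISEASE": cov.disease_class, "REGIMEN": cov.regimen_label,
            "INTERVAL": p.interval,
        }
        course = course_by_id.get(cov.patient_id)
        events = []
        if course is not None:
            for d in course.regimen.doses:
                events.append({"TIME": d.start_time, "EVID": 1, "AMT": d.amount,
                               "DUR": d.duration, "DV": MISSING, "BLQ": 0})
            for o in course.observations:
                events.append({"TIME": o.time, "EVID": 0, "AMT": MISSING, "DUR": MISSING,
                               "DV": o.concentration, "BLQ": int(o.below_lloq)})
        events.sort(key=lambda e: (e["TIME"], -e["EVID"]))
        for e in events:
            rows.append({**base, **e})
    return pd.DataFrame(rows, columns=COLUMNS)


def write_dataset(path: str | Path, patients: Sequence[VirtualPatient],
                  courses: Sequence | None = None) -> None:
    """Write the event-record CSV (times sorted within patient)."""
    patients_to_frame(patients, courses).to_csv(path, index=False)


def read_dataset(path: str | Path) -> dict[str, PatientRecord]:
    """Parse an event-record CSV into per-patient records.

    Raises :class:`InvalidInputError` listing offending line numbers for
    malformed rows (a row that is both dose and observation, non-numeric
    fields, unsorted times, missing mandatory columns).
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"dataset not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise InvalidInputError(f"dataset missing mandatory columns: {missing_cols}")

    errors: list[str] = []
    records: dict[str, PatientRecord] = {}
    last_time: dict[str, float] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        pid = row["ID"]
        try:
            time = float(row["TIME"])
            evid = int(row["EVID"])
            amt = _opt(row["AMT"])
            dur = _opt(row["DUR"])
            dv = _opt(row["DV"])
            blq = int(row["BLQ"]) if row["BLQ"] != MISSING else 0
        except (TypeError, ValueError):
            errors.append(f"line {line}: non-numeric field")
            continue
        if evid == 1 and dv is not None:
            errors.append(f"line {line}: row is both dose (EVID=1) and observation (DV set)")
            continue
        if evid == 0 and dv is None:
            errors.append(f"line {line}: observation row without DV")
            continue
        if evid == 1 and (amt is None or dur is None):
            errors.append(f"line {line}: dose row needs AMT and DUR")
            continue
        if pid in last_time and time < last_time[pid]:
            errors.append(f"line {line}: times not sorted within patient {pid}")
            continue
        last_time[pid] = time
        if pid not in records:
            try:
                ht = _opt(row["HT"])
                cov = PatientCovariates(
                    patient_id=pid, age=float(row["AGE"]), weight=float(row["WT"]),
                    height=ht, sex=row["SEX"], disease_class=row["DISEASE"],
                    regimen_label=row["REGIMEN"],
                )
            except (TypeError, ValueError) as exc:
                errors.append(f"line {line}: bad covariates ({exc})")
                continue
            records[pid] = PatientRecord(covariates=cov, interval=float(row["INTERVAL"]))
        rec = records[pid]
        if evid == 1:
            rec.doses.append(DoseEvent(start_time=time, amount=amt, duration=dur))
        else:
            rec.observations.append(
                ConcObservation(time=time, concentration=dv, below_lloq=bool(blq))
            )
    if errors:
        raise InvalidInputError("dataset parse errors:\n" + "\n".join(errors))
    return records


def covariates_frame(patients: Sequence[VirtualPatient]) -> pd.DataFrame:
    """Covariate table for a generated cohort (one row per patient),
    including the simulation truth (target, true CL/V)."""
    rows = []
    for p in patients:
        c = p.covariates
        rows.append({
            "ID": c.patient_id, "AGE": c.age, "WT": c.weight,
            "HT": c.height if c.height is not None else np.nan,
            "SEX": c.sex, "DISEASE": c.disease_class, "REGIMEN": c.regimen_label,
            "INTERVAL": p.interval, "CAUC_TARGET": p.target.cauc_target,
            "TRUE_CL": p.true_params.cl, "TRUE_V": p.true_params.v,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model configuration
# ---------------------------------------------------------------------------

def model_to_dict(model: PopulationModel) -> dict:
    """YAML/JSON-ready layout, one block per parameter group."""
    return {
        "structural": {"theta_cl": model.theta_cl, "theta_v": model.theta_v},
        "covariates": {
            "ffm_ref": model.ffm_ref,
            "allo_cl": model.allo_cl,
            "allo_v": model.allo_v,
            "tm50": model.tm50,
            "hill": model.hill,
            "size_descriptor": model.size_descriptor,
            "ffm_fallback_fraction": model.ffm_fallback_fraction,
            "regimen_factors": dict(model.regimen_factors),
            "reference_regimen": model.reference_regimen,
        },
        "variability": {
            "omega": np.asarray(model.omega).tolist(),
            "omega_iov_cl": model.omega_iov_cl,
        },
        "error": {"sigma_prop": model.sigma_prop, "sigma_add": model.sigma_add},
    }


def model_from_dict(cfg: dict) -> PopulationModel:
    """Inverse of :func:`model_to_dict`; validates block structure."""
    try:
        structural = cfg["structural"]
        covariates = cfg.get("covariates", {})
        variability = cfg.get("variability", {})
        error = cfg.get("error", {})
        kwargs = dict(
            theta_cl=float(structural["theta_cl"]),
            theta_v=float(structural["theta_v"]),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"model config missing structural block: {exc}") from None
    for key in ("ffm_ref", "allo_cl", "allo_v", "tm50", "hill",
                "ffm_fallback_fraction", "size_descriptor", "reference_regimen"):
        if key in covariates:
            kwargs[key] = covariates[key]
    if "regimen_factors" in covariates:
        kwargs["regimen_factors"] = {str(k): float(v)
                                     for k, v in covariates["regimen_factors"].items()}
    if "omega" in variability:
        kwargs["omega"] = np.asarray(variability["omega"], dtype=float)
    if "omega_iov_cl" in variability:
        kwargs["omega_iov_cl"] = float(variability["omega_iov_cl"])
    if "sigma_prop" in error:
        kwargs["sigma_prop"] = float(error["sigma_prop"])
    if "sigma_add" in error:
        kwargs["sigma_add"] = float(error["sigma_add"])
    return PopulationModel(**kwargs)


def load_model(path: str | Path) -> PopulationModel:
    """Load a model configuration from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"model config {path} is not a mapping")
    return model_from_dict(cfg)


def save_model(model: PopulationModel, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(model_to_dict(model), indent=2))
    else:
        path.write_text(yaml.safe_dump(model_to_dict(model), sort_keys=False))
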