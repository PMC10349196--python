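"""CSV/JSON artifact schemas and validated readers/writers.

Formats (all UTF-8, "." decimal):
- model spec JSON: structural parameters, variability, covariate law and
  the training-population demographic summary, one file per model;
- cohort CSV: one row per simulated patient with covariates and truth;
- observations CSV (long): patient_id, time_h, conc_mg_L;
- results CSV: method x n_obs metric table;
- run manifest JSON: config hash, package version, seeds.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

from .cohort import SimulatedPatient
from .pk import ConcentrationObservation, CovariateVector, PopPKModel, RandomEffects
from .zoo import DemographicSummary

__all__ = [
    "COHORT_COLUMNS",
    "OBS_COLUMNS",
    "write_model_spec",
    "read_model_spec",
    "cohort_to_frame",
    "write_cohort_csv",
    "read_cohort_csv",
    "observations_to_frame",
    "write_observations_csv",
    "read_observations_csv",
    "write_results_csv",
    "write_manifest",
]

COHORT_COLUMNS = (
    "patient_id",
    "age",
    "height",
    "weight",
    "crcl",
    "generating_model_id",
    "auc_true",
    "eta_cl_true",
    "eta_v_true",
)

OBS_COLUMNS = ("patient_id", "time_h", "conc_mg_L")


class SchemaError(ValueError):
    """A file failed validation against its documented schema."""


def write_model_spec(model: PopPKModel, summary: DemographicSummary, path) -> None:
    spec = model.to_dict()
    spec["demographics"] = summary.to_dict()
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(spec, fh, indent=2, sort_keys=True)


def read_model_spec(path) -> tuple[PopPKModel, DemographicSummary]:
    with open(path, encoding="utf-8") as fh:
        spec = json.load(fh)
    if "demographics" not in spec:
        raise SchemaError(f"{path}: model spec missing field 'demographics'")
    try:
        model = PopPKModel.from_dict(spec)
        summary = DemographicSummary.from_dict(spec["model_id"], spec["demographics"])
    except (KeyError, ValueError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    return model, summary


def cohort_to_frame(patients: list[SimulatedPatient]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "age": [p.covariates.age for p in patients],
            "height": [p.covariates.height for p in patients],
            "weight": [p.covariates.weight for p in patients],
            "crcl": [p.covariates.crcl for p in patients],
            "generating_model_id": [p.generating_model_id for p in patients],
            "auc_true": [p.auc_true for p in patients],
            "eta_cl_true": [p.eta_true.eta[0] for p in patients],
            "eta_v_true": [p.eta_true.eta[1] for p in patients],
        }
    )


def write_cohort_csv(patients: list[SimulatedPatient], path) -> None:
    cohort_to_frame(patients).to_csv(path, index=False)


def _check_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, COHORT_COLUMNS, path)
    for col in ("age", "height", "weight", "crcl"):
        bad = df.index[~np.isfinite(df[col]) | (df[col] <= 0)]
        if len(bad):
            raise SchemaError(
                f"{path}: column '{col}' must be positive and finite (first bad row {bad[0]})"
            )
    if (df["auc_true"] <= 0).any():
        raise SchemaError(f"{path}: column 'auc_true' must be positive")
    return df


def observations_to_frame(patients: list[SimulatedPatient]) -> pd.DataFrame:
    rows = [
        {"patient_id": p.patient_id, "time_h": o.time, "conc_mg_L": o.concentration}
        for p in patients
        for o in p.observations
    ]
    return pd.DataFrame(rows, columns=list(OBS_COLUMNS))


def write_observations_csv(patients: list[SimulatedPatient], path) -> None:
    observations_to_frame(patients).to_csv(path, index=False)


def read_observations_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, OBS_COLUMNS, path)
    if (df["conc_mg_L"] < 0).any():
        raise SchemaError(f"{path}: column 'conc_mg_L' must be non-negative")
    return df


def observations_for_patient(df: pd.DataFrame, patient_id) -> list[ConcentrationObservation]:
    sub = df[df["patient_id"] == patient_id].sort_values("time_h")
    return [
        ConcentrationObservation(time=float(t), concentration=float(c))
        for t, c in zip(sub["time_h"], sub["conc_mg_L"])
    ]


def write_results_csv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, index=False)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(path, config: dict, seed: int, extra: dict | None = None) -> None:
    from . import __version__

    manifest = {
        "package_version": __version__,
        "config_hash": config_hash(config),
        "config": config,
        "seed": seed,
    }
    manifest.update(extra or {})
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
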