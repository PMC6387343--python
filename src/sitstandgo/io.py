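"""Serialization of recordings, annotations, feature tables and reports.

Schemas
-------
* Recording CSV: header ``t,acc_ap,acc_ml,acc_v,gyr_ap,gyr_ml,gyr_v``; ``t``
  in seconds, one row per sample, full float precision.  A sidecar JSON
  (``<name>.json`` next to the CSV) stores subject_id, test_type, fs and the
  ground-truth/detected intervals as ``{label, start_s, end_s}`` plus a
  ``steps`` array — the same schema the segmentation stage emits, so truth
  and detected annotations round-trip identically.
* Cohort CSV: ``subject_id,age,sex,llfdi`` (extra columns such as the
  assessor-recorded standard measures are preserved).
* Feature CSV: one row per subject, canonical feature columns; unknown
  columns are ignored with a warning.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .features import ALL_FEATURES, MANUAL_FEATURES
from .types import SubphaseAnnotation, SubphaseInterval, TriaxialRecording

RECORDING_COLUMNS = ["t", "acc_ap", "acc_ml", "acc_v",
                     "gyr_ap", "gyr_ml", "gyr_v"]
COHORT_COLUMNS = ["subject_id", "age", "sex", "llfdi"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def annotation_to_dict(ann: SubphaseAnnotation) -> dict:
    return {
        "test_type": ann.test_type,
        "intervals": [{"label": iv.label, "start_s": iv.start_s,
                       "end_s": iv.end_s} for iv in ann.intervals],
        "steps": list(ann.steps),
    }


def annotation_from_dict(d: dict) -> SubphaseAnnotation:
    try:
        intervals = [SubphaseInterval(iv["label"], iv["start_s"], iv["end_s"])
                     for iv in d["intervals"]]
        return SubphaseAnnotation(test_type=d["test_type"],
                                  intervals=intervals,
                                  steps=list(d.get("steps", [])))
    except KeyError as exc:
        raise SchemaError(f"annotation JSON missing key {exc}") from exc


def write_annotation(ann: SubphaseAnnotation, path: str | Path) -> None:
    Path(path).write_text(json.dumps(annotation_to_dict(ann), indent=2) + "\n")


def read_annotation(path: str | Path) -> SubphaseAnnotation:
    return annotation_from_dict(json.loads(Path(path).read_text()))


def write_recording(rec: TriaxialRecording, path: str | Path) -> None:
    """Recording CSV plus sidecar JSON with metadata and annotation."""
    path = Path(path)
    df = pd.DataFrame({
        "t": rec.t, "acc_ap": rec.acc_ap, "acc_ml": rec.acc_ml,
        "acc_v": rec.acc_v, "gyr_ap": rec.gyr_ap, "gyr_ml": rec.gyr_ml,
        "gyr_v": rec.gyr_v,
    })
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {"subject_id": rec.subject_id, "test_type": rec.test_type,
            "fs": rec.fs,
            "truth": annotation_to_dict(rec.truth) if rec.truth else None}
    _sidecar(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_recording(path: str | Path) -> TriaxialRecording:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"recording CSV missing column(s): {missing}")
    side = _sidecar(path)
    if not side.exists():
        raise SchemaError(f"missing sidecar JSON {side.name}")
    meta = json.loads(side.read_text())
    for key in ("subject_id", "test_type", "fs"):
        if key not in meta:
            raise SchemaError(f"sidecar JSON missing key {key!r}")
    truth = (annotation_from_dict(meta["truth"])
             if meta.get("truth") else None)
    return TriaxialRecording(
        subject_id=meta["subject_id"], test_type=meta["test_type"],
        fs=float(meta["fs"]),
        acc_ap=df["acc_ap"].to_numpy(float),
        acc_ml=df["acc_ml"].to_numpy(float),
        acc_v=df["acc_v"].to_numpy(float),
        gyr_ap=df["gyr_ap"].to_numpy(float),
        gyr_ml=df["gyr_ml"].to_numpy(float),
        gyr_v=df["gyr_v"].to_numpy(float),
        truth=truth)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort table missing column(s): {missing}")
    cohort.to_csv(path, index=False, float_format="%.17g")


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort CSV missing column(s): {missing}")
    return df


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, index=False, float_format="%.17g")


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if "subject_id" not in df.columns:
        raise SchemaError("features CSV missing column 'subject_id'")
    known = ["subject_id"] + ALL_FEATURES + MANUAL_FEATURES
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"ignoring unknown feature column(s): {unknown}",
                      stacklevel=2)
        df = df.drop(columns=unknown)
    return df


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def read_config(path: str | Path):
    """Pipeline configuration from YAML (or JSON — YAML is a superset)."""
    from .pipeline import PipelineConfig

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError("config file must contain a mapping")
    try:
        return PipelineConfig.from_dict(data)
    except TypeError as exc:
        raise SchemaError(f"bad config key: {exc}") from exc


def write_config(config, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
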