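"""File interchange formats.

A case on disk is a CSV (columns time_s, ppg_1..ppg_9, force) with a JSON
sidecar (case_id, subject_id, fs_ppg, fs_force, ref_sbp, ref_dbp); a dataset
directory carries a manifest CSV listing every case.  Prepared tensors are
stored one compressed .npz per case with their own manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import PreparedCase
from .simulate import RawRecording

__all__ = [
    "ParseError",
    "write_case",
    "read_case",
    "write_dataset",
    "read_dataset",
    "write_prepared",
    "read_prepared",
]

PPG_COLUMNS = [f"ppg_{i}" for i in range(1, 10)]
SIDECAR_FIELDS = ("case_id", "subject_id", "fs_ppg", "fs_force", "ref_sbp", "ref_dbp")


class ParseError(ValueError):
    """Structured file-format error naming the offending file and field."""


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_case(rec: RawRecording, directory: Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = np.arange(rec.n_samples) / rec.fs_ppg
    df = pd.DataFrame({"time_s": t})
    for i, col in enumerate(PPG_COLUMNS):
        df[col] = rec.ppg[i]
    df["force"] = rec.force
    csv_path = directory / f"{rec.case_id}.csv"
    df.to_csv(csv_path, index=False, float_format="%.17g")
    meta = {
        "case_id": rec.case_id,
        "subject_id": rec.subject_id,
        "fs_ppg": rec.fs_ppg,
        "fs_force": rec.fs_force,
        "ref_sbp": rec.ref_sbp,
        "ref_dbp": rec.ref_dbp,
        "provenance": rec.provenance,
    }
    _sidecar_path(csv_path).write_text(json.dumps(meta, indent=1))
    return csv_path


def read_case(path: Path) -> RawRecording:
    """Read and validate one case CSV + JSON sidecar."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not path.exists():
        raise ParseError(f"{path}: case file not found")
    if not sidecar.exists():
        raise ParseError(f"{sidecar}: sidecar not found")
    meta = json.loads(sidecar.read_text())
    for fieldname in SIDECAR_FIELDS:
        if fieldname not in meta:
            raise ParseError(f"{sidecar}: missing metadata field '{fieldname}'")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ["time_s", *PPG_COLUMNS, "force"] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if not (dt > 0).all():
        raise ParseError(f"{path}: time_s column is not strictly increasing")
    expected = 1.0 / meta["fs_ppg"]
    if np.abs(dt - expected).max() > 0.01 * expected:
        raise ParseError(
            f"{path}: sample spacing inconsistent with fs_ppg={meta['fs_ppg']}"
        )
    return RawRecording(
        case_id=meta["case_id"],
        subject_id=meta["subject_id"],
        fs_ppg=float(meta["fs_ppg"]),
        fs_force=float(meta["fs_force"]),
        ppg=df[PPG_COLUMNS].to_numpy().T,
        force=df["force"].to_numpy(),
        ref_sbp=float(meta["ref_sbp"]),
        ref_dbp=float(meta["ref_dbp"]),
        provenance=meta.get("provenance", "file"),
    )


def write_dataset(recordings, directory: Path, subject_table=None) -> Path:
    """Write all cases plus a manifest CSV (and optional subject table)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        path = write_case(rec, directory)
        rows.append(
            {
                "case_id": rec.case_id,
                "subject_id": rec.subject_id,
                "file": path.name,
                "ref_sbp": rec.ref_sbp,
                "ref_dbp": rec.ref_dbp,
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    if subject_table is not None:
        subject_table.to_csv(directory / "subjects.csv", index=False)
    return manifest


def read_dataset(directory: Path) -> list[RawRecording]:
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise ParseError(f"{manifest}: dataset manifest not found")
    rows = pd.read_csv(manifest)
    if rows["case_id"].duplicated().any():
        raise ParseError(f"{manifest}: duplicate case_ids")
    return [read_case(directory / f) for f in rows["file"]]


def write_prepared(cases: list[PreparedCase], directory: Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        path = directory / f"{case.case_id}.npz"
        np.savez_compressed(
            path,
            x1=case.x1,
            x2=case.x2,
            x3=case.x3,
            meta=json.dumps(
                {
                    "case_id": case.case_id,
                    "subject_id": case.subject_id,
                    "ref_sbp": case.ref_sbp,
                    "ref_dbp": case.ref_dbp,
                }
            ),
        )
        rows.append({"case_id": case.case_id, "file": path.name})
    manifest = directory / "prepared_manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_prepared(directory: Path) -> list[PreparedCase]:
    directory = Path(directory)
    manifest = directory / "prepared_manifest.csv"
    if not manifest.exists():
        raise ParseError(f"{manifest}: prepared manifest not found")
    cases = []
    for fname in pd.read_csv(manifest)["file"]:
        with np.load(directory / fname) as z:
            meta = json.loads(str(z["meta"]))
            cases.append(
                PreparedCase(
                    case_id=meta["case_id"],
                    subject_id=meta["subject_id"],
                    x1=z["x1"],
                    x2=z["x2"],
                    x3=z["x3"],
                    ref_sbp=meta["ref_sbp"],
                    ref_dbp=meta["ref_dbp"],
                )
            )
    return cases
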