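"""Delimited-text and JSON serialization for trials, epochs, models, reports.

Trial recordings are plain CSV with a ``#``-prefixed header block carrying
sampling metadata, split per rate group: ``*_kin.csv`` (time, theta, d at
100 Hz) and ``*_plate.csv`` (time, cop_x, force_x, force_z, emg_ga, emg_ta
at 1,000 Hz).  Cleaned epochs, selected-lag tables and fit grids are CSV;
identified models are JSON documents.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .biomech import PendulumParams
from .cohort import TrialRecord
from .preprocess import CleanEpoch
from .pwarx import PWARXModel
from .regressors import LagCoordinate

__all__ = [
    "trial_basename",
    "write_trial",
    "read_trial",
    "write_epoch",
    "read_epoch",
    "write_model",
    "read_model",
]


def _write_csv(path: Path, header: dict, frame: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}: {v}\n")
        frame.to_csv(fh, index=False, float_format="%.10g")


def _read_csv(path: Path) -> tuple[dict, pd.DataFrame]:
    header: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                header[key.strip()] = val.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        frame = pd.read_csv(fh)
    return header, frame


def trial_basename(subject: int, condition: str) -> str:
    return f"S{subject:02d}_{condition}"


def write_trial(trial: TrialRecord, out_dir) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = trial_basename(trial.subject, trial.condition)
    meta = {
        "subject": trial.subject, "condition": trial.condition,
        "mass_kg": trial.params.mass, "length_m": trial.params.length,
        "gravity": trial.params.gravity, "h_ankle_m": trial.h_ankle,
        "onset_s": trial.onset,
    }
    kin_path = out_dir / f"{base}_kin.csv"
    _write_csv(kin_path, {**meta, "fs_hz": trial.fs_kin},
               pd.DataFrame({"time": trial.kin_time, "theta": trial.theta,
                             "d": trial.d}))
    plate_path = out_dir / f"{base}_plate.csv"
    _write_csv(plate_path, {**meta, "fs_hz": trial.fs_plate},
               pd.DataFrame({"time": trial.plate_time, "cop_x": trial.cop_x,
                             "force_x": trial.force_x, "force_z": trial.force_z,
                             "emg_ga": trial.emg_ga, "emg_ta": trial.emg_ta}))
    return kin_path, plate_path


def read_trial(out_dir, subject: int, condition: str) -> TrialRecord:
    out_dir = Path(out_dir)
    base = trial_basename(subject, condition)
    kin_hdr, kin = _read_csv(out_dir / f"{base}_kin.csv")
    plate_hdr, plate = _read_csv(out_dir / f"{base}_plate.csv")
    params = PendulumParams(mass=float(kin_hdr["mass_kg"]),
                            length=float(kin_hdr["length_m"]),
                            gravity=float(kin_hdr["gravity"]))
    return TrialRecord(
        subject=int(kin_hdr["subject"]), condition=kin_hdr["condition"],
        params=params, onset=float(kin_hdr["onset_s"]),
        fs_kin=float(kin_hdr["fs_hz"]), fs_plate=float(plate_hdr["fs_hz"]),
        kin_time=kin["time"].to_numpy(), theta=kin["theta"].to_numpy(),
        d=kin["d"].to_numpy(),
        plate_time=plate["time"].to_numpy(), cop_x=plate["cop_x"].to_numpy(),
        force_x=plate["force_x"].to_numpy(), force_z=plate["force_z"].to_numpy(),
        emg_ga=plate["emg_ga"].to_numpy(), emg_ta=plate["emg_ta"].to_numpy(),
        h_ankle=float(kin_hdr["h_ankle_m"]),
    )


def write_epoch(epoch: CleanEpoch, path, provenance: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {"subject": epoch.subject, "condition": epoch.condition,
              "onset_s": epoch.onset_time, "fs_hz": epoch.fs}
    if provenance:
        header.update(provenance)
    _write_csv(path, header, pd.DataFrame({
        "time": epoch.time, "tau_c": epoch.tau_c, "theta": epoch.theta,
        "ga_rms": epoch.ga_rms, "ta_rms": epoch.ta_rms,
    }))
    return path


def read_epoch(path) -> CleanEpoch:
    header, frame = _read_csv(Path(path))
    return CleanEpoch(
        tau_c=frame["tau_c"].to_numpy(), theta=frame["theta"].to_numpy(),
        ga_rms=frame["ga_rms"].to_numpy(), ta_rms=frame["ta_rms"].to_numpy(),
        onset_time=float(header["onset_s"]),
        subject=int(header["subject"]) if header.get("subject") not in (None, "None") else None,
        condition=header.get("condition"),
    )


def write_model(model: PWARXModel, path, config: dict | None = None,
                seed: int | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "columns": [str(c) for c in model.columns],
        "submodels": model.submodels.tolist(),
        "boundaries": model.boundaries.tolist() if model.boundaries is not None else None,
        "s": model.s,
        "noise_sd_hat": model.noise_sd_hat,
        "silhouette": {str(k): v for k, v in model.silhouette.items()},
        "config": config or {},
        "seed": seed,
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    return path


def read_model(path) -> PWARXModel:
    doc = json.loads(Path(path).read_text())
    model = PWARXModel(
        submodels=np.array(doc["submodels"]),
        boundaries=np.array(doc["boundaries"]) if doc["boundaries"] is not None else None,
        columns=[LagCoordinate.parse(c) for c in doc["columns"]],
        s=int(doc["s"]), noise_sd_hat=float(doc["noise_sd_hat"]),
    )
    model.silhouette = {int(k): float(v) for k, v in doc.get("silhouette", {}).items()}
    return model
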