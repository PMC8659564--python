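"""Hierarchical container (HDF5) and CSV plumbing for data sets and results."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .evaluation import EvalReport
from .preprocessing import CycleSet
from .synthetic import Recording

__all__ = [
    "FormatError",
    "save_recordings",
    "load_recordings",
    "save_cycle_sets",
    "load_cycle_sets",
    "export_recordings_csv",
    "save_report",
]


class FormatError(RuntimeError):
    """Container file is missing expected structure."""


def _key(subject_id: str, load: str) -> str:
    return f"{subject_id}__{load}"


def save_recordings(
    path: str | Path, recordings: list[Recording], config_hash: str = ""
) -> None:
    """One group per recording; signal rates and truth lags as attributes."""
    with h5py.File(path, "w") as f:
        f.attrs["config_hash"] = config_hash
        grp = f.create_group("recordings")
        for rec in recordings:
            g = grp.create_group(_key(rec.subject_id, rec.load))
            g.create_dataset("emg", data=rec.emg)
            g.create_dataset("angles", data=rec.angles)
            g.attrs["subject_id"] = rec.subject_id
            g.attrs["load"] = rec.load
            g.attrs["emg_rate"] = rec.emg_rate
            g.attrs["kin_rate"] = rec.kin_rate
            g.attrs["channels"] = list(rec.channels)
            g.attrs["joints"] = list(rec.joints)
            if rec.truth_lags_ms is not None:
                g.attrs["truth_lags_ms"] = rec.truth_lags_ms


def load_recordings(path: str | Path) -> list[Recording]:
    try:
        with h5py.File(path, "r") as f:
            if "recordings" not in f:
                raise FormatError(f"{path}: no 'recordings' group")
            out = []
            for name in sorted(f["recordings"]):
                g = f["recordings"][name]
                lags = g.attrs.get("truth_lags_ms")
                out.append(
                    Recording(
                        subject_id=str(g.attrs["subject_id"]),
                        load=str(g.attrs["load"]),
                        emg=g["emg"][()],
                        angles=g["angles"][()],
                        emg_rate=float(g.attrs["emg_rate"]),
                        kin_rate=float(g.attrs["kin_rate"]),
                        channels=tuple(str(c) for c in g.attrs["channels"]),
                        joints=tuple(str(j) for j in g.attrs["joints"]),
                        truth_lags_ms=None if lags is None else np.asarray(lags),
                    )
                )
        return out
    except OSError as exc:
        raise FormatError(f"cannot read container file {path}: {exc}") from exc


def save_cycle_sets(
    path: str | Path, cycle_sets: list[CycleSet], config_hash: str = ""
) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config_hash"] = config_hash
        grp = f.create_group("cycle_sets")
        for cs in cycle_sets:
            g = grp.create_group(_key(cs.subject_id, cs.load))
            g.create_dataset("features_raw", data=cs.features_raw)
            g.create_dataset("targets", data=cs.targets)
            g.attrs["subject_id"] = cs.subject_id
            g.attrs["load"] = cs.load
            g.attrs["cycle_boundaries"] = cs.cycle_boundaries
            g.attrs["n_points"] = cs.n_points


def load_cycle_sets(path: str | Path) -> list[CycleSet]:
    try:
        with h5py.File(path, "r") as f:
            if "cycle_sets" not in f:
                raise FormatError(f"{path}: no 'cycle_sets' group")
            out = []
            for name in sorted(f["cycle_sets"]):
                g = f["cycle_sets"][name]
                out.append(
                    CycleSet(
                        subject_id=str(g.attrs["subject_id"]),
                        load=str(g.attrs["load"]),
                        features_raw=g["features_raw"][()],
                        targets=g["targets"][()],
                        cycle_boundaries=[int(i) for i in g.attrs["cycle_boundaries"]],
                        n_points=int(g.attrs["n_points"]),
                    )
                )
        return out
    except OSError as exc:
        raise FormatError(f"cannot read container file {path}: {exc}") from exc


def export_recordings_csv(path: str | Path, recordings: list[Recording]) -> None:
    """Flat long-format export: subject, load, channel, time_s, value."""
    frames = []
    for rec in recordings:
        for names, matrix, rate in (
            (rec.channels, rec.emg, rec.emg_rate),
            (rec.joints, rec.angles, rec.kin_rate),
        ):
            t = np.arange(matrix.shape[1]) / rate
            for i, ch in enumerate(names):
                frames.append(
                    pd.DataFrame(
                        {
                            "subject": rec.subject_id,
                            "load": rec.load,
                            "channel": ch,
                            "time_s": t,
                            "value": matrix[i],
                        }
                    )
                )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def save_report(
    report: EvalReport,
    json_path: str | Path,
    csv_path: str | Path | None = None,
    extra: dict | None = None,
) -> None:
    """Serialize an evaluation report as JSON (and a table-style CSV)."""
    payload = report.to_dict()
    payload["lag_profiles"] = {
        subj: json.loads(p.to_json()) for subj, p in report.lag_profiles.items()
    }
    if extra:
        payload.update(extra)
    Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True))
    if csv_path is not None:
        report.to_frame().to_csv(csv_path, index=False)
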