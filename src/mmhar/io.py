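"""Readers and writers for trial recordings.

File formats (delimited text, comma-separated, no header):

* skeleton: one row per frame, ``t, x_0, y_0, z_0, ..., x_24, y_24, z_24``
  (76 columns), joints in :class:`~mmhar.types.JointName` index order;
* IMU: one row per sample, ``t, gx, gy, gz, ax, ay, az`` (7 columns),
  one file per sensor site;
* manifest: one JSON record per line with ``trial_id``, ``user_id``,
  ``label`` and relative paths to the five data files.

Values are written with 12 significant digits so round-trips are exact to
well below sensor resolution.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np
import pandas as pd

from .types import (
    N_JOINTS,
    BehaviorLabel,
    ImuStream,
    SensorSite,
    SkeletonSequence,
    Trial,
    ValidationError,
)

__all__ = [
    "ParseError",
    "read_skeleton",
    "read_imu",
    "read_trial",
    "write_trial",
    "write_manifest",
    "read_manifest",
    "read_manifest_trials",
]

_SKELETON_COLS = 1 + 3 * N_JOINTS  # 76
_IMU_COLS = 7
_FMT = "%.12g"


class ParseError(ValueError):
    """A data file does not conform to the documented column schema."""


def _load_table(path, n_cols: int, what: str) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{what} file not found: {path}")
    try:
        df = pd.read_csv(path, header=None, dtype=float)
    except Exception as exc:  # tokenizer errors carry the line number
        raise ParseError(f"{path}: malformed {what} file: {exc}") from exc
    if df.shape[1] != n_cols:
        raise ParseError(
            f"{path}: expected {n_cols} columns for a {what} file, got {df.shape[1]}"
        )
    values = df.to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(values).all(axis=1))[0]
    if bad.size:
        raise ParseError(f"{path}: non-finite value at line {bad[0] + 1}")
    return values


def _nominal_rate(times: np.ndarray) -> float:
    span = times[-1] - times[0]
    return (len(times) - 1) / span if span > 0 else float("nan")


def read_skeleton(path) -> SkeletonSequence:
    table = _load_table(path, _SKELETON_COLS, "skeleton")
    times = table[:, 0]
    positions = table[:, 1:].reshape(len(table), N_JOINTS, 3)
    return SkeletonSequence(times=times, positions=positions, rate_hz=_nominal_rate(times))


def read_imu(path, site: SensorSite) -> ImuStream:
    table = _load_table(path, _IMU_COLS, "IMU")
    times = table[:, 0]
    return ImuStream(
        site=site,
        times=times,
        gyro=table[:, 1:4],
        accel=table[:, 4:7],
        rate_hz=_nominal_rate(times),
    )


def read_trial(
    skeleton_path,
    imu_paths: Mapping[SensorSite, "os.PathLike | str"],
    trial_id: str = "",
    user_id: str = "",
    label: Optional[BehaviorLabel] = None,
) -> Trial:
    """Load and validate one trial from its per-modality files."""
    missing = [s for s in SensorSite if s not in imu_paths]
    if missing:
        raise ValidationError(f"missing IMU paths for sites {[s.name for s in missing]}")
    skeleton = read_skeleton(skeleton_path)
    imu = {site: read_imu(imu_paths[site], site) for site in SensorSite}
    return Trial(trial_id=trial_id, user_id=user_id, skeleton=skeleton, imu=imu, label=label)


def write_trial(trial: Trial, out_dir) -> Dict[str, Path]:
    """Write one trial's five data files; returns the paths keyed by modality."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    skel = trial.skeleton
    table = np.column_stack([skel.times, skel.positions.reshape(len(skel), -1)])
    skel_path = out_dir / f"{trial.trial_id}_skeleton.csv"
    np.savetxt(skel_path, table, fmt=_FMT, delimiter=",")
    paths["skeleton"] = skel_path
    for site in SensorSite:
        stream = trial.imu[site]
        table = np.column_stack([stream.times, stream.gyro, stream.accel])
        p = out_dir / f"{trial.trial_id}_imu_{site.name}.csv"
        np.savetxt(p, table, fmt=_FMT, delimiter=",")
        paths[f"imu_{site.name}"] = p
    return paths


def write_manifest(records: Iterable[dict], path) -> Path:
    """Write a JSON-lines manifest of trial records (paths relative to it)."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")
    return path


def read_manifest(path) -> List[dict]:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"manifest not found: {path}")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                records.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}: bad manifest record at line {lineno}: {exc}") from exc
    return records


def read_manifest_trials(path) -> List[Trial]:
    """Load every trial listed in a manifest."""
    path = Path(path)
    base = path.parent
    trials = []
    for rec in read_manifest(path):
        label = BehaviorLabel[rec["label"]] if rec.get("label") else None
        imu_paths = {SensorSite[name]: base / p for name, p in rec["imu"].items()}
        trials.append(
            read_trial(
                base / rec["skeleton"],
                imu_paths,
                trial_id=rec["trial_id"],
                user_id=rec["user_id"],
                label=label,
            )
        )
    return trials
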