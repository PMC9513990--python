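"""CSV + JSON-sidecar readers and writers for trials and EMG.

Kinematic interchange format: a CSV with header
``time,q0..q7,ee_x,ee_y,ee_z,trunk_sagittal_deg,trunk_frontal_deg,
trunk_x,trunk_y,trunk_z`` (angles in degrees, positions in meters) plus a
``<name>.json`` sidecar holding the sampling rate, units, skill, go cues,
target-layout points and arm geometry.  EMG: one column per muscle
(header = muscle names) plus a sidecar with rate and go cues.

Left-arm recordings are mirrored about the sagittal plane at load time
(Z negated; lateral-sense DOFs q1, q3, q5, q7 sign-flipped) so every
downstream metric is side-agnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .emg_metrics import EMGRecording
from .kinematics import ArmGeometry, JointAngles, Trajectory3D, speed_profile
from .taxonomy import MotorSkill

__all__ = [
    "PointLayout",
    "LoadedTrial",
    "write_trial_csv",
    "read_trial_csv",
    "write_emg_csv",
    "read_emg_csv",
]

_MIRROR_DOFS = (1, 3, 5, 7)


@dataclass
class PointLayout:
    """Target layout reconstructed from stored points."""

    points_m: dict[str, np.ndarray]
    mode: str = "rest_height"
    shoulder_height_above_desk_m: float = 0.30

    def point(self, label: str) -> np.ndarray:
        return np.asarray(self.points_m[label], dtype=float).copy()

    @property
    def shoulder(self) -> np.ndarray:
        return np.array([0.0, self.shoulder_height_above_desk_m, 0.0])


@dataclass
class LoadedTrial:
    """Trial reconstructed from CSV + sidecar (same interface as Trial)."""

    skill: MotorSkill
    layout: PointLayout
    geom: ArmGeometry | None
    rate_hz: float
    ee: Trajectory3D
    q: JointAngles | None
    trunk_sagittal_deg: np.ndarray
    trunk_frontal_deg: np.ndarray
    trunk_position: np.ndarray | None
    go_cues_s: tuple[float, ...]
    meta: dict = field(default_factory=dict)

    @property
    def t(self) -> np.ndarray:
        return self.ee.t

    def speed(self, cutoff_hz: float | None = 6.0) -> np.ndarray:
        return speed_profile(self.ee, cutoff_hz=cutoff_hz)


def _sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def write_trial_csv(trial, path) -> Path:
    """Write a trial's kinematics to CSV + JSON sidecar; returns the path."""
    path = Path(path)
    n = len(trial.ee)
    cols = {"time": trial.t}
    q_deg = trial.q.to_degrees() if trial.q is not None else np.zeros((n, 8))
    for i in range(8):
        cols[f"q{i}"] = q_deg[:, i]
    for i, ax in enumerate("xyz"):
        cols[f"ee_{ax}"] = trial.ee.xyz[:, i]
    cols["trunk_sagittal_deg"] = trial.trunk_sagittal_deg
    cols["trunk_frontal_deg"] = trial.trunk_frontal_deg
    tp = trial.trunk_position if trial.trunk_position is not None \
        else np.zeros((n, 3))
    for i, ax in enumerate("xyz"):
        cols[f"trunk_{ax}"] = tp[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")
    layout = trial.layout
    points = (layout.points if hasattr(layout, "points") else layout.points_m)
    sidecar = {
        "rate_hz": trial.rate_hz,
        "units": {"angles": "deg", "positions": "m", "time": "s"},
        "skill": str(getattr(trial.skill, "value", trial.skill)),
        "go_cues_s": list(trial.go_cues_s),
        "layout": {
            "points_m": {k: np.asarray(v).tolist() for k, v in points.items()},
            "mode": layout.mode,
            "shoulder_height_above_desk_m":
                layout.shoulder_height_above_desk_m,
        },
        "geometry": None if trial.geom is None else {
            "upper_arm_length_m": trial.geom.upper_arm_length_m,
            "forearm_length_m": trial.geom.forearm_length_m,
            "dominant_arm": trial.geom.dominant_arm,
            "evaluated_arm": trial.geom.evaluated_arm,
        },
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_trial_csv(path) -> LoadedTrial:
    """Load a trial from CSV + sidecar, mirroring left-arm data."""
    path = Path(path)
    sidecar = json.loads(_sidecar_path(path).read_text())
    df = pd.read_csv(path)
    rate = float(sidecar["rate_hz"])
    geom = None
    mirror = False
    if sidecar.get("geometry"):
        g = sidecar["geometry"]
        geom = ArmGeometry(**g)
        mirror = geom.evaluated_arm == "left"
    q = df[[f"q{i}" for i in range(8)]].to_numpy()
    ee = df[["ee_x", "ee_y", "ee_z"]].to_numpy()
    trunk = df[["trunk_x", "trunk_y", "trunk_z"]].to_numpy()
    points = {k: np.asarray(v, dtype=float)
              for k, v in sidecar["layout"]["points_m"].items()}
    if mirror:
        ee = ee * np.array([1.0, 1.0, -1.0])
        trunk = trunk * np.array([1.0, 1.0, -1.0])
        q[:, _MIRROR_DOFS] *= -1.0
        points = {k: v * np.array([1.0, 1.0, -1.0]) for k, v in points.items()}
    layout = PointLayout(
        points, sidecar["layout"].get("mode", "rest_height"),
        float(sidecar["layout"].get("shoulder_height_above_desk_m", 0.30)))
    return LoadedTrial(
        skill=MotorSkill(sidecar["skill"]),
        layout=layout,
        geom=geom,
        rate_hz=rate,
        ee=Trajectory3D(ee, rate),
        q=JointAngles.from_degrees(q, rate),
        trunk_sagittal_deg=df["trunk_sagittal_deg"].to_numpy(),
        trunk_frontal_deg=df["trunk_frontal_deg"].to_numpy(),
        trunk_position=trunk,
        go_cues_s=tuple(sidecar.get("go_cues_s", [])),
        meta={"source": str(path), "mirrored": mirror},
    )


def write_emg_csv(rec: EMGRecording, path) -> Path:
    path = Path(path)
    cols = {"time": rec.t}
    for i, name in enumerate(rec.channels):
        cols[name] = rec.data[i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")
    sidecar = {
        "rate_hz": rec.rate_hz,
        "units": "mV",
        "channels": list(rec.channels),
        "go_cues_s": list(rec.go_cues_s),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_emg_csv(path) -> EMGRecording:
    path = Path(path)
    sidecar = json.loads(_sidecar_path(path).read_text())
    df = pd.read_csv(path)
    channels = tuple(sidecar["channels"])
    data = np.stack([df[c].to_numpy() for c in channels], axis=0)
    return EMGRecording(data, float(sidecar["rate_hz"]), channels,
                        go_cues_s=tuple(sidecar.get("go_cues_s", [])),
                        meta={"source": str(path)})


def segments_to_tsv(segments, trial_id: str, path) -> Path:
    """Export primitive segments as a BED-like TSV."""
    path = Path(path)
    rows = [
        {
            "trial_id": trial_id,
            "start_s": s.start_s,
            "end_s": s.end_s,
            "primitive": s.primitive.value,
            "waypoint_from": s.waypoint_from,
            "waypoint_to": s.waypoint_to,
            "valid": s.valid,
        }
        for s in segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
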