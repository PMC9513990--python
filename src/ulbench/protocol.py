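"""Benchmarking protocol: worksheet schema, target layout, PI selection,
and report assembly.

The worksheet is the machine-readable record an assessor fills before a
session: who is tested (subject, arm geometry), with what (optional
robot, its training modality and DOF-level assistance/compensation), the
instrumentation, which skills with how many repetitions (minimum 8), the
environment, the manipulated object, a quantitatively specified
disturbance, and the outcome domains to compute.
"""

from __future__ import annotations

import json
from enum import Enum
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .kinematics import ArmGeometry
from .taxonomy import (
    Domain,
    MotorAbility,
    MotorSkill,
    PIDescriptor,
    PIStatus,
    TARGET_MUSCLES,
    classify_environment,
    registry_lookup,
)

__all__ = [
    "TrainingModality",
    "RobotSpec",
    "SubjectSpec",
    "SetupSpec",
    "SkillEntry",
    "ObjectSpec",
    "DisturbanceSpec",
    "Worksheet",
    "TargetLayout",
    "load_worksheet",
    "build_target_layout",
    "select_pis",
    "generate_report",
    "DEFAULT_REPETITIONS",
]

DEFAULT_REPETITIONS = 8


class TrainingModality(str, Enum):
    """Eight-mode robot training-modality taxonomy."""

    PATIENT_IN_CHARGE = "patient_in_charge"
    TRANSPARENT = "transparent"
    RESISTIVE = "resistive"
    ROBOT_IN_CHARGE = "robot_in_charge"
    ASSISTIVE = "assistive"
    CORRECTIVE = "corrective"
    PATH_GUIDANCE = "path_guidance"
    ERROR_AMPLIFICATION = "error_amplification"


class SubjectSpec(BaseModel):
    age: Optional[int] = Field(None, ge=0, le=120)
    sex: Optional[str] = None
    pathology: Optional[str] = None
    upper_arm_cm: float = Field(..., gt=0)
    forearm_cm: float = Field(..., gt=0)
    dominant_arm: Literal["left", "right"] = "right"
    evaluated_arm: Literal["left", "right"] = "right"
    neuropsych_notes: Optional[str] = None

    def geometry(self) -> ArmGeometry:
        return ArmGeometry(self.upper_arm_cm / 100.0, self.forearm_cm / 100.0,
                           self.dominant_arm, self.evaluated_arm)


class RobotSpec(BaseModel):
    type: Literal["exoskeleton", "end_effector", "soft_device"]
    training_modality: TrainingModality
    n_dofs: int = Field(..., ge=1)
    # (joint name, resistance/assistance level in [-1, +1])
    actuated_dofs: list[tuple[str, float]] = Field(default_factory=list)
    # (joint name, gravity compensation level in [0, 1])
    passive_dofs: list[tuple[str, float]] = Field(default_factory=list)

    @field_validator("actuated_dofs")
    @classmethod
    def _check_assistance(cls, v):
        for joint, level in v:
            if not -1.0 <= level <= 1.0:
                raise ValueError(
                    f"actuated DOF {joint!r}: assistance level {level} "
                    "outside [-1, +1]")
        return v

    @field_validator("passive_dofs")
    @classmethod
    def _check_compensation(cls, v):
        for joint, level in v:
            if not 0.0 <= level <= 1.0:
                raise ValueError(
                    f"passive DOF {joint!r}: gravity compensation {level} "
                    "outside [0, 1]")
        return v


class SetupSpec(BaseModel):
    kin_sensor_type: Optional[str] = None
    kin_sensor_placement: Optional[str] = None
    emg_electrode_type: Optional[str] = None
    muscles: list[str] = Field(default_factory=list)

    @field_validator("muscles")
    @classmethod
    def _check_muscles(cls, v):
        unknown = [m for m in v if m not in TARGET_MUSCLES]
        if unknown:
            raise ValueError(
                f"unknown muscle name(s) {unknown}; valid: {list(TARGET_MUSCLES)}")
        return v


class SkillEntry(BaseModel):
    skill: MotorSkill
    repetitions: int = Field(DEFAULT_REPETITIONS, ge=1)
    target_height: Literal["rest_height", "shoulder_height"] = "rest_height"


class ObjectSpec(BaseModel):
    shape: Literal["cylinder"] = "cylinder"
    volume_l: float = Field(0.5, gt=0)
    payload_mass_kg: float = Field(0.0, ge=0)


class DisturbanceSpec(BaseModel):
    kind: Literal["none", "payload", "cognitive", "motor_perturbation",
                  "other"] = "none"
    payload_mass_kg: Optional[float] = Field(None, ge=0)
    direction: Optional[str] = None
    location: Optional[str] = None
    magnitude: Optional[float] = None
    frequency_hz: Optional[float] = None
    waveform: Optional[str] = None
    description: Optional[str] = None

    @model_validator(mode="after")
    def _require_parameters(self):
        if self.kind == "none":
            return self
        if self.kind == "payload" and self.payload_mass_kg is None:
            raise ValueError("payload disturbance requires payload_mass_kg")
        if self.kind == "motor_perturbation" and (
                self.magnitude is None or self.frequency_hz is None):
            raise ValueError(
                "motor perturbation must be quantitatively specified "
                "(magnitude, frequency, waveform)")
        if self.kind in ("cognitive", "other") and not self.description:
            raise ValueError(
                f"{self.kind} disturbance requires a description: the "
                "disturbance must be quantitatively specified and replicable")
        return self


class Worksheet(BaseModel):
    """Machine-readable assessment worksheet."""

    system: Literal["subject_only", "subject_plus_robot"] = "subject_only"
    subject: SubjectSpec
    robot: Optional[RobotSpec] = None
    setup: SetupSpec = Field(default_factory=SetupSpec)
    skills: list[SkillEntry] = Field(default_factory=list)
    object: ObjectSpec = Field(default_factory=ObjectSpec)
    disturbance: DisturbanceSpec = Field(default_factory=DisturbanceSpec)
    outcome_domains: list[Domain] = Field(
        default_factory=lambda: [Domain.KINEMATICS])
    seatback_angle_deg: Optional[float] = None
    shoulder_height_above_desk_m: float = Field(0.30, gt=0)
    # agonist/antagonist pair for co-contraction and coherence
    agonist: str = "biceps_brachii"
    antagonist: str = "triceps_brachii"

    @field_validator("seatback_angle_deg")
    @classmethod
    def _check_seatback(cls, v):
        if v is not None and not 100.0 <= v <= 110.0:
            raise ValueError("seatback angle must lie in [100, 110] degrees")
        return v

    @model_validator(mode="after")
    def _check_system(self):
        if self.system == "subject_plus_robot" and self.robot is None:
            raise ValueError("system declares a robot but none is described")
        if self.system == "subject_only" and self.robot is not None:
            raise ValueError("robot described for a subject-only system")
        if Domain.EMG in self.outcome_domains and not self.setup.muscles:
            raise ValueError(
                "EMG outcome domain declared but no muscles in the set-up")
        return self

    def dump(self) -> dict:
        return json.loads(self.model_dump_json())


def load_worksheet(source) -> Worksheet:
    """Load and validate a worksheet from a JSON/YAML path, text or dict.

    The legacy five-skill listing names "hand to mouth" undivided; it is
    expanded into the with/without-object variants through the entry's
    ``object_present`` flag.
    """
    if isinstance(source, dict):
        doc = source
    else:
        text = None
        try:
            from pathlib import Path
            p = Path(source)
            if p.exists():
                text = p.read_text()
        except (OSError, TypeError):
            pass
        if text is None:
            text = str(source)
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError("worksheet document must be a mapping")
    doc = dict(doc)
    skills = []
    for entry in doc.get("skills", []):
        entry = dict(entry)
        name = entry.get("skill", "")
        if name == "hand_to_mouth":
            obj = bool(entry.pop("object_present", False))
            entry["skill"] = ("hand_to_mouth_with_object" if obj
                              else "hand_to_mouth_without_object")
        skills.append(entry)
    if skills:
        doc["skills"] = skills
    return Worksheet.model_validate(doc)


# --------------------------------------------------------------------------
# Target layout
# --------------------------------------------------------------------------

class TargetLayout:
    """Protocol target points in the ground frame (origin at A, desk level).

    A (rest) sits under the navel on the desk; B is anterior at the reach
    distance; C (contralateral, toward the midline) and D (ipsilateral)
    are at +-45 degrees from the A-B line at the same reach distance; E is
    the mouth point.  For rest-height mode targets stay at desk level and
    the reach distance is sqrt(arm_length^2 - h^2) with h the vertical
    drop from shoulder to desk; for shoulder-height mode targets are at
    shoulder level and the reach distance equals the arm length.
    """

    def __init__(self, geom: ArmGeometry, shoulder_height_above_desk_m: float,
                 mode: str = "rest_height",
                 mouth_offset_m: tuple[float, float] = (0.15, 0.25)):
        if mode not in ("rest_height", "shoulder_height"):
            raise ValueError("mode must be rest_height or shoulder_height")
        arm = geom.arm_length_m
        h = shoulder_height_above_desk_m if mode == "rest_height" else 0.0
        if h >= arm:
            raise ValueError(
                f"infeasible layout: vertical drop {h} m is not smaller than "
                f"the arm length {arm} m")
        r = float(np.sqrt(arm * arm - h * h))
        self.mode = mode
        self.reach_distance_m = r
        self.shoulder_height_above_desk_m = shoulder_height_above_desk_m
        y = 0.0 if mode == "rest_height" else shoulder_height_above_desk_m
        c45 = np.cos(np.deg2rad(45.0))
        s45 = np.sin(np.deg2rad(45.0))
        # +Z is lateral toward the evaluated side (left-arm data are
        # mirrored at load time), so C (contralateral) sits at -Z
        self._points = {
            "A": np.array([0.0, 0.0, 0.0]),
            "B": np.array([r, y, 0.0]),
            "C": np.array([r * c45, y, -r * s45]),
            "D": np.array([r * c45, y, r * s45]),
            "E": np.array([mouth_offset_m[0],
                           shoulder_height_above_desk_m + mouth_offset_m[1],
                           0.0]),
            # object rest location for the drinking task ("close to" A)
            "A_object": np.array([0.10, 0.0, 0.0]),
        }
        #: shoulder position in the same frame (above A)
        self.shoulder = np.array([0.0, shoulder_height_above_desk_m, 0.0])

    def point(self, label: str) -> np.ndarray:
        return self._points[label].copy()

    @property
    def points(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self._points.items()}

    def as_dict(self) -> dict:
        return {k: v.tolist() for k, v in self._points.items()}


def build_target_layout(
    geom: ArmGeometry,
    shoulder_height_above_desk_m: float,
    mode: str = "rest_height",
) -> TargetLayout:
    """Construct the A-E target layout for a subject's geometry."""
    return TargetLayout(geom, shoulder_height_above_desk_m, mode)


# --------------------------------------------------------------------------
# PI selection
# --------------------------------------------------------------------------

def select_pis(
    worksheet: Worksheet,
    abilities: list[MotorAbility] | None = None,
    mandatory_only: bool = False,
) -> list[PIDescriptor]:
    """Registry descriptors applicable to a worksheet's declared domains.

    Mandatory descriptors are always retained whenever their domain is
    declared; requesting an ability whose descriptors all fall outside
    the declared domains is a configuration error.
    """
    domains = set(worksheet.outcome_domains)
    wanted = list(abilities) if abilities is not None else list(MotorAbility)
    out: list[PIDescriptor] = []
    for ability in wanted:
        ability = MotorAbility(ability)
        rows = registry_lookup(ability)
        in_domain = [d for d in rows if d.domain in domains]
        if abilities is not None and not in_domain:
            raise ValueError(
                f"ability {ability.value!r} has no indicator in the declared "
                f"outcome domains {sorted(d.value for d in domains)}")
        for d in in_domain:
            if d.mandatory or not mandatory_only:
                out.append(d)
    return out


# --------------------------------------------------------------------------
# Report
# --------------------------------------------------------------------------

def generate_report(
    worksheet: Worksheet,
    trial_results: list[dict],
    constants: dict | None = None,
) -> dict:
    """Assemble the benchmark report document.

    ``trial_results`` is one dict per repetition with keys ``trial_id``,
    ``skill``, ``validity`` (ValidityReport), and ``pi_records`` (list of
    PIRecord).  Invalid repetitions are excluded from the aggregates and
    listed under exclusions; mandatory indicators that could not be
    computed are listed in a warnings block.
    """
    if not trial_results:
        raise ValueError("at least one trial is required")
    env = classify_environment(worksheet)
    included, excluded = [], []
    for tr in trial_results:
        (included if tr["validity"].valid else excluded).append(tr)
    # aggregate per (skill, ability, pi): mean +- SD over valid repetitions
    table: dict[str, dict[str, dict[str, dict]]] = {}
    warnings_block: list[str] = []
    for tr in included:
        skill = str(tr["skill"])
        for rec in tr["pi_records"]:
            cell = table.setdefault(skill, {}).setdefault(
                rec.ability.value, {})
            for name, piv in rec.values.items():
                entry = cell.setdefault(name, {
                    "values": [], "units": piv.units,
                    "status": piv.status.value})
                if piv.computable and piv.value is not None:
                    entry["values"].append(piv.value)
                elif piv.status is PIStatus.MANDATORY:
                    warnings_block.append(
                        f"mandatory indicator {name!r} not computable for "
                        f"{skill}: {piv.reason or 'unknown reason'}")
    for skill_tab in table.values():
        for cell in skill_tab.values():
            for name, entry in cell.items():
                vals = entry.pop("values")
                entry["n"] = len(vals)
                entry["mean"] = float(np.mean(vals)) if vals else None
                entry["sd"] = (float(np.std(vals, ddof=1))
                               if len(vals) > 1 else None)
    report = {
        "worksheet": worksheet.dump(),
        "environment": {
            "gravity_mode": env.gravity_mode.value,
            "disturbance_present": env.disturbance_present,
            "notes": list(env.notes),
        },
        "n_repetitions_included": len(included),
        "exclusions": [
            {
                "trial_id": tr.get("trial_id"),
                "reasons": tr["validity"].reasons,
                "max_sagittal_trunk_deg": tr["validity"].max_sagittal_trunk_deg,
                "max_frontal_trunk_deg": tr["validity"].max_frontal_trunk_deg,
            }
            for tr in excluded
        ],
        "performance_indicators": table,
        "warnings": warnings_block,
        "constants": constants or {},
    }
    return report
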