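"""Motor-primitive / motor-skill / motor-ability taxonomy.

The benchmarking scheme decomposes functional upper-limb tasks into six
elemental *motor primitives*, composes them into six protocol *motor
skills*, and quantifies performance along ten *motor abilities*, each
measured by one or more *performance indicators* (PIs) drawn from the
kinematic or EMG domain.  This module is the single source of truth for
those enumerations and for the two classification rules (environment and
function) that the rest of the pipeline consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "MotorPrimitive",
    "MotorSkill",
    "MotorAbility",
    "Domain",
    "PIStatus",
    "PIDescriptor",
    "EnvironmentClass",
    "FunctionClass",
    "GravityMode",
    "FunctionGoal",
    "PRIMITIVE_DEFINITIONS",
    "SKILL_FLOWS",
    "ABILITY_INFO",
    "PI_REGISTRY",
    "TARGET_MUSCLES",
    "STABILITY_THRESHOLD_S",
    "classify_function",
    "classify_environment",
    "registry_lookup",
    "registry_to_json",
]

#: Hold duration (s) above which a primitive counts as *stability* rather
#: than *transport* (strict inequality: a hold of exactly 1 s is transport).
STABILITY_THRESHOLD_S = 1.0

#: End-effector speed (m/s) below which the arm location counts as
#: "unchanged" when measuring hold duration.
STILLNESS_SPEED_MS = 0.02


class MotorPrimitive(str, Enum):
    """The six elemental building-block motions."""

    IDLE = "idle"
    STABILIZE = "stabilize"
    POINT_TO_POINT_REACH = "point_to_point_reach"
    REACH_FOR_GRASP = "reach_for_grasp"
    TRANSPORT = "transport"
    REPOSITION = "reposition"

    @property
    def definition(self) -> str:
        return PRIMITIVE_DEFINITIONS[self]

    @property
    def moves(self) -> bool:
        """True for primitives that displace the end-effector."""
        return self not in (MotorPrimitive.IDLE, MotorPrimitive.STABILIZE)


PRIMITIVE_DEFINITIONS: dict[MotorPrimitive, str] = {
    MotorPrimitive.IDLE: (
        "Holding the upper limb in a stable position without contact with any object"
    ),
    MotorPrimitive.STABILIZE: (
        "Holding a target object still. There is the grasp of a target object "
        "throughout the minimal-motion"
    ),
    MotorPrimitive.POINT_TO_POINT_REACH: (
        "Reaching a target point without contact with any object"
    ),
    MotorPrimitive.REACH_FOR_GRASP: (
        "Reaching a target object and make contact with it through grasping"
    ),
    MotorPrimitive.TRANSPORT: "Moving a target object in space",
    MotorPrimitive.REPOSITION: (
        "Moving away from the target object toward the idle position, without "
        "contact with any other object"
    ),
}


class MotorSkill(str, Enum):
    """The six protocol tasks, each an ordered primitive sequence."""

    ANTERIOR_REACHING_REST_HEIGHT = "anterior_reaching_rest_height"
    ANTERIOR_REACHING_SHOULDER_HEIGHT = "anterior_reaching_shoulder_height"
    MOVE_OBJECTS_REST_HEIGHT = "move_objects_rest_height"
    MOVE_OBJECTS_SHOULDER_HEIGHT = "move_objects_shoulder_height"
    HAND_TO_MOUTH_WITHOUT_OBJECT = "hand_to_mouth_without_object"
    HAND_TO_MOUTH_WITH_OBJECT = "hand_to_mouth_with_object"

    @property
    def primitive_flow(self) -> tuple[tuple[MotorPrimitive, str], ...]:
        return SKILL_FLOWS[self]

    @property
    def uses_object(self) -> bool:
        return any(
            p in (MotorPrimitive.REACH_FOR_GRASP, MotorPrimitive.TRANSPORT,
                  MotorPrimitive.STABILIZE)
            for p, _ in self.primitive_flow
        )


_P = MotorPrimitive
_ANTERIOR_REACHING_FLOW = (
    (_P.IDLE, "A"),
    (_P.POINT_TO_POINT_REACH, "B"),
    (_P.REPOSITION, "A"),
    (_P.POINT_TO_POINT_REACH, "C"),
    (_P.REPOSITION, "A"),
    (_P.POINT_TO_POINT_REACH, "D"),
    (_P.REPOSITION, "A"),
)
_MOVE_OBJECTS_FLOW = (
    (_P.IDLE, "A"),
    (_P.REACH_FOR_GRASP, "B"),
    (_P.TRANSPORT, "C"),
    (_P.REPOSITION, "A"),
    (_P.IDLE, "A"),
    (_P.REACH_FOR_GRASP, "C"),
    (_P.TRANSPORT, "D"),
    (_P.REPOSITION, "A"),
    (_P.IDLE, "A"),
    (_P.REACH_FOR_GRASP, "D"),
    (_P.TRANSPORT, "B"),
    (_P.REPOSITION, "A"),
)

#: Ordered (primitive, waypoint) flow per skill.  The waypoint is where the
#: primitive ends: a reach to B carries "B", a reposition carries "A", an
#: idle carries the waypoint at which the arm rests.
SKILL_FLOWS: dict[MotorSkill, tuple[tuple[MotorPrimitive, str], ...]] = {
    MotorSkill.ANTERIOR_REACHING_REST_HEIGHT: _ANTERIOR_REACHING_FLOW,
    MotorSkill.ANTERIOR_REACHING_SHOULDER_HEIGHT: _ANTERIOR_REACHING_FLOW,
    MotorSkill.MOVE_OBJECTS_REST_HEIGHT: _MOVE_OBJECTS_FLOW,
    MotorSkill.MOVE_OBJECTS_SHOULDER_HEIGHT: _MOVE_OBJECTS_FLOW,
    MotorSkill.HAND_TO_MOUTH_WITHOUT_OBJECT: (
        (_P.IDLE, "A"),
        (_P.POINT_TO_POINT_REACH, "E"),
        (_P.IDLE, "E"),
        (_P.REPOSITION, "A"),
    ),
    MotorSkill.HAND_TO_MOUTH_WITH_OBJECT: (
        (_P.IDLE, "A"),
        (_P.REACH_FOR_GRASP, "A"),
        (_P.TRANSPORT, "E"),
        (_P.STABILIZE, "E"),
        (_P.TRANSPORT, "A"),
        (_P.REPOSITION, "A"),
    ),
}


class Domain(str, Enum):
    KINEMATICS = "kinematics"
    EMG = "emg"


class MotorAbility(str, Enum):
    """The ten capacity dimensions quantified by the scheme."""

    ACCURACY = "accuracy"
    EFFICACY = "efficacy"
    EFFICIENCY = "efficiency"
    MOVEMENT_AMPLITUDE = "movement_amplitude"
    MUSCULAR_EFFORT = "muscular_effort"
    INTRA_LIMB_COORDINATION = "intra_limb_coordination"
    PLANNING_PREDICTABILITY = "planning_predictability"
    POWER = "power"
    SMOOTHNESS = "smoothness"
    SPEED = "speed"

    @property
    def description(self) -> str:
        return ABILITY_INFO[self][0]

    @property
    def domains(self) -> frozenset[Domain]:
        return ABILITY_INFO[self][1]


_K = frozenset({Domain.KINEMATICS})
_E = frozenset({Domain.EMG})
_KE = frozenset({Domain.KINEMATICS, Domain.EMG})

ABILITY_INFO: dict[MotorAbility, tuple[str, frozenset[Domain]]] = {
    MotorAbility.ACCURACY: (
        "Spatial error of movements relative to optimal behavior", _K),
    MotorAbility.EFFICACY: (
        "Successful achievement of a targeted task goal", _K),
    MotorAbility.EFFICIENCY: (
        "Quality of how a targeted task goal is reached", _KE),
    MotorAbility.MOVEMENT_AMPLITUDE: (
        "Maximally reachable area or volume with a specific joint and "
        "position-related aspects of single or multiple joints", _K),
    MotorAbility.MUSCULAR_EFFORT: (
        "Muscular activation associated with the production of muscle "
        "tension while achieving a task", _E),
    MotorAbility.INTRA_LIMB_COORDINATION: (
        "Correlation and redundancies in upper limb joints that produce "
        "different strategies to complete the task", _KE),
    MotorAbility.PLANNING_PREDICTABILITY: (
        "Ability to perform goal-directed movements in a feedforward manner",
        _KE),
    MotorAbility.POWER: (
        "Ability to produce force or power while performing exercises", _E),
    MotorAbility.SMOOTHNESS: (
        "Quality of feedforward control based on the deviation of the "
        "velocity profile to an optimal, bell-shaped velocity profile", _KE),
    MotorAbility.SPEED: ("How fast movements are performed", _K),
}


class PIStatus(str, Enum):
    MANDATORY = "mandatory"
    RECOMMENDED = "recommended"


@dataclass(frozen=True)
class PIDescriptor:
    """One performance-indicator row of the benchmarking registry."""

    name: str
    ability: MotorAbility
    domain: Domain
    status: PIStatus
    description: str

    @property
    def mandatory(self) -> bool:
        return self.status is PIStatus.MANDATORY


def _pi(name, ability, domain, status, description):
    return PIDescriptor(name, ability, domain, status, description)


_A = MotorAbility
_M = PIStatus.MANDATORY
_R = PIStatus.RECOMMENDED
_DK = Domain.KINEMATICS
_DE = Domain.EMG

#: Full performance-indicator registry, in canonical (ability-grouped) order.
PI_REGISTRY: tuple[PIDescriptor, ...] = (
    # --- accuracy (kinematics; no mandatory PI) ---
    _pi("trajectory_absolute_error", _A.ACCURACY, _DK, _R,
        "Mean or maximal distance between ideal and actual trajectory "
        "between movement onset and end"),
    _pi("end_point_error", _A.ACCURACY, _DK, _R,
        "Euclidean distance between actual and target position at movement end"),
    _pi("variable_error", _A.ACCURACY, _DK, _R,
        "Standard deviation of the end-point error across repetitions"),
    _pi("area_index", _A.ACCURACY, _DK, _R,
        "Area between the desired straight line and the path actually performed"),
    # --- efficacy ---
    _pi("success_rate", _A.EFFICACY, _DK, _R,
        "Number of accomplished objectives divided by the total number of attempts"),
    _pi("number_of_movement_stops", _A.EFFICACY, _DK, _M,
        "Number of times the velocity curve dropped below a percentage of "
        "peak velocity after movement onset"),
    # --- efficiency ---
    _pi("movement_time", _A.EFFICIENCY, _DK, _R,
        "Time from the onset to the end of a task or movement"),
    _pi("path_traveled", _A.EFFICIENCY, _DK, _R,
        "Path length covered between onset and end of a movement or task"),
    _pi("path_length_ratio", _A.EFFICIENCY, _DK, _M,
        "Ratio between the path traveled and the shortest possible distance "
        "between movement onset and end"),
    _pi("trunk_compensation", _A.EFFICIENCY, _DK, _R,
        "Ratio between trunk displacement and hand displacement in the "
        "sagittal plane"),
    _pi("waveform_length", _A.EFFICIENCY, _DE, _R,
        "Cumulative length of the waveform of the EMG signal over the segment"),
    _pi("average_amplitude_change", _A.EFFICIENCY, _DE, _R,
        "Mean of the cumulative length of the waveform of the EMG signal"),
    _pi("difference_absolute_standard_deviation_value", _A.EFFICIENCY, _DE, _R,
        "Standard deviation of the sample-to-sample differences of the EMG signal"),
    # --- intra-limb coordination (no mandatory PI) ---
    _pi("joint_angle_correlation", _A.INTRA_LIMB_COORDINATION, _DK, _R,
        "Correlation between shoulder and elbow flexion-extension joint "
        "angle time profiles"),
    _pi("elbow_peak_velocity", _A.INTRA_LIMB_COORDINATION, _DK, _R,
        "Highest value of the elbow flexion/extension joint velocity profile"),
    _pi("time_to_peak_elbow_extension", _A.INTRA_LIMB_COORDINATION, _DK, _R,
        "Time to reach peak elbow extension angle relative to movement duration"),
    _pi("muscular_synergies", _A.INTRA_LIMB_COORDINATION, _DE, _R,
        "Non-negative matrix factorization of muscle envelopes into "
        "spatial weights and temporal activations"),
    _pi("cocontraction_index", _A.INTRA_LIMB_COORDINATION, _DE, _R,
        "Percentage of overlapping activity of EMG linear envelopes between "
        "agonist and antagonist"),
    _pi("intermuscular_coherence", _A.INTRA_LIMB_COORDINATION, _DE, _R,
        "Square of the cross-spectrum normalized by the auto-spectra of "
        "agonist and antagonist EMG"),
    # --- movement amplitude ---
    _pi("joint_range_of_motion", _A.MOVEMENT_AMPLITUDE, _DK, _M,
        "Range of the anatomical joint angles between movement onset and end"),
    _pi("maximum_reached_distance", _A.MOVEMENT_AMPLITUDE, _DK, _R,
        "Maximum distance reached from the starting position"),
    _pi("trunk_displacement", _A.MOVEMENT_AMPLITUDE, _DK, _R,
        "Euclidean distance covered by the trunk between movement onset and end"),
    _pi("normalized_reaching_area", _A.MOVEMENT_AMPLITUDE, _DK, _R,
        "Maximally reached position divided by the length of the user's arm"),
    # --- muscular effort ---
    _pi("integrated_emg", _A.MUSCULAR_EFFORT, _DE, _R,
        "Summation of rectified EMG signal amplitude"),
    _pi("root_mean_square", _A.MUSCULAR_EFFORT, _DE, _R,
        "Square root of the mean square of the EMG signal amplitude"),
    _pi("activation_level", _A.MUSCULAR_EFFORT, _DE, _M,
        "Average of the absolute value of the EMG signal amplitude in a segment"),
    _pi("variance_of_emg", _A.MUSCULAR_EFFORT, _DE, _R,
        "Average of squared (mean-removed) EMG signal amplitude"),
    _pi("mean_absolute_value_slope", _A.MUSCULAR_EFFORT, _DE, _R,
        "Differences between mean absolute values of adjacent sub-segments"),
    # --- planning predictability ---
    _pi("time_to_peak_velocity", _A.PLANNING_PREDICTABILITY, _DK, _R,
        "Time to reach peak velocity relative to the duration of the movement"),
    _pi("reaction_time", _A.PLANNING_PREDICTABILITY, _DK, _M,
        "Time between the go cue and the actual onset of the movement "
        "(10% of peak velocity)"),
    _pi("muscle_onset", _A.PLANNING_PREDICTABILITY, _DE, _R,
        "Time between the go cue and the EMG onset detected by the "
        "Teager-Kaiser energy operator"),
    _pi("initial_movement_direction_error", _A.PLANNING_PREDICTABILITY, _DK, _R,
        "Distance between ideal and actual trajectory at an initial time "
        "point right after movement onset"),
    _pi("aiming_angle", _A.PLANNING_PREDICTABILITY, _DK, _R,
        "Angular difference between target direction and direction of travel "
        "from start to peak-speed point"),
    # --- power (EMG; no mandatory PI) ---
    _pi("mean_frequency", _A.POWER, _DE, _R,
        "Spectral centroid of the EMG power spectrum"),
    _pi("median_frequency", _A.POWER, _DE, _R,
        "Frequency splitting the EMG power spectrum into two equal-power regions"),
    _pi("mean_power", _A.POWER, _DE, _R,
        "Average power of the EMG power spectrum"),
    _pi("power_spectral_density", _A.POWER, _DE, _R,
        "Amount of power per frequency interval of the EMG power spectrum"),
    _pi("frequency_ratio", _A.POWER, _DE, _R,
        "Ratio between low-frequency and high-frequency components of the "
        "EMG power spectrum"),
    _pi("power_spectrum_ratio", _A.POWER, _DE, _R,
        "Ratio between the energy near the spectral peak and the whole "
        "energy of the EMG power spectrum"),
    # --- smoothness ---
    _pi("number_of_velocity_peaks", _A.SMOOTHNESS, _DK, _M,
        "Number of maxima above a threshold in the velocity profile between "
        "movement onset and end"),
    _pi("speed_correlation_to_ideal", _A.SMOOTHNESS, _DK, _R,
        "Correlation between actual speed profile and idealized "
        "minimum-jerk velocity profile"),
    _pi("movement_arrest_period_ratio", _A.SMOOTHNESS, _DK, _R,
        "Proportion of time that movement speed exceeds a given percentage "
        "of peak speed"),
    _pi("peak_speed_ratio", _A.SMOOTHNESS, _DK, _R,
        "Mean speed divided by the peak speed"),
    _pi("normalized_dimensionless_jerk", _A.SMOOTHNESS, _DK, _R,
        "Time-integral of squared jerk normalized by duration^5 / length^2"),
    _pi("spectral_arc_length", _A.SMOOTHNESS, _DK, _R,
        "Arc length of the magnitude-normalized Fourier spectrum of the "
        "velocity profile"),
    _pi("mean_acceleration", _A.SMOOTHNESS, _DK, _R,
        "Mean value of the acceleration profile between movement onset and end"),
    _pi("emg_zero_crossing", _A.SMOOTHNESS, _DE, _R,
        "Number of times the EMG signal amplitude crosses zero"),
    _pi("slope_sign_change", _A.SMOOTHNESS, _DE, _R,
        "Number of times the slope of the EMG signal changes sign"),
    # --- speed ---
    _pi("peak_velocity", _A.SPEED, _DK, _R,
        "Maximal value of the velocity profile between movement onset and end"),
    _pi("mean_velocity", _A.SPEED, _DK, _M,
        "Mean value of the velocity profile between movement onset and end"),
    _pi("mean_velocity_variability", _A.SPEED, _DK, _R,
        "Difference between the actual velocity profile and the ideal "
        "velocity profile of the movement"),
)

#: The nine target muscles for surface-EMG recording.
TARGET_MUSCLES: tuple[str, ...] = (
    "trapezius_descendens",
    "pectoralis_major",
    "anterior_deltoid",
    "medial_deltoid",
    "posterior_deltoid",
    "triceps_brachii",
    "biceps_brachii",
    "brachioradialis",
    "pronator_teres",
)


class GravityMode(str, Enum):
    MICRO_GRAVITY = "micro_gravity"
    GRAVITY = "gravity"


@dataclass(frozen=True)
class EnvironmentClass:
    """One cell of the 2x2 environment grid: gravity mode x disturbance."""

    gravity_mode: GravityMode
    disturbance_present: bool
    notes: tuple[str, ...] = ()


class FunctionGoal(str, Enum):
    STABILITY = "stability"
    TRANSPORT = "transport"


@dataclass(frozen=True)
class FunctionClass:
    goal: FunctionGoal
    object_manipulation: bool


# Robot training modalities that leave the user working against gravity.
GRAVITY_MODALITIES = frozenset({"patient_in_charge", "transparent", "resistive"})


def hold_duration(
    t: np.ndarray,
    speed: np.ndarray,
    stillness_speed_ms: float = STILLNESS_SPEED_MS,
) -> float:
    """Longest contiguous interval (s) with end-effector speed below tolerance."""
    t = np.asarray(t, dtype=float)
    speed = np.asarray(speed, dtype=float)
    if t.size == 0:
        raise ValueError("empty segment: cannot measure hold duration")
    still = speed < stillness_speed_ms
    best = 0.0
    start = None
    for i, s in enumerate(still):
        if s and start is None:
            start = i
        elif not s and start is not None:
            best = max(best, t[i - 1] - t[start])
            start = None
    if start is not None:
        best = max(best, t[-1] - t[start])
    return float(best)


def classify_function(
    t: np.ndarray,
    speed: np.ndarray,
    *,
    object_manipulation: bool = False,
    stability_threshold_s: float = STABILITY_THRESHOLD_S,
    stillness_speed_ms: float = STILLNESS_SPEED_MS,
) -> FunctionClass:
    """Classify a labeled interval as *stability* or *transport*.

    The goal is stability iff the longest still interval (speed below
    ``stillness_speed_ms``) strictly exceeds ``stability_threshold_s``
    (default 1 s); otherwise the function is transport.

    Parameters
    ----------
    t, speed
        Time stamps (s) and end-effector speed (m/s) over the segment.
    object_manipulation
        Whether an object is grasped during the segment (copied from
        segment metadata into the returned class).
    """
    hold = hold_duration(t, speed, stillness_speed_ms)
    goal = (FunctionGoal.STABILITY if hold > stability_threshold_s
            else FunctionGoal.TRANSPORT)
    return FunctionClass(goal=goal, object_manipulation=bool(object_manipulation))


def classify_environment(worksheet) -> EnvironmentClass:
    """Classify the task environment from a worksheet.

    Rules: no robot -> *gravity*; robot whose training modality is
    patient-in-charge, transparent or resistive -> *gravity* (the robot
    neither assists nor supports arm weight); any other modality, or any
    passive-DOF gravity compensation above the compensation threshold ->
    *micro-gravity*.  The disturbance flag is copied from the worksheet.
    """
    robot = getattr(worksheet, "robot", None)
    disturbance = getattr(worksheet, "disturbance", None)
    disturbed = disturbance is not None and getattr(disturbance, "kind", "none") != "none"
    notes: list[str] = []
    if robot is None:
        mode = GravityMode.GRAVITY
    else:
        modality = getattr(robot, "training_modality", None)
        if modality is None:
            raise ValueError("robot present but training modality missing")
        modality = str(getattr(modality, "value", modality))
        if modality in GRAVITY_MODALITIES:
            mode = GravityMode.GRAVITY
            # partial gravity compensation on passive DOFs overrides:
            # any compensation > 0 counts as weight support
            comp = [lvl for _, lvl in getattr(robot, "passive_dofs", []) or []]
            if any(level > 0.0 for level in comp):
                mode = GravityMode.MICRO_GRAVITY
                notes.append(
                    "passive-DOF gravity compensation > 0 forced micro_gravity")
        else:
            mode = GravityMode.MICRO_GRAVITY
    return EnvironmentClass(gravity_mode=mode, disturbance_present=disturbed,
                            notes=tuple(notes))


def registry_lookup(
    ability: MotorAbility | str,
    mandatory_only: bool = False,
) -> list[PIDescriptor]:
    """Return the registry descriptors for one ability, in registry order."""
    try:
        ability = MotorAbility(ability)
    except ValueError:
        valid = ", ".join(a.value for a in MotorAbility)
        raise ValueError(
            f"unknown motor ability {ability!r}; valid names: {valid}"
        ) from None
    rows = [d for d in PI_REGISTRY if d.ability is ability]
    if mandatory_only:
        rows = [d for d in rows if d.mandatory]
    return rows


def registry_to_json(indent: int = 2) -> str:
    """Machine-readable export of the full taxonomy."""
    payload = {
        "motor_primitives": {p.value: p.definition for p in MotorPrimitive},
        "motor_skills": {
            s.value: [[p.value, w] for p, w in s.primitive_flow]
            for s in MotorSkill
        },
        "motor_abilities": {
            a.value: {
                "description": a.description,
                "domains": sorted(d.value for d in a.domains),
            }
            for a in MotorAbility
        },
        "performance_indicators": [
            {
                "name": d.name,
                "ability": d.ability.value,
                "domain": d.domain.value,
                "status": d.status.value,
                "description": d.description,
            }
            for d in PI_REGISTRY
        ],
        "target_muscles": list(TARGET_MUSCLES),
        "stability_threshold_s": STABILITY_THRESHOLD_S,
    }
    return json.dumps(payload, indent=indent, sort_keys=False)
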