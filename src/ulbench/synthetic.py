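"""Protocol-conformant synthetic trial generator.

Generates kinematic + EMG recordings of the six protocol skills with
ground-truth labels, so every pipeline stage can be exercised without
recorded patient data.  Movements are minimum-jerk reaches through the
A-E target layout at a self-selected-speed default of 1.0 s per
transport; impairment is modelled phenomenologically: sequential
submovements (smoothness loss and movement stops), reaction delays,
trunk lean, path curvature, slowed movements, EMG co-contraction and
noise.  EMG is an amplitude-modulated band-limited Gaussian carrier —
sufficient to exercise every EMG indicator, not a motor-unit model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.optimize import brentq

from .kinematics import (
    ArmGeometry,
    JointAngles,
    Trajectory3D,
    inverse_kinematics,
    speed_profile,
)
from .profiles import minimum_jerk_path
from .protocol import DisturbanceSpec, TargetLayout
from .emg_metrics import EMGRecording
from .taxonomy import MotorPrimitive, MotorSkill, TARGET_MUSCLES

__all__ = [
    "ImpairmentParams",
    "GroundTruthSegment",
    "GroundTruth",
    "Trial",
    "min_jerk",
    "synth_trial",
    "synth_emg",
    "apply_disturbance",
]

DEFAULT_KIN_RATE_HZ = 100.0
DEFAULT_EMG_RATE_HZ = 1000.0
#: Idle/stabilize dwell, strictly above the 1 s stability rule.
IDLE_DWELL_S = 1.5
#: Pause between consecutive movement primitives that share no idle step
#: (grasp/release pauses, inter-reach rests); below the stability rule.
SHORT_PAUSE_S = 0.5
#: Dwell between sequential submovements of one impaired movement unit.
SUBMOVEMENT_GAP_S = 0.08
#: Nominal transport duration at self-selected speed.
MOVEMENT_DURATION_S = 1.0
#: Object rest location offset from A for the drinking task (the object
#: sits "close to" the rest position).
OBJECT_OFFSET_M = np.array([0.10, 0.0, 0.0])

# normalized time of the 10%-of-peak upward crossing of a minimum-jerk bump
TAU_ONSET_10PCT = brentq(lambda x: 30 * x**2 * (1 - x) ** 2 - 0.1875, 0.0, 0.5)


@dataclass(frozen=True)
class ImpairmentParams:
    """Tunable impairment model for the generator."""

    n_submovements: int = 1
    reaction_delay_s: float = 0.0
    trunk_lean_deg: float = 0.0
    curvature_gain: float = 0.0
    speed_scale: float = 1.0          # <1 slows every movement down
    cocontraction_gain: float = 0.0   # antagonist burst as fraction of agonist
    emg_noise_sd: float = 0.01        # mV, baseline carrier noise
    emg_onset_latency_s: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_submovements < 1:
            raise ValueError("n_submovements must be >= 1")
        if self.speed_scale <= 0:
            raise ValueError("speed_scale must be positive")


@dataclass
class GroundTruthSegment:
    primitive: MotorPrimitive
    waypoint_from: str
    waypoint_to: str
    start_s: float
    end_s: float
    go_cue_s: float | None = None      # moving primitives only
    onset_10pct_s: float | None = None  # 10%-of-peak rule applied analytically


@dataclass
class GroundTruth:
    segments: list[GroundTruthSegment] = field(default_factory=list)
    muscle_onset_latency_s: dict[str, float] = field(default_factory=dict)
    params: ImpairmentParams | None = None

    @property
    def moving_segments(self) -> list[GroundTruthSegment]:
        return [s for s in self.segments if s.primitive.moves]


@dataclass
class Trial:
    """One synthetic motor-skill execution."""

    skill: MotorSkill
    layout: TargetLayout
    geom: ArmGeometry
    rate_hz: float
    ee: Trajectory3D
    q: JointAngles
    trunk_sagittal_deg: np.ndarray
    trunk_frontal_deg: np.ndarray
    trunk_position: np.ndarray
    go_cues_s: tuple[float, ...]
    ground_truth: GroundTruth
    meta: dict = field(default_factory=dict)

    @property
    def t(self) -> np.ndarray:
        return self.ee.t

    def speed(self, cutoff_hz: float | None = 6.0) -> np.ndarray:
        return speed_profile(self.ee, cutoff_hz=cutoff_hz)


def min_jerk(start, end, duration_s: float,
             rate_hz: float = DEFAULT_KIN_RATE_HZ) -> Trajectory3D:
    """Minimum-jerk point-to-point trajectory segment."""
    return Trajectory3D(minimum_jerk_path(start, end, duration_s, rate_hz),
                        rate_hz)


def _perpendicular(direction: np.ndarray) -> np.ndarray:
    up = np.array([0.0, 1.0, 0.0])
    perp = np.cross(direction, up)
    n = np.linalg.norm(perp)
    if n < 1e-9:
        perp, n = np.array([1.0, 0.0, 0.0]), 1.0
    return perp / n


def _movement_samples(start: np.ndarray, end: np.ndarray, duration_s: float,
                      rate_hz: float, impair: ImpairmentParams
                      ) -> tuple[np.ndarray, float]:
    """Sampled positions of one (possibly fragmented) movement unit.

    With ``n_submovements`` > 1 the chord is covered by n sequential
    minimum-jerk submovements separated by brief rests, producing n
    velocity peaks and n-1 movement stops.  Returns (positions, duration
    of the first submovement) — the latter anchors the analytic
    10%-of-peak onset time.
    """
    n_sub = impair.n_submovements
    total = duration_s / impair.speed_scale
    sub_d = total / n_sub
    chord = end - start
    length = float(np.linalg.norm(chord))
    frames: list[np.ndarray] = []
    pos = start
    for i in range(n_sub):
        nxt = start + chord * (i + 1) / n_sub
        seg = minimum_jerk_path(pos, nxt, sub_d, rate_hz)[1:]
        frames.append(seg)
        if i < n_sub - 1:
            n_gap = int(round(SUBMOVEMENT_GAP_S * rate_hz))
            frames.append(np.repeat(nxt[None, :], n_gap, axis=0))
        pos = nxt
    path = np.concatenate(frames, axis=0)
    if impair.curvature_gain > 0 and length > 1e-9:
        u = chord / length
        perp = _perpendicular(u)
        # detour shaped by chordwise progress, not time: lateral velocity
        # is zero whenever chord progress pauses (movement start/end,
        # submovement gaps), so onsets and stops stay chord-governed
        prog = ((path - start[None, :]) @ u) / length
        path = path + (impair.curvature_gain * length
                       * np.sin(np.pi * np.clip(prog, 0, 1)))[:, None] \
            * perp[None, :]
    return path, sub_d


def synth_trial(
    skill: MotorSkill | str,
    layout: TargetLayout,
    geom: ArmGeometry,
    impair: ImpairmentParams | None = None,
    rate_hz: float = DEFAULT_KIN_RATE_HZ,
    transport_duration_scale: float = 1.0,
) -> tuple[Trial, GroundTruth]:
    """Generate one protocol-conformant trial with ground truth.

    ``transport_duration_scale`` slows object-transport primitives only
    (the payload-disturbance model uses 1.1).
    """
    skill = MotorSkill(skill)
    impair = impair or ImpairmentParams()
    truth = GroundTruth(params=impair)
    dt = 1.0 / rate_hz

    def waypoint_pos(label: str, primitive: MotorPrimitive) -> np.ndarray:
        if (skill is MotorSkill.HAND_TO_MOUTH_WITH_OBJECT and label == "A"
                and primitive in (MotorPrimitive.REACH_FOR_GRASP,
                                  MotorPrimitive.TRANSPORT)):
            try:
                return layout.point("A_object")
            except KeyError:
                return layout.point("A") + OBJECT_OFFSET_M
        return layout.point(label)

    frames: list[np.ndarray] = [layout.point("A")[None, :]]
    n_samples = 1
    go_cues: list[float] = []
    pos = layout.point("A")
    prev_wp = "A"
    prev_moving = False
    for primitive, waypoint in skill.primitive_flow:
        t_now = (n_samples - 1) * dt
        if not primitive.moves:
            n_dwell = int(round(IDLE_DWELL_S * rate_hz))
            frames.append(np.repeat(pos[None, :], n_dwell, axis=0))
            n_samples += n_dwell
            truth.segments.append(GroundTruthSegment(
                primitive, waypoint, waypoint, t_now, t_now + n_dwell * dt))
            prev_moving = False
            continue
        if prev_moving:
            n_pause = int(round(SHORT_PAUSE_S * rate_hz))
            frames.append(np.repeat(pos[None, :], n_pause, axis=0))
            n_samples += n_pause
            t_now += n_pause * dt
        go_cue = t_now
        go_cues.append(go_cue)
        if impair.reaction_delay_s > 0:
            n_delay = int(round(impair.reaction_delay_s * rate_hz))
            frames.append(np.repeat(pos[None, :], n_delay, axis=0))
            n_samples += n_delay
            t_now += n_delay * dt
        target = waypoint_pos(waypoint, primitive)
        duration = MOVEMENT_DURATION_S * (
            transport_duration_scale
            if primitive is MotorPrimitive.TRANSPORT else 1.0)
        path, first_sub_d = _movement_samples(
            pos, target, duration, rate_hz, impair)
        start_s = t_now
        frames.append(path)
        n_samples += path.shape[0]
        end_s = (n_samples - 1) * dt
        truth.segments.append(GroundTruthSegment(
            primitive, prev_wp, waypoint, start_s, end_s,
            go_cue_s=go_cue,
            onset_10pct_s=start_s + TAU_ONSET_10PCT * first_sub_d))
        pos = target
        prev_wp = waypoint
        prev_moving = True
    # trailing rest so the last offset is inside the record
    n_tail = int(round(0.5 * rate_hz))
    frames.append(np.repeat(pos[None, :], n_tail, axis=0))
    ee_xyz = np.concatenate(frames, axis=0)
    n = ee_xyz.shape[0]
    t = np.arange(n) * dt

    # trunk lean ramps up and back within each movement
    lean = np.zeros(n)
    if impair.trunk_lean_deg != 0.0:
        for seg in truth.moving_segments:
            m = (t >= seg.start_s) & (t <= seg.end_s)
            prog = (t[m] - seg.start_s) / max(seg.end_s - seg.start_s, dt)
            lean[m] = impair.trunk_lean_deg * np.sin(np.pi * prog)
    lean_rad = np.deg2rad(lean)
    h_s = layout.shoulder_height_above_desk_m
    shoulder = np.stack([h_s * np.sin(lean_rad),
                         h_s * np.cos(lean_rad),
                         np.zeros(n)], axis=1)
    trunk_marker = shoulder.copy()

    # inverse-kinematics-consistent joint stream
    q = np.zeros((n, 8))
    for i in range(n):
        q[i] = inverse_kinematics(ee_xyz[i] - shoulder[i], geom,
                                  q0=lean_rad[i])

    trial = Trial(
        skill=skill,
        layout=layout,
        geom=geom,
        rate_hz=rate_hz,
        ee=Trajectory3D(ee_xyz, rate_hz),
        q=JointAngles(q, rate_hz),
        trunk_sagittal_deg=lean,
        trunk_frontal_deg=np.zeros(n),
        trunk_position=trunk_marker,
        go_cues_s=tuple(go_cues),
        ground_truth=truth,
        meta={
            "recipe": {
                "skill": skill.value,
                "mode": layout.mode,
                "impair": impair,
                "rate_hz": rate_hz,
                "transport_duration_scale": transport_duration_scale,
            },
            "disturbance": None,
        },
    )
    return trial, truth


# --------------------------------------------------------------------------
# EMG synthesis
# --------------------------------------------------------------------------

# relative burst amplitude per muscle and movement primitive
_MUSCLE_GAINS: dict[str, dict[MotorPrimitive, float]] = {
    "anterior_deltoid": {
        MotorPrimitive.POINT_TO_POINT_REACH: 1.0,
        MotorPrimitive.REACH_FOR_GRASP: 1.0,
        MotorPrimitive.TRANSPORT: 0.9,
        MotorPrimitive.REPOSITION: 0.5,
    },
    "medial_deltoid": {
        MotorPrimitive.POINT_TO_POINT_REACH: 0.6,
        MotorPrimitive.REACH_FOR_GRASP: 0.6,
        MotorPrimitive.TRANSPORT: 0.5,
        MotorPrimitive.REPOSITION: 0.3,
    },
    "posterior_deltoid": {
        MotorPrimitive.REPOSITION: 0.7,
        MotorPrimitive.TRANSPORT: 0.2,
    },
    "trapezius_descendens": {
        MotorPrimitive.POINT_TO_POINT_REACH: 0.4,
        MotorPrimitive.REACH_FOR_GRASP: 0.4,
        MotorPrimitive.TRANSPORT: 0.5,
    },
    "pectoralis_major": {
        MotorPrimitive.POINT_TO_POINT_REACH: 0.5,
        MotorPrimitive.TRANSPORT: 0.4,
    },
    "biceps_brachii": {
        MotorPrimitive.POINT_TO_POINT_REACH: 0.8,
        MotorPrimitive.REACH_FOR_GRASP: 0.8,
        MotorPrimitive.TRANSPORT: 1.0,
    },
    "brachioradialis": {
        MotorPrimitive.TRANSPORT: 0.6,
        MotorPrimitive.REACH_FOR_GRASP: 0.4,
    },
    "pronator_teres": {
        MotorPrimitive.REACH_FOR_GRASP: 0.3,
        MotorPrimitive.TRANSPORT: 0.3,
    },
}
#: Muscles whose activity scales with arm weight (payload disturbance).
ANTIGRAVITY_MUSCLES = ("anterior_deltoid", "medial_deltoid",
                       "trapezius_descendens", "biceps_brachii")
BURST_AMPLITUDE_MV = 0.5
BURST_RAMP_S = 0.05


def _burst_window(t: np.ndarray, start: float, end: float,
                  ramp_s: float = BURST_RAMP_S) -> np.ndarray:
    """Trapezoidal burst: sharp cosine ramps at both ends."""
    w = np.zeros_like(t)
    core = (t >= start) & (t <= end)
    w[core] = 1.0
    rise = (t >= start) & (t < start + ramp_s)
    w[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - start) / ramp_s))
    fall = (t > end - ramp_s) & (t <= end)
    w[fall] = 0.5 * (1 - np.cos(np.pi * (end - t[fall]) / ramp_s))
    return w


def synth_emg(
    trial: Trial,
    muscles: tuple[str, ...] = TARGET_MUSCLES,
    impair: ImpairmentParams | None = None,
    rate_hz: float = DEFAULT_EMG_RATE_HZ,
) -> EMGRecording:
    """Synthesize a multi-channel surface-EMG recording for a trial.

    Each muscle's linear envelope is a sum of bursts aligned to the
    ground-truth movement segments (amplitudes from a fixed muscle-role
    map; the antagonist triceps mirrors the biceps envelope scaled by the
    co-contraction gain), modulating a 20-450 Hz Gaussian carrier, plus
    baseline carrier noise.  Deterministic under the impairment seed.
    """
    impair = impair or (trial.ground_truth.params or ImpairmentParams())
    unknown = [m for m in muscles if m not in TARGET_MUSCLES]
    if unknown:
        raise ValueError(
            f"unknown muscle name(s) {unknown}; valid: {list(TARGET_MUSCLES)}")
    rng = np.random.default_rng(impair.seed + 7919)
    duration = float(trial.t[-1])
    n = int(round(duration * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    sos = sps.butter(4, [20.0, min(450.0, 0.45 * rate_hz)], btype="band",
                     fs=rate_hz, output="sos")
    payload_kg = 0.0
    dist = trial.meta.get("disturbance")
    if dist is not None and dist.get("kind") == "payload":
        payload_kg = float(dist.get("payload_mass_kg") or 0.0)

    envelopes = {m: np.zeros(n) for m in muscles}
    latencies: dict[str, float] = {}
    for seg in trial.ground_truth.moving_segments:
        if impair.emg_onset_latency_s is not None and seg.go_cue_s is not None:
            start = seg.go_cue_s + impair.emg_onset_latency_s
        else:
            # muscle activity leads the mechanical movement slightly
            start = max(seg.go_cue_s or seg.start_s, seg.start_s - 0.05)
        end = seg.end_s
        w = _burst_window(t, start, end)
        for m in muscles:
            gain = _MUSCLE_GAINS.get(m, {}).get(seg.primitive, 0.0)
            if m in ANTIGRAVITY_MUSCLES and payload_kg > 0:
                gain *= 1.0 + 0.5 * payload_kg
            if gain > 0:
                envelopes[m] = np.maximum(envelopes[m],
                                          gain * BURST_AMPLITUDE_MV * w)
            if seg.go_cue_s is not None and gain > 0 and m not in latencies:
                latencies[m] = start - seg.go_cue_s
    if "triceps_brachii" in envelopes and "biceps_brachii" in envelopes:
        envelopes["triceps_brachii"] = (
            impair.cocontraction_gain * envelopes["biceps_brachii"])
        if impair.cocontraction_gain > 0 and "biceps_brachii" in latencies:
            latencies["triceps_brachii"] = latencies["biceps_brachii"]

    data = np.zeros((len(muscles), n))
    for i, m in enumerate(muscles):
        carrier = sps.sosfiltfilt(sos, rng.standard_normal(n))
        carrier /= max(np.std(carrier), 1e-12)
        noise = sps.sosfiltfilt(sos, rng.standard_normal(n))
        noise /= max(np.std(noise), 1e-12)
        data[i] = envelopes[m] * carrier + impair.emg_noise_sd * noise
    trial.ground_truth.muscle_onset_latency_s = latencies
    return EMGRecording(
        data, rate_hz, tuple(muscles),
        go_cues_s=trial.go_cues_s,
        meta={"synthetic": True, "seed": impair.seed,
              "payload_kg": payload_kg},
    )


# --------------------------------------------------------------------------
# Disturbances
# --------------------------------------------------------------------------

def apply_disturbance(trial: Trial, spec: DisturbanceSpec) -> Trial:
    """Apply a validated disturbance to a trial.

    * ``none`` — identity.
    * ``payload`` — documented toy model: the trial is re-synthesized from
      its recipe with transport durations x1.1, and anti-gravity muscle
      EMG amplitudes are scaled at EMG-synthesis time.
    * ``motor_perturbation`` — additive waveform on the end-effector path
      (sinusoid of the given magnitude/frequency along the given axis);
      joint angles are re-solved so the q stream stays consistent.
    * ``cognitive`` / ``other`` — recorded verbatim in metadata.
    """
    spec = DisturbanceSpec.model_validate(spec.model_dump()
                                          if hasattr(spec, "model_dump")
                                          else spec)
    if spec.kind == "none":
        return trial
    meta_dist = spec.model_dump()
    if spec.kind == "payload":
        recipe = trial.meta["recipe"]
        slowed, _ = synth_trial(recipe["skill"], trial.layout, trial.geom,
                                recipe["impair"], recipe["rate_hz"],
                                transport_duration_scale=1.1)
        slowed.meta["disturbance"] = meta_dist
        return slowed
    if spec.kind == "motor_perturbation":
        axis = {"x": 0, "y": 1, "z": 2}.get((spec.direction or "z").lower(), 2)
        t = trial.t
        wave = spec.magnitude * np.sin(2 * np.pi * spec.frequency_hz * t)
        xyz = trial.ee.xyz.copy()
        xyz[:, axis] += wave
        q = np.zeros_like(trial.q.q)
        lean_rad = np.deg2rad(trial.trunk_sagittal_deg)
        h_s = trial.layout.shoulder_height_above_desk_m
        shoulder = np.stack([h_s * np.sin(lean_rad), h_s * np.cos(lean_rad),
                             np.zeros(len(t))], axis=1)
        # the hand cannot be pushed beyond full extension: project any
        # perturbed sample back onto the reach sphere
        rel = xyz - shoulder
        dist = np.linalg.norm(rel, axis=1)
        arm = trial.geom.arm_length_m
        over = dist > arm
        xyz[over] = shoulder[over] + rel[over] * (arm / dist[over])[:, None]
        for i in range(len(t)):
            q[i] = inverse_kinematics(xyz[i] - shoulder[i], trial.geom,
                                      q0=lean_rad[i])
        new = replace(
            trial,
            ee=Trajectory3D(xyz, trial.rate_hz),
            q=JointAngles(q, trial.rate_hz),
            meta={**trial.meta, "disturbance": meta_dist},
        )
        return new
    new = replace(trial, meta={**trial.meta, "disturbance": meta_dist})
    return new
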