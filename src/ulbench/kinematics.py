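"""8-DOF upper-limb kinematic model and signal conditioning.

The limb is modelled as a rigid chain following the ISB recommendation:
a single thorax flexion/extension DOF (q0), a glenohumeral ball-and-socket
joint expressed as plane of elevation (q1), elevation (q2) and axial
rotation (q3) with the Y-X'-Y'' Euler sequence, elbow flexion/extension
(q4), forearm pronation/supination (q5), and wrist flexion/extension (q6)
and ulnar/radial deviation (q7).

Ground frame (ISB): X anterior, Y up, Z lateral toward the evaluated side.
Neutral pose: arm hanging along -Y.  Angles are radians internally and
degrees at every I/O boundary.  Left-arm recordings are mirrored about the
sagittal plane at load time so all downstream metrics are side-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.spatial.transform import Rotation

__all__ = [
    "ArmGeometry",
    "JointAngles",
    "Trajectory3D",
    "ShoulderAnglesRobotics",
    "forward_kinematics",
    "forward_kinematics_trajectory",
    "inverse_kinematics",
    "isb_from_robotics",
    "robotics_from_isb",
    "lowpass_filter",
    "differentiate",
    "speed_profile",
    "trunk_angles_from_direction",
]

DEFAULT_CUTOFF_HZ = 6.0
DEFAULT_FILTER_ORDER = 4


@dataclass(frozen=True)
class ArmGeometry:
    """Subject arm segment lengths (m) and laterality."""

    upper_arm_length_m: float
    forearm_length_m: float
    dominant_arm: str = "right"
    evaluated_arm: str = "right"

    def __post_init__(self):
        if self.upper_arm_length_m <= 0 or self.forearm_length_m <= 0:
            raise ValueError("segment lengths must be strictly positive")
        for side in (self.dominant_arm, self.evaluated_arm):
            if side not in ("left", "right"):
                raise ValueError(f"arm side must be 'left' or 'right', got {side!r}")

    @property
    def arm_length_m(self) -> float:
        return self.upper_arm_length_m + self.forearm_length_m


@dataclass
class JointAngles:
    """Sampled q0..q7 trajectory, radians internally.

    ``q`` has shape (n_samples, 8).  Use :meth:`from_degrees` /
    :meth:`to_degrees` at I/O boundaries.
    """

    q: np.ndarray
    rate_hz: float

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[1] != 8:
            raise ValueError("q must have shape (n_samples, 8)")
        if not np.all(np.isfinite(self.q)):
            raise ValueError("joint angles must be finite")
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @classmethod
    def from_degrees(cls, q_deg: np.ndarray, rate_hz: float) -> "JointAngles":
        return cls(np.deg2rad(np.asarray(q_deg, dtype=float)), rate_hz)

    def to_degrees(self) -> np.ndarray:
        return np.rad2deg(self.q)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.q.shape[0]) / self.rate_hz

    def __len__(self) -> int:
        return self.q.shape[0]


@dataclass
class Trajectory3D:
    """Per-sample 3-D positions (m) of one landmark in the ground frame."""

    xyz: np.ndarray
    rate_hz: float
    label: str = "end_effector"

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n_samples, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("positions must be finite")
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.xyz.shape[0]) / self.rate_hz

    def __len__(self) -> int:
        return self.xyz.shape[0]


@dataclass(frozen=True)
class ShoulderAnglesRobotics:
    """Shoulder pose in the robotics convention (degrees)."""

    flexion_extension_deg: float
    horizontal_adduction_deg: float
    humeral_rotation_deg: float
    singular: bool = False


def _rot_y(a):  # noqa: D103
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_x(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_z(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def shoulder_rotation_isb(q1: float, q2: float, q3: float) -> np.ndarray:
    """Humeral rotation matrix from ISB angles (Y-X'-Y'' sequence).

    Plane of elevation q1 about Y, elevation q2 (positive = arm raised,
    implemented as -q2 about the rotated X), axial rotation q3 about the
    humeral long axis.  Plane of elevation 0 is abduction in the frontal
    plane; 90 deg is forward flexion.
    """
    return _rot_y(q1) @ _rot_x(-q2) @ _rot_y(q3)


def forward_kinematics(
    q_sample: np.ndarray, geom: ArmGeometry
) -> dict[str, np.ndarray]:
    """Positions (m) of elbow, wrist/end-effector for one q0..q7 sample.

    Positions are relative to the glenohumeral joint centre with the trunk
    flexion q0 applied to the whole chain (trunk rotates about the lateral
    Z axis).  The end-effector is the wrist point, so the straight arm
    spans upper-arm + forearm length exactly.
    """
    q = np.asarray(q_sample, dtype=float)
    if q.shape != (8,):
        raise ValueError("q_sample must be a length-8 vector")
    if not np.all(np.isfinite(q)):
        raise ValueError("q must be finite")
    r_trunk = _rot_z(q[0])
    r_sh = r_trunk @ shoulder_rotation_isb(q[1], q[2], q[3])
    elbow = r_sh @ np.array([0.0, -geom.upper_arm_length_m, 0.0])
    # elbow flexion about local +Z, then pronation about the forearm long axis
    r_fa = r_sh @ _rot_z(q[4]) @ _rot_y(-q[5])
    wrist = elbow + r_fa @ np.array([0.0, -geom.forearm_length_m, 0.0])
    # wrist DOFs orient the hand frame; they do not displace the wrist point
    r_hand = r_fa @ _rot_z(q[6]) @ _rot_x(q[7])
    return {"elbow": elbow, "wrist": wrist, "end_effector": wrist,
            "hand_rotation": r_hand}


def forward_kinematics_trajectory(
    angles: JointAngles, geom: ArmGeometry
) -> Trajectory3D:
    """End-effector trajectory (relative to the shoulder) for a q stream."""
    pts = np.empty((len(angles), 3))
    for i, qs in enumerate(angles.q):
        pts[i] = forward_kinematics(qs, geom)["end_effector"]
    return Trajectory3D(pts, angles.rate_hz)


def inverse_kinematics(
    p_wrist: np.ndarray,
    geom: ArmGeometry,
    q0: float = 0.0,
) -> np.ndarray:
    """One q0..q7 solution placing the wrist at ``p_wrist`` (shoulder frame).

    Redundancy resolution: the elbow lies in the plane spanned by the
    shoulder-wrist line and the vertical (swivel angle zero), wrist DOFs
    and pronation are zero.  Raises if the point is out of reach.
    """
    p = _rot_z(-q0) @ np.asarray(p_wrist, dtype=float)  # undo trunk rotation
    l1, l2 = geom.upper_arm_length_m, geom.forearm_length_m
    d = float(np.linalg.norm(p))
    # allow up to 1 mm overshoot at full extension (clamped), e.g. from
    # trunk-lean geometry at fully extended targets
    if d > l1 + l2 + 1e-3 or d < abs(l1 - l2) - 1e-3:
        raise ValueError(f"target at {d:.3f} m unreachable for arm {l1 + l2:.3f} m")
    if d > l1 + l2:
        p *= (l1 + l2) / d
        d = l1 + l2
    cos_q4 = np.clip((d * d - l1 * l1 - l2 * l2) / (2 * l1 * l2), -1.0, 1.0)
    q4 = float(np.arccos(cos_q4))  # 0 = straight arm
    # humerus direction: rotate the shoulder->wrist direction within the
    # vertical plane containing it, by the shoulder triangle angle
    u_sw = p / d
    cos_phi = np.clip((l1 * l1 + d * d - l2 * l2) / (2 * l1 * d), -1.0, 1.0)
    phi = float(np.arccos(cos_phi))
    vertical = np.array([0.0, 1.0, 0.0])
    axis = np.cross(u_sw, vertical)
    nrm = np.linalg.norm(axis)
    if nrm < 1e-12:  # wrist straight above/below the shoulder
        axis = np.array([0.0, 0.0, 1.0])
    else:
        axis = axis / nrm
    u_hum = Rotation.from_rotvec(axis * phi).apply(u_sw)
    # decompose humerus direction into plane of elevation / elevation
    uy = np.clip(-u_hum[1], -1.0, 1.0)
    q2 = float(np.arccos(uy))
    if abs(np.sin(q2)) < 1e-9:
        q1 = 0.0
    else:
        q1 = float(np.arctan2(u_hum[0], u_hum[2]))
    # axial rotation q3 closes the chain onto the wrist point
    elbow = u_hum * l1
    w = (p - elbow) / l2
    a_mat = _rot_y(q1) @ _rot_x(-q2)
    g = a_mat.T @ w
    s4 = np.sin(q4)
    if abs(s4) < 1e-9:
        q3 = 0.0
    else:
        q3 = float(np.arctan2(-g[2] / s4, g[0] / s4))
    return np.array([q0, q1, q2, q3, q4, 0.0, 0.0, 0.0])


# --------------------------------------------------------------------------
# Shoulder convention conversion
# --------------------------------------------------------------------------

def _robotics_rotation(flexion: float, h_add: float, hum_rot: float) -> np.ndarray:
    """Rotation matrix from robotics shoulder angles (Z-X'-Y'' sequence).

    Flexion/extension raises the arm forward about the lateral Z axis,
    horizontal adduction/abduction rotates about the (rotated) X axis,
    humeral rotation spins about the humeral long axis.
    """
    return _rot_z(flexion) @ _rot_x(-h_add) @ _rot_y(hum_rot)


def isb_from_robotics(
    a: ShoulderAnglesRobotics,
) -> tuple[float, float, float, bool]:
    """Convert robotics shoulder angles to ISB (q1, q2, q3) in degrees.

    Both conventions parameterize the same humeral rotation matrix; the
    conversion composes the robotics matrix and decomposes it with the ISB
    Y-X'-Y'' sequence.  Near the elevation singularity (|q2| ~ 0) the plane
    of elevation is undefined: q1 is set to 0 and the result flagged.
    """
    r = _robotics_rotation(
        np.deg2rad(a.flexion_extension_deg),
        np.deg2rad(a.horizontal_adduction_deg),
        np.deg2rad(a.humeral_rotation_deg),
    )
    return _decompose_isb(r)


def _decompose_isb(r: np.ndarray) -> tuple[float, float, float, bool]:
    # humerus direction = r @ (0,-1,0); elevation from its Y component
    u = r @ np.array([0.0, -1.0, 0.0])
    q2 = float(np.arccos(np.clip(-u[1], -1.0, 1.0)))
    singular = abs(np.sin(q2)) < 1e-6
    if singular:
        q1 = 0.0
    else:
        q1 = float(np.arctan2(u[0], u[2]))
    # q3 from the residual rotation about the humeral axis
    r_residual = (_rot_y(q1) @ _rot_x(-q2)).T @ r
    q3 = float(np.arctan2(r_residual[0, 2], r_residual[0, 0]))
    return (np.rad2deg(q1), np.rad2deg(q2), np.rad2deg(q3), singular)


def robotics_from_isb(
    q1_deg: float, q2_deg: float, q3_deg: float
) -> ShoulderAnglesRobotics:
    """Convert ISB shoulder angles to the robotics convention (degrees)."""
    r = shoulder_rotation_isb(
        np.deg2rad(q1_deg), np.deg2rad(q2_deg), np.deg2rad(q3_deg))
    u = r @ np.array([0.0, -1.0, 0.0])
    # flexion about Z moves the arm in the X-Y plane; horizontal adduction
    # is the remaining rotation about the flexed X axis
    flexion = float(np.arctan2(u[0], -u[1])) if (abs(u[0]) > 1e-12 or abs(u[1]) > 1e-12) else 0.0
    # after undoing flexion, arm direction lies in the Y-Z plane
    u2 = _rot_z(-flexion) @ u
    h_add = float(np.arctan2(u2[2], -u2[1]))
    singular = bool(np.linalg.norm([u[0], u[2]]) < 1e-6 and abs(h_add) < 1e-6
                    and abs(flexion) < 1e-6)
    r_residual = (_rot_z(flexion) @ _rot_x(-h_add)).T @ r
    hum = float(np.arctan2(r_residual[0, 2], r_residual[0, 0]))
    return ShoulderAnglesRobotics(
        np.rad2deg(flexion), np.rad2deg(h_add), np.rad2deg(hum),
        singular=singular)


# --------------------------------------------------------------------------
# Filtering and differentiation
# --------------------------------------------------------------------------

def lowpass_filter(
    x: np.ndarray,
    rate_hz: float,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
    axis: int = 0,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward)."""
    sos = butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    return sosfiltfilt(sos, x, axis=axis)


def differentiate(
    x: np.ndarray,
    rate_hz: float,
    order: int = 1,
    *,
    cutoff_hz: float | None = DEFAULT_CUTOFF_HZ,
    filter_order: int = DEFAULT_FILTER_ORDER,
    t: np.ndarray | None = None,
) -> np.ndarray:
    """Numerical derivative of a uniformly sampled series.

    A zero-phase Butterworth low-pass (default 4th order, 6 Hz) is applied
    first unless ``cutoff_hz`` is None, then central differences are taken
    ``order`` times (one-sided stencils at the endpoints, length preserved).

    Parameters
    ----------
    x : array, shape (n,) or (n, k)
        Samples along axis 0.
    order : int
        1 = velocity, 2 = acceleration, 3 = jerk.
    t : optional
        Explicit timestamps; rejected if non-uniform (resample first).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 9:
        raise ValueError("need at least 9 samples to differentiate")
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    if t is not None:
        dt = np.diff(np.asarray(t, dtype=float))
        if dt.size and (np.max(dt) - np.min(dt)) > 1e-6 * np.mean(dt) + 1e-12:
            raise ValueError(
                "non-uniform timestamps: resample to a uniform grid before "
                "differentiating")
    dt = 1.0 / rate_hz
    y = x if cutoff_hz is None else lowpass_filter(x, rate_hz, cutoff_hz, filter_order)
    for _ in range(order):
        y = np.gradient(y, dt, axis=0)
    return y


def third_derivative(x: np.ndarray, rate_hz: float) -> np.ndarray:
    """Direct O(h^2) third derivative (jerk) of a sampled series.

    Uses the five-point central stencil in the interior and one-sided
    second-order stencils at the edges; far more accurate for jerk than
    differentiating three times, which compounds stencil smoothing.
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if x.shape[0] < 5:
        raise ValueError("third derivative needs at least 5 samples")
    h3 = (1.0 / rate_hz) ** 3
    out = np.empty_like(x)
    out[2:-2] = (-x[:-4] + 2 * x[1:-3] - 2 * x[3:-1] + x[4:]) / (2 * h3)
    fwd = (-2.5 * x[0:2] + 9 * x[1:3] - 12 * x[2:4] + 7 * x[3:5]
           - 1.5 * x[4:6]) / h3
    bwd = (2.5 * x[-2:] - 9 * x[-3:-1] + 12 * x[-4:-2] - 7 * x[-5:-3]
           + 1.5 * x[-6:-4]) / h3
    out[:2] = fwd
    out[-2:] = bwd
    return out[:, 0] if squeeze else out


def speed_profile(
    traj: Trajectory3D,
    *,
    cutoff_hz: float | None = DEFAULT_CUTOFF_HZ,
) -> np.ndarray:
    """Scalar end-effector speed (m/s) from a 3-D trajectory."""
    v = differentiate(traj.xyz, traj.rate_hz, order=1, cutoff_hz=cutoff_hz)
    return np.linalg.norm(v, axis=1)


# --------------------------------------------------------------------------
# Trunk angles
# --------------------------------------------------------------------------

def trunk_angles_from_q0(q0_rad: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sagittal/frontal trunk lean (degrees) from the q0 flexion trace.

    The single-DOF thorax model only measures sagittal lean; the frontal
    series is zero.  Angles are relative to the first sample.
    """
    q0 = np.asarray(q0_rad, dtype=float)
    if q0.size == 0:
        raise ValueError("q0 trace required (trunk not recorded)")
    sag = np.degrees(q0 - q0[0])
    return sag, np.zeros_like(sag)


def trunk_angles_from_direction(directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sagittal and frontal trunk lean (degrees) from trunk axis vectors.

    ``directions`` is an (n, 3) stream of pelvis-to-sternum unit vectors in
    the ground frame.  Angles are measured relative to the first sample's
    orientation: sagittal = forward(+X) lean, frontal = lateral(+Z) lean.
    """
    d = np.asarray(directions, dtype=float)
    if d.ndim != 2 or d.shape[1] != 3:
        raise ValueError("trunk directions must have shape (n, 3)")
    if d.shape[0] == 0:
        raise ValueError("trunk direction stream required (trunk not recorded)")
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise ValueError("zero-length trunk direction vector")
    d = d / norms
    sagittal = np.degrees(np.arctan2(d[:, 0], d[:, 1]))
    frontal = np.degrees(np.arctan2(d[:, 2], d[:, 1]))
    return sagittal - sagittal[0], frontal - frontal[0]
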