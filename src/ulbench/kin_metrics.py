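"""Kinematic performance indicators, grouped by motor ability.

Every function returns a :class:`PIRecord` whose keys match the taxonomy
registry for that ability.  Indicators that cannot be computed on the
given input (zero variance, single repetition, degenerate chord, ...) are
returned marked not-computable with a reason instead of raising, so a
benchmark report can always be assembled.

Conventions: the "ideal" movement is the straight chord from segment
start to target with a minimum-jerk speed profile; onset/offset and all
relative thresholds share the 10%-of-peak constant used by segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import pearsonr

from .kinematics import differentiate, lowpass_filter, third_derivative
from .profiles import minimum_jerk_position, minimum_jerk_speed
from .segmentation import DEFAULT_THRESHOLD_FRACTION
from .taxonomy import MotorAbility, PIStatus, registry_lookup

__all__ = [
    "PIValue",
    "PIRecord",
    "IdealPath",
    "accuracy_pis",
    "efficacy_pis",
    "efficiency_pis",
    "coordination_pis",
    "amplitude_pis",
    "planning_pis",
    "smoothness_pis",
    "speed_pis",
    "variable_error",
    "sparc",
    "normalized_dimensionless_jerk",
]

#: Relative speed threshold shared by velocity-peak counting, MAPR and
#: movement-stop detection.
SPEED_THRESHOLD_FRACTION = DEFAULT_THRESHOLD_FRACTION
#: Minimum separation between counted velocity peaks.
PEAK_MIN_SEPARATION_S = 0.1

# SPARC parameters (reported alongside every value)
SPARC_PAD_FACTOR = 4          # zero-pad to 4x the next power of two
SPARC_CUTOFF_HZ = 20.0
SPARC_AMPLITUDE_THRESHOLD = 0.05


@dataclass
class PIValue:
    value: float | None
    units: str = ""
    status: PIStatus = PIStatus.RECOMMENDED
    computable: bool = True
    reason: str = ""

    def __post_init__(self):
        if self.value is None:
            self.computable = False


@dataclass
class PIRecord:
    """Named performance-indicator values for one motor ability.

    ``extras`` carries non-scalar companions (per-DOF ranges, spectra)
    that accompany a registry indicator without being one.
    """

    ability: MotorAbility
    values: dict[str, PIValue] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> PIValue:
        return self.values[name]

    def add(self, name: str, value, units: str = "", reason: str = ""):
        status = _status(self.ability, name)
        if value is not None and np.isscalar(value):
            value = float(value)
        self.values[name] = PIValue(value, units, status,
                                    computable=value is not None,
                                    reason=reason)

    def as_dict(self) -> dict:
        return {
            name: {
                "value": v.value,
                "units": v.units,
                "status": v.status.value,
                "computable": v.computable,
                **({"reason": v.reason} if v.reason else {}),
            }
            for name, v in self.values.items()
        }


def _status(ability: MotorAbility, name: str) -> PIStatus:
    for d in registry_lookup(ability):
        if d.name == name:
            return d.status
    return PIStatus.RECOMMENDED


@dataclass
class IdealPath:
    """Straight chord with a minimum-jerk speed profile."""

    start: np.ndarray
    target: np.ndarray
    duration_s: float

    def __post_init__(self):
        self.start = np.asarray(self.start, dtype=float)
        self.target = np.asarray(self.target, dtype=float)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.target - self.start))

    def position(self, tau: np.ndarray) -> np.ndarray:
        s = minimum_jerk_position(tau)
        return self.start[None, :] + np.atleast_1d(s)[:, None] * (
            self.target - self.start)[None, :]

    def speed(self, tau: np.ndarray) -> np.ndarray:
        return minimum_jerk_speed(tau, self.length, self.duration_s)


def _point_line_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray
                         ) -> np.ndarray:
    """Perpendicular distance from each point to the infinite line a-b."""
    ab = b - a
    nrm = np.linalg.norm(ab)
    if nrm < 1e-12:
        return np.linalg.norm(points - a[None, :], axis=1)
    u = ab / nrm
    rel = points - a[None, :]
    proj = rel @ u
    return np.linalg.norm(rel - proj[:, None] * u[None, :], axis=1)


def _best_fit_plane_area(path: np.ndarray) -> float:
    """Unsigned area enclosed between the path and its closing chord.

    3-D paths are projected onto their best-fit (least-squares) plane and
    the polygon path + chord is measured with the shoelace formula.
    """
    centred = path - path.mean(axis=0, keepdims=True)
    # plane basis from the two leading right singular vectors
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    xy = centred @ vt[:2].T
    x, y = xy[:, 0], xy[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


# --------------------------------------------------------------------------
# Ability suites
# --------------------------------------------------------------------------

def accuracy_pis(
    t: np.ndarray,
    pos: np.ndarray,
    ideal: IdealPath,
    endpoint_errors: np.ndarray | None = None,
) -> PIRecord:
    """Accuracy indicators for one transport-type segment.

    ``endpoint_errors`` (end-point error of each repetition of the same
    reach) enables the across-repetition variable error; with fewer than
    two repetitions it is reported not-computable.
    """
    pos = np.asarray(pos, dtype=float)
    if pos.shape[0] < 2:
        raise ValueError("accuracy PIs need at least 2 samples")
    rec = PIRecord(MotorAbility.ACCURACY)
    d = _point_line_distance(pos, ideal.start, ideal.target)
    rec.add("trajectory_absolute_error", float(np.mean(d)), "m")
    rec.extras["trajectory_absolute_error_max_m"] = float(np.max(d))
    rec.add("end_point_error",
            float(np.linalg.norm(pos[-1] - ideal.target)), "m")
    rec.add("area_index", _best_fit_plane_area(pos), "m^2")
    if endpoint_errors is not None and len(endpoint_errors) >= 2:
        rec.add("variable_error", float(np.std(endpoint_errors, ddof=1)), "m")
    else:
        rec.add("variable_error", None, "m",
                reason="requires at least two repetitions")
    return rec


def variable_error(endpoint_errors: np.ndarray) -> float:
    """SD (ddof=1) of end-point errors across repetitions."""
    e = np.asarray(endpoint_errors, dtype=float)
    if e.size < 2:
        raise ValueError("variable error requires at least two repetitions")
    return float(np.std(e, ddof=1))


def efficacy_pis(
    n_reached: int,
    n_attempts: int,
    movement_stops: int,
) -> PIRecord:
    """Trial-level efficacy: success rate and total movement stops."""
    rec = PIRecord(MotorAbility.EFFICACY)
    if n_attempts > 0:
        rec.add("success_rate", n_reached / n_attempts, "")
    else:
        rec.add("success_rate", None, "", reason="zero attempts")
    rec.add("number_of_movement_stops", int(movement_stops), "count")
    return rec


def efficiency_pis(
    t: np.ndarray,
    pos: np.ndarray,
    onset_s: float,
    end_s: float,
    trunk_sagittal_deg: np.ndarray | None = None,
    trunk_position: np.ndarray | None = None,
) -> PIRecord:
    """Efficiency indicators over one movement segment.

    Trunk compensation is the ratio of trunk to hand displacement in the
    sagittal (ground X-Y) plane; it needs a trunk marker stream aligned
    with ``t``.
    """
    t = np.asarray(t, dtype=float)
    pos = np.asarray(pos, dtype=float)
    mask = (t >= onset_s) & (t <= end_s)
    p = pos[mask]
    rec = PIRecord(MotorAbility.EFFICIENCY)
    rec.add("movement_time", end_s - onset_s, "s")
    path = float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))
    rec.add("path_traveled", path, "m")
    chord = float(np.linalg.norm(p[-1] - p[0]))
    if chord > 1e-9:
        rec.add("path_length_ratio", path / chord, "")
    else:
        rec.add("path_length_ratio", None, "",
                reason="zero chord: movement starts and ends at the same point")
    if trunk_position is not None:
        tp = np.asarray(trunk_position, dtype=float)[mask]
        trunk_sag = float(np.linalg.norm(tp[-1, :2] - tp[0, :2]))
        hand_sag = float(np.linalg.norm(p[-1, :2] - p[0, :2]))
        if hand_sag > 1e-9:
            rec.add("trunk_compensation", trunk_sag / hand_sag, "")
        else:
            rec.add("trunk_compensation", None, "",
                    reason="zero hand sagittal displacement")
    else:
        rec.add("trunk_compensation", None, "", reason="trunk not recorded")
    return rec


def coordination_pis(
    t: np.ndarray,
    q_deg: np.ndarray,
    rate_hz: float,
    onset_s: float,
    end_s: float,
) -> PIRecord:
    """Intra-limb coordination from the q0..q7 stream over a segment.

    Joint-angle correlation is the Pearson r between shoulder elevation
    (q2) and elbow flexion/extension (q4); peak elbow extension is the
    minimum flexion angle (extension = elbow straightening toward q4 = 0).
    """
    t = np.asarray(t, dtype=float)
    q = np.asarray(q_deg, dtype=float)
    mask = (t >= onset_s) & (t <= end_s)
    q2 = q[mask, 2]
    q4 = q[mask, 4]
    rec = PIRecord(MotorAbility.INTRA_LIMB_COORDINATION)
    if np.std(q2) < 1e-9 or np.std(q4) < 1e-9:
        rec.add("joint_angle_correlation", None, "",
                reason="constant joint trace (zero variance)")
    else:
        rec.add("joint_angle_correlation", float(pearsonr(q2, q4)[0]), "")
    dq4 = differentiate(q[:, 4], rate_hz, order=1)[mask]
    rec.add("elbow_peak_velocity", float(np.max(np.abs(dq4))), "deg/s")
    duration = end_s - onset_s
    i_ext = int(np.argmin(q4))  # peak extension = minimum flexion angle
    rec.add("time_to_peak_elbow_extension",
            float((t[mask][i_ext] - onset_s) / duration), "")
    return rec


def amplitude_pis(
    t: np.ndarray,
    q_deg: np.ndarray | None,
    pos: np.ndarray,
    onset_s: float,
    end_s: float,
    arm_length_m: float,
    trunk_position: np.ndarray | None = None,
) -> PIRecord:
    """Movement-amplitude indicators over a segment."""
    t = np.asarray(t, dtype=float)
    pos = np.asarray(pos, dtype=float)
    mask = (t >= onset_s) & (t <= end_s)
    p = pos[mask]
    rec = PIRecord(MotorAbility.MOVEMENT_AMPLITUDE)
    if q_deg is not None:
        q = np.asarray(q_deg, dtype=float)[mask]
        rom = np.max(q, axis=0) - np.min(q, axis=0)
        rec.add("joint_range_of_motion", float(np.max(rom)), "deg")
        rec.extras["joint_range_of_motion_per_dof_deg"] = rom.tolist()
    else:
        rec.add("joint_range_of_motion", None, "deg",
                reason="joint angles not recorded")
    dist = np.linalg.norm(p - p[0][None, :], axis=1)
    rec.add("maximum_reached_distance", float(np.max(dist)), "m")
    if trunk_position is not None:
        tp = np.asarray(trunk_position, dtype=float)[mask]
        rec.add("trunk_displacement",
                float(np.linalg.norm(tp[-1] - tp[0])), "m")
    else:
        rec.add("trunk_displacement", None, "m", reason="trunk not recorded")
    rec.add("normalized_reaching_area", float(np.max(dist)) / arm_length_m, "")
    return rec


def planning_pis(
    t: np.ndarray,
    pos: np.ndarray,
    speed: np.ndarray,
    ideal: IdealPath,
    go_cue_s: float,
    onset_s: float | None,
    end_s: float,
) -> PIRecord:
    """Planning-predictability indicators for one reach.

    ``onset_s`` is the 10%-of-peak onset from segmentation; None means no
    movement was detected, and every indicator is reported not-computable
    (the failure itself feeds the efficacy success rate).
    """
    rec = PIRecord(MotorAbility.PLANNING_PREDICTABILITY)
    names = ("time_to_peak_velocity", "reaction_time",
             "initial_movement_direction_error", "aiming_angle")
    if onset_s is None:
        for name in names:
            rec.add(name, None, "", reason="no movement detected")
        return rec
    t = np.asarray(t, dtype=float)
    pos = np.asarray(pos, dtype=float)
    speed = np.asarray(speed, dtype=float)
    mask = (t >= onset_s) & (t <= end_s)
    tm, pm, sm = t[mask], pos[mask], speed[mask]
    duration = end_s - onset_s
    i_peak = int(np.argmax(sm))
    rec.add("time_to_peak_velocity", float((tm[i_peak] - onset_s) / duration), "")
    rec.add("reaction_time", onset_s - go_cue_s, "s")
    # position error against the ideal path at the onset (10%-of-peak) time
    tau_onset = 0.0
    ideal_at_onset = ideal.position(np.array([tau_onset]))[0]
    rec.add("initial_movement_direction_error",
            float(np.linalg.norm(pm[0] - ideal_at_onset)), "m")
    travel = pm[i_peak] - pm[0]
    target_dir = ideal.target - pm[0]
    nt, nv = np.linalg.norm(target_dir), np.linalg.norm(travel)
    if nt < 1e-9 or nv < 1e-9:
        rec.add("aiming_angle", None, "deg", reason="degenerate direction")
    else:
        cosang = np.clip(travel @ target_dir / (nt * nv), -1.0, 1.0)
        rec.add("aiming_angle", float(np.degrees(np.arccos(cosang))), "deg")
    return rec


def sparc(
    speed: np.ndarray,
    rate_hz: float,
    cutoff_hz: float = SPARC_CUTOFF_HZ,
    amplitude_threshold: float = SPARC_AMPLITUDE_THRESHOLD,
    pad_factor: int = SPARC_PAD_FACTOR,
) -> float:
    """Spectral arc length of a speed profile (more negative = less smooth).

    The magnitude spectrum is zero-padded to ``pad_factor`` x the next
    power of two, normalized by its peak, truncated at ``cutoff_hz`` and
    then at the last frequency whose amplitude exceeds
    ``amplitude_threshold``; the reported value is the negative arc length
    of the (normalized frequency, amplitude) curve.  Invariant to
    amplitude and duration scaling of the movement.
    """
    speed = np.asarray(speed, dtype=float)
    if speed.size < 4:
        raise ValueError("speed profile too short for SPARC")
    nfft = pad_factor * int(2 ** np.ceil(np.log2(speed.size)))
    spectrum = np.abs(np.fft.rfft(speed, nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate_hz)
    spectrum = spectrum / np.max(spectrum)
    sel = freqs <= cutoff_hz
    f_sel, m_sel = freqs[sel], spectrum[sel]
    above = np.flatnonzero(m_sel >= amplitude_threshold)
    if above.size:
        f_sel = f_sel[: above[-1] + 1]
        m_sel = m_sel[: above[-1] + 1]
    if f_sel.size < 2:
        return 0.0
    f_span = f_sel[-1] - f_sel[0]
    df = np.diff(f_sel) / f_span
    dm = np.diff(m_sel)
    return float(-np.sum(np.sqrt(df**2 + dm**2)))


def normalized_dimensionless_jerk(
    pos: np.ndarray,
    rate_hz: float,
    *,
    cutoff_hz: float | None = None,
) -> float:
    """NDJ = integral of squared jerk x duration^5 / length^2.

    ``pos`` is the (n, 3) or (n,) position over exactly the movement
    interval; length is the traveled arc length.  The minimum-jerk reach
    scores 720, the analytic lower bound for point-to-point movements.
    """
    pos = np.asarray(pos, dtype=float)
    if pos.ndim == 1:
        pos = pos[:, None]
    n = pos.shape[0]
    if n < 9:
        raise ValueError("NDJ needs at least 9 samples")
    duration = (n - 1) / rate_hz
    length = float(np.sum(np.linalg.norm(np.diff(pos, axis=0), axis=1)))
    if length < 1e-12 or duration <= 0:
        raise ValueError("degenerate zero-length movement")
    src = pos if cutoff_hz is None else lowpass_filter(pos, rate_hz, cutoff_hz)
    jerk = third_derivative(src, rate_hz)
    j2 = np.sum(jerk**2, axis=1)
    integral = float(np.trapezoid(j2, dx=1.0 / rate_hz))
    return integral * duration**5 / length**2


def smoothness_pis(
    t: np.ndarray,
    pos: np.ndarray,
    speed: np.ndarray,
    rate_hz: float,
    onset_s: float,
    end_s: float,
    ideal: IdealPath | None = None,
    threshold_fraction: float = SPEED_THRESHOLD_FRACTION,
) -> PIRecord:
    """Smoothness indicators over one movement segment."""
    t = np.asarray(t, dtype=float)
    pos = np.asarray(pos, dtype=float)
    speed = np.asarray(speed, dtype=float)
    mask = (t >= onset_s) & (t <= end_s)
    if int(np.sum(mask)) < 20:
        raise ValueError("smoothness PIs need at least 20 samples in segment")
    tm, pm, sm = t[mask], pos[mask], speed[mask]
    duration = end_s - onset_s
    peak = float(np.max(sm))
    rec = PIRecord(MotorAbility.SMOOTHNESS)
    if peak <= 0 or duration <= 0:
        raise ValueError("degenerate zero-length movement")
    min_sep = max(1, int(round(PEAK_MIN_SEPARATION_S * rate_hz)))
    peaks, _ = find_peaks(sm, height=threshold_fraction * peak,
                          distance=min_sep)
    # a profile whose maximum sits at the segment edge still has one peak
    n_peaks = int(len(peaks))
    if n_peaks == 0 and peak > 0:
        n_peaks = 1
    rec.add("number_of_velocity_peaks", n_peaks, "count")
    if ideal is not None:
        tau = (tm - onset_s) / duration
        v_ideal = ideal.speed(tau)
        if np.std(v_ideal) > 1e-12 and np.std(sm) > 1e-12:
            rec.add("speed_correlation_to_ideal",
                    float(pearsonr(sm, v_ideal)[0]), "")
        else:
            rec.add("speed_correlation_to_ideal", None, "",
                    reason="zero-variance profile")
    else:
        rec.add("speed_correlation_to_ideal", None, "",
                reason="no ideal profile supplied")
    rec.add("movement_arrest_period_ratio",
            float(np.mean(sm > threshold_fraction * peak)), "")
    rec.add("peak_speed_ratio", float(np.mean(sm)) / peak, "")
    rec.add("normalized_dimensionless_jerk",
            normalized_dimensionless_jerk(pm, rate_hz), "")
    rec.add("spectral_arc_length", sparc(sm, rate_hz), "")
    acc = differentiate(speed, rate_hz, order=1, cutoff_hz=None)[mask]
    rec.add("mean_acceleration", float(np.mean(np.abs(acc))), "m/s^2")
    return rec


def speed_pis(
    t: np.ndarray,
    speed: np.ndarray,
    onset_s: float,
    end_s: float,
    ideal: IdealPath | None = None,
) -> PIRecord:
    """Speed indicators over one movement segment."""
    t = np.asarray(t, dtype=float)
    speed = np.asarray(speed, dtype=float)
    mask = (t >= onset_s) & (t <= end_s)
    tm, sm = t[mask], speed[mask]
    duration = end_s - onset_s
    rec = PIRecord(MotorAbility.SPEED)
    rec.add("peak_velocity", float(np.max(sm)), "m/s")
    rec.add("mean_velocity", float(np.mean(sm)), "m/s")
    if ideal is not None:
        tau = (tm - onset_s) / duration
        v_ideal = ideal.speed(tau)
        rec.add("mean_velocity_variability",
                float(np.sqrt(np.mean((sm - v_ideal) ** 2))), "m/s")
    else:
        rec.add("mean_velocity_variability", None, "m/s",
                reason="no ideal profile supplied")
    return rec
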