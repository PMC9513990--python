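"""Trial segmentation: onset/offset detection, primitive-flow cutting,
movement-stop counting, and trial-validity rules.

A trial of one motor skill is cut into the ordered primitive sequence of
its skill template.  Movement intervals are found by thresholding the
end-effector speed at a fraction of its peak (default 10%) with a 50 ms
hysteresis, then each boundary is refined to the nearest near-zero speed
minimum so that detected boundaries track the true start/stop of motion
rather than the threshold-crossing point.  Dwells longer than the 1 s
stability rule are idle/stabilize segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .taxonomy import (
    STABILITY_THRESHOLD_S,
    MotorPrimitive,
    MotorSkill,
)

__all__ = [
    "PrimitiveSegment",
    "SegmentationResult",
    "ValidityReport",
    "detect_onset",
    "movement_intervals",
    "segment_trial",
    "count_movement_stops",
    "check_validity",
    "DEFAULT_THRESHOLD_FRACTION",
    "CAPTURE_RADIUS_M",
    "TRUNK_VALIDITY_THRESHOLD_DEG",
]

DEFAULT_THRESHOLD_FRACTION = 0.10
#: Hysteresis on threshold crossings (s) to suppress noise chatter.
SUSTAIN_S = 0.05
#: End-effector-to-target distance that counts as waypoint arrival.
CAPTURE_RADIUS_M = 0.03
#: Trunk lean above which a trial is invalid (strict inequality).
TRUNK_VALIDITY_THRESHOLD_DEG = 20.0
#: Boundary refinement: walk from the threshold crossing to the nearest
#: sample below this fraction of peak speed.
BOUNDARY_FLOOR_FRACTION = 0.02
#: Sub-threshold dwell (s) below which two supra-threshold stretches are
#: one movement unit with a stop in it, not two template primitives.
MAX_STOP_GAP_S = 0.2
#: Low-pass cutoff for the segmentation speed trace.  Wider than the 6 Hz
#: metric filter: zero-phase smoothing smears bump edges symmetrically by
#: roughly its impulse-response width, and boundary detection needs sharp
#: edges more than it needs a quiet baseline.
SEGMENTATION_CUTOFF_HZ = 12.0


@dataclass
class PrimitiveSegment:
    """One labeled time interval of a trial."""

    primitive: MotorPrimitive
    start_s: float
    end_s: float
    waypoint_from: str
    waypoint_to: str
    valid: bool = True

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError("segment must have end_s > start_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SegmentationResult:
    segments: list[PrimitiveSegment]
    incomplete: bool = False

    def __iter__(self):
        return iter(self.segments)

    def __len__(self):
        return len(self.segments)


@dataclass
class ValidityReport:
    valid: bool
    max_sagittal_trunk_deg: float
    max_frontal_trunk_deg: float
    reasons: list[str] = field(default_factory=list)


def detect_onset(
    t: np.ndarray,
    speed: np.ndarray,
    go_cue_s: float,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    sustain_s: float = SUSTAIN_S,
) -> float | None:
    """Movement onset after a go cue, or None if no movement is detected.

    Onset is the first time at or after ``go_cue_s`` where the speed
    crosses ``threshold_fraction`` x (peak speed after the cue) upward and
    stays above it for at least ``sustain_s``.  A flat profile that never
    crosses is a "no movement" outcome (returned as None); it feeds the
    efficacy success rate rather than raising.
    """
    t = np.asarray(t, dtype=float)
    speed = np.asarray(speed, dtype=float)
    if np.any(speed < -1e-12):
        raise ValueError("speed must be nonnegative")
    if not (t[0] <= go_cue_s <= t[-1]):
        raise ValueError("go cue outside the recording")
    if threshold_fraction == 0.0:
        return float(go_cue_s)
    mask = t >= go_cue_s
    peak = float(np.max(speed[mask]))
    if peak <= 0.0:
        return None
    thr = threshold_fraction * peak
    idx = np.flatnonzero(mask)
    above = speed[idx] >= thr
    n_sustain = max(1, int(round(sustain_s * _rate(t))))
    run = 0
    for j, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= n_sustain:
            return float(t[idx[j - run + 1]])
    # tail shorter than the hysteresis window still counts if it reaches
    # the end of the record while above threshold
    if run > 0:
        return float(t[idx[len(above) - run]])
    return None


def _rate(t: np.ndarray) -> float:
    return 1.0 / float(np.median(np.diff(t)))


def _refine_to_minimum(speed: np.ndarray, idx: int, direction: int,
                       floor: float) -> int:
    """Walk from a threshold crossing to the nearest speed minimum.

    Steps in ``direction`` while the speed decreases; above ``floor`` it
    also steps through flat stretches, below the floor it stops at the
    first non-decreasing sample (the motion start/stop).
    """
    n = len(speed)
    i = idx
    while 0 <= i + direction < n:
        j = i + direction
        if speed[i] <= floor:
            if speed[j] < speed[i]:
                i = j
                continue
            break
        if speed[j] >= speed[i]:
            break  # local minimum above the floor
        i = j
    return i


def movement_intervals(
    t: np.ndarray,
    speed: np.ndarray,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    sustain_s: float = SUSTAIN_S,
) -> list[tuple[int, int]]:
    """Index intervals [i0, i1] of sustained supra-threshold movement.

    The threshold is relative to the global peak speed; crossings shorter
    than ``sustain_s`` are ignored; each boundary is then refined to the
    nearest sample where the speed drops below 2% of peak (or its local
    minimum), approximating the true motion start/stop.
    """
    t = np.asarray(t, dtype=float)
    speed = np.asarray(speed, dtype=float)
    peak = float(np.max(speed)) if speed.size else 0.0
    if peak <= 0:
        return []
    thr = threshold_fraction * peak
    floor = BOUNDARY_FLOOR_FRACTION * peak
    above = speed >= thr
    n_sustain = max(1, int(round(sustain_s * _rate(t))))
    raw: list[tuple[int, int]] = []
    i = 0
    n = len(speed)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j - i + 1 >= n_sustain:
                raw.append((i, j))
            i = j + 1
        else:
            i += 1
    # merge intervals separated by brief dips: a sub-threshold dwell shorter
    # than MAX_STOP_GAP_S is a movement stop inside one movement unit, not a
    # boundary between two template primitives
    n_gap = max(n_sustain, int(round(MAX_STOP_GAP_S * _rate(t))))
    merged: list[tuple[int, int]] = []
    for a, b in raw:
        if merged and a - merged[-1][1] <= n_gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    refined = []
    for a, b in merged:
        a2 = _refine_to_minimum(speed, a, -1, floor)
        b2 = _refine_to_minimum(speed, b, +1, floor)
        refined.append((a2, b2))
    return refined


def segment_trial(
    trial,
    skill: MotorSkill | None = None,
    layout=None,
    *,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    capture_radius_m: float = CAPTURE_RADIUS_M,
    stability_threshold_s: float = STABILITY_THRESHOLD_S,
) -> SegmentationResult:
    """Cut a trial into the primitive sequence of its skill template.

    Movement intervals (in order) are matched to the template's moving
    primitives; idle/stabilize template steps claim the dwell preceding
    the next movement (dwells shorter than the stability threshold merge
    into the surrounding flow, e.g. the grasp pause between a reach and
    the following transport).  If the trial contains fewer movement units
    than the template, the partial segmentation is returned with
    ``incomplete=True`` rather than raising, to support severely impaired
    users who cannot finish the task.
    """
    skill = MotorSkill(skill if skill is not None else trial.skill)
    layout = layout if layout is not None else getattr(trial, "layout", None)
    t = trial.t
    speed = trial.speed(cutoff_hz=SEGMENTATION_CUTOFF_HZ)
    flow = skill.primitive_flow
    intervals = movement_intervals(t, speed, threshold_fraction)
    pos = trial.ee.xyz

    segments: list[PrimitiveSegment] = []
    incomplete = False
    mi = 0  # next unconsumed movement interval
    prev_end = float(t[0])
    prev_wp = flow[0][1]
    for primitive, waypoint in flow:
        if primitive.moves:
            if mi >= len(intervals):
                incomplete = True
                break
            a, b = intervals[mi]
            mi += 1
            start, end = float(t[a]), float(t[b])
            valid = True
            if layout is not None:
                targets = [layout.point(waypoint)]
                if waypoint == "A" and primitive in (
                        MotorPrimitive.REACH_FOR_GRASP,
                        MotorPrimitive.TRANSPORT):
                    # grasp/transport "at A" ends at the object rest spot
                    try:
                        targets.append(layout.point("A_object"))
                    except KeyError:
                        pass
                valid = any(
                    np.linalg.norm(pos[b] - tp) <= capture_radius_m
                    for tp in targets)
            segments.append(PrimitiveSegment(
                primitive, start, end, prev_wp, waypoint, valid=valid))
            prev_end, prev_wp = end, waypoint
        else:
            # idle/stabilize: dwell from the previous segment end to the
            # next movement start (or trial end)
            nxt = float(t[intervals[mi][0]]) if mi < len(intervals) else float(t[-1])
            if nxt - prev_end <= 0:
                incomplete = True
                break
            valid = (nxt - prev_end) > stability_threshold_s
            segments.append(PrimitiveSegment(
                primitive, prev_end, nxt, waypoint, waypoint, valid=valid))
            prev_end = nxt
            prev_wp = waypoint
    if mi < len(intervals) and not incomplete:
        # extra movement units beyond the template: flag, keep template cut
        incomplete = True
    return SegmentationResult(segments=segments, incomplete=incomplete)


def count_movement_stops(
    t: np.ndarray,
    speed: np.ndarray,
    onset_s: float,
    end_s: float,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> int:
    """Number of sub-threshold dips strictly inside (onset, end).

    A stop is a maximal interval where the speed drops below
    ``threshold_fraction`` x peak speed (peak taken within the movement);
    dips touching the onset or end boundary are not stops.
    """
    if onset_s >= end_s:
        raise ValueError("onset must precede end")
    t = np.asarray(t, dtype=float)
    speed = np.asarray(speed, dtype=float)
    mask = (t >= onset_s) & (t <= end_s)
    s = speed[mask]
    if s.size == 0:
        return 0
    thr = threshold_fraction * float(np.max(s))
    below = s < thr
    stops = 0
    i = 0
    n = len(below)
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            if i > 0 and j < n - 1:  # strictly inside
                stops += 1
            i = j + 1
        else:
            i += 1
    return stops


def check_validity(
    sagittal_deg: np.ndarray | None,
    frontal_deg: np.ndarray | None,
    threshold_deg: float = TRUNK_VALIDITY_THRESHOLD_DEG,
) -> ValidityReport:
    """Trunk-compensation validity rule.

    The trial is invalid iff the absolute trunk lean exceeds the threshold
    (strictly) in the sagittal or frontal plane, or if trunk data were not
    recorded at all (recording the trunk is itself a protocol requirement).
    """
    reasons: list[str] = []
    if sagittal_deg is None or frontal_deg is None or len(np.atleast_1d(
            sagittal_deg if sagittal_deg is not None else [])) == 0:
        return ValidityReport(False, float("nan"), float("nan"),
                              ["trunk_not_recorded"])
    max_sag = float(np.max(np.abs(sagittal_deg)))
    max_fro = float(np.max(np.abs(frontal_deg)))
    if max_sag > threshold_deg:
        reasons.append("trunk_sagittal")
    if max_fro > threshold_deg:
        reasons.append("trunk_frontal")
    return ValidityReport(not reasons, max_sag, max_fro, reasons)
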