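"""Minimum-jerk reference profiles.

The idealized point-to-point movement used throughout the scheme is the
minimum-jerk trajectory: position follows the quintic
``s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5`` along the straight chord, with
zero velocity and acceleration at both ends.  Its speed profile is the
bell ``v(tau) = (L/D) * 30 tau^2 (1-tau)^2`` with peak ``1.875 L/D`` at
mid-movement.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "minimum_jerk_position",
    "minimum_jerk_speed",
    "minimum_jerk_path",
    "MINIMUM_JERK_PEAK_FACTOR",
]

#: Peak speed of a minimum-jerk reach in units of L/D.
MINIMUM_JERK_PEAK_FACTOR = 1.875


def minimum_jerk_position(tau: np.ndarray) -> np.ndarray:
    """Normalized chord progress s(tau) for tau in [0, 1]."""
    tau = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def minimum_jerk_speed(tau: np.ndarray, length: float = 1.0,
                       duration: float = 1.0) -> np.ndarray:
    """Speed (length-units/s) at normalized time tau."""
    tau = np.asarray(tau, dtype=float)
    v = 30 * tau**2 * (1 - tau) ** 2
    v = np.where((tau < 0) | (tau > 1), 0.0, v)
    return (length / duration) * v


def minimum_jerk_path(
    start: np.ndarray, end: np.ndarray, duration_s: float, rate_hz: float
) -> np.ndarray:
    """Sampled 3-D minimum-jerk trajectory from start to end (inclusive)."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    n = int(round(duration_s * rate_hz)) + 1
    tau = np.linspace(0.0, 1.0, n)
    s = minimum_jerk_position(tau)
    return start[None, :] + s[:, None] * (end - start)[None, :]
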