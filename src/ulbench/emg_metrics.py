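"""Surface-EMG conditioning and the full EMG performance-indicator suite.

Processing follows common surface-EMG practice: 20-450 Hz band-pass
(zero-phase Butterworth), optional 50 Hz harmonic notches, full-wave
rectification + 5 Hz low-pass for linear envelopes.  Feature definitions:

* time domain — waveform length, average amplitude change, DASDV, iEMG,
  RMS, mean absolute value (activation level), variance, MAV slope, zero
  crossings and slope-sign changes (both with a 10 uV deadband);
* frequency domain — Welch PSD (Hann, 512-sample segments, 50% overlap)
  feeding mean/median frequency, mean power, low/high frequency ratio and
  power-spectrum ratio around the spectral peak;
* burst onset via the Teager-Kaiser energy operator;
* co-contraction index in the Falconer-Winter overlap form;
* magnitude-squared intermuscular coherence with the Welch estimator;
* muscle synergies by non-negative matrix factorization with a
  variance-accounted-for (VAF) stopping rule.

All constants are keyword-configurable and echoed into reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import NMF

from .taxonomy import TARGET_MUSCLES

__all__ = [
    "EMGRecording",
    "Envelope",
    "SynergySet",
    "condition",
    "time_features",
    "frequency_features",
    "muscle_onset",
    "cocontraction_index",
    "intermuscular_coherence",
    "extract_synergies",
]

BAND_HZ = (20.0, 450.0)
ENVELOPE_CUTOFF_HZ = 5.0
FILTER_ORDER = 4
#: Deadband (signal units; 10 uV for mV-scaled data) for ZC/SSC counting.
DEADBAND = 0.01
#: Default low/high split for the frequency ratio.
FREQUENCY_RATIO_SPLIT_HZ = 60.0
#: Half-width of the spectral-peak neighborhood for the power spectrum ratio.
PSR_HALF_WIDTH_HZ = 10.0


@dataclass
class EMGRecording:
    """Multi-channel surface-EMG block (channels x samples, mV)."""

    data: np.ndarray
    rate_hz: float
    channels: tuple[str, ...]
    go_cues_s: tuple[float, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel count does not match data rows")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        unknown = [c for c in self.channels if c not in TARGET_MUSCLES]
        if unknown:
            raise ValueError(
                f"unknown muscle name(s) {unknown}; valid: {list(TARGET_MUSCLES)}")
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.rate_hz < 1000.0:
            warnings.warn(
                f"sampling rate {self.rate_hz} Hz is below the recommended "
                "1000 Hz; frequency-domain indicators above Nyquist will be "
                "suppressed", stacklevel=2)

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.data.shape[1]) / self.rate_hz


@dataclass
class Envelope:
    """Nonnegative linear envelopes (channels x samples)."""

    data: np.ndarray
    rate_hz: float
    channels: tuple[str, ...]
    normalization: str = "none"  # none | peak | mvc

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if np.any(self.data < -1e-9):
            raise ValueError("envelope values must be nonnegative")
        self.data = np.clip(self.data, 0.0, None)

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]

    def normalized(self, mode: str = "peak",
                   mvc: np.ndarray | None = None) -> "Envelope":
        if mode == "peak":
            scale = np.max(self.data, axis=1, keepdims=True)
        elif mode == "mvc":
            if mvc is None:
                raise ValueError("MVC normalization requires an MVC amplitude "
                                 "per channel")
            scale = np.asarray(mvc, dtype=float)[:, None]
        else:
            raise ValueError("mode must be 'peak' or 'mvc'")
        scale = np.where(scale <= 0, 1.0, scale)
        return Envelope(self.data / scale, self.rate_hz, self.channels, mode)


def condition(
    raw: EMGRecording,
    band_hz: tuple[float, float] = BAND_HZ,
    notch_50hz: bool = False,
    envelope_cutoff_hz: float = ENVELOPE_CUTOFF_HZ,
    filter_order: int = FILTER_ORDER,
) -> tuple[EMGRecording, Envelope]:
    """Band-pass filter a raw recording and derive linear envelopes."""
    nyq = raw.rate_hz / 2
    hi = min(band_hz[1], 0.95 * nyq)
    sos = sps.butter(filter_order, [band_hz[0], hi], btype="band",
                     fs=raw.rate_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, raw.data, axis=1)
    if notch_50hz:
        for f0 in np.arange(50.0, min(nyq, band_hz[1]), 50.0):
            b, a = sps.iirnotch(f0, Q=30.0, fs=raw.rate_hz)
            filtered = sps.filtfilt(b, a, filtered, axis=1)
    sos_env = sps.butter(filter_order, envelope_cutoff_hz, btype="low",
                         fs=raw.rate_hz, output="sos")
    # low-pass ringing can undershoot zero slightly; envelopes are
    # nonnegative by definition
    env = np.clip(sps.sosfiltfilt(sos_env, np.abs(filtered), axis=1), 0.0, None)
    meta = dict(raw.meta)
    meta.update({
        "band_hz": [band_hz[0], hi],
        "notch_50hz": notch_50hz,
        "envelope_cutoff_hz": envelope_cutoff_hz,
        "filter_order": filter_order,
    })
    out = EMGRecording(filtered, raw.rate_hz, raw.channels, raw.go_cues_s, meta)
    return out, Envelope(env, raw.rate_hz, raw.channels)


# --------------------------------------------------------------------------
# Time-domain features
# --------------------------------------------------------------------------

def time_features(
    x: np.ndarray,
    n_subsegments: int = 3,
    deadband: float = DEADBAND,
) -> dict[str, float | list[float]]:
    """Time-domain feature set of one filtered channel segment."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("time features need at least 2 samples")
    dx = np.diff(x)
    wl = float(np.sum(np.abs(dx)))
    mav = float(np.mean(np.abs(x)))
    # zero crossings / slope sign changes with a deadband against noise
    zc = int(np.sum((x[:-1] * x[1:] < 0)
                    & (np.abs(x[:-1] - x[1:]) >= deadband)))
    d1, d2 = x[1:-1] - x[:-2], x[1:-1] - x[2:]
    ssc = int(np.sum((d1 * d2 > 0)
                     & ((np.abs(d1) >= deadband) | (np.abs(d2) >= deadband))))
    bounds = np.linspace(0, n, n_subsegments + 1).astype(int)
    mavs_parts = [float(np.mean(np.abs(x[a:b]))) if b > a else 0.0
                  for a, b in zip(bounds[:-1], bounds[1:])]
    return {
        "waveform_length": wl,
        "average_amplitude_change": wl / n,
        "difference_absolute_standard_deviation_value":
            float(np.sqrt(np.sum(dx**2) / (n - 1))),
        "integrated_emg": float(np.sum(np.abs(x))),
        "root_mean_square": float(np.sqrt(np.mean(x**2))),
        "activation_level": mav,
        "variance_of_emg": float(np.var(x)),
        "mean_absolute_value_slope": list(np.diff(mavs_parts)),
        "emg_zero_crossing": zc,
        "slope_sign_change": ssc,
    }


# --------------------------------------------------------------------------
# Frequency-domain features
# --------------------------------------------------------------------------

def frequency_features(
    x: np.ndarray,
    rate_hz: float,
    band_hz: tuple[float, float] = BAND_HZ,
    nperseg: int = 512,
    fr_split_hz: float = FREQUENCY_RATIO_SPLIT_HZ,
    psr_half_width_hz: float = PSR_HALF_WIDTH_HZ,
) -> dict:
    """Welch-PSD features of one filtered channel segment."""
    x = np.asarray(x, dtype=float)
    if x.size < 256:
        raise ValueError("frequency features need at least 256 samples")
    if x.size < nperseg:
        warnings.warn(
            f"window of {x.size} samples shorter than the {nperseg}-sample "
            "Welch segment; shrinking the segment length", stacklevel=2)
        nperseg = x.size
    f, p = sps.welch(x, fs=rate_hz, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2)
    total = float(np.sum(p))
    if total <= 0:
        raise ValueError("zero-power signal")
    mnf = float(np.sum(f * p) / total)
    cum = np.cumsum(p)
    mdf = float(np.interp(total / 2, cum, f))
    hi = min(band_hz[1], rate_hz / 2)
    low = (f >= band_hz[0]) & (f < fr_split_hz)
    high = (f >= fr_split_hz) & (f <= hi)
    p_high = float(np.sum(p[high]))
    i_peak = int(np.argmax(p))
    near = np.abs(f - f[i_peak]) <= psr_half_width_hz
    return {
        "mean_frequency": mnf,
        "median_frequency": mdf,
        "mean_power": float(np.mean(p)),
        "power_spectral_density": {"f_hz": f.tolist(), "psd": p.tolist()},
        "frequency_ratio":
            float(np.sum(p[low]) / p_high) if p_high > 0 else float("inf"),
        "power_spectrum_ratio": float(np.sum(p[near]) / total),
    }


# --------------------------------------------------------------------------
# Onset, co-contraction, coherence
# --------------------------------------------------------------------------

def teager_kaiser(x: np.ndarray) -> np.ndarray:
    """TKEO psi[i] = x[i]^2 - x[i-1] x[i+1] (endpoints zero-padded)."""
    x = np.asarray(x, dtype=float)
    psi = np.zeros_like(x)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    return psi


def muscle_onset(
    x: np.ndarray,
    rate_hz: float,
    go_cue_s: float,
    baseline_s: float = 0.2,
    smooth_s: float = 0.05,
    n_sd: float = 3.0,
    sustain_s: float = 0.025,
) -> float | None:
    """EMG burst latency after the go cue, or None without supra-threshold
    activity.

    The Teager-Kaiser energy of the filtered signal is smoothed (50 ms
    moving average); onset is the first post-cue time where it exceeds the
    pre-cue baseline mean + ``n_sd`` SD for at least ``sustain_s``.
    """
    x = np.asarray(x, dtype=float)
    t = np.arange(x.size) / rate_hz
    if go_cue_s < baseline_s:
        raise ValueError(
            f"need at least {baseline_s * 1e3:.0f} ms of pre-cue baseline")
    psi = teager_kaiser(x)
    win = max(1, int(round(smooth_s * rate_hz)))
    # causal (trailing) moving average: smoothing must not anticipate the
    # burst, or detected onsets shift earlier than the true activity
    psi = np.convolve(psi, np.ones(win) / win, mode="full")[: psi.size]
    base = psi[t < go_cue_s - 0.0][-int(baseline_s * rate_hz):]
    thr = float(np.mean(base) + n_sd * np.std(base))
    post = np.flatnonzero(t >= go_cue_s)
    above = psi[post] > thr
    n_sustain = max(1, int(round(sustain_s * rate_hz)))
    run = 0
    for j, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= n_sustain:
            onset = t[post[j - run + 1]]
            return float(onset - go_cue_s)
    return None


def cocontraction_index(
    env_agonist: np.ndarray,
    env_antagonist: np.ndarray,
) -> float | None:
    """Falconer-Winter co-contraction index (percent).

    CCI = 100 * 2 * sum(min(e1, e2)) / sum(e1 + e2); 100% for identical
    envelopes, 0% for disjoint activity.  Returns None when both
    envelopes are identically zero.
    """
    e1 = np.asarray(env_agonist, dtype=float)
    e2 = np.asarray(env_antagonist, dtype=float)
    if e1.shape != e2.shape:
        raise ValueError("envelopes must have matching shapes")
    denom = float(np.sum(e1 + e2))
    if denom <= 0:
        return None
    return float(100.0 * 2.0 * np.sum(np.minimum(e1, e2)) / denom)


def intermuscular_coherence(
    x1: np.ndarray,
    x2: np.ndarray,
    rate_hz: float,
    band_hz: tuple[float, float] = (15.0, 30.0),
    nperseg: int | None = None,
) -> dict:
    """Magnitude-squared coherence between two EMG channels.

    Welch estimator with 1 s Hann segments and 50% overlap;  reports the
    coherence spectrum, its mean over ``band_hz``, and the 95% confidence
    level ``1 - 0.05**(1/(L-1))`` for L averaged segments — band means
    above that level indicate significant coupling.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    nperseg = nperseg or int(rate_hz)
    step = nperseg // 2
    n_seg = max(0, (x1.size - nperseg) // step + 1)
    if n_seg < 2:
        raise ValueError("need at least 2 Welch segments for coherence")
    f, c = sps.coherence(x1, x2, fs=rate_hz, window="hann",
                         nperseg=nperseg, noverlap=step)
    sel = (f >= band_hz[0]) & (f <= band_hz[1])
    conf = 1.0 - 0.05 ** (1.0 / (n_seg - 1))
    return {
        "f_hz": f,
        "coherence": c,
        "band_hz": band_hz,
        "band_mean": float(np.mean(c[sel])),
        "confidence_level_95": float(conf),
        "n_segments": int(n_seg),
    }


# --------------------------------------------------------------------------
# Muscle synergies
# --------------------------------------------------------------------------

@dataclass
class SynergySet:
    """NMF decomposition E ~= W @ H of an envelope matrix."""

    weights: np.ndarray       # muscles x k, nonnegative
    activations: np.ndarray   # k x samples, nonnegative
    k: int
    vaf: float
    vaf_by_k: dict[int, float] = field(default_factory=dict)

    def reconstruction(self) -> np.ndarray:
        return self.weights @ self.activations


def _vaf(e: np.ndarray, w: np.ndarray, h: np.ndarray) -> float:
    """VAF = 1 - SSE/SST, SST about the grand mean of the matrix."""
    sse = float(np.sum((e - w @ h) ** 2))
    sst = float(np.sum((e - np.mean(e)) ** 2))
    return 1.0 - sse / sst if sst > 0 else 1.0


def _fit_nmf(e: np.ndarray, k: int, n_restarts: int, seed: int,
             tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray]:
    best = None
    for r in range(n_restarts):
        model = NMF(n_components=k, init="random", solver="mu",
                    beta_loss="frobenius", tol=tol, max_iter=max_iter,
                    random_state=seed + r)
        w = model.fit_transform(e)
        h = model.components_
        err = float(np.sum((e - w @ h) ** 2))
        if best is None or err < best[0]:
            best = (err, w, h)
    return best[1], best[2]


def extract_synergies(
    env: Envelope | np.ndarray,
    k: int | None = None,
    vaf_target: float = 0.90,
    n_restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> SynergySet:
    """Extract muscle synergies by NMF (multiplicative updates).

    With ``k`` fixed the factorization rank is used as given; otherwise
    the smallest rank whose VAF reaches ``vaf_target`` is selected.  Each
    rank is fitted ``n_restarts`` times from seeded random starts and the
    lowest-error solution kept.
    """
    e = env.data if isinstance(env, Envelope) else np.asarray(env, dtype=float)
    if np.any(e < 0):
        raise ValueError("negative envelope values: conditioning bug upstream")
    n_muscles = e.shape[0]
    if n_muscles < 2:
        raise ValueError("synergy extraction needs at least 2 muscles")
    vaf_by_k: dict[int, float] = {}
    if k is not None:
        w, h = _fit_nmf(e, k, n_restarts, seed, tol, max_iter)
        vaf_by_k[k] = _vaf(e, w, h)
        return SynergySet(w, h, k, vaf_by_k[k], vaf_by_k)
    for kk in range(1, n_muscles + 1):
        w, h = _fit_nmf(e, kk, n_restarts, seed, tol, max_iter)
        vaf_by_k[kk] = _vaf(e, w, h)
        if vaf_by_k[kk] >= vaf_target:
            return SynergySet(w, h, kk, vaf_by_k[kk], vaf_by_k)
    return SynergySet(w, h, n_muscles, vaf_by_k[n_muscles], vaf_by_k)
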