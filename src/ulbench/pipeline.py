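"""Benchmark pipeline: validate -> segment -> compute -> report.

`run_benchmark` executes the full deterministic procedure for one
worksheet and a set of repetition recordings, producing the benchmark
report plus a run manifest (input hashes, every tunable constant used,
software version, seeds, per-stage timings).  Re-running on the same
inputs reproduces the report byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np

from . import __version__
from .emg_metrics import (
    cocontraction_index,
    condition,
    extract_synergies,
    frequency_features,
    intermuscular_coherence,
    muscle_onset,
    time_features,
)
from .io import read_emg_csv, read_trial_csv
from .kin_metrics import (
    IdealPath,
    PIRecord,
    accuracy_pis,
    amplitude_pis,
    coordination_pis,
    efficacy_pis,
    efficiency_pis,
    planning_pis,
    smoothness_pis,
    speed_pis,
)
from .segmentation import (
    CAPTURE_RADIUS_M,
    DEFAULT_THRESHOLD_FRACTION,
    check_validity,
    count_movement_stops,
    detect_onset,
    segment_trial,
)
from .kin_metrics import (
    PEAK_MIN_SEPARATION_S,
    SPARC_AMPLITUDE_THRESHOLD,
    SPARC_CUTOFF_HZ,
    SPARC_PAD_FACTOR,
)
from .kinematics import DEFAULT_CUTOFF_HZ
from .protocol import Worksheet, generate_report, load_worksheet
from .taxonomy import Domain, MotorAbility

__all__ = ["compute_trial_pis", "run_benchmark", "PIPELINE_CONSTANTS"]

#: Every tunable constant a PI value can depend on; echoed in the manifest.
PIPELINE_CONSTANTS = {
    "speed_threshold_fraction": DEFAULT_THRESHOLD_FRACTION,
    "capture_radius_m": CAPTURE_RADIUS_M,
    "kin_lowpass_cutoff_hz": DEFAULT_CUTOFF_HZ,
    "velocity_peak_min_separation_s": PEAK_MIN_SEPARATION_S,
    "sparc_cutoff_hz": SPARC_CUTOFF_HZ,
    "sparc_amplitude_threshold": SPARC_AMPLITUDE_THRESHOLD,
    "sparc_pad_factor": SPARC_PAD_FACTOR,
    "trunk_validity_threshold_deg": 20.0,
    "stability_threshold_s": 1.0,
    "emg_band_hz": [20.0, 450.0],
    "emg_envelope_cutoff_hz": 5.0,
    "synergy_vaf_target": 0.90,
}


def compute_trial_pis(
    trial,
    emg=None,
    agonist: str = "biceps_brachii",
    antagonist: str = "triceps_brachii",
    synergy_seed: int = 0,
) -> tuple[list[PIRecord], "object"]:
    """Segment one trial and compute every applicable PI record.

    Returns (records, validity).  Kinematic records are produced per
    moving segment plus trial-level efficacy; EMG records (if a recording
    is supplied) cover the whole trial window per muscle, with the
    agonist/antagonist pair feeding co-contraction and coherence.
    """
    validity = check_validity(trial.trunk_sagittal_deg, trial.trunk_frontal_deg)
    seg = segment_trial(trial)
    t = trial.t
    speed = trial.speed()
    pos = trial.ee.xyz
    q_deg = trial.q.to_degrees() if trial.q is not None else None
    records: list[PIRecord] = []
    moving = [s for s in seg.segments if s.primitive.moves]
    stops = 0
    reached = 0
    go_iter = list(trial.go_cues_s)
    for i, s in enumerate(moving):
        target = (trial.layout.point(s.waypoint_to)
                  if trial.layout is not None else pos[-1])
        mask = (t >= s.start_s) & (t <= s.end_s)
        p_seg = pos[mask]
        ideal = IdealPath(p_seg[0], target, s.duration_s)
        go_cue = go_iter[i] if i < len(go_iter) else s.start_s
        window = (t >= go_cue) & (t <= s.end_s)
        onset = detect_onset(t, np.where(window, speed, 0.0), go_cue)
        stops += count_movement_stops(t, speed, s.start_s, s.end_s)
        reached += int(s.valid)
        records.append(accuracy_pis(t[mask], p_seg, ideal))
        records.append(efficiency_pis(t, pos, s.start_s, s.end_s,
                                      trunk_position=trial.trunk_position))
        if q_deg is not None:
            records.append(coordination_pis(t, q_deg, trial.rate_hz,
                                            s.start_s, s.end_s))
            records.append(amplitude_pis(t, q_deg, pos, s.start_s, s.end_s,
                                         trial.geom.arm_length_m,
                                         trial.trunk_position))
        records.append(planning_pis(t, pos, speed, ideal, go_cue,
                                    onset, s.end_s))
        records.append(smoothness_pis(t, pos, speed, trial.rate_hz,
                                      s.start_s, s.end_s, ideal))
        records.append(speed_pis(t, speed, s.start_s, s.end_s, ideal))
    records.append(efficacy_pis(reached, len(moving), stops))

    if emg is not None:
        filtered, env = condition(emg)
        for name in emg.channels:
            x = filtered.channel(name)
            tf = time_features(x)
            eff = PIRecord(MotorAbility.EFFICIENCY)
            for k in ("waveform_length", "average_amplitude_change",
                      "difference_absolute_standard_deviation_value"):
                eff.add(k, tf[k], "mV")
            records.append(eff)
            me = PIRecord(MotorAbility.MUSCULAR_EFFORT)
            me.add("integrated_emg", tf["integrated_emg"], "mV")
            me.add("root_mean_square", tf["root_mean_square"], "mV")
            me.add("activation_level", tf["activation_level"], "mV")
            me.add("variance_of_emg", tf["variance_of_emg"], "mV^2")
            mavs = tf["mean_absolute_value_slope"]
            me.add("mean_absolute_value_slope",
                   float(np.mean(mavs)) if mavs else None, "mV")
            records.append(me)
            sm = PIRecord(MotorAbility.SMOOTHNESS)
            sm.add("emg_zero_crossing", tf["emg_zero_crossing"], "count")
            sm.add("slope_sign_change", tf["slope_sign_change"], "count")
            records.append(sm)
            ff = frequency_features(x, emg.rate_hz)
            pw = PIRecord(MotorAbility.POWER)
            for k in ("mean_frequency", "median_frequency"):
                pw.add(k, ff[k], "Hz")
            pw.add("mean_power", ff["mean_power"], "mV^2")
            pw.add("power_spectral_density", None, "mV^2/Hz",
                   reason="exported as spectrum in extras")
            pw.extras["power_spectral_density"] = ff["power_spectral_density"]
            pw.add("frequency_ratio", ff["frequency_ratio"], "")
            pw.add("power_spectrum_ratio", ff["power_spectrum_ratio"], "")
            records.append(pw)
            # burst latency is only meaningful for the muscles driving the
            # cued movement: restrict to the declared agonist/antagonist
            if emg.go_cues_s and name in (agonist, antagonist):
                pl = PIRecord(MotorAbility.PLANNING_PREDICTABILITY)
                lat = muscle_onset(x, emg.rate_hz, emg.go_cues_s[0])
                pl.add("muscle_onset", lat, "s",
                       reason="" if lat is not None else "no onset detected")
                records.append(pl)
        co = PIRecord(MotorAbility.INTRA_LIMB_COORDINATION)
        if agonist in emg.channels and antagonist in emg.channels:
            cci = cocontraction_index(env.channel(agonist),
                                      env.channel(antagonist))
            co.add("cocontraction_index", cci, "%",
                   reason="" if cci is not None else "zero envelopes")
            try:
                coh = intermuscular_coherence(
                    filtered.channel(agonist), filtered.channel(antagonist),
                    emg.rate_hz)
                co.add("intermuscular_coherence", coh["band_mean"], "")
                co.extras["coherence_confidence_level_95"] = \
                    coh["confidence_level_95"]
            except ValueError as exc:
                co.add("intermuscular_coherence", None, "", reason=str(exc))
        else:
            co.add("cocontraction_index", None, "%",
                   reason="agonist/antagonist pair not recorded")
            co.add("intermuscular_coherence", None, "",
                   reason="agonist/antagonist pair not recorded")
        # envelopes are 5 Hz band-limited: decimate to ~50 Hz before NMF
        step = max(1, int(round(emg.rate_hz / 50.0)))
        syn = extract_synergies(env.data[:, ::step], seed=synergy_seed)
        co.add("muscular_synergies", float(syn.k), "synergies")
        co.extras["synergy_vaf"] = syn.vaf
        records.append(co)
    return records, validity


def _hash_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_benchmark(
    worksheet_path,
    kin_paths,
    emg_paths=None,
    out_dir=None,
    seed: int = 0,
) -> tuple[dict, dict]:
    """Execute the full benchmark procedure; returns (report, manifest).

    Raises on an invalid worksheet (no computation is attempted) and on
    missing EMG files when the EMG outcome domain is declared.  The report
    carries a warnings block for mandatory indicators that could not be
    computed; callers deciding an exit status should treat a non-empty
    block as failure.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    ws = (worksheet_path if isinstance(worksheet_path, Worksheet)
          else load_worksheet(worksheet_path))
    timings["validate_s"] = time.perf_counter() - t0
    kin_paths = list(kin_paths)
    emg_paths = list(emg_paths or [])
    if Domain.EMG in ws.outcome_domains and len(emg_paths) != len(kin_paths):
        raise ValueError(
            "outcome domain 'emg' declared but EMG recordings do not match "
            f"the {len(kin_paths)} kinematic repetition(s)")
    trial_results = []
    t0 = time.perf_counter()
    endpoint_errors: dict[str, list[float]] = {}
    for i, kp in enumerate(kin_paths):
        trial = read_trial_csv(kp)
        emg = read_emg_csv(emg_paths[i]) if emg_paths else None
        records, validity = compute_trial_pis(
            trial, emg, ws.agonist, ws.antagonist, synergy_seed=seed)
        trial_results.append({
            "trial_id": Path(kp).stem,
            "skill": trial.skill.value,
            "validity": validity,
            "pi_records": records,
        })
        if validity.valid:
            seg = segment_trial(trial)
            for s in seg.segments:
                if s.primitive.moves:
                    target = trial.layout.point(s.waypoint_to)
                    mask = (trial.t >= s.start_s) & (trial.t <= s.end_s)
                    err = float(np.linalg.norm(
                        trial.ee.xyz[mask][-1] - target))
                    endpoint_errors.setdefault(s.waypoint_to, []).append(err)
    timings["compute_s"] = time.perf_counter() - t0
    t0 = time.perf_counter()
    report = generate_report(ws, trial_results, constants=PIPELINE_CONSTANTS)
    # across-repetition variable error, per direction and pooled
    ve = {}
    pooled: list[float] = []
    for wp, errs in sorted(endpoint_errors.items()):
        if len(errs) >= 2:
            ve[wp] = float(np.std(errs, ddof=1))
        pooled.extend(errs)
    if len(pooled) >= 2:
        ve["pooled"] = float(np.std(pooled, ddof=1))
    report["variable_error_m"] = ve
    timings["report_s"] = time.perf_counter() - t0
    manifest = {
        "software_version": __version__,
        "inputs": {
            str(p): _hash_file(p)
            for p in [*kin_paths, *emg_paths]
            if Path(str(p)).exists()
        },
        "constants": PIPELINE_CONSTANTS,
        "seeds": {"synergy_nmf": seed},
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
    return report, manifest
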