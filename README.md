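# ulbench — unified benchmarking of upper-limb motor capacity

`ulbench` is a toolkit for standardized, quantitative assessment of
upper-limb movement in neurological rehabilitation — with or without a
rehabilitation robot in the loop.  It is aimed at motion-analysis and
rehabilitation-robotics researchers who need the same protocol, the same
segmentation rules and the same performance indicators computed the same
way across labs and devices.

The scheme it implements:

* **Taxonomy.** Functional tasks are decomposed into six *motor
  primitives* (idle, stabilize, point-to-point reach, reach for grasp,
  transport, reposition), composed into six protocol *motor skills*
  (anterior reaching and moving objects, each at rest or shoulder
  height, and hand-to-mouth with/without an object).  Capacity is scored
  along ten *motor abilities* (accuracy, efficacy, efficiency, movement
  amplitude, muscular effort, intra-limb coordination, planning
  predictability, power, smoothness, speed), each quantified by one or
  more *performance indicators* (PIs) from the kinematic or surface-EMG
  domain.  Seven indicators are *mandatory* — one per ability where a
  clinically anchored choice exists.
* **Kinematics.** An 8-DOF thorax–shoulder–elbow–wrist chain in the ISB
  convention: trunk flexion q0; glenohumeral plane of elevation q1,
  elevation q2, axial rotation q3 (Y-X′-Y″ Euler sequence); elbow
  flexion q4 and pronation q5; wrist flexion q6 and deviation q7.
  Conversion to and from the robotics shoulder convention
  (flexion / horizontal adduction / humeral rotation) is done through the
  shared rotation matrix.
* **Protocol.** A validated worksheet (subject, robot training modality
  and per-DOF assistance in [−1, +1], gravity compensation in [0, 1],
  skills with ≥ 8 repetitions, disturbance, outcome domains), the A–E
  target layout (targets at full elbow extension, C and D at ±45° from
  the A–B line), the environment rule (gravity vs. micro-gravity from
  the robot's training modality) and the trial-validity rule (trunk lean
  > 20° in the sagittal or frontal plane invalidates the trial).
* **Metrics.** The full PI suite, e.g. smoothness via the number of
  velocity peaks, the spectral arc length (SPARC) and the normalized
  dimensionless jerk NDJ = ∫j²(t)dt · D⁵/L² (720 for a minimum-jerk
  reach); EMG features from waveform length to median frequency, burst
  onset via the Teager–Kaiser energy operator, the Falconer–Winter
  co-contraction index, intermuscular coherence, and muscle synergies by
  non-negative matrix factorization with a VAF stopping rule.
* **Simulator.** A synthetic-trial generator (minimum-jerk reaches
  through the target layout, amplitude-modulated band-limited EMG) with
  ground-truth labels and tunable impairment, so the whole pipeline is
  testable without any recorded patient data.

## Worked example

Simulate eight repetitions of anterior reaching at rest height for a
subject with a 30 cm upper arm and 25 cm forearm, with a mildly impaired
movement model (120 ms reaction delay, slight path curvature, 30% EMG
co-contraction), then run the full benchmark:

```python
import json, pathlib
from ulbench import (ArmGeometry, ImpairmentParams, build_target_layout,
                     synth_trial, synth_emg)
from ulbench.io import write_trial_csv, write_emg_csv
from ulbench.pipeline import run_benchmark

geom = ArmGeometry(0.30, 0.25)
layout = build_target_layout(geom, 0.30, "rest_height")
d = pathlib.Path("run"); d.mkdir(exist_ok=True)
kin, emg = [], []
for i in range(8):
    impair = ImpairmentParams(seed=i, reaction_delay_s=0.12,
                              curvature_gain=0.04, cocontraction_gain=0.3)
    trial, _ = synth_trial("anterior_reaching_rest_height", layout, geom, impair)
    kin.append(write_trial_csv(trial, d / f"rep{i}.csv"))
    emg.append(write_emg_csv(synth_emg(trial, impair=impair), d / f"rep{i}_emg.csv"))
sheet = d / "sheet.json"
sheet.write_text(json.dumps({
    "subject": {"upper_arm_cm": 30, "forearm_cm": 25},
    "skills": [{"skill": "anterior_reaching_rest_height"}],
    "outcome_domains": ["kinematics", "emg"],
    "setup": {"muscles": ["biceps_brachii", "triceps_brachii", "anterior_deltoid"]},
}))
report, manifest = run_benchmark(sheet, kin, emg, d / "out", seed=1)
```

Selected rows of the aggregated PI table it prints (`M` = mandatory,
mean ± SD over repetitions; `n` counts segment-level values):

```
[efficiency]
  path_length_ratio (M): 1.004 +- 4.43e-08  (n=48)
[planning_predictability]
  reaction_time (M): 0.21 +- 5.18e-16 s (n=48)
  muscle_onset (R): 0.08519 +- 0.00442 s (n=16)
[smoothness]
  number_of_velocity_peaks (M): 1 +- 0 count (n=48)
  movement_arrest_period_ratio (R): 0.8218 +- 0  (n=48)
  normalized_dimensionless_jerk (R): 761.5 +- 0.0417  (n=48)
  spectral_arc_length (R): -1.377 +- 3.3e-07  (n=48)
[speed]
  peak_velocity (R): 0.8641 +- 9.91e-07 m/s (n=48)
  mean_velocity (M): 0.4583 +- 6.33e-08 m/s (n=48)
[intra_limb_coordination]
  cocontraction_index (R): 50.84 +- 0.769 % (n=8)
  muscular_synergies (R): 2 +- 0 synergies (n=8)
```

Reading the numbers: the path-length ratio of 1.004 says the hand path
is 0.4% longer than the straight chord (the injected curvature); the
reaction time of 0.21 s is the injected 120 ms delay plus the ~86 ms the
10%-of-peak onset rule takes to trigger on a 1 s minimum-jerk reach; one
velocity peak and a movement-arrest-period ratio of 0.822 (analytic
minimum-jerk value ≈ 0.827) say the reaches are smooth; NDJ of 761
vs. the minimum-jerk floor of 720 quantifies the small smoothness cost
of the curved path; peak velocity 0.864 m/s ≈ 1.875 × reach / duration.

The same pipeline runs from a shell:

```bash
ulbench simulate --skill anterior_reaching_rest_height --seed 1 --out run/
ulbench validate run/worksheet.json
ulbench run run/worksheet.json --kin run/kin.csv --emg run/emg.csv --out out/
ulbench report out/
```

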