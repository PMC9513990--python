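# Methods

This note documents the models, rules, constants and design choices
behind `ulbench`, and what the synthetic-data tests do and do not show
about real recordings.

## Taxonomy and classification rules

The registry (`ulbench.taxonomy`) is the single source of truth: six
motor primitives with their verbatim definitions, six motor skills as
ordered (primitive, waypoint) flows of lengths 7/7/12/12/4/6, ten motor
abilities with their kinematics/EMG domain flags, and the full
performance-indicator table with mandatory/recommended status (seven
mandatory indicators; accuracy, intra-limb coordination and power have
none).

*Function* classification: a labeled interval is **stability** iff its
longest still stretch strictly exceeds 1 s ("more than 1 s" is read as a
strict inequality; a hold of exactly 1 s is transport).  "Still" means
end-effector speed below 2 cm/s — a tolerance the rule itself does not
specify, chosen at the scale of postural sway and configurable.  The
hold is measured on the hand end-effector (not the object).

*Environment* classification: **gravity** when no robot is present or
its training modality is patient-in-charge, transparent or resistive;
**micro-gravity** otherwise.  The modality enum has eight members
(patient_in_charge, transparent, resistive, robot_in_charge, assistive,
corrective, path_guidance, error_amplification); only the first three
affect classification.  Open point resolved here: any non-zero gravity
compensation on a passive DOF also forces micro-gravity, and the
override is flagged in the output, because partial weight support
already changes the anti-gravity demand the ability scores assume.
Skills that can be performed sliding on the desk remain a worksheet
choice; the classifier does not override the declared environment.

## Kinematic model

Ground frame: ISB (X anterior, Y up, Z lateral toward the evaluated
side).  Left-arm recordings are mirrored about the sagittal plane at
load time (positions Z-negated, lateral-sense DOFs q1/q3/q5/q7
sign-flipped) so every downstream metric is side-agnostic.

The chain is thorax (q0, flexion about Z) → glenohumeral ball-and-socket
(Y-X′-Y″: plane of elevation q1, elevation q2, axial rotation q3) →
elbow (flexion q4 about the local Z, pronation q5 about the forearm
axis) → wrist (q6, q7, orienting the hand without displacing the wrist
point).  The end-effector is the wrist point, so the straight arm spans
upper-arm + forearm length exactly, and link lengths are conserved for
any pose.  Zero posture: arm hanging, palm medial (ISB neutral) — the
zero for q1–q3 is not self-evident from the protocol and must be stated
in every report.

The robotics shoulder convention (flexion/extension, horizontal
adduction/abduction, humeral rotation; Z-X′-Y″ sequence) converts to and
from ISB by composing the rotation matrix and re-decomposing it.  The
conversion is exact away from the elevation singularity; at |q2| ≈ 0 the
plane of elevation is undefined, q1 is set to 0 and the result flagged.
Inverse kinematics resolves the arm's redundancy by placing the elbow in
the vertical plane through the shoulder–wrist line (zero swivel), and
tolerates a 1 mm overshoot at full extension (clamped) because
trunk-lean geometry can push a fully extended target microns outside the
reach sphere.

**Filtering and differentiation.**  Kinematic series are low-passed with
a zero-phase 4th-order Butterworth at 6 Hz (configurable) and
differentiated by central differences (2nd-order one-sided stencils at
the ends).  Jerk for the NDJ uses a direct five-point third-derivative
stencil rather than three repeated first differences: repeated
differencing compounds stencil smoothing and underestimates the
squared-jerk integral by ~8% at 100 Hz, while the direct stencil is
within 1%.  Segmentation uses a wider 12 Hz cutoff: zero-phase smoothing
smears movement edges symmetrically by roughly the filter's
impulse-response width, and boundary detection needs sharp edges more
than a quiet baseline.

## Segmentation

Movement intervals are found by thresholding the end-effector speed at
10% of its peak with a 50 ms hysteresis; sub-threshold dwells shorter
than 200 ms are movement *stops* inside one movement unit rather than
boundaries.  Each boundary is then refined to the nearest speed minimum
below 2% of peak, approximating the physical motion start/stop (the raw
10% crossing on a 1 s minimum-jerk reach is ~86 ms late, which would
defeat any sub-50 ms boundary requirement).  Onset for reaction-time
purposes stays defined as the 10%-of-peak crossing sustained ≥ 50 ms —
the two definitions serve different indicators and are both reported.
Offset is symmetric with onset.

Template matching: moving primitives consume movement intervals in
order; idle/stabilize steps claim the dwell before the next movement and
are valid when it exceeds the 1 s stability rule.  Waypoint arrival is
an end-effector-to-target distance below 3 cm (configurable; the
protocol states no capture radius).  For the drinking task the grasp and
return-transport "at A" are checked against the object's rest spot
(10 cm anterior of A), since the object sits close to, not at, the rest
position.  A trial with fewer movement units than its template returns a
partial segmentation flagged `incomplete` instead of raising, to support
severely impaired users.

Validity: a trial is invalid iff |trunk lean| strictly exceeds 20° in
the sagittal or frontal plane (exactly 20° is valid, "higher than"), or
if trunk data are absent — recording the trunk is itself a protocol
requirement, so absence is a failed check, not a missing feature.

## Kinematic indicators

The "ideal" movement is the straight chord from segment start to target
with a minimum-jerk speed profile v(τ) = (L/D)·30τ²(1−τ)² (peak
1.875·L/D).  Notable concretizations, each configurable and echoed into
the run manifest:

* **Area index** — unsigned shoelace area between the path and its
  chord, in the path's best-fit (SVD) plane; no projection plane is
  prescribed by the scheme.
* **SPARC** — FFT zero-padded to 4× the next power of two, magnitude
  normalized by its peak, 20 Hz cutoff, 0.05 amplitude threshold.
* **Velocity peaks** — maxima above 10% of peak speed, ≥ 100 ms apart.
* **MAPR** — fraction of movement time with speed above 10% of peak;
  the threshold is shared with onset detection on purpose (one constant,
  one meaning).  Minimum-jerk value 1 − 2τ₀ ≈ 0.827.
* **NDJ** — ∫j² dt · D⁵/L² with L the traveled arc length; 720 for the
  minimum-jerk reach.
* **Variable error** — SD of end-point errors across repetitions,
  computed per target direction and pooled (both reported; the scheme
  does not say which).
* **Normalized reaching area** — implemented as max reached distance ÷
  arm length (a distance ratio, per the indicator's description, despite
  the areal name).
* **Trunk compensation** — trunk ÷ hand displacement in the ground X–Y
  (sagittal) plane.
* Elbow "peak extension" is the minimum flexion angle (extension =
  straightening toward q4 = 0).

## EMG processing and indicators

Conditioning: 20–450 Hz band-pass (4th-order Butterworth, zero-phase),
optional 50 Hz harmonic notches, envelopes by full-wave rectification +
5 Hz low-pass (clipped at zero against filter undershoot).  Sampling
below 1000 Hz records a warning and suppresses spectral indicators above
Nyquist.  Normalization is peak-of-trial by default; MVC normalization
is used when an MVC recording is supplied.  All band/window constants
are design choices (the guideline the protocol points to prescribes
electrode placement, not feature parameters) and are echoed in reports.

Feature definitions follow the standard time-domain set (WL, AAC, DASDV,
iEMG, RMS, MAV/activation level, variance, MAV-slope over 3
sub-segments, ZC and SSC with a 10 µV deadband) and Welch-PSD
frequency-domain set (Hann, 512-sample segments, 50% overlap; MNF, MDF,
mean power, exported PSD, frequency ratio with a 20–60 / 60–450 Hz
split, power-spectrum ratio within ±10 Hz of the spectral peak).  Burst
onset: Teager–Kaiser energy, smoothed with a *causal* 50 ms moving
average (a centered window anticipates the burst and biases latencies
early), thresholded at baseline mean + 3 SD sustained ≥ 25 ms.
Co-contraction uses the Falconer–Winter overlap form
CCI = 100·2·Σmin(e₁,e₂)/Σ(e₁+e₂); the agonist/antagonist pair defaults
to biceps/triceps and is set in the worksheet.  Coherence uses 1 s Hann
segments with 50% overlap and reports the 95% confidence level
1 − 0.05^{1/(L−1)}.  Synergies: scikit-learn NMF (multiplicative
updates, 20 seeded restarts, tol 1e-6), rank fixed by the user or the
smallest rank with VAF = 1 − SSE/SST ≥ 0.90; envelopes are decimated to
~50 Hz before factorization (they are 5 Hz band-limited, so this loses
nothing and keeps NMF fast).

## Protocol objects

The worksheet is a pydantic schema with range validation (assistance
∈ [−1, +1], gravity compensation ∈ [0, 1], seatback ∈ [100°, 110°],
repetitions ≥ 8 with default exactly 8) and field-path error messages.
The legacy five-skill listing ("hand to mouth" undivided) expands into
the two variants via an `object_present` flag.  Target layout: reach
distance r = √(arm² − h²) with h the shoulder-to-target vertical drop
(h = 0 at shoulder height ⇒ r = arm length); C is contralateral (−Z,
toward the midline), D ipsilateral, both at ±45° from A–B; the mouth
point E defaults to 0.15 m anterior and 0.25 m above the sternal notch
and is subject-overridable.  Verbal-cue prohibition and self-selected
speed are protocol text, not machine-checked.  Reports aggregate valid
repetitions (mean ± SD), list exclusions with their trunk maxima, flag
uncomputable mandatory indicators prominently, and embed every tunable
constant; identical inputs and seeds reproduce the report byte-for-byte.

## Synthetic trials

The generator emulates the protocol conditions: idle/stabilize dwells of
1.5 s (strictly above the stability rule), transports of 1.0 s at
self-selected speed, 0.5 s pauses where consecutive movements share no
idle step (grasp/release, inter-reach rests), minimum-jerk paths through
the subject's layout, and inverse-kinematics-consistent q0–q7 emitted
alongside the end-effector path.  Impairment knobs: n submovements
(sequential minimum-jerk fragments with 80 ms rests → n velocity peaks,
n−1 stops), reaction delay, trunk lean (ramped within each movement;
moves the shoulder, flagged by the validity rule), path curvature (a
lateral detour shaped by *chordwise progress*, not time, so lateral
velocity vanishes whenever progress pauses and onsets stay
chord-governed), speed scale, EMG co-contraction gain and noise.  Ground
truth records physical segment boundaries, go cues, the analytic
10%-of-peak onset times, and muscle burst latencies.  EMG is
phenomenological — burst envelopes (trapezoidal, 50 ms ramps) from a
fixed muscle-role map modulating a band-limited Gaussian carrier — which
exercises every EMG feature but does not model motor-unit statistics,
volume conduction or electrode artifacts.

Disturbances: payload re-synthesizes the trial from its recorded recipe
with transport durations ×1.1 and scales anti-gravity muscle amplitudes
by (1 + 0.5·mass/kg) — a documented toy model; motor perturbation adds
the specified waveform to the end-effector path, projects samples back
inside the reach sphere, and re-solves the joint stream; cognitive/other
disturbances are recorded verbatim.

**What passing tests show.**  Parameter recovery (boundaries ≤ 50 ms,
reaction ≤ 15 ms, exact peak counts, CCI ordering, synergy cosine
≥ 0.95) demonstrates the pipeline's rules are implemented consistently
with their definitions at the protocol's own scales.  It does not
demonstrate robustness to soft-tissue artifact, marker dropout, EMG
crosstalk or pathological movement outside the impairment model; those
require real recordings.

## Problem sizes and numerical notes

Kinematics at 100 Hz, EMG at 1000 Hz; the acceptance script uses 20
seeded trials across all six skills with four impairment grades, and
1000 Hz minimum-jerk profiles for the analytic values (NDJ converges to
720 within 0.01% there; at 100 Hz the discretization error is ~0.03%).
Degenerate inputs (zero chord, zero variance, single repetition, zero
attempts, silent EMG) yield not-computable indicators with reasons, not
exceptions; mandatory indicators that are not computable trigger a
prominent report warning and a non-zero CLI exit.  Interchange formats
are CSV with JSON sidecars for kinematics and EMG, TSV for segments and
JSON for reports; angles are degrees and positions meters at every I/O
boundary, radians internally.
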