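# Methods

## Overview

`ergoreba` scores musculoskeletal-injury risk from 3D pose-landmark
sequences using the REBA worksheet, frame by frame, and aggregates the
per-frame integer scores into procedure-level means. This note documents
the model, its parameters, the synthetic-data generator, the numerical
choices, and the known limitations.

## Coordinate frame and landmark model

All geometry lives in a right-handed world frame in metres with +Y
opposing gravity; the origin convention is the subject's mid-hip per
frame. A gravity-aligned frame is essential because REBA posture
categories are defined against the vertical (e.g. trunk flexion is
deviation from upright). Pose-estimation backends differ in their native
conventions, so the adapter contract requires conversion before landmarks
enter the pipeline.

The canonical topology is the 33-landmark full-body set popularised by
the BlazePose family. Scoring needs only a core subset (nose, ears,
shoulders, elbows, wrists, hips, knees, ankles); a frame is dropped —
and counted in the report — when any core landmark is missing or has
visibility below `min_visibility` (default 0.5). A file whose frames
mostly lack core landmarks is rejected outright. Sequences are capped at
60 frames/s, the declared maximum processing rate; faster recordings must
be explicitly downsampled.

## Joint-angle extraction

A per-frame anatomical triad is built from the subject's own hips:
`right` along the hip line, `up` the world vertical, `forward`
completing the right-handed triad. Because the triad is intrinsic, every
angle output is invariant to rigid translation and to rotation of the
whole skeleton about the vertical (verified to 1e-6 degrees), and
mirroring the skeleton swaps left/right outputs exactly.

Signed flexion angles use a single-axis convention (extension = negative
flexion). Trunk flexion is the angle of the trunk vector's
*sagittal-plane projection* from the vertical; the lateral component is
reported separately as side-bend. The projection decomposition (rather
than the full 3D angle from vertical) was chosen so that flexion and
side-bend are independent quantities — a laterally leaning trunk does not
register spurious forward flexion — and so that generator round-trips are
exact. Neck flexion is the difference of sagittal angles between the neck
vector (mid-shoulder → mid-ear, nose fallback) and the trunk vector.
Upper-arm elevation is the full 3D angle between the upper arm and the
downward trunk direction, matching how the worksheet's arm diagram is
read; elbow, wrist and knee flexion are 180° minus the interior angle at
the joint.

Boolean posture flags are threshold detections (all configurable,
defaults in degrees / metres):

| flag | rule | default |
|---|---|---|
| trunk/neck twisted | horizontal-plane angle between shoulder line and hip line (ear line and shoulder line) | > 15° |
| trunk/neck side-bent | lateral tilt component | > 10° |
| arm abducted | angular deviation of the upper arm from the sagittal plane | > 20° |
| shoulder raised | shoulder-line tilt with the scored side higher | > 10° |
| unilateral support | ankle height difference | > 0.10 m |

The thresholds are round values consistent with how REBA appraisers read
the worksheet diagrams; they are exposed in `KinematicsConfig` so
sensitivity can be studied. Arm support and wrist deviation/twist are not
reliably observable from body landmarks alone; support defaults to false
(overridable in `ScoringConfig`), and when hand landmarks are absent the
wrist posture is scored with a configurable default of 1, visibly
recorded in the report's config snapshot.

No temporal smoothing is applied by default — frames are scored
independently. An optional centred moving-average window
(`KinematicsConfig.smoothing_window`) exists for noisy video-derived
landmarks.

## REBA scoring

Sub-score categorisation follows the published worksheet: neck 1–3,
trunk 1–5 (with a 5° upright tolerance instead of a knife-edge 0° so
noisy near-vertical postures are not misclassified), legs 1–4, upper arm
1–6, lower arm 1–2, wrist 1–3. Twist/side-bend/abduction/raised-shoulder
add +1 each and arm support subtracts 1; because these adjustments can
push a category past the printed table axis, sub-scores are clamped into
the table domains (floor 1 after the support credit). Tables A
(3×5×4), B (6×2×3) and C (12×12) ship as CSV data files transcribed from
the published worksheet and are checksum-verified at import; an
exhaustive test asserts their ranges, corner cells and monotonicity in
every argument. Score A = Table A + load, Score B = Table B + coupling
computed for both arms with the worse side scored (ties to the right —
conservative for risk screening), REBA = Table C(A, B) + activity,
clamped to [1, 15], then banded (1 negligible, 2–3 low, 4–7 medium, 8–10
high, 11–15 very high).

Defaults for the endoscopy setting: load 0 (an endoscope weighs well
under the 5 kg worksheet threshold), coupling 0 (good handle grip),
activity from the temporal detector or pinned by config.

## Temporal activity detection

The worksheet's activity adjustment is operationalised over a trailing
window (default 60 s): +1 when the posture is static (every tracked angle
spans < 5° across a full-length window), +1 when direction reversals of
any tracked angle exceed 4/min (steps below 1° are ignored as numerical
noise), and +1 when any angle jumps > 30° between consecutive frames;
capped at 3. Windows shorter than the configured length cannot earn the
static bonus. The detector is optional; analyses that should be fully
determined by table lookups pin activity to 0.

## Aggregation

The procedure-level score is the arithmetic mean of per-frame integer
REBA values over scored frames — never the REBA of averaged angles —
along with per-joint mean sub-scores, frame accounting (total, scored,
dropped with reasons) and a full config snapshot. A report is refused
when fewer than 10% of frames scored. Reports are byte-identical across
repeated runs on the same input; this determinism is what makes the
pipeline's internal agreement (average pairwise Spearman rho across
repeated scorings of the same items) exactly 1.

## Validation statistics

Spearman rho uses average ranks for ties and is undefined (an error) for
constant vectors; identical rankings return exactly 1.0 with no
floating-point round-off. Rater agreement is the unweighted mean rho over
all unordered rater pairs, each restricted to commonly scored items;
tool-versus-raters correlation aggregates human raters by per-item
arithmetic mean first. The paired comparison is a two-sided paired
t-test, t = mean(d)/(sd(d)/√n) with the sample (n−1) standard deviation
and n−1 degrees of freedom. Computation delegates to scipy.stats; tests
cross-check against an independent brute-force rank oracle (1e-12) and a
closed-form t at n = 2, and verify type-I-error calibration (10,000
simulated null replicates; empirical rejection rate within ±0.01 of
α = 0.05).

## Synthetic data generator

The generator builds a proportioned skeleton — segment lengths as fixed
fractions of stature from standard anthropometric proportion tables
(trunk 0.288 H, upper arm 0.186 H, forearm 0.146 H, thigh 0.245 H, shank
0.246 H, …) — and applies posture rotations using *exactly the angle
definitions the kinematics module measures*, so noise-free recovery is
exact to floating-point (tested: ≤ 0.5° over 1,000 random postures,
observed worst error ~1e-10). Optional isotropic Gaussian jitter
(`noise_sd_m`) emulates pose-estimator noise. All randomness derives from
a single seed through per-(stream, frame) `SeedSequence` spawn keys, so
any frame's posture is reproducible independently of generation order.

Two scenario distributions emulate the bed-height study conditions:

* `optimal_bed` — near-neutral work: trunk U(0°, 10°), neck U(0°, 15°),
  arms low (elevation U(0°, 15°), elbow U(60°, 100°)), knees U(0°, 10°),
  no twist. Every frame scores REBA ≤ 3.
* `low_bed` — crouched, contorted work: trunk U(25°, 60°) with twist
  U(15°, 35°) in a random direction, neck U(15°, 35°), arm elevation
  U(30°, 70°), elbow U(30°, 130°), wrists U(−30°, 30°), knees
  U(20°, 60°).

These distributions are the package's own construction — no kinematic
measurements of real endoscopists are available — and claim only
*directional* fidelity: the low bed must score systematically worse, as
it does (a 10-subject synthetic cohort spanning statures 160–193 cm,
120 frames per condition, gives a significant paired difference at
α = 0.05). The synthetic cohort's effect size should not be read as an
estimate of the real effect.

### Noise sensitivity

Angular noise scales inversely with segment length: with 5 mm landmark
jitter, the trunk (~0.50 m), upper arm (~0.33 m) and thigh/shank
(~0.43 m each) give per-frame angle errors within 3° in ≥ 95% of frames,
and the tests assert exactly that. The forearm (~0.26 m), hand (~0.19 m)
and ear-to-shoulder neck segment (~0.21 m) are short enough that 5 mm
jitter alone produces errors with σ ≈ 2–2.7°, so no implementation can
keep those angles within 3° for 95% of single frames. For those angles
the guarantee is stated — and tested — after the pipeline's
moving-average smoothing (window 5) on a held posture, which restores
the 3°/95% bound for every angle including elbow and wrist.

## Problem sizes

Default test and reproduction workloads are deliberately modest: 120
frames per scenario, 10 synthetic subjects, 1,000 random postures for
recovery, 10,000 replicates for t-test calibration. All complete in
seconds to a few minutes on a single CPU; the generator and pipeline
scale linearly in frame count for larger studies.

## Known limitations

* Arm support, wrist deviation/twist, and load/coupling cannot be
  inferred from body landmarks; they are config inputs, not detections.
* The twist/side-bend/abduction thresholds are defaults, not calibrated
  constants; real-world use should check sensitivity around them.
* Whether combined twist + side-bend adjustments should be capped before
  or after the table lookup is not specified by the worksheet tradition;
  this implementation clamps after summing, at the table axes.
* Single-subject scenes only; multi-person handling is the adapter's
  responsibility.
* Scoring operates on 3D world landmarks; 2D image-space input is out of
  scope.
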