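# ergoreba

Frame-wise **REBA** (Rapid Entire Body Assessment) ergonomic risk scoring
from 3D human-pose landmarks, built for occupational-ergonomics analysis of
procedural work such as endoscopy.

Endoscopists sustain high rates of work-related musculoskeletal injury, and
conventional ergonomic assessment requires a trained human appraiser to
score still images by hand. `ergoreba` automates the assessment: given a
per-frame sequence of 33 named body landmarks (the BlazePose-style
convention produced by modern pose estimators), it

1. extracts joint angles — neck and trunk flexion/extension, twist and
   side-bend, upper-arm elevation, elbow and wrist flexion, knee flexion
   and weight-bearing asymmetry — in an anatomical frame derived from the
   subject's own hips;
2. categorises each frame through the published REBA worksheet: posture
   sub-scores per joint group, Table A (neck/trunk/legs) + load → Score A,
   Table B (upper arm/lower arm/wrist) + coupling → Score B (worse arm
   scored), Table C(A, B) + activity → the final REBA score 1–15 and its
   action-level risk band (negligible / low / medium / high / very high);
3. averages per-frame scores into a procedure-level mean REBA with
   per-joint mean sub-scores — averaging scores is what yields the familiar
   non-integer procedure values such as 2.58;
4. provides the validation statistics used in this setting: Spearman rank
   agreement between raters or repeated runs, and a paired two-sided
   t-test comparing conditions (e.g. two bed heights).

A synthetic-skeleton generator with exactly known ground-truth angles is a
first-class part of the package: it emulates an endoscopist working at an
optimally positioned bed (5–10 cm below elbow height) versus a low bed
(slightly above knee height), and underpins the kinematic recovery tests.

## Worked example

Generate the two synthetic bed-height scenarios for a 168 cm subject,
score them, and compare:

```sh
ergoreba synth --scenario optimal_bed --subject-height 168 --frames 120 --seed 42 --out opt.json
ergoreba synth --scenario low_bed     --subject-height 168 --frames 120 --seed 42 --out low.json
ergoreba score --landmarks opt.json --out opt_report.json --activity off
# scored 120/120 frames (0 dropped); mean REBA 1.000
ergoreba score --landmarks low.json --out low_report.json --activity off
# scored 120/120 frames (0 dropped); mean REBA 6.242
ergoreba compare --a opt_report.json --b low_report.json
```

The comparison prints

```json
{
 "condition_a": "optimal_bed",
 "condition_b": "low_bed",
 "n_pairs": 120,
 "mean_a": 1.0,
 "mean_b": 6.241666666666666,
 "mean_difference": 5.241666666666666,
 "t_statistic": 42.818857234096185,
 "degrees_of_freedom": 119,
 "p_value": 3.8208135004466944e-74
}
```

i.e. at the optimal bed every frame is at the REBA minimum of 1
(negligible risk), while the crouched, twisted low-bed postures average
6.24 (medium risk, action necessary). The report JSON also carries
per-joint mean sub-scores; for the low-bed run the trunk is the dominant
contributor (`"trunk": 4.0` of a possible 5) followed by the upper arms
(≈ 2.7 of 6).

The same machinery is available as a library:

```python
import ergoreba as eg

seq = eg.make_scenario_sequence(
    eg.ScenarioConfig("low_bed", n_frames=120, seed=42), subject_height_cm=168
)
report = eg.score_sequence(seq, eg.PipelineConfig(activity=eg.ActivityConfig(mode="off")))
print(report.mean_reba)          # 6.241666666666666
print(report.per_joint_means["trunk"])  # 4.0
```

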