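# medreba

Occlusion-resistant REBA (Rapid Entire Body Assessment) scoring from
video-derived pose landmarks, plus a response-surface layer over the
resulting scores.

The pipeline consumes per-frame landmark streams from up to three
time-synchronized cameras (33-point body schema; 478-point face schema for
the camera that sees the face), computes joint angles in each camera's image
plane, estimates the neck angle from six face landmarks via
perspective-n-point head-pose recovery, grades every joint with the REBA
worksheet, fuses the per-joint points across cameras by maximum (so a joint
occluded in one view survives through another), averages the fused points
over time, and assembles the final 1-15 REBA score and risk band.  A
Box-Behnken / linear-regression / desirability-optimization layer models how
the score depends on the neck, trunk, upper-arm and lower-arm points.

## Layout

| module | role |
|---|---|
| `medreba.landmark_io` | landmark data model, JSON-lines/CSV stream I/O, frame-offset synchronization, REBA points tables |
| `medreba.head_pose` | Rodrigues/Euler rotation plumbing, pinhole projection, iterative PnP, neck angle |
| `medreba.joint_angles` | trunk/upper-arm/lower-arm/wrist/knee descriptors with visibility and foreshortening gating |
| `medreba.reba_core` | angle graders, worksheet tables A/B/C, score assembly, risk bands |
| `medreba.fusion_aggregation` | per-instant max fusion, zero-inclusive temporal averaging, end-to-end session assessment |
| `medreba.rsm` | Box-Behnken design, chart-scored responses, OLS fit (R2 / adjusted / PRESS-predicted, ANOVA), desirability optimization |
| `medreba.synth_scene` | synthetic articulated skeleton + head rendered to three ring cameras with seeded noise/occlusion and ground truth |
| `medreba.datasets` | bundled reference tables (18-subject cohort, camera instant, frame series, reference linear model) |

## CLI

```sh
# grade a per-subject points CSV (columns subject,neck,trunk,legs,upper_arm,lower_arm,wrist)
medreba score --points cohort.csv --load 1 --coupling 1 --activity 1 --out report.json

# per-joint maximum fusion of per-camera points tables
medreba fuse --cam A.csv --cam B.csv --cam C.csv --out fused.csv

# full pipeline over a session YAML (landmark streams + config)
medreba assess --session session.yaml --out report.json --offsets 0,2,1

# render a synthetic three-camera scene (JSON-lines streams + ground truth)
medreba simulate --seed 7 --out scenes/

# response-surface workflow
medreba rsm design --out design.csv
medreba rsm score --design design.csv --out scored.csv
medreba rsm fit --design scored.csv --out fit.json
medreba rsm optimize --goal minimize --out opt.json
```

A session YAML names the streams and optional config:

```yaml
streams:
  - {camera: A, body: camA_body.jsonl, face: camA_face.jsonl}
  - {camera: B, body: camB_body.jsonl}
  - {camera: C, body: camC_body.jsonl}
offsets: [0, 2, 1]
config:
  visibility_threshold: 0.5
  adjustments: {load: 1, coupling: 1, activity: 1}
  flags: {wrist_deviated: false}
  neck_reference: absolute
```

## Conventions worth knowing

* Per-joint REBA *points* use 0 as an occlusion sentinel; it is never a valid
  grade and must be removed by fusion or clamping before chart scoring.
* Temporal averaging is zero-inclusive: mean per joint, round half away from
  zero, then clamp to a minimum grade of 1.
* Angles are measured in each camera's 2-D image plane (aspect-corrected);
  the landmark z channel is used only to discard segments that tilt too far
  out of the image plane, whose projected angles would be meaningless.
* Default adjustments are load=coupling=activity=1; graders and bands follow
  the standard REBA worksheet with boundaries inclusive at the lower grade.
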