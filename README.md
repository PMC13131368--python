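# calfface

Facial keypoint phenotyping for dairy calves. Pose-estimation networks
can place anatomical landmarks on a calf's face in ordinary farm video;
what welfare researchers actually want are the traits behind those
landmarks — how long each ear is held forward or back, how often the ears
move, how wide the eyes are open, how far apart the nostrils sit. This
package implements everything downstream of the detector:

* **Evaluation** — object keypoint similarity (OKS) between predicted and
  ground-truth landmarks, swept over thresholds 0.50–0.95 to yield
  precision/recall per threshold, their means (AP, AR), and F1.
* **Phenotyping** — per-frame geometry (law-of-cosines ear angle at the
  ear base, with > 90° classified backward and ≤ 90° frontward; eye
  opening; nostril distance) and temporal aggregation (time in each ear
  posture from the frame rate; ear movements counted only within runs of
  ≥ 20 consecutive frames), with pixel→cm calibration from the animal's
  ear tag, a fiducial of known physical size.
* **Data handling** — COCO-keypoints JSON and YOLO pose text I/O for a
  10-landmark calf-face schema, animal-grouped train/val/test splitting
  with no identity leakage, and Table-style descriptive summaries
  (min / mean / max / SD / CV%).
* **Simulation** — a synthetic head-trajectory generator (rigid template,
  two-state Markov ear dynamics, Gaussian keypoint noise, exact ground
  truth) so the full pipeline is testable without video data.

The OKS score for one instance is

    OKS = Σᵢ exp(−dᵢ² / (2 s² kᵢ²)) · 1[vᵢ>0] / Σᵢ 1[vᵢ>0]

with dᵢ the pixel displacement of keypoint i, s² the object area, kᵢ a
per-keypoint constant (default 0.05) and vᵢ the ground-truth visibility.

## Worked example

```python
import calfface as cf

# simulate a 2-minute session at 1 frame/s with known ground truth
params = cf.HeadModelParams(n_frames=120, seed=7)
observed, truth = cf.simulate_trajectory(params)

# extract per-session traits using the ear-tag calibration
rec = cf.extract_trajectory_phenotypes(observed, truth.calibration)
print(f"nostril_distance_cm   {rec.nostril_distance_cm:.3f}")
print(f"eye_opening_left_cm   {rec.eye_opening_left_cm:.3f}")
print(f"time_front_left_s     {rec.time_front_left_s:.1f}")
print(f"ear_movement_per_window {rec.ear_movement_per_window:.2f}")

# evaluate a degraded copy of the truth as if it were a model prediction
pred = cf.corrupt_keypoints(truth.true_trajectory, 3.0, 0.0, seed=1)
report = cf.evaluate(list(zip(pred.frames, truth.true_trajectory.frames)),
                     schema=cf.CALF_FACE_10)
print(f"AP={report.ap_mean:.3f} AR={report.ar_mean:.3f} F1={report.f1:.3f}")
```

Output:

```
nostril_distance_cm   5.926
eye_opening_left_cm   2.753
time_front_left_s     87.0
ear_movement_per_window 3.42
AP=0.854 AR=0.854 F1=0.854
```

The generator's true nostril distance is 5.93 cm and true left eye
opening 2.75 cm; with 1 px keypoint noise at 12 px/cm the extracted means
land within a few hundredths of a cm. The left ear spent 87 s frontward
and 33 s backward of the 120 s session, and averaged 3.42 posture
transitions per 20-frame window. With 3 px of injected prediction error,
every frame still clears the 0.75 OKS cut (AP@0.75 = 1.000) but the
sweep mean drops to 0.854.

The same stages are available from the shell:

```bash
calfface simulate --n-frames 120 --seed 7 --out-dir session/
calfface phenotype --input session/observed.json --out-dir out/ \
    --tag-size-cm 7.5 --tag-extent-px 90
calfface evaluate --pred session/observed.json --truth session/truth.json \
    --out-dir out/
calfface split --units units.csv --fractions 0.7,0.15,0.15 --seed 3 --out split.csv
```

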