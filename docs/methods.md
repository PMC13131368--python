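# Methods

`calfface` implements the post-detection half of a calf facial-phenotyping
workflow: given per-frame facial keypoints for one animal (produced
upstream by any pose-estimation network), it (a) scores predicted
keypoints against ground truth with object keypoint similarity (OKS), and
(b) converts keypoint trajectories into welfare-related traits — ear
posture and movement, eye opening, nostril distance — with a fiducial
pixel-to-centimeter calibration. Detector training, image handling and
video decoding are explicitly out of scope; the package starts where the
detector's output ends.

## Keypoint model

The canonical schema has 10 facial landmarks: per side, an ear tip, an ear
attachment (base) point, upper and lower eyelid points, and a nostril.
Frames are read from COCO keypoints JSON or YOLO pose text; the YOLO
reader denormalizes to pixels immediately, so all geometry operates in
pixel units (origin top-left, y down, sub-pixel values). COCO visibility
semantics are kept: v=0 absent, v=1 occluded, v=2 visible. Occluded
landmarks are used for geometry but the frame is flagged low-confidence;
absent landmarks make the dependent trait missing rather than raising.
YOLO keypoint confidences are binarized at a configurable threshold
(default 0.5 — the dialect does not carry true visibility).

## OKS evaluation

For a predicted frame against its truth,

    OKS = Σᵢ exp(−dᵢ² / (2 s² kᵢ²)) · 1[vᵢ>0] / Σᵢ 1[vᵢ>0]

with dᵢ the Euclidean pixel displacement, s² the object area and kᵢ a
per-keypoint tolerance. Choices:

* **kᵢ = 0.05 uniform** by default (configurable per label). No
  calf-face constants are established in the literature; 0.05 is of the
  magnitude used for fine facial landmarks, and a uniform value keeps
  labels exchangeable.
* **s²** is the bounding-box area when a bbox is present, else the area of
  the axis-aligned bounding box of the labeled keypoints.
* **Matching**: frames hold a single animal, so each prediction is paired
  with its frame's truth directly — no Hungarian assignment, no
  detection-confidence PR curves. At threshold τ a score ≥ τ is a true
  positive ("within the threshold" is read inclusively), below is a false
  positive; truths without a scored prediction are false negatives. With
  one prediction per truth, per-threshold recall equals precision; both
  are exposed because missed detections can make them diverge.
* **AP/AR** are arithmetic means of per-threshold precision/recall over
  the COCO-style sweep τ ∈ {0.50, 0.55, …, 0.95}; the 0.75 and 0.95 cuts
  are reported by name; F1 is the harmonic mean of AP and AR.

Under this rule precision is necessarily non-increasing in τ; an
aggregation in which AP at 0.95 exceeds AP at 0.75 is not reproducible
from the stated classification rule, so this package implements the rule
literally and makes the per-threshold table available for inspection.

## Geometric traits

* **Ear angle**: law of cosines at the ear *base* — the only head landmark
  among the three and the hinge of ear rotation — in the triangle
  (ear tip, ear base, eye-top of the same side). The eye-top landmark is
  the supra-ocular reference; the 10-point schema has no other candidate.
  The vertex convention is configurable in code should a different
  anatomical reference be preferred. The cosine is clamped to [−1, 1];
  landmark pairs closer than ε = 1e-6 px raise a degenerate-geometry
  error naming the pair.
* **Posture**: backward iff angle > 90°, frontward at or below 90° — the
  boundary case is frontward.
* **Eye opening / nostril distance**: Euclidean distances converted to cm
  by `cm_per_px = tag_size_cm / tag_extent_px`, where the ear tag is the
  fiducial of known physical size and its pixel extent is its larger
  image dimension, supplied by the user or the generator (no visual tag
  detection is performed). Calibration is per-frame when available; the
  default tag size is 7.5 cm, a standard large cattle ear-tag width.

## Temporal traits

Each frame with a defined posture contributes 1/frame_rate seconds to its
posture's time budget (default 1 fps), so `time_front + time_back` equals
the defined-frame count over the frame rate. Ear movements (posture
transitions between consecutive frames) are counted only where at least 20
consecutive defined frames exist: missing postures cut the sequence into
maximal runs, runs shorter than 20 frames yield nothing, and qualifying
runs are tiled with non-overlapping 20-frame windows from the run start
(trailing partials dropped). Tumbling windows prevent double-counting a
transition; a sliding mode is available for sensitivity analyses. No
transition is ever counted across a gap, and no smoothing or interpolation
is applied — interpolation would invent behavior.

## Dataset splitting

`group_split` assigns whole animals to train/val/test so that image-count
proportions approach the targets (70/15/15 by default) with zero identity
leakage: animals are shuffled deterministically by seed, each subset is
seeded with one animal, and remaining animals go greedily to the subset
with the largest image deficit. `holdout_count` rounds `total × fraction`
to the nearest integer and retains the remainder for prediction.

## Descriptive summary

Per-trait rows report min, mean, max, sample SD (n−1 denominator, the norm
for "±SD" reporting) and CV = 100·SD/mean rounded to the nearest integer
percent (missing when the mean is not positive). The phenotype table keeps
left and right ears separate; the summary pools the two ears into single
time-front, time-back and ear-movement rows.

## Synthetic data generator

Real recordings of the study type are not publicly deposited, so the
generator is the test bed. It emits keypoints directly (no images): a
rigid head template in cm — nostrils 5.93 cm apart, eye openings 2.75 cm
(left) and 2.76 cm (right), fixed ear bases — with each ear tip placed by
rotating the base→eye-top direction about the base so the ear angle equals
the current latent state's mean plus Gaussian jitter (SD 5°). Each ear
follows an independent two-state Markov chain (front 60°, back 120°;
p(front→back) = 0.15, p(back→front) = 0.27, giving a stationary front
fraction of ≈ 0.64 and ≈ 3.7 transitions per 20-frame window, plausible
for the study population). The template is scaled at 12 px/cm, centered
in a 640×640 frame with Gaussian camera jitter (SD 3 px), and each
keypoint gets isotropic Gaussian noise (SD 1 px). The ear-tag fiducial is
emitted as `tag_size_cm × scale_px_per_cm` pixels, so calibration is exact
by construction. `corrupt_keypoints` degrades a trajectory into a mock
prediction (Gaussian displacement + random visibility drops) for OKS
tests.

A binary latent state with angular jitter is the minimal structure that
makes every downstream estimator identifiable; it deliberately omits
head yaw and foreshortening, correlated left/right ear motion, detector
failure modes with heavy-tailed errors, and any appearance variation.
Passing tests therefore demonstrate correctness of the computations, not
robustness to real-video nuisance factors.

## Problem sizes and numerical checks

The test suite runs the geometry oracle on 10,000 random triangles, OKS
invariances on 1,000 random instances, and parameter recovery on a
5,000-frame simulation (recovering distance traits within 2% and the
per-window transition rate within 3 Monte-Carlo SE of 19·p_switch, where
p_switch = 2pq/(p+q) is the chain's stationary switch rate). The whole
suite completes in a few seconds on one CPU. All randomness is seeded;
re-running any pipeline with the same inputs and config yields
byte-identical CSVs.

## Known limitations

* Distances assume a fronto-parallel head; yaw shortens measured
  distances and no 3D correction is attempted.
* The ear-tag fiducial is treated as lying in the facial plane; depth
  offset between tag and face biases the scale.
* OKS constants for calf faces are a convention, not an estimate; scores
  are comparable within this package but not across tools using other
  constants.
* The movement count's windowing (tumbling by default) is one of two
  defensible readings of a per-20-s quantification; both are implemented.
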