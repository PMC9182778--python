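# Methods

## Windowing model

A pose estimator reduces each video frame to at most a few skeletons of 17
COCO keypoints, each keypoint a triple (x, y, s) in pixel coordinates
(origin top-left, y increasing downward) with joint score s ∈ [0, 1], plus
an overall detection score per skeleton. The pipeline assumes:

- exactly one person of interest per video; when several people are
  detected in a frame, the skeleton with the highest overall score is the
  volunteer (ties broken by file order). No identity tracking is attempted.
- frames with no detection carry no information and are dropped; the
  retained frames are treated as temporally consecutive for windowing.
  Original frame indices are kept for traceability only.
- frame-level activity labels exist for every frame with a detection
  (vocabulary 1–12; ids 1–5 are falls).

A window of W seconds spans `SWL = round(fps × W)` frames (half-up
rounding; floored at 2 so a window always has distinct endpoints) and
slides one frame at a time, giving `max(0, n − SWL + 1)` windows. Videos
shorter than SWL are skipped with a warning. From each window, S skeleton
positions `offset(k) = ⌊k (SWL−1)/(S−1)⌋` (k = 0…S−1) are selected —
integer truncation, so S = 3 picks the first, middle and last frame — and
their 51-value views concatenated in temporal order (F = 51 × S). The
window label is the mode of its frame labels with ties broken toward the
smallest label id; the smallest-id rule is arbitrary but deterministic, and
favors fall classes, which is the conservative direction for a fall
detector.

The S upper bound is SWL for every window duration, i.e. up to fps × W
skeletons in a 2-second window; with the default grid {0.5, 1, 2} s at
18 fps this yields 8 + 17 + 35 = 60 search candidates.

## Evaluation protocol

"Cross-validation" here is Monte-Carlo: `rounds` (default 10) independent
random 70/30 train/test splits at window level, round r seeded with
`base_seed + r`; a split whose training part misses a class is redrawn
with a seed offset past the per-round seeds, with a warning. Window-level
splitting means overlapping windows from the same video can land in both
train and test; this is deliberate — it is the standard protocol for this
family of methods — but it inflates absolute numbers relative to
video-level splits, and the synthetic generator is designed so that video
identity is not informative (see below).

Classifiers are scikit-learn estimators at library-default
hyperparameters; only the random seeds of the stochastic models (random
forest, MLP, AdaBoost) are pinned, making reports bit-reproducible for a
fixed config. No feature scaling is applied by default;
`ProtocolConfig(standardize=True)` inserts a StandardScaler (useful for
SVM/MLP) and logs that it is active.

Metrics are computed from confusion counts exactly as defined
(percentages): accuracy, precision, recall, specificity, F1. Zero
denominators report 0 with a warning (including the F1 = 0 convention when
precision + recall = 0). Multiclass reports are the global accuracy plus
unweighted macro means of per-class one-vs-rest values; classes absent
from the truth vector are excluded from the macro means with a warning.
Macro averaging (rather than weighted) is used because the datasets of
interest are heavily imbalanced and per-class behaviour is the point of
the analysis.

The exhaustive search maximizes the protocol's mean recall — macro recall
for the multiclass task (the default objective), positive-class recall for
binary — and breaks exact ties toward smaller F, then smaller W,
preferring the cheapest equally-good representation.

## Synthetic data generator

The generator emulates what a pose estimator emits on staged activity
recordings: one volunteer skeleton per frame following an
activity-specific motif, occasional bystanders, occasional empty frames.
Twelve motifs (5 falls, 7 daily activities) are built from five posture
templates (stand, lie, sit, kneel, bend) interpolated linearly along a
keyframe timeline, with optional horizontal drift (walking) and vertical
bobbing (jumping), plus i.i.d. Gaussian keypoint noise (default sd 3 px,
typical estimator jitter). Fall descents take 0.3–0.6 s; deliberate
transitions (sitting, lying down, kneeling) take 0.8–1.6 s. Volunteer
joint scores are U(0.7, 1) and the overall score is their mean;
distractors get the same joint scores but an overall score reduced by a
configurable gap (default 0.3, which makes the highest-score filter
essentially always correct — the generator does not model a bystander
outscoring the volunteer). All randomness flows from one seeded generator
per track; dataset files are byte-stable for a fixed config.

Non-walking activities are performed at a fixed stage point, as in staged
datasets recorded at a marked spot under a fixed camera. This is also a
statistical necessity: a per-video random position would make position a
proxy for video identity, which window-level splits would exploit,
contaminating any windowed-vs-frame comparison.

The `confusable_pair` conditions used for the headline experiment: 18 fps,
4-second videos, a standing lead-in of U(0.5, 1.5) s, then falling
sideways (descent 0.4 s, id 5) or lying down (descent 1.6 s, id 11), both
ending in the same lying posture; 3 videos per class (~210 two-second
windows, ~420 frames). Because the two classes share their endpoint
postures and traverse the same intermediate poses, a single frame is
nearly uninformative, while a 2-second window almost always covers enough
of the descent to expose its duration. Recall therefore rises
monotonically with W, and the 60-candidate exhaustive search selects
W = 2 s. These sizes keep the full search to a few minutes on one CPU
while leaving the effect unambiguous (windowed−baseline recall gap ≈ 30
percentage points against round-to-round sds of ~3).

What the generator does **not** model — perspective and camera motion,
occlusion, pose-estimator failure modes (left/right swaps, missing
limbs), correlated keypoint noise, multi-activity transitions within the
discriminative window, bystanders who outscore the volunteer. Passing
tests on this data therefore validate the pipeline's mechanics and the
temporal-context claim under clean conditions, not performance on real
video.

## Numerical choices and degenerate inputs

- `fps × W` non-integral: rounded half-up (the datasets of interest are
  18 fps where all grid products are integral); SWL floored at 2.
- Offset arithmetic is exact integer division; offsets are strictly
  increasing for any 2 ≤ S ≤ SWL.
- Joint scores outside [0, 1] are clamped with a warning rather than
  rejected (estimators occasionally emit slightly out-of-range scores);
  malformed records (wrong keypoint count, non-numeric score, unparseable
  frame id) are format errors naming the frame.
- Feature tables are written with 17 significant digits and read with
  round-trip float parsing, so CSV round-trips are bit-exact.
- Empty tracks, all-empty videos and too-short videos produce empty
  results (with warnings) rather than errors wherever a downstream pooling
  step can absorb them; operations on genuinely empty inputs (mode of zero
  labels, metrics of an all-zero confusion table) raise.

## Known limitations

- The per-skeleton-prediction variant of window labeling (classify each
  skeleton, then take the mode of predictions) is not implemented; windows
  are labeled from ground-truth frame labels and classified as one
  concatenated vector, the configuration used for all results here.
- Window-level splits leak temporal context between train and test (see
  above); `run_protocol(..., groups=video_ids)` switches to split-by-video
  for honest generalization estimates, but the window-level protocol is the
  default and the one all headline comparisons use.
- The search re-windows the tracks for every candidate; windowing is
  vectorized and negligible next to model fitting at these problem sizes,
  but a cache would help for very large track collections.
- Deep sequence models (e.g. LSTMs) are out of scope; the point of the
  representation is that classical models on concatenated skeletons
  suffice.
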