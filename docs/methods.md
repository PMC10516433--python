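# Methods

This note documents the models, parameters and design choices behind
`beetrack`, and what its synthetic-data tests do and do not demonstrate.

## Data association

The tracker follows the tracking-by-detection paradigm: an upstream
detector produces per-frame bounding boxes (with confidences and,
optionally, appearance descriptors), and the tracker's only job is to
link them into identity-stable tracks.

**Motion model.** Each track carries an 8-dimensional state
(cx, cy, a, h, vcx, vcy, va, vh): box center in pixels, aspect ratio w/h,
box height, and per-frame velocities, filtered by a constant-velocity
Kalman filter with unit frame interval (the detection format carries no
timestamps).  Process and measurement noise standard deviations scale
with the box height h — position weight 1/20·h, velocity weight 1/160·h
by default (`motion.std_weight_position`, `motion.std_weight_velocity`) —
so the filter treats near (large) and far (small) animals consistently.
The motion cost between a track and a detection is the squared
Mahalanobis distance in the 4-dimensional measurement space, using the
innovation covariance S = HPHᵀ + R.  Under the model this statistic is
χ² with 4 degrees of freedom, which fixes the admissibility gate at the
0.95 quantile 9.4877 (`motion.gating_chi2_quantile`); the self-consistency
harness in `motion.simulate_filter_consistency` verifies the calibration
empirically by simulating the filter's own linear-Gaussian model with
noise scales frozen at a reference height (state-dependent noise would
otherwise break the exact χ² law).

**Appearance model.** Each track keeps a rolling gallery of the unit
descriptors of its 100 most recent associated detections; the appearance
cost is the minimum cosine distance between the detection's descriptor
and any gallery member, in [0, 2], gated at 0.25 (`appearance.gate`,
a typical value for cosine-distance gates in this tracker family).
Descriptors normally come from an external re-identification model via a
sidecar file; `appearance.describe` provides a deterministic fallback
(blockwise intensity means plus gradient-orientation histograms on a
95×95 resample, projected to 128 dimensions by a fixed seeded random
projection) so the pipeline runs with no trained model.  The fallback is
a weak descriptor: it distinguishes visually distinct patches, not
individual bumblebees.

**Association.** Per frame, after predicting all tracks:

1. *Appearance cascade.* Confirmed tracks, grouped by ascending frames
   since last update, are matched level by level against the remaining
   detections by minimum-total appearance cost, with the appearance gate
   always applied and the Mahalanobis gate applied only at age 1.  The
   cascade ordering prevents long-occluded tracks from stealing
   detections from currently-tracked animals.
2. *IoU stage.* Tentative tracks and confirmed tracks missed exactly once
   are matched to leftover detections on 1 − IoU (admissible at
   IoU ≥ 0.3).  When both sides carry appearance information the
   appearance gate also applies here: box overlap alone must not overrule
   a clear appearance mismatch, or crossing animals swap identities.
3. *Appearance rescue.* Any still-unmatched track is given a final
   appearance-only chance at the remaining detections.

The rescue stage, and restricting the hard motion gate to age-1 tracks,
are deliberate departures from the pedestrian-tracking convention of
gating every appearance match by motion.  Flying insects violate the
constant-velocity assumption at every saccade — on simulated flights with
realistic accelerations, over half of true continuations fail the χ²
gate under the default noise weights — and the stale prediction after an
occlusion is even less informative.  Appearance is the cue that is
actually reliable for this problem (erratic motion is the stated reason a
motion model alone is insufficient for insects), so motion prioritizes
but never vetoes an unambiguous appearance match.  The appearance gate
(0.25 cosine distance) is what protects against false reclaims; random
or clutter descriptors sit near distance 1.

**Lifecycle.** New tracks are tentative, confirmed after `n_init = 3`
consecutive hits, deleted on any miss while tentative, and deleted after
`max_age = 100` consecutive misses once confirmed — the 100-frame
appearance memory is what allows occlusion recovery.  Output records
carry the associated detection's box, not the Kalman posterior: the
filter state is used for prediction and gating only.  A smoothed box
would lag on curved flight and contaminate triangulation; with this
choice the noise-free reconstruction round trip is exact.  The frames of
a track's tentative phase are emitted retroactively once it confirms, so
a confirmed track covers its whole observed life.

**Confidence threshold.** Detections below `tracker.ct` are discarded
before association.  The threshold is detector-specific and chosen on the
precision–recall curve (`metrics.pr_curve`), favoring precision: a missed
detection behaves like a short occlusion, which the tracker absorbs,
while a false positive can seed a ghost track or steal an update.

## Cross-camera matching

Identities are per-camera; triangulation requires knowing which camera-1
track is which camera-2 (or camera-3) track.  For each candidate pair the
matcher computes, on every shared frame, the epiline l₁ = F·x₂ of the
camera-2 box center and its perpendicular pixel distance to the camera-1
box center, where F is the fundamental matrix assembled from the
calibration (F = [e₁]ₓ P₁ P₂⁺, satisfying x₁ᵀFx₂ = 0).  The largest 10%
of the per-frame distances are dropped — a distribution-free guard
against brief tracking glitches — and the mean of the rest is compared to
an 8 px threshold.  Pairs sharing fewer than `min_overlap = 10` frames
are undefined and never matched: a mean over fewer frames is meaningless
at 8 px precision.  Thresholding alone permits many-to-many matches, so
the boolean matrix is resolved to a one-to-one correspondence by a
minimum-total-mean-distance assignment over the admissible entries;
triangulating conflicting matches would be ill-defined.  Box centers are
the image points throughout: they are the only landmark both views share
semantically.  Frame synchronization across cameras is assumed exact.

## Reconstruction

Matched identity pairs are triangulated frame by frame with the linear
DLT method (SVD of the 4×4 design matrix built from both projection
constraints), without bundle refinement; on noise-free input this is
exact to numerical precision, and with jitter its error is dominated by
stereo geometry, not the solver.  Results live in the camera-1 frame,
which the calibration loader enforces as the world frame (re-expressing
all cameras relative to camera 1 if needed), and keep the camera-1 track
identity so 2D and 3D outputs cross-reference.  Rays meeting at less than
1° are flagged low-confidence.  Short detection gaps (≤ `max_gap = 10`
frames) are closed beforehand by componentwise linear interpolation of
the box parameters; interpolated frames are flagged in the 2D output and
counted per 3D track (`interpolated_fraction`), so downstream analysis
can discount them.  Camera pairs 1–2 and 1–3 are reconstructed
independently and compared per frame (`compare_pairs`); the discrepancy
between them is an internal accuracy estimate that requires no ground
truth.

## Evaluation

`metrics.evaluate` implements the CLEAR protocol: per frame,
correspondences persisting from the previous frame are kept while their
IoU stays ≥ 0.5, the remainder are matched by maximum-cardinality,
maximum-IoU assignment, and fp / fn / identity switches accumulate into
MOTA = 1 − (fp + fn + IDS)/|GT|.  An identity switch is counted when a
ground-truth object's assigned predicted identity differs from the last
identity it ever held (so a switch survives a coverage gap).  A fragment
is an interruption of coverage that later resumes; losing an object for
good is not a fragment.  MOTP is reported as mean IoU over matches (the
convention consistent with reporting MOTP as a percentage next to
IoU-based scores); the misalignment direction 1 − IoU is available via a
flag.  The implementation is cross-checked in the test suite against an
independent naive transliteration of the published protocol on randomized
scenarios.

## Synthetic scenes

The generator reproduces the structure of the target experiment: animals
fly in a 2000×300×300 mm tunnel watched by two top-view cameras (200 mm
baseline) and one side-view camera, all with 1696×1710 px sensors and
1200 px focal length, camera 1 defining the world frame and every tunnel
point projecting inside every image.

- *Flight*: mean-reverting (Ornstein–Uhlenbeck) velocity with stationary
  RMS `speed_scale = 8 mm/frame` per axis and relaxation ~10 frames
  (`damping = 0.1`), plus Poisson-timed impulse turns
  (`turn_rate = 0.02`/frame) that resample the heading outright, and
  reflection at the walls.  8 mm/frame corresponds to roughly 0.25–0.5 m/s
  at common camera rates (30–60 fps) — cruising speed in an obstacle-laden
  tunnel — and the impulse turns reproduce the sudden course changes that
  make insect motion hard to predict.
- *Appearance (projection)*: each animal is a square box of physical side
  35 mm — body plus wing extent, which is what a detector boxes — so
  apparent size scales as f·35/Z and varies with depth.
- *Corruption*: independent per-box misses, Gaussian center/size jitter,
  Poisson clutter with plausible sizes, scheduled occlusions (an animal's
  detections dropped for a frame span), confidences Beta(8,2) for true
  boxes vs Beta(2,4) for clutter (overlapping distributions give a
  nontrivial PR curve), and descriptors drawn per identity: fixed mean
  unit directions pairwise ≥ 60° apart, within-identity angular
  perturbation |N(0, σ)| with σ = 5° by default (wingbeat-scale
  variation), in 128 dimensions.
- Identities are shared across cameras, so the generator is its own
  correspondence and 3D ground-truth oracle.  Everything is deterministic
  given the seeds.

**What the synthetic tests do not show.** Descriptors are simulated in
vector space with a guaranteed between-identity separation; real
re-identification networks on near-identical animals deliver noisier,
less separable embeddings, so passing identity-stability tests here
bounds the association logic, not descriptor quality on real video.
Likewise the clutter model is spatially uniform, while real false
positives (reflections, shadows) correlate with scene structure, and
detection misses are independent rather than burst-correlated.

## Numerical choices and edge cases

- Assignment uses `scipy.optimize.linear_sum_assignment` with infeasible
  pairs mapped to a large finite sentinel and discarded afterwards; a
  tiny index-ordered perturbation makes tie-breaking lexicographic and
  platform-stable.  The solver is verified against exhaustive permutation
  search up to 6×6.
- Boxes are continuous reals end to end; nothing is rounded to pixels,
  preserving sub-pixel triangulation accuracy.
- Frame indices are 1-based in every file and 0-based in memory,
  converted only at I/O boundaries.
- Degenerate inputs fail loudly: non-orthonormal rotations, coincident
  camera centers, duplicate (frame, id) records, normalized coordinates
  outside [0, 1], empty galleries, singular innovation covariances.
  Points at an epipole yield flagged, excluded epilines.  An all-constant
  image patch has no structure to describe and maps to a fixed canonical
  descriptor with a warning.
- Problem sizes in the test and acceptance runs (hundreds of frames, 2–6
  animals, tens to hundreds of seeds per property) are chosen to give
  stable statistics on a single CPU in minutes; all scale linearly if
  larger runs are wanted.

## Known limitations

- The matcher needs tracks to overlap in time and to differ along the
  epipolar geometry; two animals flying at the same tunnel cross-section
  position for an entire overlap window would be ambiguous (the
  one-to-one resolution then picks the smaller mean distance).
- The two stereo reconstructions are reported side by side, never fused;
  fusing them (or bundle-adjusting) is out of scope by design.
- Appearance-descriptor quality is a contract, not a deliverable: with
  descriptors absent the tracker degrades to motion + IoU association,
  which is markedly weaker for erratic fliers.
- The pipeline is frame-recursive (online); no global offline
  optimization over whole trajectories is attempted.
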