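# beetrack

Multi-animal tracking-by-detection and 3D flight-path reconstruction for
insects filmed by a calibrated multi-camera rig.

Tracking several flying bumblebees in the same video is hard for classic
tools: the animals look nearly identical, change appearance with every
wingbeat, maneuver abruptly, and occlude each other. `beetrack`
implements the data-association half of the problem — per-frame detector
output goes in, identity-stable tracks come out — plus everything needed
to turn three synchronized camera views into 3D flight paths:

- a **tracker** combining an appearance-descriptor gallery with a
  constant-velocity Kalman filter.  The appearance cost between track *i*
  and detection *j* is the matching degree
  *d*⁽¹⁾(*i*, *j*) = min<sub>k</sub> {1 − **r**<sub>j</sub>·**r**<sub>k</sub>}
  over the track's gallery of its 100 most recent unit descriptors
  **r**<sub>k</sub>; the motion cost is the squared Mahalanobis distance
  *d*⁽²⁾(*i*, *j*) = (**d**<sub>j</sub> − **y**<sub>i</sub>)ᵀ **S**<sub>i</sub>⁻¹ (**d**<sub>j</sub> − **y**<sub>i</sub>)
  between the detection and the Kalman-predicted measurement, gated at the
  χ²₄ 0.95 quantile (9.4877).  Assignment is solved to optimality per
  frame, cascading over recently-seen tracks first.
- a **cross-camera matcher**: for candidate track pairs the epiline
  **l**₁ = **F** **x**₂ of each camera-2 box center is intersected with the
  camera-1 track; the outlier-trimmed mean point-to-epiline distance,
  thresholded at 8 px, fills a boolean match matrix that is resolved to a
  one-to-one identity correspondence.
- a **reconstructor**: linear (DLT) triangulation of matched box centers
  through camera pairs 1–2 and 1–3, in the camera-1 world frame, with
  linear interpolation of short detection gaps and a discrepancy report
  between the two stereo pairs.
- a **CLEAR-MOT evaluation suite** (fp, fn, IDS, FM, precision, recall,
  MOTA, MOTP) and precision–recall operating-point analysis for choosing
  a detector confidence threshold (precision is deliberately favored over
  recall: the tracker recovers from a missed detection like from a brief
  occlusion, while a false positive can seed or steal a track).
- a **synthetic scene generator** emulating the target setup — insects
  flying in a 2000×300×300 mm tunnel filmed by two top-view cameras and
  one side-view camera — with detection jitter, misses, clutter,
  scheduled occlusions and identity-clustered appearance descriptors, so
  the whole pipeline is testable without any video data.

Detection itself is out of scope: detections arrive as MOT-Challenge-style
CSV files from whatever detector you run upstream, optionally with a
descriptor sidecar file from a re-identification model (a deterministic
hand-crafted descriptor is included as a fallback).

## Worked example

```python
import numpy as np
from beetrack import (SceneConfig, NoiseConfig, simulate_flight, make_rig,
                      project, corrupt, track_sequence, TrackerConfig,
                      fundamental_from_cameras, match_tracks,
                      reconstruct_tracks, evaluate)

rig = make_rig()                                  # camera 1 = world frame
scene = SceneConfig(n_bees=3, n_frames=300, seed=42)
traj = simulate_flight(scene)                     # ground-truth 3D paths, mm
gt = project(traj, rig)                           # exact 2D boxes per camera
noise = NoiseConfig(jitter_px=1.0, miss_rate=0.02, clutter_rate=0.2,
                    descriptor_angle_deg=5.0)
dets, sidecars, _ = corrupt(gt, noise, seed=43)   # detector-like output

tracks = {c: track_sequence(dets[c], TrackerConfig()) for c in (1, 2, 3)}
report = evaluate(gt[1], tracks[1])
print(f"camera 1: MOTA {100*report.mota:.1f}%  MOTP {100*report.motp:.1f}%  "
      f"IDS {report.ids}  fp {report.fp}  fn {report.fn}")

F12 = fundamental_from_cameras(rig[0], rig[1])
m12 = match_tracks(tracks[1], tracks[2], F12)
print("cross-camera identity pairs (cam1, cam2):", m12.pairs())

t12 = reconstruct_tracks(tracks[1], tracks[2], m12, rig[0], rig[1], 12)
for t in t12:
    best = min(range(3), key=lambda b: np.mean(
        np.linalg.norm(traj[b, t.frames] - t.positions, axis=1)))
    rmse = np.sqrt(np.mean(np.sum(
        (traj[best, t.frames] - t.positions) ** 2, axis=1)))
    print(f"identity {t.track_id}: {len(t.frames)} frames, 3D RMSE {rmse:.1f} mm")
```

prints

```
camera 1: MOTA 97.9%  MOTP 86.3%  IDS 0  fp 0  fn 19
cross-camera identity pairs (cam1, cam2): [(1, 1), (2, 2), (3, 3)]
identity 1: 288 frames, 3D RMSE 16.4 mm
identity 2: 288 frames, 3D RMSE 19.9 mm
identity 3: 289 frames, 3D RMSE 18.1 mm
```

With 1 px detection jitter, 2% misses and clutter, the tracker keeps all
three identities (zero switches, no false tracks) and loses only a few
frames; the ~18 mm 3D error is the expected stereo depth uncertainty of
1 px noise on a 200 mm baseline at ~1.6 m range.  On noise-free
detections the same chain is exact to numerical precision.

The same pipeline runs from the shell:

```sh
beetrack --seed 5 simulate --outdir fixtures/
beetrack run --det1 fixtures/det_cam1.csv --det2 fixtures/det_cam2.csv \
    --det3 fixtures/det_cam3.csv --desc1 fixtures/desc_cam1.csv \
    --desc2 fixtures/desc_cam2.csv --desc3 fixtures/desc_cam3.csv \
    --gt1 fixtures/gt_cam1.csv --calib fixtures/calib.yaml --outdir out/
```

Subcommands: `simulate`, `track`, `match`, `reconstruct` (via `run`),
`evaluate`, `prcurve`, `run`.

## File formats

- detections: `frame,id,bb_left,bb_top,bb_width,bb_height,conf,x,y,z`
  (MOT dialect, 1-based frames, unused columns −1); a normalized
  center-format dialect (`yolo_normalized`) is also supported;
- 2D tracks: same layout plus an `interpolated` ∈ {0,1} column;
- 3D tracks: `frame,id,x_mm,y_mm,z_mm,pair`;
- calibration: YAML with per-camera `camera_id, K, R, t, image_size`
  (camera 1 is normalized to the world frame at load time);
- descriptor sidecar: `frame,det_index,v1..vd` with unit-norm rows.
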