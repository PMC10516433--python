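"""Synthetic multi-camera flight scenes for testing the whole pipeline.

The generator emulates the experimental setup the pipeline targets:
several insects flying inside a 2000 x 300 x 300 mm flight tunnel, filmed
by three synchronized cameras — two from above with a lateral baseline,
one from the side.  It produces:

* smooth-but-erratic 3D trajectories (mean-reverting velocity with
  occasional impulse turns, reflected at the tunnel walls);
* a calibrated camera rig, with camera 1 defining the world frame;
* exact projected 2D ground-truth tracks per camera, with apparent box
  size shrinking with distance (pinhole geometry of a fixed physical
  body size);
* corrupted detections: center/size jitter, missed detections, clutter
  boxes, scheduled occlusions, confidence scores drawn from separate
  distributions for true and clutter boxes, and identity-clustered
  unit-vector appearance descriptors with configurable within-identity
  angular noise (standing in for wingbeat-driven appearance variation).

Ground-truth identities are shared across cameras, so the generator is
its own cross-camera correspondence oracle.  Everything is deterministic
given the seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import CameraModel, Detection, TrackRecord2D

__all__ = ["SceneConfig", "NoiseConfig", "simulate_flight", "make_rig",
           "project", "corrupt", "identity_descriptors", "permute_ids",
           "TUNNEL_MM", "RIG_DEPTH_MM"]

TUNNEL_MM = (2000.0, 300.0, 300.0)   # length x width x height of the flight tunnel
RIG_DEPTH_MM = 1500.0                # distance from the top cameras to the tunnel ceiling
IMAGE_SIZE = (1696, 1710)            # px
FOCAL_PX = 1200.0
BODY_SIZE_MM = 35.0                  # apparent extent of one animal incl. wings


@dataclass(frozen=True)
class SceneConfig:
    """Ground-truth scene: how many animals, for how long, moving how."""

    n_bees: int = 3
    n_frames: int = 300
    tunnel: tuple[float, float, float] = TUNNEL_MM
    speed_scale: float = 8.0      # stationary RMS velocity per axis, mm/frame
    turn_rate: float = 0.02       # impulse turns per bee per frame (Poisson)
    damping: float = 0.1          # velocity mean-reversion per frame
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bees <= 0 or self.n_frames <= 0:
            raise ValueError("n_bees and n_frames must be positive")
        if any(v <= 0 for v in self.tunnel):
            raise ValueError("tunnel dimensions must be positive")
        if self.speed_scale < 0 or not (0 < self.damping < 1):
            raise ValueError("invalid motion parameters")


@dataclass(frozen=True)
class NoiseConfig:
    """Detection corruption: what real detectors get wrong."""

    jitter_px: float = 0.0
    miss_rate: float = 0.0
    clutter_rate: float = 0.0
    occlusion: tuple[tuple[int, tuple[int, int]], ...] = ()
    descriptor_angle_deg: float = 0.0
    descriptor_separation_deg: float = 60.0
    descriptor_dim: int = 128

    def __post_init__(self) -> None:
        if not (0.0 <= self.miss_rate <= 1.0):
            raise ValueError("miss_rate must be in [0, 1]")
        if self.jitter_px < 0 or self.clutter_rate < 0:
            raise ValueError("rates must be non-negative")


def _tunnel_bounds(tunnel: tuple[float, float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Tunnel volume in camera-1 coordinates.

    The tunnel axis runs along camera x, its width along camera y, and its
    height along the camera's optical axis z (camera 1 looks straight down
    into it from RIG_DEPTH_MM above the ceiling).
    """
    L, W, H = tunnel
    lo = np.array([-L / 2.0, -W / 2.0, RIG_DEPTH_MM])
    hi = np.array([L / 2.0, W / 2.0, RIG_DEPTH_MM + H])
    return lo, hi


def simulate_flight(cfg: SceneConfig) -> np.ndarray:
    """Simulate (n_bees, n_frames, 3) trajectories in camera-1 mm.

    Velocities follow a mean-reverting (damped random acceleration)
    process whose stationary RMS equals ``speed_scale``; Poisson-timed
    impulse turns resample the velocity direction entirely, mimicking the
    sudden course changes of real flight.  Positions reflect at the
    tunnel walls.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = _tunnel_bounds(cfg.tunnel)
    span = hi - lo
    n, T = cfg.n_bees, cfg.n_frames

    # stationary std of v_{t+1} = (1-damping) v_t + sigma w_t
    a = 1.0 - cfg.damping
    sigma = cfg.speed_scale * np.sqrt(max(1.0 - a * a, 0.0))

    pos = lo + rng.uniform(0.1, 0.9, size=(n, 3)) * span
    vel = rng.standard_normal((n, 3)) * (cfg.speed_scale if cfg.speed_scale > 0 else 0.0)
    out = np.empty((n, T, 3))
    for t in range(T):
        out[:, t] = pos
        vel = a * vel + sigma * rng.standard_normal((n, 3))
        turns = rng.random(n) < cfg.turn_rate
        if np.any(turns):
            speeds = np.linalg.norm(vel[turns], axis=1)
            fresh = rng.standard_normal((turns.sum(), 3))
            fresh /= np.linalg.norm(fresh, axis=1, keepdims=True)
            vel[turns] = fresh * speeds[:, None]
        pos = pos + vel
        # reflect at walls (component-wise)
        for k in range(3):
            under = pos[:, k] < lo[k]
            pos[under, k] = 2 * lo[k] - pos[under, k]
            vel[under, k] *= -1
            over = pos[:, k] > hi[k]
            pos[over, k] = 2 * hi[k] - pos[over, k]
            vel[over, k] *= -1
        pos = np.clip(pos, lo, hi)
    return out


def make_rig(
    image_size: tuple[int, int] = IMAGE_SIZE,
    focal_px: float = FOCAL_PX,
    baseline_mm: float = 200.0,
) -> list[CameraModel]:
    """Default three-camera rig in the camera-1 (world) frame.

    Camera 1 looks down into the tunnel and defines the world frame;
    camera 2 is a second top view offset by ``baseline_mm`` along y;
    camera 3 views the tunnel from the side (its optical axis along
    world +y).  The geometry keeps every point of the default tunnel
    volume inside every image.
    """
    w, h = image_size
    K = np.array([[focal_px, 0.0, w / 2.0],
                  [0.0, focal_px, h / 2.0],
                  [0.0, 0.0, 1.0]])
    cam1 = CameraModel(1, K, np.eye(3), np.zeros(3), image_size)

    C2 = np.array([0.0, baseline_mm, 0.0])
    cam2 = CameraModel(2, K, np.eye(3), -C2, image_size)

    R3 = np.array([[1.0, 0.0, 0.0],
                   [0.0, 0.0, -1.0],
                   [0.0, 1.0, 0.0]])
    C3 = np.array([0.0, -(RIG_DEPTH_MM + 100.0), RIG_DEPTH_MM + TUNNEL_MM[2] / 2.0])
    cam3 = CameraModel(3, K, R3, -R3 @ C3, image_size)
    return [cam1, cam2, cam3]


def project(
    trajectories: np.ndarray,
    cameras: list[CameraModel],
    body_size_mm: float = BODY_SIZE_MM,
) -> dict[int, list[TrackRecord2D]]:
    """Exact 2D ground truth per camera.

    Each animal's center projects through the pinhole model; the box is a
    square of apparent side ``f * body_size / depth`` px, so nearer
    animals appear larger.  Ground-truth identities (1-based animal
    index) are identical across cameras.
    """
    n, T, _ = trajectories.shape
    out: dict[int, list[TrackRecord2D]] = {}
    for cam in cameras:
        recs: list[TrackRecord2D] = []
        for b in range(n):
            pts = trajectories[b]
            cam_pts = pts @ cam.R.T + cam.t
            if np.any(cam_pts[:, 2] <= 0):
                raise ValueError(f"animal {b + 1} behind camera {cam.camera_id}")
            img = cam_pts @ cam.K.T
            centers = img[:, :2] / img[:, 2:3]
            sizes = cam.K[0, 0] * body_size_mm / cam_pts[:, 2]
            for t in range(T):
                s = sizes[t]
                cx, cy = centers[t]
                recs.append(TrackRecord2D(t, b + 1, (cx - s / 2, cy - s / 2, s, s)))
        out[cam.camera_id] = recs
    return out


def identity_descriptors(
    n: int, dim: int, separation_deg: float, seed: int, max_tries: int = 1000
) -> np.ndarray:
    """(n, dim) unit mean directions, pairwise at least ``separation_deg`` apart."""
    rng = np.random.default_rng(seed)
    cos_max = np.cos(np.radians(separation_deg))
    means: list[np.ndarray] = []
    for _ in range(n):
        for _ in range(max_tries):
            v = rng.standard_normal(dim)
            v /= np.linalg.norm(v)
            if all(abs(np.dot(v, m)) <= cos_max for m in means):
                means.append(v)
                break
        else:
            raise RuntimeError(f"could not place {n} directions {separation_deg} deg apart")
    return np.stack(means)


def _perturb_direction(mean: np.ndarray, angle_deg_sigma: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Rotate ``mean`` by |N(0, sigma)| degrees in a random orthogonal direction."""
    if angle_deg_sigma == 0.0:
        return mean.copy()
    theta = abs(rng.normal(0.0, np.radians(angle_deg_sigma)))
    u = rng.standard_normal(mean.shape[0])
    u -= np.dot(u, mean) * mean
    norm = np.linalg.norm(u)
    if norm < 1e-12:
        return mean.copy()
    u /= norm
    return np.cos(theta) * mean + np.sin(theta) * u


def corrupt(
    gt: dict[int, list[TrackRecord2D]],
    noise: NoiseConfig,
    seed: int,
) -> tuple[dict[int, dict[int, list[Detection]]],
           dict[int, dict[tuple[int, int], np.ndarray]],
           np.ndarray]:
    """Corrupt ground truth into detector-like output for every camera.

    Returns ``(detections, sidecars, identity_means)``:

    * detections: camera_id -> frame -> list of Detection (descriptors
      attached);
    * sidecars: camera_id -> (frame, det_index) -> descriptor, the
      external-descriptor file content;
    * identity_means: the per-identity mean descriptor directions.

    True boxes survive with probability ``1 - miss_rate`` (scheduled
    occlusions drop an animal's boxes outright), get Gaussian jitter on
    center and size, a confidence from Beta(8, 2), and a descriptor drawn
    around their identity's mean direction.  Clutter boxes arrive at a
    Poisson rate with uniform placement, plausible random size,
    confidence from Beta(2, 4), and an unclustered random descriptor.
    """
    rng = np.random.default_rng(seed)
    ids = sorted({r.track_id for recs in gt.values() for r in recs})
    means = identity_descriptors(len(ids), noise.descriptor_dim,
                                 noise.descriptor_separation_deg, seed + 1)
    mean_of = {tid: means[i] for i, tid in enumerate(ids)}
    occluded = {(bee, f) for bee, (f0, f1) in noise.occlusion for f in range(f0, f1 + 1)}

    detections: dict[int, dict[int, list[Detection]]] = {}
    sidecars: dict[int, dict[tuple[int, int], np.ndarray]] = {}
    for cam_id, recs in gt.items():
        frames: dict[int, list[Detection]] = {}
        n_frames = max((r.frame_index for r in recs), default=-1) + 1
        for f in range(n_frames):
            frames[f] = []
        for rec in recs:
            if (rec.track_id, rec.frame_index) in occluded:
                continue
            if rng.random() < noise.miss_rate:
                continue
            left, top, w, h = rec.box
            if noise.jitter_px > 0:
                dx, dy, dw, dh = rng.normal(0.0, noise.jitter_px, 4)
                left, top = left + dx, top + dy
                w, h = max(w + dw, 1.0), max(h + dh, 1.0)
            conf = float(rng.beta(8, 2))
            desc = _perturb_direction(mean_of[rec.track_id],
                                      noise.descriptor_angle_deg, rng)
            desc /= np.linalg.norm(desc)
            frames[rec.frame_index].append(
                Detection(rec.frame_index, (left, top, w, h), conf, desc))
        # clutter
        if noise.clutter_rate > 0:
            sizes = np.array([max(r.box[2], 1.0) for r in recs]) if recs else np.array([20.0])
            for f in range(n_frames):
                for _ in range(rng.poisson(noise.clutter_rate)):
                    s = float(rng.uniform(0.5, 1.5) * np.median(sizes))
                    cx = rng.uniform(0, 1696)
                    cy = rng.uniform(0, 1710)
                    conf = float(rng.beta(2, 4))
                    desc = rng.standard_normal(noise.descriptor_dim)
                    desc /= np.linalg.norm(desc)
                    frames[f].append(
                        Detection(f, (cx - s / 2, cy - s / 2, s, s), conf, desc))
        sidecar = {}
        for f, dets in frames.items():
            for j, det in enumerate(dets):
                sidecar[(f, j)] = det.descriptor
        detections[cam_id] = frames
        sidecars[cam_id] = sidecar
    return detections, sidecars, means


def permute_ids(records: list[TrackRecord2D], mapping: dict[int, int]) -> list[TrackRecord2D]:
    """Relabel track identities (used to scramble the correspondence)."""
    return [TrackRecord2D(r.frame_index, mapping[r.track_id], r.box, r.flag_interpolated)
            for r in records]
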