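"""Triangulation of matched 2D track pairs into 3D flight paths.

The three cameras combine into the stereo pairs 1-2 and 1-3; each pair
independently triangulates the box centers of a matched identity pair on
every common frame, giving two alternative 3D trajectories per animal in
the camera-1 (world) frame that can be compared against each other as an
internal consistency check.  Short detection gaps in the 2D tracks are
closed beforehand by linear interpolation of the box parameters, with
interpolated frames flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import CameraModel, TrackRecord2D, TrackRecord3D
from .multicam import MatchMatrix

__all__ = ["Track3D", "interpolate_gaps", "triangulate_point",
           "reconstruct_tracks", "compare_pairs", "PairComparison"]

logger = logging.getLogger(__name__)

# rays closer to parallel than this are flagged low-confidence
MIN_RAY_ANGLE_DEG = 1.0


@dataclass
class Track3D:
    track_id: int
    frames: list[int]
    positions: np.ndarray          # (n, 3) mm, camera-1 frame
    source_pair: int               # 12 or 13
    interpolated_fraction: float = 0.0

    def records(self) -> list[TrackRecord3D]:
        return [TrackRecord3D(f, self.track_id, tuple(p), self.source_pair)
                for f, p in zip(self.frames, self.positions)]


def interpolate_gaps(track: list[TrackRecord2D], max_gap: int = 10) -> list[TrackRecord2D]:
    """Close detection gaps of at most ``max_gap`` missing frames by
    componentwise linear interpolation of the box; longer gaps stay open.
    """
    recs = sorted(track, key=lambda r: r.frame_index)
    if not recs:
        return []
    out = [recs[0]]
    for prev, nxt in zip(recs, recs[1:]):
        gap = nxt.frame_index - prev.frame_index - 1
        if 0 < gap <= max_gap:
            b0 = np.asarray(prev.box)
            b1 = np.asarray(nxt.box)
            for k in range(1, gap + 1):
                alpha = k / (gap + 1)
                box = tuple((1 - alpha) * b0 + alpha * b1)
                out.append(TrackRecord2D(prev.frame_index + k, prev.track_id, box, True))
        out.append(nxt)
    return out


def triangulate_point(
    cam_a: CameraModel, cam_b: CameraModel,
    x_a: np.ndarray, x_b: np.ndarray,
) -> tuple[np.ndarray, float, bool]:
    """Linear (DLT) triangulation of a pixel correspondence.

    Solves the two projection constraints in the least-squares sense via
    SVD of the 4x4 design matrix.  Returns ``(X, residual, ok)`` with
    ``X`` in the world (camera-1) frame in mm, ``residual`` the RMS
    reprojection error in px, and ``ok`` False when the viewing rays are
    nearly parallel (angle below 1 degree), i.e. the depth is poorly
    constrained.
    """
    P_a, P_b = cam_a.projection_matrix, cam_b.projection_matrix
    xa, ya = float(x_a[0]), float(x_a[1])
    xb, yb = float(x_b[0]), float(x_b[1])
    A = np.stack([
        xa * P_a[2] - P_a[0],
        ya * P_a[2] - P_a[1],
        xb * P_b[2] - P_b[0],
        yb * P_b[2] - P_b[1],
    ])
    _, _, Vt = np.linalg.svd(A)
    Xh = Vt[-1]
    if abs(Xh[3]) < 1e-15:
        raise ValueError("triangulation degenerate: point at infinity")
    X = Xh[:3] / Xh[3]

    # ray-parallelism check
    ray_a = X - cam_a.center
    ray_b = X - cam_b.center
    cosang = np.dot(ray_a, ray_b) / (np.linalg.norm(ray_a) * np.linalg.norm(ray_b))
    ok = np.degrees(np.arccos(np.clip(abs(cosang), 0.0, 1.0))) >= MIN_RAY_ANGLE_DEG

    resid = 0.0
    for cam, x in ((cam_a, (xa, ya)), (cam_b, (xb, yb))):
        proj = cam.project(X[None, :])[0]
        resid += float(np.sum((proj - np.asarray(x)) ** 2))
    return X, float(np.sqrt(resid / 2.0)), bool(ok)


def reconstruct_tracks(
    tracks_1: list[TrackRecord2D],
    tracks_other: list[TrackRecord2D],
    match: MatchMatrix,
    cam_1: CameraModel,
    cam_other: CameraModel,
    pair_label: int,
) -> list[Track3D]:
    """Triangulate every matched identity pair on every common frame.

    3D tracks keep the camera-1 identity so 2D and 3D outputs
    cross-reference.
    """
    by_id_1: dict[int, dict[int, TrackRecord2D]] = {}
    for rec in tracks_1:
        by_id_1.setdefault(rec.track_id, {})[rec.frame_index] = rec
    by_id_2: dict[int, dict[int, TrackRecord2D]] = {}
    for rec in tracks_other:
        by_id_2.setdefault(rec.track_id, {})[rec.frame_index] = rec

    out: list[Track3D] = []
    for id1, id2 in match.pairs():
        t1, t2 = by_id_1.get(id1, {}), by_id_2.get(id2, {})
        common = sorted(set(t1) & set(t2))
        if not common:
            logger.warning("matched pair (%d, %d) shares no frames: skipped", id1, id2)
            continue
        positions = []
        n_interp = 0
        for f in common:
            X, _, ok = triangulate_point(
                cam_1, cam_other, np.asarray(t1[f].center), np.asarray(t2[f].center))
            if not ok:
                logger.warning("low-confidence triangulation id %d frame %d", id1, f)
            positions.append(X)
            if t1[f].flag_interpolated or t2[f].flag_interpolated:
                n_interp += 1
        out.append(Track3D(id1, common, np.asarray(positions), pair_label,
                           n_interp / len(common)))
    return out


@dataclass(frozen=True)
class PairComparison:
    """Per-identity discrepancy between the two stereo pairs (mm)."""

    per_identity: dict[int, dict]       # id -> {mean, median, max, n_frames}
    uncompared: list[int]               # ids present in only one pair


def compare_pairs(tracks_12: list[Track3D], tracks_13: list[Track3D]) -> PairComparison:
    """Per-frame Euclidean distance between the two pairs' estimates."""
    m12 = {t.track_id: t for t in tracks_12}
    m13 = {t.track_id: t for t in tracks_13}
    per_identity: dict[int, dict] = {}
    uncompared = sorted(set(m12) ^ set(m13))
    for tid in sorted(set(m12) & set(m13)):
        a, b = m12[tid], m13[tid]
        fa = {f: p for f, p in zip(a.frames, a.positions)}
        fb = {f: p for f, p in zip(b.frames, b.positions)}
        common = sorted(set(fa) & set(fb))
        if not common:
            uncompared.append(tid)
            continue
        d = np.array([np.linalg.norm(fa[f] - fb[f]) for f in common])
        per_identity[tid] = {
            "mean": float(d.mean()), "median": float(np.median(d)),
            "max": float(d.max()), "n_frames": len(common),
        }
    return PairComparison(per_identity, sorted(uncompared))
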