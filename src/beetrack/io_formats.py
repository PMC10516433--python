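"""File formats and camera geometry shared by the whole pipeline.

Everything the pipeline reads or writes goes through this module: per-frame
detections (MOT-Challenge CSV or normalized YOLO rows), 2D track CSVs,
3D track CSVs and the camera calibration document.  Conventions enforced
at every boundary:

* frame indices are 1-based in files and 0-based in memory;
* bounding boxes are ``(left, top, width, height)`` in pixels with the
  origin at the image's top-left corner, stored as continuous reals;
* the world coordinate frame is the frame of camera 1 — calibration
  loading re-expresses every camera relative to camera 1.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "Detection",
    "CameraModel",
    "TrackRecord2D",
    "TrackRecord3D",
    "read_detections",
    "write_detections",
    "read_tracks_2d",
    "write_tracks_2d",
    "read_tracks_3d",
    "write_tracks_3d",
    "read_calibration",
    "write_calibration",
    "fundamental_from_cameras",
    "read_descriptor_sidecar",
    "write_descriptor_sidecar",
]


@dataclass(frozen=True)
class Detection:
    """One frame-local observation of an animal.

    ``box`` is ``(left, top, width, height)`` in pixels; ``descriptor``
    is an optional unit-norm appearance vector.
    """

    frame_index: int
    box: tuple[float, float, float, float]
    confidence: float
    descriptor: np.ndarray | None = None

    def __post_init__(self) -> None:
        left, top, w, h = self.box
        if not (w > 0 and h > 0):
            raise ValueError(f"non-positive box dimensions {self.box!r}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        if self.descriptor is not None:
            norm = float(np.linalg.norm(self.descriptor))
            if abs(norm - 1.0) > 1e-9:
                raise ValueError(f"descriptor norm {norm} != 1")

    @property
    def center(self) -> tuple[float, float]:
        left, top, w, h = self.box
        return (left + w / 2.0, top + h / 2.0)


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera: ``x ~ K (R X + t)`` with ``X`` in world mm."""

    camera_id: int
    K: np.ndarray
    R: np.ndarray
    t: np.ndarray
    image_size: tuple[int, int]  # (width, height) px

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float).reshape(3, 3)
        R = np.asarray(self.R, dtype=float).reshape(3, 3)
        t = np.asarray(self.t, dtype=float).reshape(3)
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)
        if np.linalg.norm(R @ R.T - np.eye(3)) > 1e-6:
            raise ValueError(f"camera {self.camera_id}: R is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError(f"camera {self.camera_id}: det(R) != +1")
        if np.any(np.abs(K[np.tril_indices(3, -1)]) > 1e-12) or np.any(np.diag(K)[:2] <= 0):
            raise ValueError(f"camera {self.camera_id}: K not upper-triangular with positive diagonal")

    @property
    def projection_matrix(self) -> np.ndarray:
        """3x4 matrix ``P = K [R | t]``."""
        return self.K @ np.hstack([self.R, self.t.reshape(3, 1)])

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates (mm)."""
        return -self.R.T @ self.t

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project world points (n, 3) mm to pixel coordinates (n, 2)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cam = pts @ self.R.T + self.t
        if np.any(cam[:, 2] <= 0):
            raise ValueError("point behind camera")
        img = cam @ self.K.T
        return img[:, :2] / img[:, 2:3]


@dataclass(frozen=True)
class TrackRecord2D:
    frame_index: int
    track_id: int
    box: tuple[float, float, float, float]
    flag_interpolated: bool = False

    @property
    def center(self) -> tuple[float, float]:
        left, top, w, h = self.box
        return (left + w / 2.0, top + h / 2.0)


@dataclass(frozen=True)
class TrackRecord3D:
    frame_index: int
    track_id: int
    position: tuple[float, float, float]  # mm, camera-1 frame
    source_pair: int  # 12 or 13


# ---------------------------------------------------------------------------
# detections


def read_detections(
    path: str | Path,
    dialect: str = "mot",
    image_size: tuple[int, int] | None = None,
) -> dict[int, list[Detection]]:
    """Read per-frame detections.

    ``mot`` rows: ``frame,id,bb_left,bb_top,bb_width,bb_height,conf,...``
    (1-based frames).  ``yolo_normalized`` rows:
    ``frame,class,x_center,y_center,width,height,conf`` with coordinates
    normalized by image width/height; requires ``image_size``.
    """
    if dialect not in ("mot", "yolo_normalized"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "yolo_normalized" and image_size is None:
        raise ValueError("yolo_normalized dialect requires image_size")
    frames: dict[int, list[Detection]] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            try:
                if dialect == "mot":
                    frame = int(float(row[0]))
                    left, top, w, h = (float(v) for v in row[2:6])
                    conf = float(row[6]) if len(row) > 6 else 1.0
                else:
                    frame = int(float(row[0]))
                    xc, yc, wn, hn = (float(v) for v in row[2:6])
                    conf = float(row[6]) if len(row) > 6 else 1.0
                    for v in (xc, yc, wn, hn):
                        if not (0.0 <= v <= 1.0):
                            raise ValueError(f"normalized coordinate {v} outside [0, 1]")
                    iw, ih = image_size  # type: ignore[misc]
                    w, h = wn * iw, hn * ih
                    left, top = xc * iw - w / 2.0, yc * ih - h / 2.0
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            det = Detection(frame_index=frame - 1, box=(left, top, w, h), confidence=conf)
            frames.setdefault(frame - 1, []).append(det)
    return frames


def write_detections(frames: dict[int, list[Detection]], path: str | Path) -> None:
    """Write detections in the MOT dialect (unused columns are -1)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for frame in sorted(frames):
            for det in frames[frame]:
                left, top, w, h = det.box
                writer.writerow(
                    [frame + 1, -1, f"{left:.6f}", f"{top:.6f}", f"{w:.6f}", f"{h:.6f}",
                     f"{det.confidence:.6f}", -1, -1, -1]
                )


# ---------------------------------------------------------------------------
# 2D tracks

_TRACKS2D_HEADER = ["frame", "id", "bb_left", "bb_top", "bb_width", "bb_height",
                    "conf", "x", "y", "z", "interpolated"]


def write_tracks_2d(tracks: Sequence[TrackRecord2D], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TRACKS2D_HEADER)
        for rec in sorted(tracks, key=lambda r: (r.frame_index, r.track_id)):
            left, top, w, h = rec.box
            writer.writerow(
                [rec.frame_index + 1, rec.track_id, f"{left:.6f}", f"{top:.6f}",
                 f"{w:.6f}", f"{h:.6f}", 1, -1, -1, -1, int(rec.flag_interpolated)]
            )


def read_tracks_2d(path: str | Path) -> list[TrackRecord2D]:
    records: list[TrackRecord2D] = []
    seen: set[tuple[int, int]] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0] == "frame":
                continue
            try:
                frame = int(row[0]) - 1
                tid = int(row[1])
                box = tuple(float(v) for v in row[2:6])
                interp = bool(int(row[10])) if len(row) > 10 else False
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            key = (frame, tid)
            if key in seen:
                raise ValueError(f"{path}: duplicate (frame, id) {key} at line {lineno}")
            seen.add(key)
            records.append(TrackRecord2D(frame, tid, box, interp))  # type: ignore[arg-type]
    return records


# ---------------------------------------------------------------------------
# 3D tracks

_TRACKS3D_HEADER = ["frame", "id", "x_mm", "y_mm", "z_mm", "pair"]


def write_tracks_3d(tracks: Sequence[TrackRecord3D], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TRACKS3D_HEADER)
        for rec in sorted(tracks, key=lambda r: (r.source_pair, r.track_id, r.frame_index)):
            x, y, z = rec.position
            writer.writerow([rec.frame_index + 1, rec.track_id,
                             f"{x:.3f}", f"{y:.3f}", f"{z:.3f}", rec.source_pair])


def read_tracks_3d(path: str | Path) -> list[TrackRecord3D]:
    records: list[TrackRecord3D] = []
    seen: set[tuple[int, int, int]] = set()
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or row[0] == "frame":
                continue
            try:
                frame = int(row[0]) - 1
                tid = int(row[1])
                pos = tuple(float(v) for v in row[2:5])
                pair = int(row[5])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            key = (frame, tid, pair)
            if key in seen:
                raise ValueError(f"{path}: duplicate (frame, id, pair) {key} at line {lineno}")
            seen.add(key)
            records.append(TrackRecord3D(frame, tid, pos, pair))  # type: ignore[arg-type]
    return records


# ---------------------------------------------------------------------------
# calibration


def _camera_to_dict(cam: CameraModel) -> dict:
    return {
        "camera_id": cam.camera_id,
        "K": [float(v) for v in cam.K.ravel()],
        "R": [float(v) for v in cam.R.ravel()],
        "t": [float(v) for v in cam.t.ravel()],
        "image_size": [int(cam.image_size[0]), int(cam.image_size[1])],
    }


def write_calibration(cameras: Sequence[CameraModel], path: str | Path) -> None:
    doc = {"cameras": [_camera_to_dict(c) for c in cameras]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_calibration(path: str | Path) -> list[CameraModel]:
    """Load a calibration document and normalize to the camera-1 frame.

    If camera 1's pose is not already the identity, every camera (and hence
    every triangulated point) is re-expressed relative to camera 1, which
    serves as the global coordinate system.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "cameras" not in doc:
        raise ValueError(f"{path}: expected a document with a 'cameras' list")
    cams = []
    for entry in doc["cameras"]:
        cams.append(
            CameraModel(
                camera_id=int(entry["camera_id"]),
                K=np.asarray(entry["K"], dtype=float).reshape(3, 3),
                R=np.asarray(entry["R"], dtype=float).reshape(3, 3),
                t=np.asarray(entry["t"], dtype=float).reshape(3),
                image_size=tuple(int(v) for v in entry["image_size"]),  # type: ignore[arg-type]
            )
        )
    cams.sort(key=lambda c: c.camera_id)
    ref = next((c for c in cams if c.camera_id == 1), None)
    if ref is None:
        raise ValueError(f"{path}: no camera with camera_id 1")
    if np.allclose(ref.R, np.eye(3), atol=1e-12) and np.allclose(ref.t, 0, atol=1e-12):
        return cams
    # re-express: X' = R1 X + t1  =>  x_i = (R_i R1^T) X' + (t_i - R_i R1^T t1)
    R1, t1 = ref.R, ref.t
    out = []
    for cam in cams:
        R_new = cam.R @ R1.T
        t_new = cam.t - R_new @ t1
        out.append(CameraModel(cam.camera_id, cam.K, R_new, t_new, cam.image_size))
    return out


def fundamental_from_cameras(cam_a: CameraModel, cam_b: CameraModel) -> np.ndarray:
    """Fundamental matrix F with ``x_a^T F x_b = 0`` for homogeneous pixels.

    Computed as ``F = [e_a]_x P_a P_b^+`` where ``e_a`` is the epipole
    (projection of camera b's center into camera a).
    """
    center_b = cam_b.center
    if np.linalg.norm(center_b - cam_a.center) < 1e-9:
        raise ValueError("coincident camera centers: epipolar geometry undefined")
    P_a, P_b = cam_a.projection_matrix, cam_b.projection_matrix
    e_a = P_a @ np.append(center_b, 1.0)
    ex = np.array([[0, -e_a[2], e_a[1]],
                   [e_a[2], 0, -e_a[0]],
                   [-e_a[1], e_a[0], 0]])
    F = ex @ P_a @ np.linalg.pinv(P_b)
    # fix scale for reproducibility
    norm = np.linalg.norm(F)
    if norm == 0:
        raise ValueError("degenerate camera pair")
    return F / norm


# ---------------------------------------------------------------------------
# descriptor sidecar


def write_descriptor_sidecar(
    descriptors: dict[tuple[int, int], np.ndarray], path: str | Path
) -> None:
    """Write per-detection descriptors, keyed by (frame_index, det_index)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for (frame, det_index) in sorted(descriptors):
            vec = descriptors[(frame, det_index)]
            writer.writerow([frame + 1, det_index] + [f"{v:.9f}" for v in vec])


def read_descriptor_sidecar(path: str | Path) -> dict[tuple[int, int], np.ndarray]:
    out: dict[tuple[int, int], np.ndarray] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row:
                continue
            try:
                frame = int(row[0]) - 1
                det_index = int(row[1])
                vec = np.asarray([float(v) for v in row[2:]], dtype=float)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            norm = np.linalg.norm(vec)
            if norm == 0:
                raise ValueError(f"{path}: zero descriptor at line {lineno}")
            out[(frame, det_index)] = vec / norm
    return out
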