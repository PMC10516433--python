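"""Cross-camera identity matching by epiline-point distances.

Tracks carry camera-local identities; triangulation needs to know which
identity in camera 1 is the same animal as which identity in camera 2
(or 3).  For a candidate pair of tracks the matcher computes, on every
frame the two tracks share, the epiline in camera 1 of the camera-2 box
center, ``l1 = F x2``, and the perpendicular distance of the camera-1 box
center from that line.  For a genuine correspondence this distance is
near zero on every frame; for distinct animals it is large on most.  The
largest 10% of the per-frame distances are discarded (robustness to brief
tracking glitches) and the mean of the rest is thresholded at 8 px to
fill a boolean match matrix, which is then resolved to a one-to-one
correspondence by minimum-total-distance assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .association import solve_assignment
from .io_formats import TrackRecord2D

__all__ = ["MatchMatrix", "epilines", "point_line_distance",
           "track_pair_distance", "match_tracks", "MATCH_THRESHOLD_PX"]

logger = logging.getLogger(__name__)

MATCH_THRESHOLD_PX = 8.0          # empirically appropriate epiline-distance gate
DEFAULT_OUTLIER_FRACTION = 0.1
DEFAULT_MIN_OVERLAP = 10          # frames


def epilines(F: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Epilines ``l = F x`` for pixel points (n, 2), normalized to a^2+b^2=1.

    A zero line (the point maps to the epipole image) yields a NaN row,
    flagged for exclusion downstream.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    hom = np.hstack([pts, np.ones((len(pts), 1))])
    lines = hom @ F.T
    scale = np.hypot(lines[:, 0], lines[:, 1])
    bad = scale < 1e-12
    if np.any(bad):
        logger.warning("%d point(s) at the epipole image: epiline undefined", bad.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        lines = lines / scale[:, None]
    lines[bad] = np.nan
    return lines


def point_line_distance(line: np.ndarray, point: np.ndarray) -> float:
    """Perpendicular distance (px) of a point from a normalized line."""
    a, b, c = line
    x, y = point
    return abs(a * x + b * y + c)


def _centers_by_frame(track: list[TrackRecord2D]) -> dict[int, np.ndarray]:
    return {rec.frame_index: np.asarray(rec.center) for rec in track}


def track_pair_distance(
    track_1: list[TrackRecord2D],
    track_2: list[TrackRecord2D],
    F: np.ndarray,
    outlier_fraction: float = DEFAULT_OUTLIER_FRACTION,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> float | None:
    """Outlier-trimmed mean epiline distance between two tracks, or None.

    ``F`` must satisfy ``x1^T F x2 = 0``; image points are box centers.
    Returns None (undefined) when the tracks share fewer than
    ``min_overlap`` frames.
    """
    c1 = _centers_by_frame(track_1)
    c2 = _centers_by_frame(track_2)
    common = sorted(set(c1) & set(c2))
    if len(common) < min_overlap:
        return None
    p1 = np.array([c1[f] for f in common])
    p2 = np.array([c2[f] for f in common])
    lines = epilines(F, p2)
    valid = ~np.isnan(lines[:, 0])
    if valid.sum() < min_overlap:
        return None
    d = np.abs(np.einsum("ij,ij->i", lines[valid, :2], p1[valid]) + lines[valid, 2])
    n_drop = int(len(d) * outlier_fraction)
    if n_drop > 0:
        d = np.sort(d)[: len(d) - n_drop]
    return float(np.mean(d))


@dataclass(frozen=True)
class MatchMatrix:
    """Boolean identity correspondence between two cameras' track sets."""

    ids_1: list[int]
    ids_2: list[int]
    entries: np.ndarray         # bool, resolved one-to-one
    raw_entries: np.ndarray     # bool, pre-resolution thresholding
    mean_distances: np.ndarray  # px; NaN where undefined

    def pairs(self) -> list[tuple[int, int]]:
        """Matched (id_1, id_2) pairs."""
        out = []
        for i, j in zip(*np.nonzero(self.entries)):
            out.append((self.ids_1[i], self.ids_2[j]))
        return sorted(out)

    def as_mapping(self) -> dict[int, int]:
        return dict(self.pairs())


def _group_by_id(records: list[TrackRecord2D]) -> dict[int, list[TrackRecord2D]]:
    groups: dict[int, list[TrackRecord2D]] = {}
    for rec in records:
        groups.setdefault(rec.track_id, []).append(rec)
    return groups


def match_tracks(
    tracks_1: list[TrackRecord2D],
    tracks_2: list[TrackRecord2D],
    F: np.ndarray,
    threshold: float = MATCH_THRESHOLD_PX,
    outlier_fraction: float = DEFAULT_OUTLIER_FRACTION,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> MatchMatrix:
    """Match camera-1 identities to camera-2 identities.

    An entry is raw-True when the trimmed mean epiline distance is below
    ``threshold``; conflicting raw matches are resolved one-to-one by a
    minimum-total-mean-distance assignment over the True entries.
    """
    g1, g2 = _group_by_id(tracks_1), _group_by_id(tracks_2)
    ids_1, ids_2 = sorted(g1), sorted(g2)
    D = np.full((len(ids_1), len(ids_2)), np.nan)
    for i, id1 in enumerate(ids_1):
        for j, id2 in enumerate(ids_2):
            dist = track_pair_distance(g1[id1], g2[id2], F, outlier_fraction, min_overlap)
            if dist is not None:
                D[i, j] = dist
    with np.errstate(invalid="ignore"):
        raw = D < threshold
    cost = np.where(raw, D, np.inf)
    res = solve_assignment(cost)
    resolved = np.zeros_like(raw)
    for i, j in res.matches:
        resolved[i, j] = True
    return MatchMatrix(ids_1, ids_2, resolved, raw, D)
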