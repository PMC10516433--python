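"""Frame-recursive data association: the tracker core.

Each frame, every live track's Kalman state is predicted forward, then
detections are associated to tracks in two stages:

1. a matching cascade over confirmed tracks, most recently updated first,
   using the appearance matching degree as the assignment cost with both
   the appearance gate and the squared-Mahalanobis motion gate applied as
   hard admissibility constraints;
2. an IoU stage for the remaining tracks (tentative tracks and confirmed
   tracks missed exactly once) against the remaining detections.

Matched tracks are Kalman-updated and their galleries extended; unmatched
detections start tentative tracks; tentative tracks are confirmed after
``n_init`` consecutive hits and dropped on any miss; confirmed tracks are
dropped after ``max_age`` consecutive misses — the appearance gallery is
what lets an identity survive a long occlusion and be reclaimed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .appearance import GALLERY_CAPACITY, Gallery, matching_degree
from .io_formats import Detection, TrackRecord2D
from .metrics import iou
from .motion import CHI2_95_4DOF, KalmanFilter, KalmanState, measurement_to_box

__all__ = ["Track", "AssociationResult", "TrackerConfig", "Tracker",
           "build_cost_matrices", "gate", "solve_assignment", "track_sequence"]

logger = logging.getLogger(__name__)

INFEASIBLE = np.inf

TENTATIVE, CONFIRMED, DELETED = "tentative", "confirmed", "deleted"


@dataclass
class Track:
    track_id: int
    state: KalmanState
    gallery: Gallery
    status: str = TENTATIVE
    hits: int = 1
    time_since_update: int = 0


@dataclass(frozen=True)
class AssociationResult:
    matches: list[tuple[int, int]]          # (track index, detection index)
    unmatched_tracks: list[int]
    unmatched_detections: list[int]


@dataclass(frozen=True)
class TrackerConfig:
    """Tunables of the association stage.

    ``ct`` is the detector confidence threshold applied before association;
    the remaining values gate and govern the track lifecycle.
    """

    ct: float = 0.0
    n_init: int = 3
    max_age: int = 100
    iou_gate: float = 0.3
    appearance_gate: float = 0.25
    motion_gate: float = CHI2_95_4DOF
    gallery_capacity: int = GALLERY_CAPACITY
    std_weight_position: float = 1.0 / 20
    std_weight_velocity: float = 1.0 / 160


def build_cost_matrices(
    kf: KalmanFilter, tracks: list[Track], detections: list[Detection]
) -> tuple[np.ndarray, np.ndarray]:
    """Appearance (D1) and motion (D2) cost matrices, |tracks| x |detections|.

    D1 entries are +inf where either side lacks appearance information.
    """
    n, m = len(tracks), len(detections)
    D1 = np.full((n, m), INFEASIBLE)
    D2 = np.zeros((n, m))
    for i, trk in enumerate(tracks):
        if m == 0:
            continue
        D2[i] = kf.squared_mahalanobis(trk.state, detections)
        if len(trk.gallery) == 0:
            continue
        G = trk.gallery.as_matrix()
        for j, det in enumerate(detections):
            if det.descriptor is not None:
                D1[i, j] = float(np.min(1.0 - G @ det.descriptor))
    return D1, D2


def gate(D1: np.ndarray, D2: np.ndarray, appearance_gate: float,
         motion_gate: float) -> np.ndarray:
    """Combined cost: appearance distance where both gates pass, else +inf."""
    if D1.shape != D2.shape:
        raise ValueError("cost matrices must share a shape")
    C = np.where((D1 <= appearance_gate) & (D2 <= motion_gate), D1, INFEASIBLE)
    return C


def solve_assignment(C: np.ndarray) -> AssociationResult:
    """Minimum-cost one-to-one matching over the admissible (finite) pairs.

    Ties are broken lexicographically on (row, column) by adding an
    epsilon-scale perturbation far below any meaningful cost difference.
    """
    n, m = C.shape
    if n == 0 or m == 0 or not np.isfinite(C).any():
        return AssociationResult([], list(range(n)), list(range(m)))
    # Replace +inf by a large finite sentinel so infeasible pairs can be
    # selected by the solver but are discarded afterwards.
    finite = np.isfinite(C)
    big = (np.abs(C[finite]).max() + 1.0) * (n + m + 1)
    work = np.where(finite, C, big)
    # lexicographic tie-break: tiny strictly increasing offset
    eps = np.finfo(float).eps * max(big, 1.0) * 8
    rows = np.arange(n)[:, None]
    cols = np.arange(m)[None, :]
    work = work + eps * (rows * m + cols)
    ri, ci = linear_sum_assignment(work)
    matches = [(int(i), int(j)) for i, j in zip(ri, ci) if finite[i, j]]
    matched_r = {i for i, _ in matches}
    matched_c = {j for _, j in matches}
    return AssociationResult(
        sorted(matches),
        [i for i in range(n) if i not in matched_r],
        [j for j in range(m) if j not in matched_c],
    )


class Tracker:
    """Stateful multi-object tracker: feed detections frame by frame."""

    def __init__(self, config: TrackerConfig | None = None) -> None:
        self.config = config or TrackerConfig()
        self.kf = KalmanFilter(self.config.std_weight_position,
                               self.config.std_weight_velocity)
        self.tracks: list[Track] = []
        self._next_id = 1

    # -- lifecycle helpers ------------------------------------------------
    def _initiate(self, det: Detection) -> Track:
        gallery = Gallery(self.config.gallery_capacity)
        if det.descriptor is not None:
            gallery.add(det.descriptor)
        status = CONFIRMED if self.config.n_init <= 1 else TENTATIVE
        trk = Track(self._next_id, self.kf.initiate(det), gallery, status=status)
        self._next_id += 1
        return trk

    def _mark_missed(self, trk: Track) -> None:
        if trk.status == TENTATIVE:
            trk.status = DELETED
        elif trk.time_since_update > self.config.max_age:
            trk.status = DELETED

    # -- one frame --------------------------------------------------------
    def step(self, detections: list[Detection]) -> tuple[list[Track], AssociationResult]:
        """Advance one frame; returns live tracks and the association."""
        cfg = self.config
        detections = [d for d in detections if d.confidence >= cfg.ct]

        for trk in self.tracks:
            trk.state = self.kf.predict(trk.state)
            trk.time_since_update += 1

        confirmed = [i for i, t in enumerate(self.tracks) if t.status == CONFIRMED]
        tentative = [i for i, t in enumerate(self.tracks) if t.status == TENTATIVE]

        matches: list[tuple[int, int]] = []
        unmatched_dets = list(range(len(detections)))

        # stage 1: appearance cascade over confirmed tracks by ascending age
        for age in range(1, cfg.max_age + 2):
            if not unmatched_dets:
                break
            level = [i for i in confirmed if self.tracks[i].time_since_update == age]
            if not level:
                continue
            dets_level = [detections[j] for j in unmatched_dets]
            D1, D2 = build_cost_matrices(self.kf, [self.tracks[i] for i in level], dets_level)
            # The Kalman prediction is only trustworthy for tracks seen last
            # frame; after an occlusion the stale prediction must not veto the
            # appearance reclaim, so the motion gate applies at age 1 only.
            motion_gate = cfg.motion_gate if age == 1 else INFEASIBLE
            C = gate(D1, D2, cfg.appearance_gate, motion_gate)
            res = solve_assignment(C)
            for li, lj in res.matches:
                matches.append((level[li], unmatched_dets[lj]))
            unmatched_dets = [unmatched_dets[lj] for lj in res.unmatched_detections]

        matched_tracks = {i for i, _ in matches}
        # stage 2: IoU for tentative tracks + confirmed tracks missed once
        iou_candidates = [i for i in tentative if i not in matched_tracks]
        iou_candidates += [i for i in confirmed
                           if i not in matched_tracks and self.tracks[i].time_since_update == 1]
        if iou_candidates and unmatched_dets:
            C = np.full((len(iou_candidates), len(unmatched_dets)), INFEASIBLE)
            for a, i in enumerate(iou_candidates):
                trk = self.tracks[i]
                tb = measurement_to_box(trk.state.mean[:4])
                for b, j in enumerate(unmatched_dets):
                    det = detections[j]
                    ov = iou(tb, det.box)
                    if ov < cfg.iou_gate:
                        continue
                    # overlap alone must not overrule a clear appearance
                    # mismatch, or crossing animals swap identities
                    if det.descriptor is not None and len(trk.gallery) > 0:
                        if matching_degree(trk.gallery, det.descriptor) > cfg.appearance_gate:
                            continue
                    C[a, b] = 1.0 - ov
            res = solve_assignment(C)
            for a, b in res.matches:
                matches.append((iou_candidates[a], unmatched_dets[b]))
            unmatched_dets = [unmatched_dets[b] for b in res.unmatched_detections]

        matched_tracks = {i for i, _ in matches}
        # stage 3: appearance-only rescue.  A track seen last frame whose
        # gated association failed (sudden maneuver breaks both the motion
        # gate and the IoU overlap) is treated like the onset of occlusion:
        # occluded tracks are reclaimed by appearance alone, so the same
        # reclaim applies immediately when the appearance is unambiguous.
        rescue = [i for i in confirmed + tentative if i not in matched_tracks]
        if rescue and unmatched_dets:
            dets_left = [detections[j] for j in unmatched_dets]
            D1, _ = build_cost_matrices(self.kf, [self.tracks[i] for i in rescue], dets_left)
            C = np.where(D1 <= cfg.appearance_gate, D1, INFEASIBLE)
            res = solve_assignment(C)
            for a, b in res.matches:
                matches.append((rescue[a], unmatched_dets[b]))
            unmatched_dets = [unmatched_dets[b] for b in res.unmatched_detections]

        matched_tracks = {i for i, _ in matches}
        # apply updates
        self.last_matched: list[tuple[Track, int]] = []
        for i, j in matches:
            trk, det = self.tracks[i], detections[j]
            self.last_matched.append((trk, j))
            trk.state = self.kf.update(trk.state, det)
            if det.descriptor is not None:
                trk.gallery.add(det.descriptor)
            trk.hits += 1
            trk.time_since_update = 0
            if trk.status == TENTATIVE and trk.hits >= self.config.n_init:
                trk.status = CONFIRMED

        unmatched_track_idx = [i for i in range(len(self.tracks)) if i not in matched_tracks]
        for i in unmatched_track_idx:
            self._mark_missed(self.tracks[i])

        self.last_initiated: list[tuple[Track, int]] = []
        for j in unmatched_dets:
            trk = self._initiate(detections[j])
            self.tracks.append(trk)
            self.last_initiated.append((trk, j))

        result = AssociationResult(sorted(matches), unmatched_track_idx, unmatched_dets)
        self._assert_partition(result, len(detections))
        self.tracks = [t for t in self.tracks if t.status != DELETED]
        logger.debug("tracks=%d matches=%d births=%d",
                     len(self.tracks), len(result.matches), len(unmatched_dets))
        return self.tracks, result

    @staticmethod
    def _assert_partition(res: AssociationResult, n_dets: int) -> None:
        det_ids = [j for _, j in res.matches] + list(res.unmatched_detections)
        assert len(det_ids) == len(set(det_ids)) == n_dets, "detections not partitioned"
        trk_ids = [i for i, _ in res.matches]
        assert len(trk_ids) == len(set(trk_ids)), "track matched twice"


def track_sequence(
    frames: dict[int, list[Detection]],
    config: TrackerConfig | None = None,
) -> list[TrackRecord2D]:
    """Run the tracker over a whole sequence of per-frame detections.

    Emits one record per confirmed track per frame in which it was updated,
    carrying the associated detection's box; the frames of a track's
    tentative phase are emitted retroactively once it confirms, so a track
    covers its whole observed life.  Deterministic: the same inputs and
    config always produce the same records.
    """
    tracker = Tracker(config)
    records: list[TrackRecord2D] = []
    if not frames:
        return records
    cfg = tracker.config
    pending: dict[int, list[TrackRecord2D]] = {}  # tentative-phase buffers
    last = max(frames)
    for frame in range(0, last + 1):
        dets = [d for d in frames.get(frame, []) if d.confidence >= cfg.ct]
        tracker.step(dets)
        for trk, det_j in tracker.last_initiated:
            rec = TrackRecord2D(frame, trk.track_id, dets[det_j].box)
            if trk.status == CONFIRMED:
                records.append(rec)
            else:
                pending[trk.track_id] = [rec]
        for trk, det_j in tracker.last_matched:
            rec = TrackRecord2D(frame, trk.track_id, dets[det_j].box)
            if trk.status == CONFIRMED:
                records.extend(pending.pop(trk.track_id, []))
                records.append(rec)
            else:
                pending.setdefault(trk.track_id, []).append(rec)
    return records
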