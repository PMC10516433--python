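"""CLEAR-MOT evaluation and precision-recall operating-point analysis.

``evaluate`` scores predicted identity-labeled tracks against ground
truth with the CLEAR protocol: per frame, correspondences surviving from
the previous frame are kept when still valid (IoU at or above the
threshold), the remainder are matched by minimum-cost assignment on
1 - IoU, and the error events are accumulated:

* fp — predicted boxes matched to no ground truth;
* fn — ground-truth boxes matched to no prediction;
* IDS — a matched ground-truth object whose assigned predicted identity
  differs from the identity it last held;
* FM — a ground-truth track's matched status being interrupted
  (matched -> unmatched transitions, excluding the track's end);
* MOTA = 1 - (fp + fn + IDS) / total ground-truth boxes;
* MOTP — mean overlap (IoU) over all matches, or mean misalignment
  1 - IoU when ``motp_as_distance`` is set.

``pr_curve`` sweeps a detector's confidence threshold and reports the
detection precision/recall trade-off used to pick the tracker's
operating point (precision is favored over recall: the tracker recovers
from a missed detection as it does from occlusion, while a false
positive can seed or steal a track).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io_formats import Detection, TrackRecord2D

__all__ = ["MOTReport", "iou", "match_frame", "evaluate", "detection_pr", "pr_curve"]

Box = tuple[float, float, float, float]


def iou(box_a: Box, box_b: Box) -> float:
    """Intersection over union of two (left, top, w, h) boxes."""
    ax, ay, aw, ah = box_a
    bx, by, bw, bh = box_b
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        raise ValueError("boxes must have positive dimensions")
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union


@dataclass(frozen=True)
class MOTReport:
    fp: int
    fn: int
    ids: int
    fm: int
    precision: float
    recall: float
    mota: float
    motp: float

    def as_dict(self) -> dict:
        return {
            "fp": self.fp, "fn": self.fn, "ids": self.ids, "fm": self.fm,
            "precision": self.precision, "recall": self.recall,
            "mota": self.mota, "motp": self.motp,
        }


def match_frame(
    gt_boxes: dict[int, Box],
    pred_boxes: dict[int, Box],
    prev_correspondence: dict[int, int],
    iou_threshold: float = 0.5,
) -> dict[int, int]:
    """One frame of the CLEAR correspondence protocol.

    Returns a mapping gt_id -> pred_id.  Pairs from ``prev_correspondence``
    persist when both boxes are present and still overlap at or above the
    threshold; the rest are matched by minimum-cost assignment on 1 - IoU,
    admissible only at IoU >= threshold.
    """
    corr: dict[int, int] = {}
    used_pred: set[int] = set()
    for g, p in prev_correspondence.items():
        if g in gt_boxes and p in pred_boxes and p not in used_pred:
            if iou(gt_boxes[g], pred_boxes[p]) >= iou_threshold:
                corr[g] = p
                used_pred.add(p)
    free_gt = [g for g in sorted(gt_boxes) if g not in corr]
    free_pred = [p for p in sorted(pred_boxes) if p not in used_pred]
    if free_gt and free_pred:
        # large sentinel: minimum cost then equals maximum cardinality,
        # tie-broken by maximum total IoU
        C = np.full((len(free_gt), len(free_pred)), 1e9)
        ok = np.zeros_like(C, dtype=bool)
        for i, g in enumerate(free_gt):
            for j, p in enumerate(free_pred):
                ov = iou(gt_boxes[g], pred_boxes[p])
                if ov >= iou_threshold:
                    C[i, j] = 1.0 - ov
                    ok[i, j] = True
        ri, ci = linear_sum_assignment(C)
        for i, j in zip(ri, ci):
            if ok[i, j]:
                corr[free_gt[i]] = free_pred[j]
    return corr


def _by_frame(records: list[TrackRecord2D]) -> dict[int, dict[int, Box]]:
    frames: dict[int, dict[int, Box]] = {}
    for rec in records:
        frames.setdefault(rec.frame_index, {})[rec.track_id] = rec.box
    return frames


def evaluate(
    gt: list[TrackRecord2D],
    pred: list[TrackRecord2D],
    iou_threshold: float = 0.5,
    motp_as_distance: bool = False,
) -> MOTReport:
    """Score predicted tracks against ground truth (CLEAR-MOT)."""
    if not gt:
        raise ValueError("metrics undefined for empty ground truth")
    gt_frames = _by_frame(gt)
    pred_frames = _by_frame(pred)
    all_frames = sorted(set(gt_frames) | set(pred_frames))

    fp = fn = ids = tp = 0
    overlaps: list[float] = []
    total_gt = sum(len(v) for v in gt_frames.values())
    corr: dict[int, int] = {}
    last_pred_of_gt: dict[int, int] = {}  # last identity each GT object held
    was_matched: dict[int, bool] = {}
    interruptions: list[tuple[int, int]] = []  # (gt id, frame it lost coverage)
    last_matched_frame: dict[int, int] = {}

    per_frame_events = 0
    for frame in all_frames:
        gt_boxes = gt_frames.get(frame, {})
        pred_boxes = pred_frames.get(frame, {})
        corr = match_frame(gt_boxes, pred_boxes, corr, iou_threshold)
        frame_fp = len(pred_boxes) - len(corr)
        frame_fn = len(gt_boxes) - len(corr)
        frame_ids = 0
        fp += frame_fp
        fn += frame_fn
        tp += len(corr)
        for g, p in corr.items():
            overlaps.append(iou(gt_boxes[g], pred_boxes[p]))
            if g in last_pred_of_gt and last_pred_of_gt[g] != p:
                ids += 1
                frame_ids += 1
            last_pred_of_gt[g] = p
        for g in gt_boxes:
            matched_now = g in corr
            if matched_now:
                last_matched_frame[g] = frame
            elif was_matched.get(g, False):
                interruptions.append((g, frame))
            was_matched[g] = matched_now
        per_frame_events += frame_fp + frame_fn + frame_ids
    # the MOTA numerator must decompose exactly into per-frame contributions
    assert per_frame_events == fp + fn + ids, "per-frame event decomposition broken"
    # a fragmentation is an interruption of coverage that later resumes;
    # losing the object for good (track end) is not a fragment
    fm = sum(1 for g, f in interruptions if last_matched_frame.get(g, -1) > f)

    precision = tp / (tp + fp) if (tp + fp) > 0 else 1.0
    recall = tp / (tp + fn)
    mota = 1.0 - (fp + fn + ids) / total_gt
    if overlaps:
        motp = float(np.mean([1.0 - o for o in overlaps])) if motp_as_distance \
            else float(np.mean(overlaps))
    else:
        motp = float("nan")
    return MOTReport(fp, fn, ids, fm, precision, recall, mota, motp)


def detection_pr(
    detections: list[Detection],
    gt_boxes: dict[int, list[Box]],
    ct: float,
    iou_threshold: float = 0.5,
) -> tuple[float, float]:
    """Detection precision/recall at confidence threshold ``ct``.

    Greedy matching in descending confidence order within each frame; each
    ground-truth box can satisfy at most one detection.  With no
    predictions precision is 1 by convention (no false positives made).
    """
    total_gt = sum(len(v) for v in gt_boxes.values())
    if total_gt == 0:
        raise ValueError("no ground-truth boxes")
    by_frame: dict[int, list[Detection]] = {}
    for det in detections:
        if det.confidence >= ct:
            by_frame.setdefault(det.frame_index, []).append(det)
    tp = fp = 0
    for frame, dets in by_frame.items():
        remaining = list(gt_boxes.get(frame, []))
        for det in sorted(dets, key=lambda d: -d.confidence):
            best_i, best_ov = -1, iou_threshold
            for i, g in enumerate(remaining):
                ov = iou(det.box, g)
                if ov >= best_ov:
                    best_i, best_ov = i, ov
            if best_i >= 0:
                tp += 1
                remaining.pop(best_i)
            else:
                fp += 1
    precision = tp / (tp + fp) if (tp + fp) > 0 else 1.0
    recall = tp / total_gt
    return precision, recall


def pr_curve(
    detections: list[Detection],
    gt_boxes: dict[int, list[Box]],
    iou_threshold: float = 0.5,
) -> list[tuple[float, float, float]]:
    """Operating points (ct, precision, recall) over all observed confidences.

    Recall is non-increasing in ct: raising the threshold only removes
    detections.
    """
    cts = sorted({d.confidence for d in detections})
    return [(ct, *detection_pr(detections, gt_boxes, ct, iou_threshold)) for ct in cts]
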