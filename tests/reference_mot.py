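"""Independent reference implementation of the CLEAR multi-object-tracking
protocol, used only as a cross-check oracle in tests.

Deliberately written as a naive, frame-by-frame transliteration of the
published protocol (Bernardin & Stiefelhagen 2008), with no shared code
with the package implementation: explicit loops, per-object bookkeeping,
greedy-free Hungarian matching via brute-force enumeration for the small
scenario sizes used in tests.
"""

from __future__ import annotations

from itertools import permutations


def _iou(a, b):
    ax1, ay1 = a[0], a[1]
    ax2, ay2 = a[0] + a[2], a[1] + a[3]
    bx1, by1 = b[0], b[1]
    bx2, by2 = b[0] + b[2], b[1] + b[3]
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a[2] * a[3] + b[2] * b[3] - inter)


def _best_assignment(gt_ids, pred_ids, gt_boxes, pred_boxes, thr):
    """Max-cardinality, then max-total-IoU matching by brute force."""
    best = {}
    best_key = (-1, -1.0)
    k = min(len(gt_ids), len(pred_ids))
    if not gt_ids or not pred_ids:
        return {}
    if len(pred_ids) >= len(gt_ids):
        pairings = ((gt_ids, perm) for perm in permutations(pred_ids, k))
    else:
        pairings = ((perm, pred_ids) for perm in permutations(gt_ids, k))
    for gs, ps in pairings:
        pairs = []
        total = 0.0
        for g, p in zip(gs, ps):
            ov = _iou(gt_boxes[g], pred_boxes[p])
            if ov >= thr:
                pairs.append((g, p))
                total += ov
        key = (len(pairs), total)
        if key > best_key:
            best_key = key
            best = dict(pairs)
    return best


def clear_mot(gt_records, pred_records, iou_threshold=0.5):
    """Returns (fp, fn, ids, mota, motp_mean_iou, precision, recall).

    ``*_records`` are iterables of objects with frame_index, track_id, box.
    """
    gt_frames, pred_frames = {}, {}
    for r in gt_records:
        gt_frames.setdefault(r.frame_index, {})[r.track_id] = r.box
    for r in pred_records:
        pred_frames.setdefault(r.frame_index, {})[r.track_id] = r.box

    fp = fn = ids = tp = 0
    total_gt = sum(len(v) for v in gt_frames.values())
    overlaps = []
    mapping = {}       # gt id -> pred id carried between frames
    last_seen = {}     # gt id -> last pred id it was ever matched to

    for frame in sorted(set(gt_frames) | set(pred_frames)):
        gt_b = gt_frames.get(frame, {})
        pr_b = pred_frames.get(frame, {})
        # step 1: keep still-valid correspondences
        new_map = {}
        used = set()
        for g in sorted(mapping):
            p = mapping[g]
            if g in gt_b and p in pr_b and p not in used \
                    and _iou(gt_b[g], pr_b[p]) >= iou_threshold:
                new_map[g] = p
                used.add(p)
        # step 2: optimally match the rest
        free_g = [g for g in sorted(gt_b) if g not in new_map]
        free_p = [p for p in sorted(pr_b) if p not in used]
        extra = _best_assignment(free_g, free_p,
                                 gt_b, pr_b, iou_threshold)
        new_map.update(extra)
        # step 3: count events
        for g, p in new_map.items():
            overlaps.append(_iou(gt_b[g], pr_b[p]))
            if g in last_seen and last_seen[g] != p:
                ids += 1
            last_seen[g] = p
        tp += len(new_map)
        fp += len(pr_b) - len(new_map)
        fn += len(gt_b) - len(new_map)
        mapping = new_map

    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn)
    mota = 1.0 - (fp + fn + ids) / total_gt
    motp = sum(overlaps) / len(overlaps) if overlaps else float("nan")
    return fp, fn, ids, mota, motp, precision, recall
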