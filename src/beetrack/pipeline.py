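"""End-to-end pipeline: detections -> 2D tracks -> cross-camera match ->
3D reconstruction -> metrics, driven by one configuration tree.

Inputs never get mutated; every output is a function of (inputs, config,
seed).  The pipeline mirrors the framework's separation of concerns: the
detector is upstream and outside — detections arrive as files (or from
the synthetic scene generator)."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import io_formats as iof
from .association import track_sequence
from .config import load_config, tracker_config_from
from .metrics import evaluate
from .multicam import match_tracks
from .reconstruction import compare_pairs, interpolate_gaps, reconstruct_tracks

logger = logging.getLogger(__name__)

__all__ = ["simulate_fixtures", "run_pipeline"]


def simulate_fixtures(cfg: dict, outdir: str | Path) -> dict[str, Path]:
    """Generate a full synthetic fixture set on disk.

    Writes ``calib.yaml``, per-camera ``gt_cam{i}.csv`` and
    ``det_cam{i}.csv``, descriptor sidecars ``desc_cam{i}.csv``,
    ``correspondence.csv`` (the ground-truth cross-camera identity map)
    and ``truth3d.csv``.
    """
    from .synthetic import (NoiseConfig, SceneConfig, corrupt, make_rig,
                            project, simulate_flight)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scene = SceneConfig(
        n_bees=cfg["scene"]["n_bees"], n_frames=cfg["scene"]["n_frames"],
        tunnel=tuple(cfg["scene"]["tunnel"]), speed_scale=cfg["scene"]["speed_scale"],
        turn_rate=cfg["scene"]["turn_rate"], damping=cfg["scene"]["damping"],
        seed=cfg["seed"],
    )
    noise = NoiseConfig(
        jitter_px=cfg["noise"]["jitter_px"], miss_rate=cfg["noise"]["miss_rate"],
        clutter_rate=cfg["noise"]["clutter_rate"],
        descriptor_angle_deg=cfg["noise"]["descriptor_angle_deg"],
        descriptor_separation_deg=cfg["noise"]["descriptor_separation_deg"],
        descriptor_dim=cfg["appearance"]["dim"],
    )
    cameras = make_rig()
    traj = simulate_flight(scene)
    gt = project(traj, cameras)
    detections, sidecars, _ = corrupt(gt, noise, seed=cfg["seed"] + 1)

    paths: dict[str, Path] = {}
    paths["calib"] = outdir / "calib.yaml"
    iof.write_calibration(cameras, paths["calib"])
    for cam in cameras:
        cid = cam.camera_id
        paths[f"gt{cid}"] = outdir / f"gt_cam{cid}.csv"
        iof.write_tracks_2d(gt[cid], paths[f"gt{cid}"])
        paths[f"det{cid}"] = outdir / f"det_cam{cid}.csv"
        iof.write_detections(detections[cid], paths[f"det{cid}"])
        paths[f"desc{cid}"] = outdir / f"desc_cam{cid}.csv"
        iof.write_descriptor_sidecar(sidecars[cid], paths[f"desc{cid}"])
    # correspondence oracle: identities are shared across cameras
    paths["correspondence"] = outdir / "correspondence.csv"
    ids = sorted({r.track_id for r in gt[1]})
    with open(paths["correspondence"], "w") as fh:
        fh.write("id_cam1,id_cam2,id_cam3\n")
        for tid in ids:
            fh.write(f"{tid},{tid},{tid}\n")
    paths["truth3d"] = outdir / "truth3d.csv"
    recs3d = [iof.TrackRecord3D(t, b + 1, tuple(traj[b, t]), 0)
              for b in range(traj.shape[0]) for t in range(traj.shape[1])]
    iof.write_tracks_3d(recs3d, paths["truth3d"])
    return paths


def _attach_descriptors(frames, sidecar):
    out = {}
    for f, dets in frames.items():
        out[f] = [
            iof.Detection(d.frame_index, d.box, d.confidence,
                          sidecar.get((f, j)))
            for j, d in enumerate(dets)
        ]
    return out


def run_pipeline(
    det_paths: dict[int, str | Path],
    calib_path: str | Path,
    outdir: str | Path,
    cfg: dict | None = None,
    desc_paths: dict[int, str | Path] | None = None,
    gt_paths: dict[int, str | Path] | None = None,
) -> dict:
    """Track each camera, match identities across cameras, reconstruct 3D
    paths with both stereo pairs, compare them, and (with ground truth)
    evaluate.  Returns a summary dict; all artifacts are written under
    ``outdir``."""
    cfg = cfg or load_config()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cid, p in det_paths.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"missing detections for camera {cid}: {p}")
    if not Path(calib_path).exists():
        raise FileNotFoundError(f"missing calibration file: {calib_path}")

    cameras = {c.camera_id: c for c in iof.read_calibration(calib_path)}
    tracker_cfg = tracker_config_from(cfg)

    tracks: dict[int, list[iof.TrackRecord2D]] = {}
    for cid, path in sorted(det_paths.items()):
        frames = iof.read_detections(path, dialect="mot")
        if desc_paths and cid in desc_paths:
            sidecar = iof.read_descriptor_sidecar(desc_paths[cid])
            frames = _attach_descriptors(frames, sidecar)
        tracks[cid] = track_sequence(frames, tracker_cfg)
        iof.write_tracks_2d(tracks[cid], outdir / f"tracks2d_cam{cid}.csv")
        logger.info("camera %d: %d track records", cid, len(tracks[cid]))

    summary: dict = {"config": cfg, "n_records_2d": {c: len(t) for c, t in tracks.items()}}

    # gap interpolation before matching/reconstruction
    interp: dict[int, list[iof.TrackRecord2D]] = {}
    for cid, recs in tracks.items():
        by_id: dict[int, list[iof.TrackRecord2D]] = {}
        for r in recs:
            by_id.setdefault(r.track_id, []).append(r)
        merged: list[iof.TrackRecord2D] = []
        for tid in sorted(by_id):
            merged.extend(interpolate_gaps(by_id[tid], cfg["reconstruction"]["max_gap"]))
        interp[cid] = merged

    tracks3d = {}
    for pair_label, other in ((12, 2), (13, 3)):
        if other not in tracks or 1 not in tracks:
            continue
        F = iof.fundamental_from_cameras(cameras[1], cameras[other])
        match = match_tracks(
            interp[1], interp[other], F,
            threshold=cfg["matcher"]["threshold_px"],
            outlier_fraction=cfg["matcher"]["outlier_fraction"],
            min_overlap=cfg["matcher"]["min_overlap"],
        )
        with open(outdir / f"match1{other}.csv", "w") as fh:
            fh.write("id1,id2,mean_distance_px,matched\n")
            for i, id1 in enumerate(match.ids_1):
                for j, id2 in enumerate(match.ids_2):
                    d = match.mean_distances[i, j]
                    fh.write(f"{id1},{id2},{'' if np.isnan(d) else f'{d:.3f}'},"
                             f"{int(match.entries[i, j])}\n")
        t3d = reconstruct_tracks(interp[1], interp[other], match,
                                 cameras[1], cameras[other], pair_label)
        tracks3d[pair_label] = t3d
        recs = [r for t in t3d for r in t.records()]
        iof.write_tracks_3d(recs, outdir / f"tracks3d_pair{pair_label}.csv")
        summary[f"matches_1{other}"] = match.pairs()
        summary[f"n_tracks3d_pair{pair_label}"] = len(t3d)

    if 12 in tracks3d and 13 in tracks3d:
        comparison = compare_pairs(tracks3d[12], tracks3d[13])
        summary["pair_comparison_mm"] = comparison.per_identity
        summary["pair_comparison_uncompared"] = comparison.uncompared

    if gt_paths:
        reports = {}
        for cid, path in sorted(gt_paths.items()):
            gt = iof.read_tracks_2d(path)
            rep = evaluate(gt, tracks[cid],
                           iou_threshold=cfg["metrics"]["iou_threshold"],
                           motp_as_distance=cfg["metrics"]["motp_as_distance"])
            reports[cid] = rep.as_dict()
        summary["mot_reports"] = reports

    with open(outdir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
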