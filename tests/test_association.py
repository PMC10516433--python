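from itertools import permutations

import numpy as np
import pytest

from beetrack.appearance import Gallery
from beetrack.association import (INFEASIBLE, Tracker, TrackerConfig,
                                  build_cost_matrices, gate, solve_assignment,
                                  track_sequence)
from beetrack.io_formats import Detection
from beetrack.metrics import evaluate, iou
from beetrack.motion import KalmanFilter
from beetrack.synthetic import (NoiseConfig, SceneConfig, corrupt, make_rig,
                                project, simulate_flight)


class TestSolveAssignment:
    def test_forced_diagonal(self):
        C = np.array([[0.1, np.inf], [np.inf, 0.2]])
        res = solve_assignment(C)
        assert res.matches == [(0, 0), (1, 1)]
        assert res.unmatched_tracks == [] and res.unmatched_detections == []

    def test_more_tracks_than_detections(self):
        C = np.array([[0.5], [0.1]])
        res = solve_assignment(C)
        assert res.matches == [(1, 0)]
        assert res.unmatched_tracks == [0]

    def test_all_infeasible_leaves_everything_unmatched(self):
        C = np.full((3, 2), np.inf)
        res = solve_assignment(C)
        assert res.matches == []
        assert res.unmatched_tracks == [0, 1, 2]
        assert res.unmatched_detections == [0, 1]

    def test_matches_exhaustive_search_on_random_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(1, 6))
            C = rng.uniform(0, 1, (n, n))
            res = solve_assignment(C)
            total = sum(C[i, j] for i, j in res.matches)
            brute = min(sum(C[i, p[i]] for i in range(n))
                        for p in permutations(range(n)))
            assert total == pytest.approx(brute, abs=1e-12)

    def test_partition_invariant_with_infeasible_entries(self):
        rng = np.random.default_rng(18)
        for _ in range(100):
            n, m = rng.integers(1, 6, 2)
            C = rng.uniform(0, 1, (n, m))
            C[rng.random((n, m)) < 0.4] = np.inf
            res = solve_assignment(C)
            rows = [i for i, _ in res.matches] + res.unmatched_tracks
            cols = [j for _, j in res.matches] + res.unmatched_detections
            assert sorted(rows) == list(range(n))
            assert sorted(cols) == list(range(m))
            assert all(np.isfinite(C[i, j]) for i, j in res.matches)

    def test_tie_break_lexicographic(self):
        C = np.array([[0.5, 0.5], [0.5, 0.5]])
        assert solve_assignment(C).matches == [(0, 0), (1, 1)]


class TestGate:
    def test_motion_gate_failure_is_infeasible(self):
        D1 = np.array([[0.1]])
        D2 = np.array([[100.0]])
        assert gate(D1, D2, 0.25, 9.49)[0, 0] == INFEASIBLE

    def test_passing_pair_keeps_appearance_cost(self):
        D1 = np.array([[0.2]])
        D2 = np.array([[5.0]])
        assert gate(D1, D2, 0.25, 9.49)[0, 0] == 0.2

    def test_appearance_gate_failure_is_infeasible(self):
        assert gate(np.array([[0.3]]), np.array([[1.0]]), 0.25, 9.49)[0, 0] == INFEASIBLE


class TestBuildCostMatrices:
    def test_shapes_and_elementwise_consistency(self):
        rng = np.random.default_rng(19)
        kf = KalmanFilter()
        from beetrack.appearance import matching_degree

        def unit():
            v = rng.standard_normal(16)
            return v / np.linalg.norm(v)

        tracks = []
        for k in range(3):
            det = Detection(0, (k * 50.0, k * 30.0, 20, 25), 1.0)
            from beetrack.association import Track
            g = Gallery()
            for _ in range(4):
                g.add(unit())
            tracks.append(Track(k + 1, kf.predict(kf.initiate(det)), g))
        dets = [Detection(1, (k * 50.0 + 2, k * 30.0 + 1, 20, 25), 1.0, unit())
                for k in range(4)]
        D1, D2 = build_cost_matrices(kf, tracks, dets)
        assert D1.shape == D2.shape == (3, 4)
        for i, trk in enumerate(tracks):
            np.testing.assert_allclose(
                D2[i], kf.squared_mahalanobis(trk.state, dets), rtol=1e-12)
            for j, det in enumerate(dets):
                assert D1[i, j] == pytest.approx(
                    matching_degree(trk.gallery, det.descriptor), abs=1e-12)

    def test_perfect_pair_has_zero_costs(self):
        kf = KalmanFilter()
        from beetrack.association import Track
        v = np.zeros(8); v[0] = 1.0
        det0 = Detection(0, (10, 10, 20, 25), 1.0, v)
        g = Gallery(); g.add(v)
        state = kf.initiate(det0)
        trk = Track(1, state, g)
        D1, D2 = build_cost_matrices(kf, [trk], [det0])
        assert D1[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert D2[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_missing_descriptor_infeasible_appearance(self):
        kf = KalmanFilter()
        from beetrack.association import Track
        det = Detection(0, (10, 10, 20, 25), 1.0)
        trk = Track(1, kf.initiate(det), Gallery())
        D1, _ = build_cost_matrices(kf, [trk], [det])
        assert D1[0, 0] == INFEASIBLE


def _scene_tracks(seed, n_bees=2, n_frames=100, noise=None, camera=1):
    scene = SceneConfig(n_bees=n_bees, n_frames=n_frames, seed=seed)
    traj = simulate_flight(scene)
    gt = project(traj, make_rig())
    dets, _, _ = corrupt(gt, noise or NoiseConfig(), seed=seed + 500)
    return gt[camera], dets[camera]


class TestTrackerLifecycle:
    def test_single_detection_starts_tentative_track(self):
        tr = Tracker()
        v = np.zeros(4); v[0] = 1.0
        tracks, res = tr.step([Detection(0, (5, 5, 10, 10), 1.0, v)])
        assert len(tracks) == 1
        assert tracks[0].status == "tentative"
        assert res.unmatched_detections == [0]

    def test_two_object_sequence_stable_identities(self):
        gt, dets = _scene_tracks(seed=23, n_frames=100)
        records = track_sequence(dets, TrackerConfig())
        rep = evaluate(gt, records)
        assert rep.ids == 0
        assert rep.mota == pytest.approx(1.0)

    def test_occlusion_recovers_original_identity(self):
        noise = NoiseConfig(descriptor_angle_deg=5.0, occlusion=((1, (40, 89)),))
        gt, dets = _scene_tracks(seed=29, n_frames=140, noise=noise)
        records = track_sequence(dets, TrackerConfig())
        gt_boxes = {r.frame_index: r.box for r in gt if r.track_id == 1}

        def id_at(frame):
            hits = [r.track_id for r in records if r.frame_index == frame
                    and iou(r.box, gt_boxes[frame]) > 0.5]
            return hits[0] if hits else None

        assert id_at(39) is not None
        assert id_at(39) == id_at(95)

    def test_track_deleted_after_max_age(self):
        v = np.zeros(4); v[0] = 1.0
        cfg = TrackerConfig(n_init=1, max_age=5)
        tr = Tracker(cfg)
        tr.step([Detection(0, (5, 5, 10, 10), 1.0, v)])
        assert tr.tracks[0].status == "confirmed"
        for _ in range(7):
            tr.step([])
        assert tr.tracks == []


class TestTrackSequence:
    def test_empty_sequence(self):
        assert track_sequence({}, TrackerConfig()) == []

    def test_deterministic(self):
        _, dets = _scene_tracks(seed=31)
        a = track_sequence(dets, TrackerConfig())
        b = track_sequence(dets, TrackerConfig())
        assert a == b

    def test_records_unique_per_frame_and_id(self):
        _, dets = _scene_tracks(seed=37, noise=NoiseConfig(jitter_px=1.0, miss_rate=0.05,
                                                           clutter_rate=0.3,
                                                           descriptor_angle_deg=5.0))
        records = track_sequence(dets, TrackerConfig())
        keys = [(r.frame_index, r.track_id) for r in records]
        assert len(keys) == len(set(keys))
        assert all(r.box[2] > 0 and r.box[3] > 0 for r in records)

    def test_confidence_threshold_filters_detections(self):
        v = np.zeros(4); v[0] = 1.0
        frames = {f: [Detection(f, (5.0 + f, 5.0, 10, 10), 0.4, v)] for f in range(10)}
        assert track_sequence(frames, TrackerConfig(ct=0.5)) == []
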