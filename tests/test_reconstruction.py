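import numpy as np
import pytest

from beetrack.association import TrackerConfig, track_sequence
from beetrack.io_formats import TrackRecord2D, fundamental_from_cameras
from beetrack.multicam import match_tracks
from beetrack.reconstruction import (compare_pairs, interpolate_gaps,
                                     reconstruct_tracks, triangulate_point)
from beetrack.synthetic import (NoiseConfig, SceneConfig, corrupt, project,
                                simulate_flight)

from conftest import random_camera_pair, visible_world_points


class TestInterpolateGaps:
    def test_midpoint_fill(self):
        recs = [TrackRecord2D(0, 1, (0, 0, 10, 10)),
                TrackRecord2D(2, 1, (2, 2, 10, 10))]
        out = interpolate_gaps(recs, max_gap=10)
        assert len(out) == 3
        mid = out[1]
        assert mid.frame_index == 1
        assert mid.box == (1, 1, 10, 10)
        assert mid.flag_interpolated

    def test_gap_longer_than_max_left_open(self):
        recs = [TrackRecord2D(0, 1, (0, 0, 10, 10)),
                TrackRecord2D(5, 1, (5, 5, 10, 10))]
        assert interpolate_gaps(recs, max_gap=3) == recs

    def test_no_gap_identity(self):
        recs = [TrackRecord2D(k, 1, (float(k), 0, 10, 10)) for k in range(5)]
        assert interpolate_gaps(recs, max_gap=10) == recs

    def test_span_contiguous_after_interpolation(self):
        recs = [TrackRecord2D(f, 1, (float(f), 0, 10, 10))
                for f in (0, 3, 4, 9)]
        out = interpolate_gaps(recs, max_gap=10)
        assert [r.frame_index for r in out] == list(range(10))


class TestTriangulatePoint:
    def test_exact_inverse_on_fixture_rig(self, rig):
        X = np.array([100.0, 50.0, 1700.0])
        x1 = rig[0].project(X)[0]
        x3 = rig[2].project(X)[0]
        Xr, resid, ok = triangulate_point(rig[0], rig[2], x1, x3)
        np.testing.assert_allclose(Xr, X, atol=1e-6)
        assert resid < 1e-6
        assert ok

    def test_property_exact_on_random_rigs(self):
        rng = np.random.default_rng(53)
        for _ in range(50):
            cam_a, cam_b = random_camera_pair(rng)
            pts = visible_world_points(cam_a, cam_b, rng, 20)
            for X in pts:
                xa = cam_a.project(X)[0]
                xb = cam_b.project(X)[0]
                Xr, resid, _ = triangulate_point(cam_a, cam_b, xa, xb)
                np.testing.assert_allclose(Xr, X, atol=1e-5)
                assert resid < 1e-5

    def test_jitter_error_regression_bound(self, rig):
        # 0.5 px jitter through the fixture stereo pair: the median 3D error
        # stays under a frozen regression bound (measured 0.94 mm at first
        # implementation on this geometry; bound set at 2 mm)
        rng = np.random.default_rng(59)
        errs = []
        for _ in range(1000):
            X = np.array([rng.uniform(-900, 900), rng.uniform(-140, 140),
                          rng.uniform(1510, 1790)])
            x1 = rig[0].project(X)[0] + rng.normal(0, 0.5, 2)
            x3 = rig[2].project(X)[0] + rng.normal(0, 0.5, 2)
            Xr, _, _ = triangulate_point(rig[0], rig[2], x1, x3)
            errs.append(np.linalg.norm(Xr - X))
        assert np.median(errs) < 2.0

    def test_reprojection_of_result(self, rig):
        X = np.array([-500.0, 100.0, 1600.0])
        x1 = rig[0].project(X)[0]
        x2 = rig[1].project(X)[0]
        Xr, _, _ = triangulate_point(rig[0], rig[1], x1, x2)
        np.testing.assert_allclose(rig[0].project(Xr)[0], x1, atol=1e-6)
        np.testing.assert_allclose(rig[1].project(Xr)[0], x2, atol=1e-6)


@pytest.fixture(scope="module")
def pipeline_3d(rig):
    """Full noise-free chain: simulate -> project -> track -> match ->
    reconstruct with both camera pairs."""
    scene = SceneConfig(n_bees=3, n_frames=150, seed=61)
    traj = simulate_flight(scene)
    gt = project(traj, rig)
    dets, _, _ = corrupt(gt, NoiseConfig(), seed=62)
    tracks = {c: track_sequence(dets[c], TrackerConfig()) for c in (1, 2, 3)}
    out = {}
    for pair_label, idx in ((12, 1), (13, 2)):
        F = fundamental_from_cameras(rig[0], rig[idx])
        mm = match_tracks(tracks[1], tracks[idx + 1], F)
        out[pair_label] = reconstruct_tracks(
            tracks[1], tracks[idx + 1], mm, rig[0], rig[idx], pair_label)
    return traj, out


class TestReconstructTracks:
    def test_round_trip_rmse_below_micron_scale(self, pipeline_3d):
        traj, out = pipeline_3d
        n_bees = traj.shape[0]
        for pair_label, tracks3d in out.items():
            assert len(tracks3d) == n_bees
            for t in tracks3d:
                best = min(
                    range(n_bees),
                    key=lambda b: np.mean(np.linalg.norm(
                        traj[b, t.frames] - t.positions, axis=1)))
                rmse = np.sqrt(np.mean(np.sum(
                    (traj[best, t.frames] - t.positions) ** 2, axis=1)))
                assert rmse < 1e-3

    def test_pair_discrepancy_noise_free(self, pipeline_3d):
        _, out = pipeline_3d
        cmp = compare_pairs(out[12], out[13])
        assert cmp.per_identity
        for stats in cmp.per_identity.values():
            assert stats["max"] < 1e-6

    def test_ids_subset_of_camera1_ids(self, pipeline_3d):
        _, out = pipeline_3d
        for tracks3d in out.values():
            assert all(t.track_id >= 1 for t in tracks3d)

    def test_unmatched_identities_produce_no_output(self, rig):
        scene = SceneConfig(n_bees=2, n_frames=80, seed=67)
        gt = project(simulate_flight(scene), rig)
        F = fundamental_from_cameras(rig[0], rig[1])
        only_one = [r for r in gt[2] if r.track_id == 1]
        mm = match_tracks(gt[1], only_one, F)
        out = reconstruct_tracks(gt[1], only_one, mm, rig[0], rig[1], 12)
        assert [t.track_id for t in out] == [1]


class TestComparePairs:
    def test_identity_only_in_one_pair_is_uncompared(self, rig):
        scene = SceneConfig(n_bees=2, n_frames=60, seed=71)
        traj = simulate_flight(scene)
        from beetrack.reconstruction import Track3D
        a = [Track3D(1, list(range(60)), traj[0], 12),
             Track3D(2, list(range(60)), traj[1], 12)]
        b = [Track3D(1, list(range(60)), traj[0], 13)]
        cmp = compare_pairs(a, b)
        assert cmp.uncompared == [2]
        assert cmp.per_identity[1]["max"] == 0.0

    def test_discrepancy_grows_with_jitter(self, rig):
        """Mean cross-pair discrepancy is monotone in detection jitter."""
        F12 = fundamental_from_cameras(rig[0], rig[1])
        F13 = fundamental_from_cameras(rig[0], rig[2])
        means = []
        for sigma in (0.5, 2.0):
            vals = []
            for seed in range(10):
                scene = SceneConfig(n_bees=1, n_frames=60, seed=seed)
                traj = simulate_flight(scene)
                gt = project(traj, rig)
                rng = np.random.default_rng(seed + 900)

                def jit(recs):
                    return [TrackRecord2D(r.frame_index, r.track_id,
                                          (r.box[0] + rng.normal(0, sigma),
                                           r.box[1] + rng.normal(0, sigma),
                                           r.box[2], r.box[3])) for r in recs]

                t1, t2, t3 = jit(gt[1]), jit(gt[2]), jit(gt[3])
                r12 = reconstruct_tracks(t1, t2, match_tracks(t1, t2, F12),
                                         rig[0], rig[1], 12)
                r13 = reconstruct_tracks(t1, t3, match_tracks(t1, t3, F13),
                                         rig[0], rig[2], 13)
                cmp = compare_pairs(r12, r13)
                vals.extend(s["mean"] for s in cmp.per_identity.values())
            means.append(np.mean(vals))
        assert means[1] > means[0]
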