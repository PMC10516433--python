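import numpy as np
import pytest

from beetrack.synthetic import SceneConfig, make_rig, project, simulate_flight


@pytest.fixture(scope="session")
def rig():
    return make_rig()


@pytest.fixture(scope="session")
def small_scene(rig):
    """Three animals, 150 frames: trajectories, rig and exact 2D ground truth."""
    scene = SceneConfig(n_bees=3, n_frames=150, seed=11)
    traj = simulate_flight(scene)
    gt = project(traj, rig)
    return scene, traj, gt


def random_camera_pair(rng):
    """A random synthetic stereo pair sharing a view of the volume around
    the origin: random centers, look-at orientations with random roll."""
    from beetrack.io_formats import CameraModel

    def look_at(center, target, roll):
        z = target - center
        z = z / np.linalg.norm(z)
        up = _unit(rng)
        while abs(up @ z) > 0.9:
            up = _unit(rng)
        x = np.cross(up, z)
        x /= np.linalg.norm(x)
        y = np.cross(z, x)
        c, s = np.cos(roll), np.sin(roll)
        return np.stack([c * x + s * y, -s * x + c * y, z])

    def one(camera_id, center):
        f = rng.uniform(800, 2000)
        K = np.array([[f, 0, rng.uniform(700, 900)],
                      [0, f, rng.uniform(700, 900)],
                      [0, 0, 1.0]])
        R = look_at(center, rng.uniform(-100, 100, 3), rng.uniform(0, 2 * np.pi))
        t = -R @ center
        return CameraModel(camera_id, K, R, t, (1600, 1600))

    c1 = rng.uniform(2000, 4000) * _unit(rng)
    c2 = c1 + rng.uniform(200, 1500) * _unit(rng)
    return one(1, c1), one(2, c2)


def _unit(rng):
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def visible_world_points(cam_a, cam_b, rng, n):
    """World points projecting inside both cameras' image frames."""
    out = []
    have = 0
    while have < n:
        batch = rng.uniform(-800, 800, size=(20000, 3))
        mask = np.ones(len(batch), dtype=bool)
        for cam in (cam_a, cam_b):
            z = batch @ cam.R.T[:, 2] + cam.t[2]
            mask &= z > 100
            img = (batch @ cam.R.T + cam.t) @ cam.K.T
            with np.errstate(divide="ignore", invalid="ignore"):
                xy = img[:, :2] / img[:, 2:3]
            w, h = cam.image_size
            mask &= np.isfinite(xy).all(axis=1)
            mask &= (xy[:, 0] >= 0) & (xy[:, 0] <= w)
            mask &= (xy[:, 1] >= 0) & (xy[:, 1] <= h)
        sel = batch[mask]
        out.append(sel)
        have += len(sel)
    return np.concatenate(out)[:n]
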