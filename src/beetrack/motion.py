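"""Constant-velocity Kalman filter over bounding-box states.

The state is the 8-vector ``(cx, cy, a, h, vcx, vcy, va, vh)``: box center
in pixels, aspect ratio ``w/h``, box height in pixels, and their per-frame
velocities.  The measurement is the first four components.  Process and
measurement noise standard deviations scale with the box height so that
the filter behaves consistently for animals near and far from the camera.

The squared Mahalanobis distance between a track's predicted measurement
and a candidate detection,

    d2(i, j) = (d_j - y_i)^T S_i^{-1} (d_j - y_i),

with ``y_i`` the predicted measurement mean and ``S_i`` the innovation
covariance, is the motion-matching cost used for gating: under the model
it is chi-squared with 4 degrees of freedom, so the 0.95 quantile 9.4877
is the default admissibility gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Detection

__all__ = [
    "KalmanState",
    "KalmanFilter",
    "CHI2_95_4DOF",
    "box_to_measurement",
    "measurement_to_box",
    "simulate_filter_consistency",
]

# 0.95 quantile of chi-squared with 4 dof (scipy.stats.chi2.ppf(0.95, 4))
CHI2_95_4DOF = 9.487729036781154


@dataclass(frozen=True)
class KalmanState:
    mean: np.ndarray        # (8,)
    covariance: np.ndarray  # (8, 8) symmetric positive definite


def box_to_measurement(box: tuple[float, float, float, float]) -> np.ndarray:
    """(left, top, w, h) -> (cx, cy, aspect, h)."""
    left, top, w, h = box
    return np.array([left + w / 2.0, top + h / 2.0, w / h, h])


def measurement_to_box(z: np.ndarray) -> tuple[float, float, float, float]:
    cx, cy, a, h = z
    w = a * h
    return (cx - w / 2.0, cy - h / 2.0, w, h)


class KalmanFilter:
    """Filter over the 8-dim box state with height-scaled noise.

    Parameters
    ----------
    std_weight_position, std_weight_velocity:
        Noise standard deviations are these weights times the current box
        height (defaults 1/20 and 1/160).
    """

    ndim = 4

    def __init__(self, std_weight_position: float = 1.0 / 20,
                 std_weight_velocity: float = 1.0 / 160) -> None:
        self._wp = std_weight_position
        self._wv = std_weight_velocity
        self._F = np.eye(8)
        self._F[:4, 4:] = np.eye(4)  # unit frame interval
        self._H = np.eye(4, 8)

    # -- noise models -----------------------------------------------------
    def _process_noise(self, h: float) -> np.ndarray:
        std = [self._wp * h, self._wp * h, 1e-2, self._wp * h,
               self._wv * h, self._wv * h, 1e-5, self._wv * h]
        return np.diag(np.square(std))

    def _measurement_noise(self, h: float) -> np.ndarray:
        std = [self._wp * h, self._wp * h, 1e-1, self._wp * h]
        return np.diag(np.square(std))

    # -- filter steps -----------------------------------------------------
    def initiate(self, detection: Detection) -> KalmanState:
        """New state from an unassociated detection: zero velocity, broad
        height-scaled covariance."""
        z = box_to_measurement(detection.box)
        h = z[3]
        if h <= 0 or z[2] <= 0:
            raise ValueError(f"non-positive box dimensions {detection.box!r}")
        mean = np.concatenate([z, np.zeros(4)])
        std = [2 * self._wp * h, 2 * self._wp * h, 1e-2, 2 * self._wp * h,
               10 * self._wv * h, 10 * self._wv * h, 1e-5, 10 * self._wv * h]
        return KalmanState(mean, np.diag(np.square(std)))

    def predict(self, state: KalmanState) -> KalmanState:
        mean = self._F @ state.mean
        cov = self._F @ state.covariance @ self._F.T + self._process_noise(state.mean[3])
        return KalmanState(mean, cov)

    def project(self, state: KalmanState) -> tuple[np.ndarray, np.ndarray]:
        """Predicted measurement mean y_i and innovation covariance S_i."""
        y = self._H @ state.mean
        S = self._H @ state.covariance @ self._H.T + self._measurement_noise(state.mean[3])
        return y, S

    def update(self, state: KalmanState, detection: Detection) -> KalmanState:
        z = box_to_measurement(detection.box)
        y, S = self.project(state)
        try:
            chol = np.linalg.cholesky(S)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular innovation covariance") from exc
        # gain K = P H^T S^-1 via two triangular solves
        PHt = state.covariance @ self._H.T
        K = np.linalg.solve(chol.T, np.linalg.solve(chol, PHt.T)).T
        mean = state.mean + K @ (z - y)
        cov = state.covariance - K @ S @ K.T
        cov = (cov + cov.T) / 2.0
        if mean[3] <= 0:
            raise ValueError("non-positive height after update")
        return KalmanState(mean, cov)

    def squared_mahalanobis(self, state: KalmanState, detections: list[Detection]) -> np.ndarray:
        """d2(i, j) for one predicted track against each detection."""
        y, S = self.project(state)
        try:
            chol = np.linalg.cholesky(S)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular innovation covariance") from exc
        Z = np.array([box_to_measurement(d.box) for d in detections])
        resid = Z - y
        solved = np.linalg.solve(chol, resid.T)
        return np.einsum("ij,ij->j", solved, solved)


def simulate_filter_consistency(
    n_steps: int, seed: int, height: float = 40.0,
    std_weight_position: float = 1.0 / 20,
    std_weight_velocity: float = 1.0 / 160,
) -> np.ndarray:
    """Self-consistency harness: simulate the filter's own linear-Gaussian
    model and return the squared Mahalanobis distance of the true
    measurement at every step.

    Noise scales are frozen at a reference box height so the injected
    process/measurement noise has exactly the covariance the filter
    assumes; the returned samples are then exactly chi-squared with 4
    degrees of freedom, which calibrates the gating threshold.
    """
    rng = np.random.default_rng(seed)
    kf = KalmanFilter(std_weight_position, std_weight_velocity)
    Q = kf._process_noise(height)
    R = kf._measurement_noise(height)
    F, H = kf._F, kf._H

    x = np.array([100.0, 100.0, 0.5, height, 1.0, 0.5, 0.0, 0.0])
    det0 = Detection(0, measurement_to_box(H @ x), 1.0)
    state = kf.initiate(det0)

    qchol = np.linalg.cholesky(Q)
    rchol = np.linalg.cholesky(R)
    d2 = np.empty(n_steps)
    for k in range(n_steps):
        x = F @ x + qchol @ rng.standard_normal(8)
        z = H @ x + rchol @ rng.standard_normal(4)
        state = KalmanState(F @ state.mean, F @ state.covariance @ F.T + Q)
        y = H @ state.mean
        S = H @ state.covariance @ H.T + R
        resid = z - y
        d2[k] = resid @ np.linalg.solve(S, resid)
        # measurement update with the frozen R
        PHt = state.covariance @ H.T
        K = PHt @ np.linalg.inv(S)
        mean = state.mean + K @ resid
        cov = state.covariance - K @ S @ K.T
        state = KalmanState(mean, (cov + cov.T) / 2.0)
    return d2
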