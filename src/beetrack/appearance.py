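"""Appearance descriptors, the per-track gallery, and the cosine matching degree.

A track keeps a rolling gallery of the unit-norm appearance descriptors of
its 100 most recent associated detections.  The appearance cost between
track ``i`` and detection ``j`` is the matching degree

    d1(i, j) = min_k { 1 - r_j . r_k },   r_k in the gallery of track i,

i.e. the smallest cosine distance between the detection's descriptor and
any gallery member.  Descriptors normally come from an external source (a
sidecar file produced by a learned re-identification model); ``describe``
provides a deterministic hand-crafted fallback built from intensity and
gradient-orientation statistics so the pipeline runs without any trained
model.
"""

from __future__ import annotations

import logging
from collections import deque
from typing import Iterable

import numpy as np
from skimage.transform import resize

__all__ = ["Gallery", "matching_degree", "describe", "GALLERY_CAPACITY", "PATCH_SIZE"]

logger = logging.getLogger(__name__)

GALLERY_CAPACITY = 100
PATCH_SIZE = 95  # descriptor input resolution, px

# fixed projection seed: the fallback descriptor must be a pure function of
# the patch, identical across processes and runs
_PROJECTION_SEED = 714025


class Gallery:
    """Rolling store of a track's most recent descriptors (oldest evicted)."""

    def __init__(self, capacity: int = GALLERY_CAPACITY) -> None:
        self.capacity = capacity
        self._items: deque[np.ndarray] = deque(maxlen=capacity)

    def add(self, descriptor: np.ndarray) -> None:
        vec = np.asarray(descriptor, dtype=float)
        norm = np.linalg.norm(vec)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"descriptor norm {norm} != 1")
        self._items.append(vec)

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self):
        return iter(self._items)

    def as_matrix(self) -> np.ndarray:
        return np.stack(list(self._items))


def matching_degree(gallery: Gallery, descriptor: np.ndarray) -> float:
    """Minimum cosine distance between ``descriptor`` and the gallery.

    Returns a value in [0, 2]; 0 iff the descriptor exactly equals a
    gallery member (unit vectors).  Raises on an empty gallery: a track
    without appearance information cannot be appearance-matched.
    """
    if len(gallery) == 0:
        raise ValueError("matching degree undefined for an empty gallery")
    sims = gallery.as_matrix() @ np.asarray(descriptor, dtype=float)
    return float(np.min(1.0 - sims))


def _projection_matrix(n_features: int, d: int) -> np.ndarray:
    rng = np.random.default_rng(_PROJECTION_SEED)
    return rng.standard_normal((d, n_features)) / np.sqrt(n_features)


def describe(patch: np.ndarray, d: int = 128) -> np.ndarray:
    """Deterministic appearance descriptor of a grayscale image patch.

    The patch is resampled to 95x95, summarized by a 5x5 grid of intensity
    means plus 8-bin gradient-orientation histograms on a 3x3 grid
    (gradient-magnitude weighted), projected to ``d`` dimensions by a
    fixed seeded Gaussian random projection and normalized to unit length.
    An all-constant patch has no structure to describe and maps to the
    canonical first basis vector (logged as a warning).
    """
    patch = np.asarray(patch, dtype=float)
    if patch.size == 0:
        raise ValueError("empty patch")
    if patch.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale patch, got shape {patch.shape}")
    if np.ptp(patch) == 0:
        logger.warning("all-constant patch: returning canonical descriptor")
        out = np.zeros(d)
        out[0] = 1.0
        return out
    img = resize(patch, (PATCH_SIZE, PATCH_SIZE), anti_aliasing=True, mode="reflect")
    img = (img - img.min()) / (img.max() - img.min())

    feats: list[float] = []
    # 5x5 blockwise intensity means
    step = PATCH_SIZE // 5
    for bi in range(5):
        for bj in range(5):
            feats.append(float(img[bi * step:(bi + 1) * step, bj * step:(bj + 1) * step].mean()))
    # 3x3 grid of 8-bin gradient orientation histograms
    gy, gx = np.gradient(img)
    mag = np.hypot(gx, gy)
    ang = np.arctan2(gy, gx)  # [-pi, pi]
    step3 = PATCH_SIZE // 3
    for bi in range(3):
        for bj in range(3):
            sl = (slice(bi * step3, (bi + 1) * step3), slice(bj * step3, (bj + 1) * step3))
            hist, _ = np.histogram(ang[sl], bins=8, range=(-np.pi, np.pi), weights=mag[sl])
            total = hist.sum()
            feats.extend(hist / total if total > 0 else hist)
    vec = np.asarray(feats)
    vec = _projection_matrix(vec.size, d) @ vec
    norm = np.linalg.norm(vec)
    if norm == 0:  # pragma: no cover - degenerate projection
        out = np.zeros(d)
        out[0] = 1.0
        return out
    return vec / norm
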