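"""Binarisation of vessel-probability volumes.

Two alternatives are provided: plain thresholding, and a seeded
region-growing scheme in which high-confidence voxels (probability >= a
seed threshold ``s``) initiate growth through all connected voxels whose
probability reaches a lower growth threshold ``t``.  The result is exactly
the union of connected components of ``{p >= t}`` that contain at least
one seed, which is how the growth is computed here (a single
connected-component labelling instead of an explicit breadth-first
flood fill).

Both operations accept a ``scope``: ``"full_volume"`` applies them to the
reassembled probability map, ``"per_patch"`` to each patch independently
(growth then cannot cross patch seams).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from murivess.preprocess import PatchSet

__all__ = [
    "PostprocessConfig",
    "threshold_mask",
    "region_grow",
    "postprocess_probabilities",
    "postprocess_patches",
]


@dataclass(frozen=True)
class PostprocessConfig:
    mode: str = "threshold"  # "threshold" | "region_growing"
    t: float = 0.45
    s: float = 0.6
    connectivity: int = 6
    scope: str = "full_volume"  # "full_volume" | "per_patch"

    def __post_init__(self):
        if self.mode not in ("threshold", "region_growing"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.t <= 1:
            raise ValueError("t must be in (0, 1]")
        if self.mode == "region_growing" and not self.t <= self.s <= 1:
            raise ValueError("region growing requires 0 < t <= s <= 1")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.scope not in ("full_volume", "per_patch"):
            raise ValueError(f"unknown scope {self.scope!r}")


def _structure(connectivity: int) -> np.ndarray:
    # 6-connectivity = face neighbours (rank-1 structure), 26 = full cube
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


def threshold_mask(prob: np.ndarray, t: float) -> np.ndarray:
    """Foreground where probability >= t (inclusive)."""
    if not 0 < t <= 1:
        raise ValueError("t must be in (0, 1]")
    return (np.asarray(prob) >= t).astype(np.uint8)


def region_grow(
    prob: np.ndarray, s: float, t: float, connectivity: int = 6
) -> np.ndarray:
    """Grow from seed voxels ``{p >= s}`` through voxels with ``p >= t``.

    Equivalent to keeping every connected component of ``{p >= t}`` that
    intersects the seed set; with ``s == t`` this degenerates exactly to
    :func:`threshold_mask`.
    """
    if t > s:
        raise ValueError("growth threshold t must not exceed seed threshold s")
    grow = np.asarray(prob) >= t
    seeds = np.asarray(prob) >= s
    if not seeds.any():
        return np.zeros(grow.shape, dtype=np.uint8)
    labels, n = ndimage.label(grow, structure=_structure(connectivity))
    seeded = np.unique(labels[seeds])
    keep = np.zeros(n + 1, dtype=bool)
    keep[seeded] = True
    keep[0] = False
    return keep[labels].astype(np.uint8)


def _apply(prob: np.ndarray, config: PostprocessConfig) -> np.ndarray:
    if config.mode == "threshold":
        return threshold_mask(prob, config.t)
    return region_grow(prob, config.s, config.t, config.connectivity)


def postprocess_probabilities(prob: np.ndarray, config: PostprocessConfig) -> np.ndarray:
    """Binarise a full probability volume according to *config*."""
    return _apply(prob, config)


def postprocess_patches(patchset: PatchSet, config: PostprocessConfig) -> PatchSet:
    """Binarise each probability patch independently (per-patch scope)."""
    out = [_apply(p, config) for p in patchset.patches]
    return PatchSet(patches=out, grid_shape=patchset.grid_shape, geometry=patchset.geometry)
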