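"""Pre-processing chain for micro-MRI stacks.

The pipeline order is fixed: masked ROI extraction, zero-padding up to a
multiple of the patch edge, Gaussian denoising, per-stack min-max
normalisation to ``[0, 1]``, and tiling into non-overlapping cubic patches.
:class:`RoiGeometry` records enough information to map any result back
into the original stack frame exactly, and :func:`reassemble` performs
that inverse mapping.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
import numpy as np
from scipy import ndimage

__all__ = [
    "PreprocessConfig",
    "RoiGeometry",
    "PatchSet",
    "extract_roi",
    "pad_to_block",
    "gaussian_smooth",
    "minmax_normalize",
    "patchify",
    "reassemble",
    "preprocess_stack",
]

DEFAULT_BLUR_SIGMA = 0.5
DEFAULT_BLOCK = 32


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the pre-processing chain.

    ``blur_sigma`` is the isotropic Gaussian standard deviation in voxels;
    ``block`` is the cubic patch edge length.
    """

    blur_sigma: float = DEFAULT_BLUR_SIGMA
    block: int = DEFAULT_BLOCK

    def __post_init__(self):
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.block < 8 or int(self.block) != self.block:
            raise ValueError("block must be an integer >= 8")


@dataclass(frozen=True)
class RoiGeometry:
    """Crop offsets and pad amounts mapping an ROI back to the stack frame.

    ``bbox_low``/``bbox_high`` delimit the half-open bounding box of the
    brain mask inside the original volume; ``pad`` is the zero padding
    appended at the high-index end of each axis.
    """

    original_shape: tuple[int, int, int]
    bbox_low: tuple[int, int, int]
    bbox_high: tuple[int, int, int]
    pad: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self):
        for lo, hi, n in zip(self.bbox_low, self.bbox_high, self.original_shape):
            if not (0 <= lo <= hi <= n):
                raise ValueError("inconsistent ROI bounding box")

    @property
    def roi_shape(self) -> tuple[int, int, int]:
        """Shape of the (possibly padded) ROI volume."""
        return tuple(
            hi - lo + p for lo, hi, p in zip(self.bbox_low, self.bbox_high, self.pad)
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "RoiGeometry":
        d = json.loads(text)
        return cls(*(tuple(d[k]) for k in ("original_shape", "bbox_low", "bbox_high", "pad")))


@dataclass
class PatchSet:
    """Ordered non-overlapping tiling of an ROI into cubic patches.

    Patches are ordered lexicographically in their ``(z, y, x)`` grid
    coordinates, so ``patches[i]`` sits at grid position
    ``np.unravel_index(i, grid_shape)``.
    """

    patches: list = field(default_factory=list)
    grid_shape: tuple[int, int, int] = (0, 0, 0)
    geometry: RoiGeometry | None = None

    @property
    def block(self) -> int:
        return self.patches[0].shape[0]

    def __len__(self) -> int:
        return len(self.patches)


def extract_roi(volume: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, RoiGeometry]:
    """Crop *volume* to the bounding box of the brain *mask*.

    Voxels inside the box but outside the mask are zeroed, restricting all
    downstream processing to the brain itself.
    """
    volume = np.asarray(volume)
    mask = np.asarray(mask)
    if volume.shape != mask.shape:
        raise ValueError(f"shape mismatch: {volume.shape} vs {mask.shape}")
    if not mask.any():
        raise ValueError("empty brain mask")

    nz = np.nonzero(mask)
    low = tuple(int(idx.min()) for idx in nz)
    high = tuple(int(idx.max()) + 1 for idx in nz)
    sl = tuple(slice(lo, hi) for lo, hi in zip(low, high))
    roi = np.where(mask[sl] != 0, volume[sl], 0)
    geom = RoiGeometry(original_shape=volume.shape, bbox_low=low, bbox_high=high)
    return roi, geom


def pad_to_block(
    roi: np.ndarray, geometry: RoiGeometry, block: int = DEFAULT_BLOCK
) -> tuple[np.ndarray, RoiGeometry]:
    """Zero-pad each axis to the smallest multiple of *block* >= its length.

    Padding is appended at the high-index end only, so ``bbox_low`` remains
    the single offset needed to invert the crop.  Idempotent.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    pad = tuple((-n) % block for n in roi.shape)
    padded = np.pad(roi, [(0, p) for p in pad])
    geom = RoiGeometry(
        original_shape=geometry.original_shape,
        bbox_low=geometry.bbox_low,
        bbox_high=geometry.bbox_high,
        pad=tuple(p0 + p for p0, p in zip(geometry.pad, pad)),
    )
    return padded, geom


def gaussian_smooth(volume: np.ndarray, sigma: float = DEFAULT_BLUR_SIGMA) -> np.ndarray:
    """Isotropic Gaussian blur with reflecting boundaries; sigma=0 is a no-op."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return volume
    return ndimage.gaussian_filter(np.asarray(volume, dtype=np.float32), sigma, mode="reflect")


def minmax_normalize(volume: np.ndarray) -> np.ndarray:
    """Rescale the whole volume to ``[0, 1]``; a constant volume maps to 0.

    Per-stack normalisation compensates for the large brightness
    differences between acquisitions (outlier stacks with several-fold
    higher mean intensity) while preserving inter-patch comparability.
    """
    volume = np.asarray(volume, dtype=np.float32)
    vmin = float(volume.min())
    vmax = float(volume.max())
    if vmax == vmin:
        return np.zeros_like(volume)
    return (volume - vmin) / (vmax - vmin)


def patchify(
    volume: np.ndarray, geometry: RoiGeometry, block: int = DEFAULT_BLOCK
) -> PatchSet:
    """Split a block-aligned ROI into non-overlapping ``block**3`` patches."""
    for n in volume.shape:
        if n % block != 0:
            raise ValueError(f"axis length {n} is not a multiple of block {block}")
    grid = tuple(n // block for n in volume.shape)
    patches = []
    for iz in range(grid[0]):
        for iy in range(grid[1]):
            for ix in range(grid[2]):
                patches.append(
                    volume[
                        iz * block : (iz + 1) * block,
                        iy * block : (iy + 1) * block,
                        ix * block : (ix + 1) * block,
                    ].copy()
                )
    return PatchSet(patches=patches, grid_shape=grid, geometry=geometry)


def reassemble(patchset: PatchSet) -> np.ndarray:
    """Tile patches back and place the ROI into the original stack frame.

    Inverts :func:`patchify` followed by the padding and the crop: padding
    is stripped and the ROI content is written at ``bbox_low`` inside a
    zero background of the original shape.
    """
    grid = patchset.grid_shape
    n_expected = int(np.prod(grid))
    if len(patchset.patches) != n_expected:
        raise ValueError(
            f"patch count {len(patchset.patches)} does not match grid {grid}"
        )
    block = patchset.block
    roi_padded = np.zeros(tuple(g * block for g in grid), dtype=patchset.patches[0].dtype)
    for i, patch in enumerate(patchset.patches):
        if patch.shape != (block, block, block):
            raise ValueError(f"patch {i} has shape {patch.shape}, expected {block}^3")
        iz, iy, ix = np.unravel_index(i, grid)
        roi_padded[
            iz * block : (iz + 1) * block,
            iy * block : (iy + 1) * block,
            ix * block : (ix + 1) * block,
        ] = patch

    geom = patchset.geometry
    if geom is None:
        return roi_padded
    core = roi_padded[
        tuple(slice(0, hi - lo) for lo, hi in zip(geom.bbox_low, geom.bbox_high))
    ]
    out = np.zeros(geom.original_shape, dtype=roi_padded.dtype)
    out[tuple(slice(lo, hi) for lo, hi in zip(geom.bbox_low, geom.bbox_high))] = core
    return out


def preprocess_stack(
    volume: np.ndarray,
    mask: np.ndarray,
    config: PreprocessConfig = PreprocessConfig(),
    patch: bool = True,
):
    """Run the full chain; returns ``(PatchSet)`` or ``(volume, geometry)``.

    With ``patch=False`` the patch-tiling step is skipped and the padded,
    blurred, normalised ROI is returned together with its geometry — the
    variant used by the vesselness baseline, which operates on the whole
    volume.
    """
    roi, geom = extract_roi(volume, mask)
    roi, geom = pad_to_block(roi, geom, config.block)
    roi = gaussian_smooth(roi, config.blur_sigma)
    roi = minmax_normalize(roi)
    if not patch:
        return roi, geom
    return patchify(roi, geom, config.block)
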