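"""Reading and writing 3D image stacks and binary masks.

Volumes are plain ``numpy`` arrays in ``(z, y, x)`` order, where ``z`` is
the slice (TIFF page) index.  Two on-disk formats are supported
interchangeably: multi-page TIFF and NIfTI-1 (``.nii`` / ``.nii.gz``).
Intensity stacks are unsigned 16-bit in ``[0, 65535]``; derived volumes
(probability maps, normalised images) are float32 in ``[0, 1]``; masks are
stored as 8-bit ``{0, 1}``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

__all__ = ["load_stack", "save_stack", "FormatError"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


class FormatError(ValueError):
    """Raised when a file does not contain a rank-3 volume."""


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in _NIFTI_SUFFIXES)


def load_stack(path, expect: str = "intensity") -> np.ndarray:
    """Load a 3D volume from a multi-page TIFF or NIfTI file.

    Parameters
    ----------
    path
        File to read.
    expect
        ``"intensity"`` returns the voxel data unchanged; ``"mask"``
        binarizes the volume (any nonzero voxel becomes 1) and returns
        ``uint8``.

    Returns
    -------
    numpy.ndarray
        Rank-3 array in ``(z, y, x)`` order.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    FormatError
        If the stored image is not rank 3.
    """
    if expect not in ("intensity", "mask"):
        raise ValueError(f"expect must be 'intensity' or 'mask', got {expect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        # NIfTI stores (x, y, z); canonical in-memory order is (z, y, x).
        if data.ndim == 3:
            data = np.transpose(data, (2, 1, 0))
    else:
        data = tifffile.imread(str(path))

    if data.ndim != 3:
        raise FormatError(f"{path}: expected a rank-3 volume, got rank {data.ndim}")

    if expect == "mask":
        values = np.unique(data)
        if len(values) > 2:
            warnings.warn(
                f"{path}: mask has {len(values)} distinct values; binarizing",
                stacklevel=2,
            )
        data = (data != 0).astype(np.uint8)
    return data


def save_stack(volume: np.ndarray, path) -> None:
    """Write a rank-3 volume; the format is chosen from the file suffix.

    Integer volumes round-trip bit-identically through :func:`load_stack`;
    floating-point volumes are written as float32.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise FormatError(f"expected a rank-3 volume, got rank {volume.ndim}")
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"parent directory does not exist: {path.parent}")

    if np.issubdtype(volume.dtype, np.floating):
        volume = volume.astype(np.float32)

    if _is_nifti(path):
        data = np.transpose(volume, (2, 1, 0))  # back to NIfTI (x, y, z)
        nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(path))
    else:
        tifffile.imwrite(str(path), volume, photometric="minisblack")
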