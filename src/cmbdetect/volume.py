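"""Core 3D containers and NIfTI I/O.

Arrays are indexed ``(x, y, z)``, 0-based, with ``z`` the slice axis.
SWI volumes are anisotropic (thicker slices), so the slice axis is the
short axis of the ``20 x 20 x 16`` analysis window used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ScanVolume", "BrainMask", "load_nifti", "save_nifti", "load_mask"]


@dataclass
class ScanVolume:
    """A 3D intensity grid with physical voxel spacing.

    Parameters
    ----------
    intensities
        Non-negative float array of shape ``(nx, ny, nz)``.
    voxel_spacing
        mm per voxel along each axis, all positive.
    """

    intensities: np.ndarray
    voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 1.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.intensities.ndim}")
        if np.any(np.asarray(self.voxel_spacing) <= 0):
            raise ValueError(f"voxel spacing must be positive, got {self.voxel_spacing}")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    def copy(self) -> "ScanVolume":
        return ScanVolume(self.intensities.copy(), tuple(self.voxel_spacing))


@dataclass
class BrainMask:
    """Binary brain mask aligned to a :class:`ScanVolume`."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.mask.ndim}")
        if not self.mask.any():
            raise ValueError("brain mask has no foreground voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_nifti(vol: ScanVolume | BrainMask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI, encoding spacing in the affine."""
    if isinstance(vol, BrainMask):
        data = vol.mask.astype(np.uint8)
        spacing = (1.0, 1.0, 1.0)
    else:
        data = vol.intensities
        spacing = tuple(vol.voxel_spacing)
    nib.save(nib.Nifti1Image(data, _affine(spacing)), str(path))


def load_nifti(path: str | Path) -> ScanVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ScanVolume(np.asarray(img.dataobj, dtype=np.float64), spacing)


def load_mask(path: str | Path) -> BrainMask:
    img = nib.load(str(path))
    return BrainMask(np.asarray(img.dataobj) > 0)
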