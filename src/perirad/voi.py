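"""Volumes, masks and the peritumoral margin.

Conventions
-----------
Arrays are indexed ``(i, j, k)`` = axes ``(0, 1, 2)``; ``spacing_mm`` is
ordered the same way, so the physical position of voxel ``(i, j, k)`` is
``origin_mm + (i, j, k) * spacing_mm``.  All distances are physical
(millimetres), measured between voxel centers, so dilation radii behave
consistently under anisotropic spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar grid in Hounsfield units with physical voxel spacing."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite values (NaN/Inf)")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing_mm}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass(frozen=True)
class VoiPair:
    """Tumor mask plus its disjoint peritumoral margin on the same grid."""

    tumor: np.ndarray
    margin: np.ndarray
    spacing_mm: tuple[float, float, float]
    width_mm: float = 5.0

    def __post_init__(self) -> None:
        tumor = np.asarray(self.tumor, dtype=bool)
        margin = np.asarray(self.margin, dtype=bool)
        if tumor.shape != margin.shape:
            raise ValueError(
                f"tumor shape {tumor.shape} != margin shape {margin.shape}"
            )
        if not tumor.any():
            raise ValueError("tumor mask is empty")
        if (tumor & margin).any():
            raise ValueError("tumor and margin masks overlap")
        object.__setattr__(self, "tumor", tumor)
        object.__setattr__(self, "margin", margin)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))


def ball_offsets(radius_mm: float, spacing_mm) -> np.ndarray:
    """Integer voxel offsets whose center-to-center physical distance is <= radius.

    Returns a boolean structuring element (odd shape, origin at the center)
    suitable for :func:`scipy.ndimage.binary_dilation`.
    """
    spacing = np.asarray(spacing_mm, dtype=float)
    if radius_mm <= 0:
        raise ValueError("radius_mm must be > 0")
    reach = np.floor(radius_mm / spacing).astype(int)
    grids = np.meshgrid(
        *(np.arange(-r, r + 1) for r in reach), indexing="ij", sparse=False
    )
    dist2 = sum((g * s) ** 2 for g, s in zip(grids, spacing))
    return dist2 <= radius_mm**2 + 1e-9


def dilate_mask(mask: np.ndarray, radius_mm: float, spacing_mm) -> np.ndarray:
    """Dilate a binary mask by a physical radius, anisotropy-aware.

    The output contains exactly the voxels whose center lies within
    ``radius_mm`` of the center of some mask voxel.  Raises if the dilated
    region would extend beyond the grid (the margin would be truncated).
    """
    mask = _as_mask(mask)
    if not mask.any():
        raise ValueError("mask is empty")
    selem = ball_offsets(radius_mm, spacing_mm)
    pad = tuple(s // 2 for s in selem.shape)
    padded = np.pad(mask, [(p, p) for p in pad])
    dilated = ndimage.binary_dilation(padded, structure=selem)
    inner = tuple(slice(p, d - p if p else None) for p, d in zip(pad, dilated.shape))
    outside = dilated.copy()
    outside[inner] = False
    if outside.any():
        raise ValueError(
            f"dilation by {radius_mm} mm exceeds the grid bounds {mask.shape}; "
            "the margin would be truncated"
        )
    return dilated[inner]


def make_margin(tumor: np.ndarray, volume: ImageVolume, width_mm: float = 5.0) -> VoiPair:
    """Build the peritumoral margin: dilate the tumor by ``width_mm`` and subtract it."""
    tumor = _as_mask(tumor)
    if tumor.shape != volume.shape:
        raise ValueError(
            f"tumor mask shape {tumor.shape} does not match volume shape {volume.shape}"
        )
    dilated = dilate_mask(tumor, width_mm, volume.spacing_mm)
    margin = dilated & ~tumor
    return VoiPair(tumor=tumor, margin=margin, spacing_mm=volume.spacing_mm, width_mm=width_mm)


def _as_mask(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype != bool:
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(
                f"mask must be binary {{0,1}}, found values {uniq[:10]}"
            )
        arr = arr.astype(bool)
    return arr


# ---------------------------------------------------------------------------
# NIfTI I/O.  The affine is diagonal with the voxel spacing; the array axis
# order is preserved as-is, so round-trips are lossless.
# ---------------------------------------------------------------------------

def write_volume(volume: ImageVolume, path) -> None:
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    affine[:3, 3] = volume.origin_mm
    nib.save(nib.Nifti1Image(volume.values.astype(np.float64), affine), str(path))


def read_volume(path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    affine = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
    origin = tuple(float(o) for o in affine[:3, 3])
    return ImageVolume(values=data, spacing_mm=spacing, origin_mm=origin)


def write_mask(mask: np.ndarray, spacing_mm, path, origin_mm=(0.0, 0.0, 0.0)) -> None:
    mask = _as_mask(mask)
    affine = np.diag(list(spacing_mm) + [1.0])
    affine[:3, 3] = origin_mm
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def read_mask(path, reference: ImageVolume | None = None) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    mask = _as_mask(data)
    if reference is not None:
        if mask.shape != reference.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match volume shape {reference.shape}"
            )
        spacing = tuple(float(s) for s in np.abs(np.diag(img.affine)[:3]))
        if not np.allclose(spacing, reference.spacing_mm, rtol=1e-5):
            raise ValueError(
                f"mask spacing {spacing} does not match volume spacing "
                f"{reference.spacing_mm}"
            )
    return mask
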