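"""Shape indices of a binary VOI: volume, sphericity, compacity.

Surface area is mesh-based by default: the binary mask is lightly smoothed
(Gaussian, 0.8 voxel) into an occupancy field and triangulated at the
0.5-level iso-surface.  Meshing the raw binary mask leaves a staircase
artifact whose ~8% area overestimate does not vanish with refinement; the
anti-aliased field restores convergence (a digital sphere's sphericity
approaches 1 as the radius grows).  A voxel-face-count variant is exact for
axis-aligned blocks and upper-bounds the mesh area.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure

_MESH_SMOOTH_SIGMA_VOX = 0.8


def surface_area_mm2(mask: np.ndarray, spacing_mm, method: str = "mesh") -> float:
    """Surface area of the mask boundary in mm^2."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    spacing = np.asarray(spacing_mm, dtype=float)
    if method == "mesh":
        padded = np.pad(mask.astype(np.float32), 3)
        field = ndimage.gaussian_filter(padded, _MESH_SMOOTH_SIGMA_VOX)
        verts, faces, _, _ = measure.marching_cubes(field, level=0.5, spacing=tuple(spacing))
        return float(measure.mesh_surface_area(verts, faces))
    if method == "voxel":
        area = 0.0
        face = {
            0: spacing[1] * spacing[2],
            1: spacing[0] * spacing[2],
            2: spacing[0] * spacing[1],
        }
        for axis in range(3):
            padded = np.pad(mask, [(1, 1) if a == axis else (0, 0) for a in range(3)])
            diff = np.diff(padded.astype(np.int8), axis=axis)
            area += np.abs(diff).sum() * face[axis]
        return float(area)
    raise ValueError(f"unknown surface method {method!r}")


def shape_features(mask: np.ndarray, spacing_mm, surface_method: str = "mesh") -> dict[str, float]:
    """Volume (mL), sphericity and compacity.

    sphericity = pi^(1/3) (6V)^(2/3) / A  (1 for a perfect sphere),
    compacity  = A^(3/2) / V              (dimensionless; larger = less compact),
    with V in mm^3 and A in mm^2.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    voxel_mm3 = float(np.prod(spacing_mm))
    volume_mm3 = mask.sum() * voxel_mm3
    area = surface_area_mm2(mask, spacing_mm, method=surface_method)
    sphericity = np.pi ** (1 / 3) * (6 * volume_mm3) ** (2 / 3) / area
    compacity = area**1.5 / volume_mm3
    return {
        "Shape_Volume_mL": volume_mm3 / 1000.0,
        "Shape_Sphericity": float(sphericity),
        "Shape_Compacity": float(compacity),
    }
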