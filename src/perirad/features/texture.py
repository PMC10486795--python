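"""3D texture matrices over a masked VOI: GLCM, GLRLM, NGLDM, GLZLM.

All matrices are computed on discretized grey levels (1..N) restricted to
in-mask voxels:

* GLCM / GLRLM use the 13 unique 3D directions at distance 1; feature values
  are averaged over directions (per-direction matrices are exposed for
  testing, and a merged-matrix mode is available on the GLCM).
* NGLDM aggregates, per grey level, the absolute difference between a voxel's
  level and the mean level of its 26-connected in-mask neighbours.
* GLZLM bins 26-connected constant-level zones by (level, zone size).

Undefined features (zero grey-level variance, single-level VOIs) are reported
as ``numpy.nan`` with a warning; keys are never dropped.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from ._discretize import DiscretizationScheme, discretize

#: the 13 unique direction vectors of the 26-neighbourhood (one per +/- pair)
DIRECTIONS: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _shift(arr: np.ndarray, d, fill=0) -> np.ndarray:
    """out[v] = arr[v + d] where in bounds, else fill."""
    out = np.full_like(arr, fill)
    src, dst = [], []
    for delta, n in zip(d, arr.shape):
        if delta >= 0:
            dst.append(slice(0, n - delta))
            src.append(slice(delta, n))
        else:
            dst.append(slice(-delta, n))
            src.append(slice(0, n + delta))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _levels(volume_values, mask, scheme):
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    values = np.asarray(volume_values, dtype=float)
    lev = np.zeros(mask.shape, dtype=np.int64)
    lev[mask] = discretize(values[mask], scheme)
    return lev, mask


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(levels: np.ndarray, mask: np.ndarray, direction) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction, in-mask pairs only."""
    n_levels = int(levels.max())
    valid = mask & _shift(mask, direction)
    i = levels[valid]
    j = _shift(levels, direction)[valid]
    mat = np.zeros((n_levels, n_levels), dtype=float)
    np.add.at(mat, (i - 1, j - 1), 1.0)
    np.add.at(mat, (j - 1, i - 1), 1.0)
    return mat


def _glcm_features_from_matrix(mat: np.ndarray) -> dict[str, float]:
    p = mat / mat.sum()
    n = p.shape[0]
    i = np.arange(1, n + 1)[:, None]
    j = np.arange(1, n + 1)[None, :]
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    var_i = float(((i - mu_i) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())
    nz = p[p > 0]
    feats = {
        "GLCM_Homogeneity": float((p / (1.0 + np.abs(i - j))).sum()),
        "GLCM_Energy": float((p**2).sum()),
        "GLCM_Contrast": float(((i - j) ** 2 * p).sum()),
        "GLCM_Entropy_log2": float(-(nz * np.log2(nz)).sum()),
        "GLCM_Entropy_log10": float(-(nz * np.log10(nz)).sum()),
        "GLCM_Dissimilarity": float((np.abs(i - j) * p).sum()),
    }
    if var_i > 0 and var_j > 0:
        feats["GLCM_Correlation"] = float(
            (((i - mu_i) * (j - mu_j) * p).sum()) / np.sqrt(var_i * var_j)
        )
    else:
        feats["GLCM_Correlation"] = float("nan")
    return feats


def glcm_features(
    volume_values, mask, scheme: DiscretizationScheme, merged: bool = False
) -> dict[str, float]:
    """Seven GLCM features; per-direction values averaged (default) or from
    a single merged matrix."""
    levels, mask = _levels(volume_values, mask, scheme)
    mats = [glcm_matrix(levels, mask, d) for d in DIRECTIONS]
    mats = [m for m in mats if m.sum() > 0]
    if not mats:
        raise ValueError("mask has no in-mask neighbour pair in any direction")
    if merged:
        per_dir = [_glcm_features_from_matrix(np.sum(mats, axis=0))]
    else:
        per_dir = [_glcm_features_from_matrix(m) for m in mats]
    out = {}
    for key in per_dir[0]:
        vals = np.array([f[key] for f in per_dir])
        if np.isnan(vals).all():
            warnings.warn(f"{key} undefined on this VOI (NaN sentinel)", stacklevel=2)
            out[key] = float("nan")
        else:
            out[key] = float(np.nanmean(vals))
    return out


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, direction) -> np.ndarray:
    """Run-length counts (level x run length) of maximal in-mask constant runs
    along one direction."""
    d = np.asarray(direction)
    back = tuple(-x for x in direction)
    is_start = mask & ~(
        _shift(mask, back) & (_shift(levels, back) == levels)
    )
    idx = np.argwhere(is_start)
    lev = levels[is_start]
    n = idx.shape[0]
    lengths = np.ones(n, dtype=np.int64)
    active = np.arange(n)
    cur = idx.copy()
    shape = np.asarray(mask.shape)
    while active.size:
        nxt = cur[active] + d
        inb = np.all((nxt >= 0) & (nxt < shape), axis=1)
        ok = np.zeros(active.size, dtype=bool)
        sub = nxt[inb]
        if sub.size:
            ok[inb] = mask[sub[:, 0], sub[:, 1], sub[:, 2]] & (
                levels[sub[:, 0], sub[:, 1], sub[:, 2]] == lev[active[inb]]
            )
        keep = active[ok]
        lengths[keep] += 1
        cur[keep] = nxt[ok]
        active = keep
    mat = np.zeros((int(levels.max()), int(lengths.max())), dtype=float)
    np.add.at(mat, (lev - 1, lengths - 1), 1.0)
    return mat


def _size_matrix_features(mat: np.ndarray, n_voxels: int, prefix: str, names) -> dict[str, float]:
    """Shared index family for GLRLM (runs) and GLZLM (zones)."""
    total = mat.sum()
    i = np.arange(1, mat.shape[0] + 1, dtype=float)[:, None]  # grey level
    s = np.arange(1, mat.shape[1] + 1, dtype=float)[None, :]  # run length / zone size
    m = mat / total
    return {
        f"{prefix}_{names[0]}": float((m / s**2).sum()),          # short/small emphasis
        f"{prefix}_{names[1]}": float((m * s**2).sum()),          # long/large emphasis
        f"{prefix}_LG{names[8]}": float((m / i**2).sum()),        # low grey
        f"{prefix}_HG{names[8]}": float((m * i**2).sum()),        # high grey
        f"{prefix}_{names[2]}": float((m / (i**2 * s**2)).sum()),
        f"{prefix}_{names[3]}": float((m * i**2 / s**2).sum()),
        f"{prefix}_{names[4]}": float((m * s**2 / i**2).sum()),
        f"{prefix}_{names[5]}": float((m * i**2 * s**2).sum()),
        f"{prefix}_{names[6]}": float((mat.sum(axis=1) ** 2).sum() / total),
        f"{prefix}_{names[7]}": float((mat.sum(axis=0) ** 2).sum() / total),
        f"{prefix}_{names[9]}": float(total / n_voxels),
    }


_GLRLM_NAMES = ("SRE", "LRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLNU", "RLNU", "RE", "RP")
_GLZLM_NAMES = ("SZE", "LZE", "SZLGE", "SZHGE", "LZLGE", "LZHGE", "GLNU", "ZLNU", "ZE", "ZP")


def glrlm_features(volume_values, mask, scheme: DiscretizationScheme) -> dict[str, float]:
    """Eleven run-length indices, averaged over the 13 directions."""
    levels, mask = _levels(volume_values, mask, scheme)
    n_vox = int(mask.sum())
    per_dir = [
        _size_matrix_features(glrlm_matrix(levels, mask, d), n_vox, "GLRLM", _GLRLM_NAMES)
        for d in DIRECTIONS
    ]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# NGLDM
# ---------------------------------------------------------------------------

def ngldm_components(levels: np.ndarray, mask: np.ndarray):
    """Per-level occupancy ``n_i`` and difference mass ``s_i``.

    ``s_i`` sums, over in-mask voxels of level ``i`` that have at least one
    in-mask 26-neighbour, the absolute difference between the voxel level and
    the mean level of those neighbours.
    """
    nsum = np.zeros(mask.shape, dtype=float)
    ncnt = np.zeros(mask.shape, dtype=float)
    for d in DIRECTIONS:
        for dd in (d, tuple(-x for x in d)):
            nb_mask = _shift(mask, dd)
            nsum += _shift(levels, dd) * nb_mask
            ncnt += nb_mask
    has_nb = mask & (ncnt > 0)
    diff = np.zeros(mask.shape, dtype=float)
    diff[has_nb] = np.abs(levels[has_nb] - nsum[has_nb] / ncnt[has_nb])
    n_levels = int(levels.max())
    n_i = np.bincount(levels[has_nb], minlength=n_levels + 1)[1:].astype(float)
    s_i = np.bincount(levels[has_nb], weights=diff[has_nb], minlength=n_levels + 1)[1:]
    return n_i, s_i


def ngldm_features(volume_values, mask, scheme: DiscretizationScheme) -> dict[str, float]:
    """Coarseness, Contrast, Busyness (Amadasun-style, in-mask neighbourhoods)."""
    levels, mask = _levels(volume_values, mask, scheme)
    n_i, s_i = ngldm_components(levels, mask)
    n_total = n_i.sum()
    if n_total == 0:
        raise ValueError("no in-mask voxel has an in-mask neighbour")
    p_i = n_i / n_total
    i = np.arange(1, len(p_i) + 1, dtype=float)
    present = p_i > 0
    n_g = int(present.sum())
    ps = float((p_i * s_i).sum())

    coarseness = 1.0 / ps if ps > 0 else float("nan")
    if n_g > 1:
        pij = p_i[present][:, None] * p_i[present][None, :]
        dij2 = (i[present][:, None] - i[present][None, :]) ** 2
        contrast = float((pij * dij2).sum() / (n_g * (n_g - 1)) * s_i.sum() / n_total)
        ip = i[present] * p_i[present]
        denom = float(np.abs(ip[:, None] - ip[None, :]).sum())
        busyness = ps / denom if denom > 0 else float("nan")
    else:
        contrast = 0.0
        busyness = float("nan")
    if not np.isfinite(coarseness) or not np.isfinite(busyness):
        warnings.warn(
            "degenerate NGLDM (single level or zero difference mass): "
            "Coarseness/Busyness undefined (NaN sentinel)",
            stacklevel=2,
        )
    return {
        "NGLDM_Coarseness": coarseness,
        "NGLDM_Contrast": contrast,
        "NGLDM_Busyness": busyness,
    }


# ---------------------------------------------------------------------------
# GLZLM
# ---------------------------------------------------------------------------

def glzlm_matrix(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zone counts (level x zone size) of 26-connected constant-level zones."""
    n_levels = int(levels.max())
    zones: list[tuple[int, int]] = []
    for lev in range(1, n_levels + 1):
        lab, n_lab = ndimage.label(mask & (levels == lev), structure=_STRUCT_26)
        if n_lab:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((lev, int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    mat = np.zeros((n_levels, max_size), dtype=float)
    for lev, s in zones:
        mat[lev - 1, s - 1] += 1.0
    return mat


def glzlm_features(volume_values, mask, scheme: DiscretizationScheme) -> dict[str, float]:
    """Eleven zone-length (size-zone) indices."""
    levels, mask = _levels(volume_values, mask, scheme)
    mat = glzlm_matrix(levels, mask)
    return _size_matrix_features(mat, int(mask.sum()), "GLZLM", _GLZLM_NAMES)
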