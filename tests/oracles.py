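"""Independent brute-force oracles used to validate the package.

Everything here is written as plain loops over voxels/pairs/matrix cells,
deliberately sharing no code with the implementation under test.
"""

from __future__ import annotations

import itertools

import numpy as np


def oracle_dilate(mask: np.ndarray, radius_mm: float, spacing_mm) -> np.ndarray:
    """Voxels whose center is within radius of some mask-voxel center."""
    spacing = np.asarray(spacing_mm, float)
    src = np.argwhere(mask)
    out = np.zeros_like(mask, dtype=bool)
    for idx in itertools.product(*(range(n) for n in mask.shape)):
        d2 = (((np.asarray(idx) - src) * spacing) ** 2).sum(axis=1)
        if (d2 <= radius_mm**2 + 1e-9).any():
            out[idx] = True
    return out


def _neighbors26(idx, shape):
    for off in itertools.product((-1, 0, 1), repeat=3):
        if off == (0, 0, 0):
            continue
        nb = tuple(i + o for i, o in zip(idx, off))
        if all(0 <= v < n for v, n in zip(nb, shape)):
            yield nb


def oracle_glcm(levels: np.ndarray, mask: np.ndarray, direction) -> np.ndarray:
    n = int(levels[mask].max())
    mat = np.zeros((n, n))
    for idx in map(tuple, np.argwhere(mask)):
        nb = tuple(i + d for i, d in zip(idx, direction))
        if all(0 <= v < s for v, s in zip(nb, mask.shape)) and mask[nb]:
            mat[levels[idx] - 1, levels[nb] - 1] += 1
            mat[levels[nb] - 1, levels[idx] - 1] += 1
    return mat


def oracle_glcm_features(mat: np.ndarray) -> dict[str, float]:
    p = mat / mat.sum()
    n = p.shape[0]
    homog = energy = contrast = dissim = ent2 = ent10 = 0.0
    mu = sum((i + 1) * p[i, j] for i in range(n) for j in range(n))
    var = sum((i + 1 - mu) ** 2 * p[i, j] for i in range(n) for j in range(n))
    corr_num = 0.0
    for i in range(n):
        for j in range(n):
            if p[i, j] == 0:
                continue
            homog += p[i, j] / (1 + abs(i - j))
            energy += p[i, j] ** 2
            contrast += (i - j) ** 2 * p[i, j]
            dissim += abs(i - j) * p[i, j]
            ent2 -= p[i, j] * np.log2(p[i, j])
            ent10 -= p[i, j] * np.log10(p[i, j])
            corr_num += (i + 1 - mu) * (j + 1 - mu) * p[i, j]
    corr = corr_num / var if var > 0 else float("nan")
    return {
        "GLCM_Homogeneity": homog, "GLCM_Energy": energy, "GLCM_Contrast": contrast,
        "GLCM_Correlation": corr, "GLCM_Entropy_log2": ent2,
        "GLCM_Entropy_log10": ent10, "GLCM_Dissimilarity": dissim,
    }


def oracle_glrlm(levels: np.ndarray, mask: np.ndarray, direction) -> np.ndarray:
    """Enumerate maximal constant-level runs by walking every chain."""
    runs = []
    d = tuple(direction)
    for idx in map(tuple, np.argwhere(mask)):
        prev = tuple(i - o for i, o in zip(idx, d))
        inb = all(0 <= v < n for v, n in zip(prev, mask.shape))
        if inb and mask[prev] and levels[prev] == levels[idx]:
            continue  # not a run start
        length = 1
        cur = idx
        while True:
            nxt = tuple(i + o for i, o in zip(cur, d))
            if not all(0 <= v < n for v, n in zip(nxt, mask.shape)):
                break
            if not mask[nxt] or levels[nxt] != levels[idx]:
                break
            cur = nxt
            length += 1
        runs.append((int(levels[idx]), length))
    n_lev = int(levels[mask].max())
    max_len = max(l for _, l in runs)
    mat = np.zeros((n_lev, max_len))
    for lev, length in runs:
        mat[lev - 1, length - 1] += 1
    return mat


def oracle_run_or_zone_features(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 11 shared run/zone indices computed cell by cell."""
    total = mat.sum()
    sre = lre = lgre = hgre = srlge = srhge = lrlge = lrhge = 0.0
    for i in range(mat.shape[0]):
        for l in range(mat.shape[1]):
            if mat[i, l] == 0:
                continue
            lev, length = i + 1, l + 1
            v = mat[i, l] / total
            sre += v / length**2
            lre += v * length**2
            lgre += v / lev**2
            hgre += v * lev**2
            srlge += v / (lev**2 * length**2)
            srhge += v * lev**2 / length**2
            lrlge += v * length**2 / lev**2
            lrhge += v * lev**2 * length**2
    glnu = sum(mat[i, :].sum() ** 2 for i in range(mat.shape[0])) / total
    rlnu = sum(mat[:, l].sum() ** 2 for l in range(mat.shape[1])) / total
    return {
        "short": sre, "long": lre, "low": lgre, "high": hgre,
        "short_low": srlge, "short_high": srhge, "long_low": lrlge,
        "long_high": lrhge, "glnu": glnu, "lnu": rlnu, "pct": total / n_voxels,
    }


def oracle_ngldm(levels: np.ndarray, mask: np.ndarray):
    """Per-level (n_i, s_i) using explicit 26-neighbour loops."""
    n_lev = int(levels[mask].max())
    n_i = np.zeros(n_lev)
    s_i = np.zeros(n_lev)
    for idx in map(tuple, np.argwhere(mask)):
        nbs = [levels[nb] for nb in _neighbors26(idx, mask.shape) if mask[nb]]
        if not nbs:
            continue
        lev = int(levels[idx])
        n_i[lev - 1] += 1
        s_i[lev - 1] += abs(lev - float(np.mean(nbs)))
    return n_i, s_i


def oracle_ngldm_features(n_i, s_i) -> dict[str, float]:
    n_total = n_i.sum()
    p = n_i / n_total
    present = [i for i in range(len(p)) if p[i] > 0]
    ps = sum(p[i] * s_i[i] for i in present)
    coarseness = 1.0 / ps if ps > 0 else float("nan")
    ng = len(present)
    if ng > 1:
        pairsum = sum(
            p[i] * p[j] * (i - j) ** 2 for i in present for j in present
        )
        contrast = pairsum / (ng * (ng - 1)) * s_i.sum() / n_total
        denom = sum(
            abs((i + 1) * p[i] - (j + 1) * p[j])
            for i in present for j in present if i != j
        )
        busyness = ps / denom if denom > 0 else float("nan")
    else:
        contrast = 0.0
        busyness = float("nan")
    return {
        "NGLDM_Coarseness": coarseness,
        "NGLDM_Contrast": contrast,
        "NGLDM_Busyness": busyness,
    }


def oracle_glzlm(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zones by flood fill over 26-connected equal-level voxels."""
    visited = np.zeros_like(mask, dtype=bool)
    zones = []
    for start in map(tuple, np.argwhere(mask)):
        if visited[start]:
            continue
        lev = levels[start]
        stack, size = [start], 0
        visited[start] = True
        while stack:
            cur = stack.pop()
            size += 1
            for nb in _neighbors26(cur, mask.shape):
                if mask[nb] and not visited[nb] and levels[nb] == lev:
                    visited[nb] = True
                    stack.append(nb)
        zones.append((int(lev), size))
    n_lev = int(levels[mask].max())
    max_size = max(s for _, s in zones)
    mat = np.zeros((n_lev, max_size))
    for lev, size in zones:
        mat[lev - 1, size - 1] += 1
    return mat


def oracle_auc(scores, labels) -> float:
    """Pairwise-concordance (Mann-Whitney) AUC with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def random_voi(rng: np.random.Generator, max_side: int = 6, n_levels: int = 4,
               fill: float = 0.7):
    """A random small VOI: integer levels 1..n_levels plus a random mask."""
    shape = tuple(rng.integers(3, max_side + 1, size=3))
    mask = rng.random(shape) < fill
    if mask.sum() < 4:
        flat = rng.choice(np.prod(shape), size=4, replace=False)
        mask.ravel()[flat] = True
    levels = rng.integers(1, n_levels + 1, size=shape)
    return levels, mask
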