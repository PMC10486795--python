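"""Grey-level descriptors and first-order histogram features.

Undefined quantities (e.g. skewness of a zero-variance VOI) are reported as
the documented sentinel ``numpy.nan`` with a warning; keys are never dropped.
"""

from __future__ import annotations

import warnings

import numpy as np

from ._discretize import DiscretizationScheme, discretize


def grey_level_descriptors(volume_values: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """HUmin, HUmean, HUstd, HUmax and the quartiles HUQ1/HUQ2/HUQ3.

    Quantiles use the inclusive linear-interpolation rule
    (``numpy.quantile(..., method="linear")``).
    """
    x = _masked(volume_values, mask)
    q1, q2, q3 = np.quantile(x, [0.25, 0.5, 0.75], method="linear")
    return {
        "HUmin": float(x.min()),
        "HUmean": float(x.mean()),
        "HUstd": float(x.std(ddof=0)),
        "HUmax": float(x.max()),
        "HUQ1": float(q1),
        "HUQ2": float(q2),
        "HUQ3": float(q3),
    }


def histogram_features(
    volume_values: np.ndarray, mask: np.ndarray, scheme: DiscretizationScheme
) -> dict[str, float]:
    """Skewness, kurtosis (Pearson, i.e. non-excess), histogram energy and entropy.

    Energy = sum(p^2) and entropy = -sum(p log2 p) over discretized-bin
    probabilities.
    """
    x = _masked(volume_values, mask)
    mu = x.mean()
    m2 = np.mean((x - mu) ** 2)
    if m2 > 0:
        skew = float(np.mean((x - mu) ** 3) / m2**1.5)
        kurt = float(np.mean((x - mu) ** 4) / m2**2)
    else:
        warnings.warn("zero-variance VOI: skewness/kurtosis undefined (NaN)", stacklevel=2)
        skew = kurt = float("nan")
    levels = discretize(x, scheme)
    p = np.bincount(levels)[1:].astype(float)
    p = p[p > 0] / levels.size
    energy = float(np.sum(p**2))
    entropy = float(-np.sum(p * np.log2(p)))
    return {
        "Skewness": skew,
        "Kurtosis": kurt,
        "Histogram_Energy": energy,
        "Histogram_Entropy": entropy,
    }


def _masked(volume_values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    return np.asarray(volume_values, dtype=float)[mask]
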