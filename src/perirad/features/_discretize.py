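"""Grey-level discretization for texture matrices.

Two IBSI modes are supported:

* ``fixed-bin-number`` (default, 64 bins): levels ``1..N`` over the VOI
  min-max (or explicit bounds), ``g = min(N, floor(N * (x - lo)/(hi - lo)) + 1)``.
  Scale/shift invariant when bounds track the VOI.
* ``fixed-bin-size``: ``g = floor((x - lo)/w) + 1``, clipped at 1, over an
  absolute HU window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MODES = ("fixed-bin-number", "fixed-bin-size")


@dataclass(frozen=True)
class DiscretizationScheme:
    mode: str = "fixed-bin-number"
    n_bins: int = 64
    bin_width_hu: float | None = None
    bounds: tuple[float, float] | None = None  # None -> VOI min/max

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "fixed-bin-number" and self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.mode == "fixed-bin-size":
            if self.bin_width_hu is None or self.bin_width_hu <= 0:
                raise ValueError("fixed-bin-size requires bin_width_hu > 0")
        if self.bounds is not None and self.bounds[0] >= self.bounds[1]:
            raise ValueError("bounds must satisfy lower < upper")


def discretize(values: np.ndarray, scheme: DiscretizationScheme) -> np.ndarray:
    """Map masked intensities to integer grey levels starting at 1."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty set of values")
    if scheme.bounds is not None:
        lo, hi = scheme.bounds
    else:
        lo, hi = float(values.min()), float(values.max())
    if scheme.mode == "fixed-bin-number":
        if hi <= lo:  # constant VOI: a single level
            return np.ones(values.shape, dtype=np.int64)
        g = np.floor(scheme.n_bins * (values - lo) / (hi - lo)).astype(np.int64) + 1
        return np.clip(g, 1, scheme.n_bins)
    g = np.floor((values - lo) / scheme.bin_width_hu).astype(np.int64) + 1
    return np.maximum(g, 1)
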