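"""Stack preprocessing: 8-bit conversion and stack-histogram contrast stretch.

Reconstructed CT volumes are converted to 8-bit grayscale and then
contrast-enhanced by clipping a small fraction of saturated voxels
(default 0.3%, split equally between the two tails) determined on the
pooled histogram of the whole stack — never per slice — and linearly
stretching the remaining range onto [0, 255].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class ContrastParams:
    """Saturation fraction plus the cut points realized from the histogram."""

    saturated_fraction: float = 0.003
    low_cut: float | None = None
    high_cut: float | None = None

    def validate(self) -> None:
        if not 0 <= self.saturated_fraction < 1:
            raise ValueError("saturated_fraction must be in [0, 1)")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def to_8bit(grid: np.ndarray) -> np.ndarray:
    """Linearly rescale [stack min, stack max] onto [0, 255] with rounding.

    A constant stack maps to all zeros.
    """
    grid = np.asarray(grid)
    if grid.size == 0:
        raise ValueError("cannot convert an empty grid")
    lo = float(grid.min())
    hi = float(grid.max())
    if hi == lo:
        return np.zeros(grid.shape, dtype=np.uint8)
    scaled = (grid.astype(np.float64) - lo) * (255.0 / (hi - lo))
    return _round_half_up(scaled).astype(np.uint8)


def enhance_contrast(grid: np.ndarray, params: ContrastParams | None = None) -> np.ndarray:
    """Percentile contrast stretch on the whole-stack histogram.

    ``saturated_fraction/2`` of voxels saturate at each tail; the transform
    is monotone non-decreasing and invariant to constant intensity offsets.
    The realized cut points are stored back on ``params``.
    """
    if params is None:
        params = ContrastParams()
    params.validate()
    grid = np.asarray(grid)
    if grid.size == 0:
        raise ValueError("cannot enhance an empty grid")
    tail = params.saturated_fraction / 2.0
    low, high = np.quantile(grid.astype(np.float64), [tail, 1.0 - tail])
    params.low_cut, params.high_cut = float(low), float(high)
    if high <= low:
        log.warning(
            "degenerate stack histogram (low_cut == high_cut == %s); "
            "returning input unchanged",
            low,
        )
        return grid.astype(np.uint8, copy=True)
    stretched = (grid.astype(np.float64) - low) * (255.0 / (high - low))
    return _round_half_up(np.clip(stretched, 0.0, 255.0)).astype(np.uint8)


def preprocess_stack(grid: np.ndarray, params: ContrastParams | None = None) -> np.ndarray:
    """Full preprocessing: 8-bit conversion followed by the contrast stretch."""
    return enhance_contrast(to_8bit(grid), params)
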