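"""Slice-stack I/O: one 8-bit grayscale PNG per z-slice plus a metadata sidecar.

CT reconstructions are exported as numbered 2-D slice images; the stack of
slices is the 3-D volume. Filenames carry a zero-padded slice index so
lexicographic file order equals numeric slice order, and a small JSON
sidecar records the physical voxel edge length.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np

SIDECAR_NAME = "stack_meta.json"
_SLICE_RE = re.compile(r"^(?P<stem>.*?)(?P<index>\d+)\.png$")


def write_slice_stack(
    grid: np.ndarray,
    directory: str | Path,
    naming_pattern: str = "slice_{:04d}.png",
    voxel_size_mm: float = 1.0,
) -> list[Path]:
    """Write ``grid`` (z, y, x) as one PNG per slice; returns written paths.

    Intensities must already be 8-bit representable (integers in [0, 255]);
    floats are rejected to keep the round trip exact.
    """
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {grid.shape}")
    if grid.dtype != np.uint8:
        if not np.issubdtype(grid.dtype, np.integer):
            raise ValueError(
                "grid must be integer-valued; run preprocess.to_8bit first"
            )
        if grid.min() < 0 or grid.max() > 255:
            raise ValueError("grid values outside [0, 255]; run preprocess.to_8bit")
        grid = grid.astype(np.uint8)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for z in range(grid.shape[0]):
        p = directory / naming_pattern.format(z)
        iio.imwrite(p, grid[z])
        paths.append(p)
    (directory / SIDECAR_NAME).write_text(
        json.dumps({"voxel_size_mm": voxel_size_mm, "n_slices": grid.shape[0]})
    )
    return paths


def read_slice_stack(directory: str | Path) -> tuple[np.ndarray, float]:
    """Read a slice stack back into a (z, y, x) uint8 volume.

    Slices are ordered by the numeric index embedded in each filename;
    missing indices raise with the list of gaps.  Returns
    ``(volume, voxel_size_mm)``.
    """
    directory = Path(directory)
    indexed = []
    for p in sorted(directory.glob("*.png")):
        m = _SLICE_RE.match(p.name)
        if m:
            indexed.append((int(m.group("index")), p))
    if not indexed:
        raise FileNotFoundError(f"no PNG slices found in {directory}")
    indexed.sort()
    indices = [i for i, _ in indexed]
    expected = range(indices[0], indices[0] + len(indices))
    gaps = sorted(set(expected) - set(indices))
    if gaps or len(set(indices)) != len(indices):
        raise ValueError(
            f"slice stack in {directory} is not contiguous; missing indices {gaps}"
        )
    slices = []
    for _, p in indexed:
        try:
            img = iio.imread(p)
        except Exception as exc:
            raise ValueError(f"failed to read slice file {p}: {exc}") from exc
        if img.ndim == 3:  # grayscale saved with redundant channels
            img = img[..., 0]
        slices.append(np.asarray(img, dtype=np.uint8))
    volume = np.stack(slices, axis=0)
    voxel_size_mm = 1.0
    sidecar = directory / SIDECAR_NAME
    if sidecar.exists():
        voxel_size_mm = float(json.loads(sidecar.read_text())["voxel_size_mm"])
    return volume, voxel_size_mm
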