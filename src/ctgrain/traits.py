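"""CT-derived kernel traits from per-unit class counts and raw intensities.

Six traits per experimental unit (one well of ``n_kernels`` kernels of one
genotype in one scan):

* average single-kernel volume — total tissue voxels (hard + soft
  endosperm + pericarp + embryo) converted to mm^3 and divided by the
  kernel count; component volumes (pericarp, embryo, endosperm) likewise;
* endosperm texture — hard-endosperm voxels / soft-endosperm voxels;
* endosperm intensity — mean 8-bit intensity of the unit's voxels within
  [70, 248], computed on the preprocessed stack without the segmentation
  (values below 70 are background, above 248 embryo).

Voids inside kernels carry the background label and therefore never enter
any component count.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

from .classes import CLASS_NAMES, KERNEL_CLASSES, Tissue

#: Trait columns, in reporting order.
TRAIT_COLUMNS = (
    "kernel_volume",
    "pericarp_volume",
    "embryo_volume",
    "endosperm_volume",
    "endosperm_texture",
    "endosperm_intensity",
)

#: Internal name -> CSV header used in exported trait tables.
CSV_NAME_MAP = {
    "kernel_volume": "CT seed size (mm3)",
    "pericarp_volume": "CT pericarp volume (mm3)",
    "embryo_volume": "CT embryo volume (mm3)",
    "endosperm_volume": "CT endosperm volume (mm3)",
    "endosperm_texture": "CT endosperm texture",
    "endosperm_intensity": "CT Endosperm Intensity",
}

INTENSITY_LOW = 70
INTENSITY_HIGH = 248


def volumes_from_counts(
    counts: Mapping[str, int], voxel_size_mm: float, n_kernels: int = 40
) -> dict[str, float]:
    """Average per-kernel component volumes (mm^3) from class voxel counts.

    ``component volume = count * voxel_size_mm**3 / n_kernels``; the kernel
    volume is the four-tissue sum, so the conservation identity
    kernel = pericarp + embryo + endosperm holds exactly on the counts.
    """
    if n_kernels <= 0:
        raise ValueError("n_kernels must be positive")
    if voxel_size_mm <= 0:
        raise ValueError("voxel_size_mm must be positive")
    v = voxel_size_mm**3 / n_kernels
    peri = counts[CLASS_NAMES[Tissue.PERICARP]] * v
    emb = counts[CLASS_NAMES[Tissue.EMBRYO]] * v
    endo = (
        counts[CLASS_NAMES[Tissue.SOFT_ENDOSPERM]]
        + counts[CLASS_NAMES[Tissue.HARD_ENDOSPERM]]
    ) * v
    return {
        "kernel_volume": peri + emb + endo,
        "pericarp_volume": peri,
        "embryo_volume": emb,
        "endosperm_volume": endo,
    }


def endosperm_texture(counts: Mapping[str, int]) -> float:
    """Hard/soft endosperm voxel ratio; NaN (not infinity) when soft = 0."""
    soft = counts[CLASS_NAMES[Tissue.SOFT_ENDOSPERM]]
    hard = counts[CLASS_NAMES[Tissue.HARD_ENDOSPERM]]
    if soft == 0:
        return float("nan")
    return hard / soft


def endosperm_intensity(
    raw_grid: np.ndarray,
    unit_mask: np.ndarray | None = None,
    low: int = INTENSITY_LOW,
    high: int = INTENSITY_HIGH,
) -> float:
    """Mean intensity of unit voxels with ``low <= value <= high``.

    Operates on the preprocessed 8-bit stack, not on segmentation labels;
    the thresholds are inclusive at both bounds.  ``unit_mask`` restricts
    to a subregion (default: the whole grid passed in).  Returns NaN when
    no voxel falls in range.
    """
    region = raw_grid if unit_mask is None else raw_grid[unit_mask]
    vals = np.asarray(region, dtype=np.float64).ravel()
    keep = vals[(vals >= low) & (vals <= high)]
    if keep.size == 0:
        return float("nan")
    return float(keep.mean())


def traits_from_counts(
    counts: pd.DataFrame, voxel_size_mm: float, n_kernels: int = 40
) -> pd.DataFrame:
    """Volume and texture traits for a per-unit count table.

    ``counts`` has one row per unit with design columns plus one count
    column per class (as produced by ``segmentation.count_pixels``).
    """
    design_cols = [c for c in ("genotype", "rep", "row", "col") if c in counts.columns]
    out = []
    for _, rec in counts.iterrows():
        row = {c: rec[c] for c in design_cols}
        row.update(volumes_from_counts(rec, voxel_size_mm, n_kernels))
        row["endosperm_texture"] = endosperm_texture(rec)
        out.append(row)
    return pd.DataFrame(out)


def build_trait_table(scan_entries) -> pd.DataFrame:
    """One trait row per experimental unit per scan.

    ``scan_entries`` is a sequence of ``(labels, raw_grid, scan_spec)``;
    ``labels`` may be ground truth or classifier output, ``raw_grid`` is the
    preprocessed 8-bit stack used for the intensity trait.  Undefined trait
    values propagate as NaN.
    """
    from .segmentation import count_pixels

    tables = []
    for labels, raw_grid, scan_spec in scan_entries:
        if labels.shape != raw_grid.shape:
            raise ValueError(
                f"label volume {labels.shape} does not match scan {raw_grid.shape}"
            )
        counts = count_pixels(labels, scan_spec)
        counts = counts[counts["genotype"] != "_unassigned"].copy()
        counts.insert(1, "rep", scan_spec.rep)
        table = traits_from_counts(
            counts, scan_spec.voxel_size_mm, scan_spec.kernels_per_well
        )
        # Intensity uses the raw stack with thresholds only — the whole well
        # box enters and the [70, 248] window excludes background and the
        # brightest (embryo/pericarp-level) voxels; no segmentation involved.
        intensities = []
        for _, rec in counts.iterrows():
            box = scan_spec.well_box(int(rec["row"]), int(rec["col"]))
            intensities.append(endosperm_intensity(raw_grid[box]))
        table["endosperm_intensity"] = intensities
        tables.append(table)
    return pd.concat(tables, ignore_index=True)


def write_trait_csv(table: pd.DataFrame, path) -> None:
    """Export a trait table with the field's reporting column names."""
    table.rename(columns=CSV_NAME_MAP).to_csv(path, index=False)


def read_trait_csv(path) -> pd.DataFrame:
    """Read a trait table written by :func:`write_trait_csv` (or raw names)."""
    df = pd.read_csv(path)
    inverse = {v: k for k, v in CSV_NAME_MAP.items()}
    return df.rename(columns=inverse)
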