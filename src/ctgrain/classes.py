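"""Tissue classes of the five-way kernel segmentation.

A scanned caryopsis is partitioned into background plus four tissues:
pericarp (outer layers), embryo (germ), and the soft (floury) and hard
(vitreous) endosperm fractions.  The integer order doubles as the
deterministic tie-break order of the classifier.
"""

from __future__ import annotations

from enum import IntEnum


class Tissue(IntEnum):
    """Voxel classes, ordered background < pericarp < embryo < soft < hard."""

    BACKGROUND = 0
    PERICARP = 1
    EMBRYO = 2
    SOFT_ENDOSPERM = 3
    HARD_ENDOSPERM = 4


#: Names in class-index order, handy for tables and reports.
CLASS_NAMES: tuple[str, ...] = tuple(t.name.lower() for t in Tissue)

#: The four non-background tissues that make up a kernel.
KERNEL_CLASSES: tuple[Tissue, ...] = (
    Tissue.PERICARP,
    Tissue.EMBRYO,
    Tissue.SOFT_ENDOSPERM,
    Tissue.HARD_ENDOSPERM,
)

#: RGB colors for QC slice rendering (background, pericarp, embryo, soft, hard).
CLASS_COLORS = (
    (0, 0, 0),
    (214, 39, 40),
    (255, 215, 0),
    (100, 149, 237),
    (34, 139, 34),
)
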