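"""Synthetic multi-well kernel scans with voxel-exact ground truth.

Real grain CT scans image a foam plate of wells, each well holding the 40
kernels of one genotype (one experimental unit), with several such scans
acting as replicates.  This module generates voxelized phantoms with the
same statistical structure: five-class kernel anatomy (background,
pericarp, embryo, soft endosperm, hard endosperm) with graded rather than
sharp class boundaries, within-class speckle texture, scan-level brightness
offsets, an optional radial attenuation gradient, occasional internal
voids, and a slightly-less-dense waxy endosperm variant.

Geometry is an ellipsoidal caryopsis: the outermost shell of a given
physical thickness is pericarp, a polar cap of a given volume fraction is
embryo, and the remaining endosperm is split into a peripheral hard
(vitreous) shell and a central soft (floury) core.  All label regions are
constructed by exact voxel counts, so the returned ground truth is exact by
construction rather than estimated.

Every random draw descends from one root seed through
``numpy.random.SeedSequence``, which makes generation bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .classes import Tissue

DEFAULT_CLASS_MEANS: dict[Tissue, float] = {
    Tissue.BACKGROUND: 8.0,
    Tissue.PERICARP: 215.0,
    Tissue.EMBRYO: 195.0,
    Tissue.SOFT_ENDOSPERM: 120.0,
    Tissue.HARD_ENDOSPERM: 175.0,
}
"""Default 8-bit class mean intensities.

Ordered background < soft < hard < embryo ~ pericarp, with the embryo and
hard-endosperm distributions overlapping in their tails — the confusion
structure seen in real kernel scans.  No published per-tissue density
calibration exists, so these are free parameters of the phantom.
"""

DEFAULT_TEXTURE_SCALES: dict[Tissue, float] = {
    Tissue.BACKGROUND: 2.0,
    Tissue.PERICARP: 5.0,
    Tissue.EMBRYO: 7.0,
    Tissue.SOFT_ENDOSPERM: 10.0,
    Tissue.HARD_ENDOSPERM: 6.0,
}

SEPARATED_CLASS_MEANS: dict[Tissue, float] = {
    Tissue.BACKGROUND: 8.0,
    Tissue.PERICARP: 235.0,
    Tissue.EMBRYO: 205.0,
    Tissue.SOFT_ENDOSPERM: 120.0,
    Tissue.HARD_ENDOSPERM: 175.0,
}
"""Well-separated radiometry: every pairwise class-mean gap is at least
four times the combined within-class scale (speckle plus scan noise).
Used to validate recovery under easy contrast; the default radiometry
above is deliberately harder."""

SEPARATED_TEXTURE_SCALES: dict[Tissue, float] = {t: 3.0 for t in Tissue}

#: Intensity decrement applied to both endosperm classes of waxy genotypes.
WAXY_DENSITY_DROP = 6.0

#: Gaussian sigma (voxels) of the class-boundary blend; ~2-voxel transition band.
BOUNDARY_BLEND_SIGMA = 0.6


@dataclass(frozen=True)
class KernelSpec:
    """Geometric and radiometric description of one genotype's kernels.

    Lengths are in mm; fractions are of voxel counts.  ``embryo_fraction``
    is relative to the whole kernel, ``hard_fraction`` is the share of
    endosperm assigned to the peripheral hard shell.
    """

    semi_axes: tuple[float, float, float] = (1.9, 1.55, 1.25)
    pericarp_thickness: float = 0.30
    embryo_fraction: float = 0.12
    hard_fraction: float = 0.55
    void_probability: float = 0.0
    waxy: bool = False
    #: Within-genotype kernel-to-kernel variability: size jitter is a
    #: downward half-normal scale (so kernels never outgrow their packing
    #: box), fraction jitters are additive Gaussians clipped to range.
    size_jitter_cv: float = 0.035
    hard_fraction_jitter_sd: float = 0.025
    embryo_fraction_jitter_sd: float = 0.01
    class_means: dict[Tissue, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MEANS)
    )
    class_texture_scales: dict[Tissue, float] = field(
        default_factory=lambda: dict(DEFAULT_TEXTURE_SCALES)
    )

    def validate(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError(f"semi_axes must be positive, got {self.semi_axes}")
        if not 0 < self.pericarp_thickness < min(self.semi_axes):
            raise ValueError(
                "pericarp_thickness must lie in (0, min(semi_axes)); "
                f"got {self.pericarp_thickness} vs semi_axes {self.semi_axes}"
            )
        for name in ("embryo_fraction", "hard_fraction", "void_probability"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for cls in Tissue:
            m = self.class_means[cls]
            if not 0 <= m <= 255:
                raise ValueError(f"class mean for {cls.name} outside [0,255]: {m}")

    def effective_means(self) -> dict[Tissue, float]:
        """Class means after the waxy density decrement, if any."""
        means = dict(self.class_means)
        if self.waxy:
            means[Tissue.SOFT_ENDOSPERM] -= WAXY_DENSITY_DROP
            means[Tissue.HARD_ENDOSPERM] -= WAXY_DENSITY_DROP
        return means


@dataclass(frozen=True)
class ScanSpec:
    """One CT scan: a grid of wells, each holding one experimental unit.

    ``layout`` must have columns ``row``, ``col`` (1-based well grid
    position) and ``genotype``.  ``well_voxel_extent`` is (z, y, x) voxels
    per well; the scan volume is one well tall in z with wells tiled in the
    y/x plane, so the well boxes partition the volume exactly.
    """

    layout: pd.DataFrame
    kernels_per_well: int = 40
    well_voxel_extent: tuple[int, int, int] = (64, 64, 64)
    brightness_offset: float = 0.0
    attenuation_gradient: float = 0.0
    noise_sd: float = 5.0
    voxel_size_mm: float = 0.25
    seed: int = 0
    rep: int = 1

    def validate(self) -> None:
        req = {"row", "col", "genotype"}
        if not req <= set(self.layout.columns):
            raise ValueError(f"layout must have columns {sorted(req)}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.kernels_per_well < 1:
            raise ValueError("kernels_per_well must be >= 1")
        dup = self.layout.duplicated(subset=["row", "col"])
        if dup.any():
            raise ValueError("layout assigns multiple genotypes to one well")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        ez, ey, ex = self.well_voxel_extent
        return (ez, int(self.layout["row"].max()) * ey, int(self.layout["col"].max()) * ex)

    def well_box(self, row: int, col: int) -> tuple[slice, slice, slice]:
        ez, ey, ex = self.well_voxel_extent
        return (
            slice(0, ez),
            slice((row - 1) * ey, row * ey),
            slice((col - 1) * ex, col * ex),
        )


@dataclass
class GroundTruth:
    """Exact labels and per-unit truth for one generated scan."""

    label_volume: np.ndarray
    unit_counts: pd.DataFrame  # genotype, rep, row, col, one column per class
    per_unit_true_traits: pd.DataFrame
    per_kernel_records: dict[tuple[int, int, int], np.ndarray]
    voxel_size_mm: float


def _ellipsoid_field(shape, semi_axes_vox):
    """Normalized squared radius ``sum((x_i/a_i)^2)`` on a centered grid."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    centers = [(s - 1) / 2.0 for s in shape]
    rho2 = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, centers, semi_axes_vox):
        rho2 = rho2 + ((g - c) / a) ** 2
    return rho2


def make_kernel(
    spec: KernelSpec, voxel_size_mm: float, seed: int | np.random.SeedSequence = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelize one kernel; return ``(intensity float32, labels uint8)``.

    The bounding box is the tight odd-sized box around the ellipsoid.
    Intensities are the class means blended over a ~2-voxel band (graded
    boundaries) plus per-class speckle; no scan-level degradation is
    applied here.
    """
    spec.validate()
    if voxel_size_mm <= 0:
        raise ValueError("voxel_size_mm must be positive")
    rng = np.random.default_rng(seed)

    semi_vox = np.asarray(spec.semi_axes, dtype=float) / voxel_size_mm
    half = np.ceil(semi_vox).astype(int)
    shape = tuple(2 * h + 1 for h in half)

    rho2_outer = _ellipsoid_field(shape, semi_vox)
    kernel_mask = rho2_outer <= 1.0
    n_kernel = int(kernel_mask.sum())
    if n_kernel == 0:
        raise ValueError(
            "kernel ellipsoid contains no voxels at this voxel size; "
            f"semi_axes {spec.semi_axes} mm vs voxel {voxel_size_mm} mm"
        )

    inner_axes = semi_vox - spec.pericarp_thickness / voxel_size_mm
    if np.any(inner_axes <= 0):
        raise ValueError("pericarp_thickness leaves no interior at this voxel size")
    rho2_inner = _ellipsoid_field(shape, inner_axes)
    interior = rho2_inner <= 1.0

    labels = np.zeros(shape, dtype=np.uint8)
    labels[kernel_mask & ~interior] = Tissue.PERICARP

    # Embryo: exact-count polar lobe embedded in the endosperm (the
    # scutellum sits inside the kernel), grown outward from a center offset
    # toward the +z pole; nearest interior voxels by scaled distance.
    izs, iys, ixs = np.nonzero(interior)
    n_embryo = int(round(spec.embryo_fraction * n_kernel))
    if n_embryo > izs.size:
        raise ValueError(
            f"embryo_fraction {spec.embryo_fraction} needs {n_embryo} voxels but the "
            f"interior holds only {izs.size}; reduce embryo_fraction or pericarp_thickness"
        )
    centers = np.array([(s - 1) / 2.0 for s in shape])
    lobe_center = centers.copy()
    lobe_center[0] += 0.5 * inner_axes[0]
    lobe_axes = np.array([inner_axes[0], 0.7 * inner_axes[1], 0.7 * inner_axes[2]])
    d2 = (
        ((izs - lobe_center[0]) / lobe_axes[0]) ** 2
        + ((iys - lobe_center[1]) / lobe_axes[1]) ** 2
        + ((ixs - lobe_center[2]) / lobe_axes[2]) ** 2
    )
    order = np.argsort(d2, kind="stable")
    emb_sel = order[:n_embryo]
    labels[izs[emb_sel], iys[emb_sel], ixs[emb_sel]] = Tissue.EMBRYO

    # Endosperm: peripheral hard shell vs central soft core, again by exact
    # voxel count on the normalized radius.
    endo_sel = order[n_embryo:]
    n_endo = endo_sel.size
    n_hard = int(round(spec.hard_fraction * n_endo))
    ez, ey, ex = izs[endo_sel], iys[endo_sel], ixs[endo_sel]
    endo_order = np.argsort(-rho2_inner[ez, ey, ex], kind="stable")
    hard_sel = endo_order[:n_hard]
    soft_sel = endo_order[n_hard:]
    labels[ez[hard_sel], ey[hard_sel], ex[hard_sel]] = Tissue.HARD_ENDOSPERM
    labels[ez[soft_sel], ey[soft_sel], ex[soft_sel]] = Tissue.SOFT_ENDOSPERM

    # Internal hollow void: an off-center ellipsoidal cavity, labeled
    # background so voids never count toward any tissue.  Determined now but
    # carved after blending — cracks and voids are fractures with crisp
    # edges, unlike the graded tissue-to-tissue transitions.
    void_mask = None
    if spec.void_probability > 0 and rng.random() < spec.void_probability:
        void_axes = np.maximum(0.30 * inner_axes, 1.0)
        offset = rng.uniform(-0.35, 0.35, size=3) * inner_axes
        offset[0] = -abs(offset[0])  # keep the void away from the embryo pole
        vcenters = [(s - 1) / 2.0 for s in shape]
        grids = np.ogrid[tuple(slice(0, s) for s in shape)]
        v2 = np.zeros(shape)
        for g, c, o, a in zip(grids, vcenters, offset, void_axes):
            v2 = v2 + ((g - (c + o)) / a) ** 2
        void_mask = (v2 <= 1.0) & interior

    means = spec.effective_means()
    mean_lut = np.array([means[Tissue(i)] for i in range(5)])
    scale_lut = np.array([spec.class_texture_scales[Tissue(i)] for i in range(5)])
    blended = ndimage.gaussian_filter(
        mean_lut[labels], BOUNDARY_BLEND_SIGMA, mode="nearest"
    )
    if void_mask is not None:
        labels[void_mask] = Tissue.BACKGROUND
        blended[void_mask] = means[Tissue.BACKGROUND]
    speckle = rng.standard_normal(shape) * scale_lut[labels]
    intensity = (blended + speckle).astype(np.float32)
    return intensity, labels


def _place_kernels_in_well(well_extent, bbox, n_kernels, rng):
    """Jittered-lattice origins of ``n_kernels`` disjoint bounding boxes.

    Kernels at the scanned density pack too tightly for sequential
    rejection sampling, so boxes are placed on a stride lattice with
    per-kernel jitter inside each lattice cell; boxes can touch but never
    overlap.  Raises when the well cannot hold the request.
    """
    slots = [e // b for e, b in zip(well_extent, bbox)]
    n_slots = int(np.prod(slots))
    if n_slots < n_kernels:
        raise ValueError(
            f"well of extent {tuple(well_extent)} holds at most {n_slots} kernels of "
            f"bounding box {tuple(bbox)}, but {n_kernels} were requested"
        )
    strides = [e // s for e, s in zip(well_extent, slots)]
    chosen = rng.permutation(n_slots)[:n_kernels]
    origins = []
    for lin in chosen:
        idx = np.unravel_index(lin, slots)
        origin = [
            int(i * st + rng.integers(0, st - b + 1))
            for i, st, b in zip(idx, strides, bbox)
        ]
        origins.append(tuple(origin))
    return origins


def make_scan(
    spec: ScanSpec, kernel_specs: dict[str, KernelSpec]
) -> tuple[np.ndarray, GroundTruth]:
    """Generate one scan volume and its exact ground truth.

    The brightness offset, attenuation gradient and additive noise degrade
    intensities only; labels and the derived true traits are computed from
    the clean volume.
    """
    from . import traits as traits_mod

    spec.validate()
    missing = set(spec.layout["genotype"]) - set(kernel_specs)
    if missing:
        raise ValueError(f"no KernelSpec for genotype(s): {sorted(missing)}")

    shape = spec.grid_shape
    root = np.random.SeedSequence((spec.seed, spec.rep))
    bg_rng = np.random.default_rng(root.spawn(1)[0])
    bg_mean = DEFAULT_CLASS_MEANS[Tissue.BACKGROUND]
    bg_scale = DEFAULT_TEXTURE_SCALES[Tissue.BACKGROUND]
    intensity = (
        bg_mean + bg_scale * bg_rng.standard_normal(shape)
    ).astype(np.float32)
    labels = np.zeros(shape, dtype=np.uint8)

    per_kernel: dict[tuple[int, int, int], np.ndarray] = {}
    layout = spec.layout.sort_values(["row", "col"]).reset_index(drop=True)
    for _, well in layout.iterrows():
        row, col = int(well["row"]), int(well["col"])
        kspec = kernel_specs[well["genotype"]]
        kspec.validate()
        semi_vox = np.asarray(kspec.semi_axes) / spec.voxel_size_mm
        bbox = tuple(2 * int(np.ceil(a)) + 1 for a in semi_vox)
        well_seq = np.random.SeedSequence((spec.seed, spec.rep, row, col))
        place_rng = np.random.default_rng(well_seq)
        origins = _place_kernels_in_well(
            spec.well_voxel_extent, bbox, spec.kernels_per_well, place_rng
        )
        box = spec.well_box(row, col)
        base = (box[0].start, box[1].start, box[2].start)
        for k, origin in enumerate(origins):
            kseq = np.random.SeedSequence((spec.seed, spec.rep, row, col, k))
            jit = np.random.default_rng(
                np.random.SeedSequence((spec.seed, spec.rep, row, col, k, 13))
            )
            scale = 1.0 - min(abs(jit.normal(0.0, kspec.size_jitter_cv)), 0.2)
            hard = kspec.hard_fraction
            if 0.0 < hard < 1.0:  # degenerate fractions stay degenerate
                hard = float(np.clip(
                    hard + jit.normal(0.0, kspec.hard_fraction_jitter_sd), 0.0, 1.0
                ))
            emb = kspec.embryo_fraction
            if emb > 0.0:
                emb = float(np.clip(
                    emb + jit.normal(0.0, kspec.embryo_fraction_jitter_sd), 0.02, 0.30
                ))
            k_spec = dataclasses.replace(
                kspec,
                semi_axes=tuple(a * scale for a in kspec.semi_axes),
                pericarp_thickness=kspec.pericarp_thickness * scale,
                hard_fraction=hard,
                embryo_fraction=emb,
            )
            k_int, k_lab = make_kernel(k_spec, spec.voxel_size_mm, kseq)
            flip_rng = np.random.default_rng(
                np.random.SeedSequence((spec.seed, spec.rep, row, col, k, 7))
            )
            for ax in range(3):
                if flip_rng.random() < 0.5:
                    k_int = np.flip(k_int, axis=ax)
                    k_lab = np.flip(k_lab, axis=ax)
            sl = tuple(
                slice(b + o, b + o + s) for b, o, s in zip(base, origin, k_lab.shape)
            )
            intensity[sl] = k_int
            labels[sl] = k_lab
            per_kernel[(row, col, k)] = np.bincount(k_lab.ravel(), minlength=5)

    truth = _ground_truth_from_labels(labels, intensity, spec, traits_mod)

    # Degradations: applied to intensity only, after truth extraction.
    degraded = intensity.astype(np.float64) + spec.brightness_offset
    if spec.attenuation_gradient:
        _, ny, nx = shape
        yy, xx = np.meshgrid(
            np.arange(ny) - (ny - 1) / 2, np.arange(nx) - (nx - 1) / 2, indexing="ij"
        )
        d2 = (yy**2 + xx**2) / ((ny / 2) ** 2 + (nx / 2) ** 2)
        degraded *= 1.0 - spec.attenuation_gradient * d2[None, :, :]
    if spec.noise_sd:
        noise_rng = np.random.default_rng(root.spawn(2)[1])
        degraded += noise_rng.normal(0.0, spec.noise_sd, size=shape)
    degraded = np.clip(degraded, 0.0, 255.0).astype(np.float32)

    truth.per_kernel_records = per_kernel
    return degraded, truth


def _ground_truth_from_labels(labels, clean_intensity, spec: ScanSpec, traits_mod):
    from .segmentation import count_pixels

    counts = count_pixels(labels, spec)
    counts.insert(0, "rep", spec.rep)
    rows = []
    for _, rec in counts.iterrows():
        box = spec.well_box(int(rec["row"]), int(rec["col"]))
        endo_mask = np.isin(
            labels[box], (int(Tissue.SOFT_ENDOSPERM), int(Tissue.HARD_ENDOSPERM))
        )
        endo_int = (
            float(clean_intensity[box][endo_mask].mean()) if endo_mask.any() else np.nan
        )
        rows.append(endo_int)
    true_traits = traits_mod.traits_from_counts(
        counts,
        voxel_size_mm=spec.voxel_size_mm,
        n_kernels=spec.kernels_per_well,
    )
    true_traits["endosperm_intensity"] = rows
    return GroundTruth(
        label_volume=labels,
        unit_counts=counts,
        per_unit_true_traits=true_traits,
        per_kernel_records={},
        voxel_size_mm=spec.voxel_size_mm,
    )


# ---------------------------------------------------------------------------
# Study-level helpers: a genotype panel and the replicated multi-scan design.
# ---------------------------------------------------------------------------

def default_panel(
    n_genotypes: int = 19,
    seed: int = 20220111,
    separated: bool = False,
    jitter: bool = True,
) -> dict[str, KernelSpec]:
    """A panel of genotypes spanning realistic kernel-trait variation.

    Size scale, endosperm texture (hard fraction), embryo fraction and
    pericarp thickness vary across genotypes; one genotype is waxy
    (slightly less dense endosperm) and one is void-prone (internal hollow
    cavities).  The hard-endosperm share spans 0.5-0.8 of endosperm,
    i.e. texture ratios of roughly 1-4, the range real sorghum panels
    cover.  With ``separated=True`` the well-separated radiometry replaces
    the default overlapping class means; ``jitter=False`` turns off
    within-genotype kernel-to-kernel variability, giving geometrically
    exact replicate kernels.  Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    panel: dict[str, KernelSpec] = {}
    waxy_idx = n_genotypes // 3
    void_idx = (2 * n_genotypes) // 3
    extra = {}
    if separated:
        extra = {
            "class_means": dict(SEPARATED_CLASS_MEANS),
            "class_texture_scales": dict(SEPARATED_TEXTURE_SCALES),
        }
    if not jitter:
        extra.update(
            size_jitter_cv=0.0,
            hard_fraction_jitter_sd=0.0,
            embryo_fraction_jitter_sd=0.0,
        )
    for i in range(n_genotypes):
        scale = rng.uniform(0.88, 1.10)
        panel[f"G{i + 1:02d}"] = KernelSpec(
            semi_axes=(1.9 * scale, 1.55 * scale, 1.25 * scale),
            pericarp_thickness=rng.uniform(0.27, 0.33),
            embryo_fraction=rng.uniform(0.10, 0.15),
            hard_fraction=rng.uniform(0.50, 0.80),
            void_probability=0.3 if i == void_idx else 0.0,
            waxy=(i == waxy_idx),
            **extra,
        )
    return panel


def rcbd_layout(
    genotypes: list[str],
    n_rows: int,
    n_cols: int,
    rep: int,
    seed: int = 0,
    check_genotype: str | None = None,
    n_check_wells: int = 1,
) -> pd.DataFrame:
    """Randomized well layout for one scan (one complete block).

    Each genotype occupies one well; the check genotype occupies
    ``n_check_wells`` wells in total (its extra wells assess within-scan
    spatial variation).  Raises if the grid size does not match.
    """
    entries = list(genotypes)
    if check_genotype is not None:
        if check_genotype not in genotypes:
            raise ValueError(f"check genotype {check_genotype!r} not in panel")
        entries += [check_genotype] * (n_check_wells - 1)
    if len(entries) != n_rows * n_cols:
        raise ValueError(
            f"{len(entries)} entries do not fill a {n_rows}x{n_cols} well grid"
        )
    rng = np.random.default_rng(np.random.SeedSequence((seed, rep)))
    entries = [entries[i] for i in rng.permutation(len(entries))]
    rows, cols = np.meshgrid(
        np.arange(1, n_rows + 1), np.arange(1, n_cols + 1), indexing="ij"
    )
    return pd.DataFrame(
        {"row": rows.ravel(), "col": cols.ravel(), "genotype": entries}
    )


def simulate_study(
    panel: dict[str, KernelSpec],
    n_scans: int = 3,
    n_rows: int = 3,
    n_cols: int = 7,
    check_genotype: str | None = None,
    n_check_wells: int = 3,
    kernels_per_well: int = 40,
    well_voxel_extent: tuple[int, int, int] = (64, 64, 64),
    brightness_offsets: tuple[float, ...] | None = None,
    attenuation_gradient: float = 0.0,
    noise_sd: float = 5.0,
    voxel_size_mm: float = 0.25,
    seed: int = 0,
) -> list[tuple[np.ndarray, GroundTruth, ScanSpec]]:
    """Generate a replicated multi-scan study (each scan = one replicate).

    ``brightness_offsets`` defaults to distinct per-scan offsets so scans
    differ in overall brightness, as replicate CT scans do.
    """
    if brightness_offsets is None:
        off_rng = np.random.default_rng(np.random.SeedSequence((seed, 917)))
        brightness_offsets = tuple(off_rng.uniform(-8.0, 8.0, size=n_scans))
    if len(brightness_offsets) != n_scans:
        raise ValueError("need one brightness offset per scan")
    out = []
    genos = sorted(panel)
    for rep in range(1, n_scans + 1):
        layout = rcbd_layout(
            genos,
            n_rows,
            n_cols,
            rep=rep,
            seed=seed,
            check_genotype=check_genotype,
            n_check_wells=n_check_wells,
        )
        spec = ScanSpec(
            layout=layout,
            kernels_per_well=kernels_per_well,
            well_voxel_extent=well_voxel_extent,
            brightness_offset=float(brightness_offsets[rep - 1]),
            attenuation_gradient=attenuation_gradient,
            noise_sd=noise_sd,
            voxel_size_mm=voxel_size_mm,
            seed=seed,
            rep=rep,
        )
        grid, truth = make_scan(spec, panel)
        out.append((grid, truth, spec))
    return out


def replace(spec, **changes):
    """``dataclasses.replace`` re-exported for ergonomic spec tweaking."""
    return dataclasses.replace(spec, **changes)
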