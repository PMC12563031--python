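"""Micro-CT porosity quantification for porous scaffolds.

Pipeline: (optional Gaussian smoothing) -> global threshold by the
Riddler–Calvard / ISODATA fixed-point rule -> despeckle -> shrink-wrap ROI
-> volumetric porosity and per-pore size distribution, with every report
also normalized to a 1 mm^3 reference volume so samples of different ROI
sizes are comparable.

Conventions: volumes are stored (z, y, x) with 0-based voxel indices; the
solid phase is the brighter (more attenuating) phase; pore/component
connectivity defaults to 26-neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian as _gaussian
from skimage.morphology import remove_small_objects

__all__ = [
    "VolumeImage",
    "BinarySegmentation",
    "PorosityReport",
    "DegenerateHistogramError",
    "despeckle",
    "riddler_calvard_threshold",
    "shrink_wrap_roi",
    "segment_volume",
    "porosity",
    "pore_size_distribution",
]


class DegenerateHistogramError(ValueError):
    """The intensity histogram has fewer than two distinct values."""


@dataclass(frozen=True)
class VolumeImage:
    """3-D grayscale volume with isotropic voxels.

    ``data`` is a (z, y, x) integer grid (8- or 16-bit grayscale);
    ``voxel_size_um`` is the voxel edge length in micrometres.
    """

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        a = np.asarray(self.data)
        if a.ndim != 3 or min(a.shape) < 1:
            raise ValueError("data must be a nonempty 3-D array")
        if not (self.voxel_size_um > 0):
            raise ValueError("voxel_size_um must be > 0")
        object.__setattr__(self, "data", a)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class BinarySegmentation:
    """Solid/ROI masks produced by the segmentation pipeline.

    Invariant: ``solid`` is a subset of ``roi``; both are congruent boolean
    grids.  ``threshold`` is the grayscale cut applied (solid = I >= T).
    """

    solid: np.ndarray
    roi: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        s = np.asarray(self.solid, dtype=bool)
        r = np.asarray(self.roi, dtype=bool)
        if s.shape != r.shape or s.ndim != 3:
            raise ValueError("solid and roi must be congruent 3-D boolean grids")
        if np.any(s & ~r):
            raise ValueError("solid mask must be a subset of the ROI mask")
        object.__setattr__(self, "solid", s)
        object.__setattr__(self, "roi", r)


@dataclass(frozen=True)
class PorosityReport:
    """Porosity summary of one segmented volume.

    ``porosity_percent`` is 100 * pore voxels / ROI voxels;
    ``normalized_pore_volume_mm3`` is the pore volume rescaled to a 1 mm^3
    reference ROI; ``pore_sizes_mm3`` holds one volume per 26-connected pore
    component, descending.
    """

    porosity_percent: float
    pore_volume_mm3: float
    roi_volume_mm3: float
    normalized_pore_volume_mm3: float
    pore_sizes_mm3: np.ndarray
    threshold: float
    voxel_size_um: float

    def to_dict(self) -> dict:
        return {
            "porosity_percent": self.porosity_percent,
            "pore_volume_mm3": self.pore_volume_mm3,
            "roi_volume_mm3": self.roi_volume_mm3,
            "normalized_pore_volume_mm3": self.normalized_pore_volume_mm3,
            "n_pores": int(len(self.pore_sizes_mm3)),
            "pore_sizes_mm3": [float(v) for v in self.pore_sizes_mm3],
            "threshold": self.threshold,
            "voxel_size_um": self.voxel_size_um,
        }


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def despeckle(mask: np.ndarray, min_component_voxels: int, connectivity: int = 26) -> np.ndarray:
    """Remove foreground components smaller than ``min_component_voxels``.

    Operates on a boolean mask (26-connectivity by default); larger
    structures pass through unchanged.
    """
    if min_component_voxels < 1:
        raise ValueError("min_component_voxels must be >= 1")
    m = np.asarray(mask)
    if m.dtype != bool:
        raise TypeError("despeckle expects a boolean mask")
    # skimage connectivity: number of orthogonal steps per neighbour hop
    conn = 3 if connectivity == 26 else 1
    if connectivity not in (6, 26):
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    # remove components with size < min_component_voxels (max_size is inclusive)
    return remove_small_objects(m, max_size=min_component_voxels - 1, connectivity=conn)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def riddler_calvard_threshold(volume: VolumeImage | np.ndarray, max_iter: int = 256) -> int:
    """Riddler–Calvard (ISODATA) threshold on the integer intensity lattice.

    Starting from the rounded global mean, iterate
    T <- round((mean(I < T) + mean(I >= T)) / 2) (ties round half up) until
    the integer threshold repeats.  Both classes are nonempty at every
    accepted iterate.  Raises :class:`DegenerateHistogramError` for a
    constant volume.
    """
    data = volume.data if isinstance(volume, VolumeImage) else np.asarray(volume)
    flat = data.ravel()
    lo, hi = int(flat.min()), int(flat.max())
    if lo == hi:
        raise DegenerateHistogramError("constant-intensity volume: threshold undefined")
    t = _round_half_up(float(flat.mean()))
    t = min(max(t, lo + 1), hi)  # keep the lower class nonempty
    seen = set()
    for _ in range(max_iter):
        low = flat[flat < t]
        high = flat[flat >= t]
        if low.size == 0 or high.size == 0:  # pragma: no cover - guarded by clamping
            break
        t_new = _round_half_up(0.5 * (float(low.mean()) + float(high.mean())))
        t_new = min(max(t_new, lo + 1), hi)
        if t_new == t or t_new in seen:
            return int(t_new)
        seen.add(t)
        t = t_new
    return int(t)


def shrink_wrap_roi(solid_mask: np.ndarray, background_connectivity: int = 6) -> np.ndarray:
    """Tight ROI around the solid: everything except background connected to
    the volume border.

    Exterior air is identified by flood-filling the non-solid phase from the
    six faces (6-connectivity by default, so the wrap cannot leak through
    voxel corners); enclosed cavities and internal pores stay inside the ROI.
    """
    solid = np.asarray(solid_mask, dtype=bool)
    if not solid.any():
        raise ValueError("empty solid mask: nothing to wrap")
    labels, _ = ndimage.label(~solid, structure=_structure(background_connectivity))
    border_labels = set()
    for axis in range(3):
        for face in (0, -1):
            border_labels.update(np.unique(np.take(labels, face, axis=axis)))
    border_labels.discard(0)
    exterior = np.isin(labels, sorted(border_labels))
    return ~exterior


def segment_volume(
    volume: VolumeImage,
    smoothing_sigma: float = 0.0,
    despeckle_min_voxels: int = 8,
    fill_pore_specks: bool = True,
    connectivity: int = 26,
) -> BinarySegmentation:
    """Full preprocessing + segmentation chain on a grayscale volume.

    Optional Gaussian smoothing (off by default), Riddler–Calvard threshold,
    removal of small solid specks and (optionally) small isolated pore
    specks inside the solid, then shrink-wrap ROI.
    """
    data = volume.data
    if smoothing_sigma > 0:
        smoothed = _gaussian(data.astype(float), sigma=smoothing_sigma, preserve_range=True)
        data = np.rint(smoothed).astype(volume.data.dtype)
    t = riddler_calvard_threshold(data)
    solid = data >= t
    if despeckle_min_voxels > 1:
        solid = despeckle(solid, despeckle_min_voxels, connectivity=connectivity)
        if fill_pore_specks:
            # fill non-solid specks (noise holes in struts) below the same size
            holes = despeckle(~solid, despeckle_min_voxels, connectivity=connectivity)
            solid = ~holes
    roi = shrink_wrap_roi(solid)
    return BinarySegmentation(solid=solid, roi=roi, threshold=float(t))


def porosity(seg: BinarySegmentation, voxel_size_um: float, connectivity: int = 26) -> PorosityReport:
    """Volumetric porosity and pore-size distribution of a segmentation.

    porosity % = 100 * (ROI - solid voxels) / ROI voxels; volumes in mm^3
    via voxel_size^3; pore sizes from connected labeling of the pore phase
    within the ROI.  The report includes the pore volume normalized to a
    1 mm^3 reference ROI.
    """
    if not (voxel_size_um > 0):
        raise ValueError("voxel_size_um must be > 0")
    n_roi = int(seg.roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    pores = seg.roi & ~seg.solid
    n_pore = int(pores.sum())
    vvox = (voxel_size_um / 1000.0) ** 3  # mm^3 per voxel
    frac = n_pore / n_roi
    sizes = pore_size_distribution_mask(pores, voxel_size_um, connectivity)
    return PorosityReport(
        porosity_percent=100.0 * frac,
        pore_volume_mm3=n_pore * vvox,
        roi_volume_mm3=n_roi * vvox,
        normalized_pore_volume_mm3=frac * 1.0,
        pore_sizes_mm3=sizes,
        threshold=seg.threshold,
        voxel_size_um=voxel_size_um,
    )


def pore_size_distribution_mask(
    pore_mask: np.ndarray, voxel_size_um: float, connectivity: int = 26
) -> np.ndarray:
    """Volumes (mm^3, descending) of connected pore components in a mask."""
    labels, n = ndimage.label(np.asarray(pore_mask, dtype=bool), structure=_structure(connectivity))
    if n == 0:
        return np.array([])
    counts = np.bincount(labels.ravel())[1:]
    vvox = (voxel_size_um / 1000.0) ** 3
    return np.sort(counts)[::-1].astype(float) * vvox


def pore_size_distribution(
    seg: BinarySegmentation, voxel_size_um: float, connectivity: int = 26
) -> tuple[np.ndarray, dict]:
    """Sorted per-pore volumes plus summary quantiles (mm^3)."""
    sizes = pore_size_distribution_mask(seg.roi & ~seg.solid, voxel_size_um, connectivity)
    if sizes.size == 0:
        summary = {k: 0.0 for k in ("min", "q25", "median", "q75", "max", "total")}
    else:
        q = np.percentile(sizes, [25, 50, 75])
        summary = {
            "min": float(sizes.min()),
            "q25": float(q[0]),
            "median": float(q[1]),
            "q75": float(q[2]),
            "max": float(sizes.max()),
            "total": float(sizes.sum()),
        }
    return sizes, summary
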