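"""Metabolic compartment segmentation on SUV volumes.

Implements relative-isocontour segmentation of a lesion into a total
(60-100% of lesion SUVmax, MTV60), peripheral (60-75%, ROI60) and central
(80-100%, ROI80) compartment, an absolute-threshold metabolic tumor volume
(k times the contralateral background mean), target-lesion selection in
multifocal masks, vessel exclusion, and the mirrored contralateral 2D
background region.

Band bounds are inclusive on both ends: a voxel at exactly 0.75*SUVmax is
peripheral, at exactly 0.80*SUVmax central; the 75-80% band belongs to MTV60
only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, SuvVolume

__all__ = [
    "CompartmentSet",
    "BackgroundRoi",
    "select_target_lesion",
    "exclude_regions",
    "lesion_suv_max",
    "isocontour_mask",
    "extract_compartments",
    "background_roi",
    "absolute_mtv",
]

#: 26-connected structuring element
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

#: compartment band definitions as (lower_frac, upper_frac) of lesion SUVmax
BANDS = {"mtv60": (0.60, 1.00), "roi60": (0.60, 0.75), "roi80": (0.80, 1.00)}


@dataclass
class CompartmentSet:
    """The four compartment masks of one lesion and their provenance."""

    suv_max: float
    mtv60: BinaryMask
    roi60: BinaryMask
    roi80: BinaryMask
    mtv_abs: Optional[BinaryMask] = None
    thresholds_used: dict = field(default_factory=dict)
    search: Optional[BinaryMask] = None  # isocontour search region

    def __post_init__(self) -> None:
        m60, r60, r80 = self.mtv60.values, self.roi60.values, self.roi80.values
        if np.any(r60 & r80):
            raise ValueError("ROI60 and ROI80 overlap")
        if np.any(r60 & ~m60) or np.any(r80 & ~m60):
            raise ValueError("compartments must nest inside MTV60")


@dataclass
class BackgroundRoi:
    """Contralateral 2D background region on the hottest tumor slice."""

    slice_index: int
    axis: int
    mask2d: np.ndarray
    mean_suv: float
    area_mm2: float
    shift_voxels: int = 0


def select_target_lesion(
    mask: BinaryMask, volume: Optional[SuvVolume] = None
) -> BinaryMask:
    """Keep the most prominent 26-connected component of a (possibly
    multifocal) lesion mask.

    Prominence is voxel volume; ties break by higher contained SUVmax (when a
    volume is supplied), then by lowest linear index, so the choice is
    deterministic.
    """
    if mask.n_voxels == 0:
        raise ValueError("empty lesion mask")
    labels, n = ndimage.label(mask.values, structure=_STRUCT_26)
    if n == 1:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = sizes.max()
    candidates = [i + 1 for i, s in enumerate(sizes) if s == best]
    if len(candidates) > 1 and volume is not None:
        mask.require_same_geometry(volume)
        peaks = ndimage.maximum(volume.values, labels, index=candidates)
        top = max(peaks)
        candidates = [c for c, p in zip(candidates, peaks) if p == top]
    if len(candidates) > 1:
        firsts = [
            int(np.flatnonzero((labels == c).ravel())[0]) for c in candidates
        ]
        candidates = [candidates[int(np.argmin(firsts))]]
    return mask.with_values(labels == candidates[0])


def exclude_regions(mask: BinaryMask, exclusion: BinaryMask) -> BinaryMask:
    """Set difference mask \\ exclusion (e.g. removing large blood vessels)."""
    mask.require_same_geometry(exclusion)
    out = mask.values & ~exclusion.values
    if not out.any():
        warnings.warn("exclusion removed the entire lesion mask", stacklevel=2)
    return mask.with_values(out)


def lesion_suv_max(
    volume: SuvVolume, lesion: BinaryMask, robust_peak: bool = False
) -> float:
    """Reference maximum for the relative isocontours.

    Default: the single hottest voxel inside the lesion.  ``robust_peak``
    averages each voxel with its 26-neighbourhood first, damping single-voxel
    noise spikes.
    """
    volume.require_same_geometry(lesion)
    if lesion.n_voxels == 0:
        raise ValueError("empty lesion mask after exclusions")
    values = volume.values
    if robust_peak:
        values = ndimage.uniform_filter(values, size=3, mode="nearest")
    return float(values[lesion.values].max())


def isocontour_mask(
    volume: SuvVolume,
    search_mask: BinaryMask,
    lower_frac: float,
    upper_frac: float,
    suv_max: float,
    label: str = "mtv60",
) -> BinaryMask:
    """Voxels of the search region whose SUV lies in
    [lower_frac*suv_max, upper_frac*suv_max] (both bounds inclusive)."""
    if not 0 < lower_frac <= upper_frac <= 1:
        raise ValueError(
            f"need 0 < lower_frac <= upper_frac <= 1, got ({lower_frac}, {upper_frac})"
        )
    volume.require_same_geometry(search_mask)
    lo = lower_frac * suv_max
    hi = upper_frac * suv_max
    sel = search_mask.values & (volume.values >= lo) & (volume.values <= hi)
    return search_mask.with_values(sel, label)


def extract_compartments(
    volume: SuvVolume,
    lesion: BinaryMask,
    exclusion: Optional[BinaryMask] = None,
    *,
    dilate_voxels: int = 2,
    robust_peak: bool = False,
    suvmax_before_exclusion: bool = False,
    background_mean: Optional[float] = None,
    k_background: float = 1.8,
) -> CompartmentSet:
    """Segment the metabolic compartments of the target lesion.

    The anatomical lesion mask is vessel-corrected, reduced to its most
    prominent component, and dilated by ``dilate_voxels`` to form the
    isocontour search region (so isocontours may slightly exceed a tight
    anatomical mask).  If ``background_mean`` is given, the absolute-threshold
    MTV (SUV >= k_background * background_mean) is computed on the same search
    region.
    """
    volume.require_same_geometry(lesion)
    raw_target = select_target_lesion(lesion, volume)
    if suvmax_before_exclusion:
        suv_max = lesion_suv_max(volume, raw_target, robust_peak)
    target = raw_target
    if exclusion is not None:
        target = exclude_regions(raw_target, exclusion)
        if target.n_voxels == 0:
            raise ValueError("lesion empty after vessel exclusion")
    if not suvmax_before_exclusion:
        suv_max = lesion_suv_max(volume, target, robust_peak)
    search_values = target.values
    if dilate_voxels > 0:
        search_values = ndimage.binary_dilation(
            search_values, structure=_STRUCT_26, iterations=dilate_voxels
        )
    if exclusion is not None:
        search_values = search_values & ~exclusion.values
    search = target.with_values(search_values)

    bands = {
        name: isocontour_mask(volume, search, lo, hi, suv_max, label=name)
        for name, (lo, hi) in BANDS.items()
    }
    if bands["roi80"].n_voxels == 0:
        raise ValueError("no central compartment (empty ROI80); CU ratio undefined")
    if bands["roi60"].n_voxels == 0:
        warnings.warn("empty peripheral compartment (ROI60)", stacklevel=2)
    thresholds = {
        name: (lo * suv_max, hi * suv_max) for name, (lo, hi) in BANDS.items()
    }
    mtv_abs = None
    if background_mean is not None:
        mtv_abs = absolute_mtv(volume, search, background_mean, k_background)
        thresholds["mtv_abs"] = (k_background * background_mean, float("inf"))
    return CompartmentSet(
        suv_max=suv_max,
        mtv60=bands["mtv60"],
        roi60=bands["roi60"],
        roi80=bands["roi80"],
        mtv_abs=mtv_abs,
        thresholds_used=thresholds,
        search=search,
    )


def _axis_from_codes(codes: tuple[str, str, str], pair: str) -> int:
    for i, c in enumerate(codes):
        if c in pair:
            return i
    raise ValueError(f"cannot identify {pair} axis from orientation codes {codes}")


def background_roi(
    volume: SuvVolume,
    tumor_mask: BinaryMask,
    mtv60: BinaryMask,
    lr_axis: Optional[int] = None,
    axial_axis: Optional[int] = None,
) -> BackgroundRoi:
    """Mirrored contralateral 2D background region of similar size.

    The representative slice is the axial slice with the highest mean SUV
    inside MTV60.  The tumor's in-slice mask is mirrored across the left-right
    mid-plane; if the mirrored region touches the tumor or leaves the grid it
    is shifted along the left-right axis to the nearest valid position
    (increasing shift magnitude, away-from-tumor direction first).
    """
    volume.require_same_geometry(tumor_mask)
    volume.require_same_geometry(mtv60)
    if tumor_mask.n_voxels == 0:
        raise ValueError("empty tumor mask")
    codes = volume.axis_codes
    if lr_axis is None:
        lr_axis = _axis_from_codes(codes, "RL")
    if axial_axis is None:
        axial_axis = _axis_from_codes(codes, "SI")

    # hottest slice: mean SUV over MTV60 voxels per axial slice
    m = mtv60.values if mtv60.n_voxels else tumor_mask.values
    sums = np.apply_over_axes(
        np.sum, volume.values * m, [a for a in range(3) if a != axial_axis]
    ).ravel()
    counts = np.apply_over_axes(
        np.sum, m.astype(float), [a for a in range(3) if a != axial_axis]
    ).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), -np.inf)
    slice_index = int(np.argmax(means))

    sl = [slice(None)] * 3
    sl[axial_axis] = slice_index
    plane_suv = volume.values[tuple(sl)]
    plane_tumor = tumor_mask.values[tuple(sl)]
    # left-right axis position within the extracted 2D plane
    lr_in_plane = lr_axis if lr_axis < axial_axis else lr_axis - 1
    mirrored = np.flip(plane_tumor, axis=lr_in_plane)

    n_lr = plane_tumor.shape[lr_in_plane]
    tumor_com = ndimage.center_of_mass(plane_tumor)[lr_in_plane]
    away = 1 if tumor_com < (n_lr - 1) / 2 else -1  # shift further from the tumor

    area = int(plane_tumor.sum())
    for magnitude in range(0, n_lr):
        for direction in ([away, -away] if magnitude else [1]):
            shift = magnitude * direction
            cand = np.roll(mirrored, shift, axis=lr_in_plane)
            # forbid wrap-around: zero the rolled-in edge
            edge = [slice(None)] * 2
            if shift > 0:
                edge[lr_in_plane] = slice(0, shift)
            elif shift < 0:
                edge[lr_in_plane] = slice(n_lr + shift, n_lr)
            if shift != 0:
                cand = cand.copy()
                cand[tuple(edge)] = False
            if int(cand.sum()) != area:
                continue  # clipped by the grid edge
            if np.any(cand & plane_tumor):
                continue
            spacing = np.delete(volume.spacing_mm, axial_axis)
            return BackgroundRoi(
                slice_index=slice_index,
                axis=axial_axis,
                mask2d=cand,
                mean_suv=float(plane_suv[cand].mean()),
                area_mm2=float(area * spacing.prod()),
                shift_voxels=shift,
            )
    raise ValueError(
        "no valid contralateral background placement on slice "
        f"{slice_index}; supply a manual background mask via the manifest"
    )


def absolute_mtv(
    volume: SuvVolume,
    search_mask: BinaryMask,
    background_mean: float,
    k: float = 1.8,
) -> BinaryMask:
    """Absolute-threshold metabolic tumor volume: SUV >= k * background mean."""
    if background_mean <= 0:
        raise ValueError("background mean must be positive")
    volume.require_same_geometry(search_mask)
    sel = search_mask.values & (volume.values >= k * background_mean)
    return search_mask.with_values(sel, "mtv_abs")
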