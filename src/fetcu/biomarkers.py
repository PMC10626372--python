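"""Scalar imaging biomarkers derived from compartment masks.

The headline quantity is the compartmental-uptake (CU) ratio: the peripheral
(60-75% of SUVmax) over the central (80-100%) compartment, taken either as a
ratio of volumes (volumetric CU) or of mean SUVs (SUV CU).  The mean
target-to-background ratio (TBR) is the central compartment's mean SUV over
the contralateral background mean.  Dice and Jaccard quantify overlap between
co-registered masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .compartments import BackgroundRoi, CompartmentSet
from .volumes import BinaryMask, SuvVolume

__all__ = [
    "LesionRecord",
    "mask_volume_cm3",
    "mean_suv",
    "cu_ratios",
    "tbr_mean",
    "dice",
    "jaccard",
    "lesion_record",
]


def mask_volume_cm3(mask: BinaryMask) -> float:
    """Voxel count times voxel volume, in cm^3."""
    return mask.n_voxels * mask.voxel_volume_mm3 / 1000.0


def mean_suv(volume: SuvVolume, mask: BinaryMask) -> float:
    """Arithmetic mean SUV over the mask."""
    volume.require_same_geometry(mask)
    if mask.n_voxels == 0:
        raise ValueError("mean SUV of an empty mask is undefined")
    return float(volume.values[mask.values].mean())


def cu_ratios(compartments: CompartmentSet, volume: SuvVolume) -> tuple[float, float]:
    """(volumetric CU, SUV CU): ROI60/ROI80 as volumes and as mean SUVs."""
    if compartments.roi80.n_voxels == 0:
        raise ValueError("empty central compartment (ROI80); CU ratio undefined")
    if compartments.roi60.n_voxels == 0:
        raise ValueError("empty peripheral compartment (ROI60); CU ratio undefined")
    cu_volumetric = mask_volume_cm3(compartments.roi60) / mask_volume_cm3(
        compartments.roi80
    )
    cu_suv = mean_suv(volume, compartments.roi60) / mean_suv(
        volume, compartments.roi80
    )
    return cu_volumetric, cu_suv


def tbr_mean(
    compartments: CompartmentSet, volume: SuvVolume, background: BackgroundRoi | float
) -> float:
    """Mean TBR: mean SUV of the central 3D VOI (ROI80) over background mean."""
    bg = background.mean_suv if isinstance(background, BackgroundRoi) else background
    if bg <= 0:
        raise ValueError("background mean must be positive")
    return mean_suv(volume, compartments.roi80) / bg


def _overlap_counts(a: BinaryMask, b: BinaryMask) -> tuple[int, int, int]:
    a.require_same_geometry(b)
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        raise ValueError("overlap of two empty masks is undefined (0/0)")
    inter = int((a.values & b.values).sum())
    return na, nb, inter


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice coefficient 2|X n Y| / (|X| + |Y|)."""
    na, nb, inter = _overlap_counts(a, b)
    return 2.0 * inter / (na + nb)


def jaccard(a: BinaryMask, b: BinaryMask) -> float:
    """Jaccard index |X n Y| / |X u Y|."""
    na, nb, inter = _overlap_counts(a, b)
    return inter / (na + nb - inter)


@dataclass
class LesionRecord:
    """Per-subject biomarker panel (volumes in cm^3, ratios dimensionless)."""

    subject_id: str
    v_mtv60_cm3: float
    v_roi60_cm3: float
    v_roi80_cm3: float
    suv_mean_roi60: float
    suv_mean_roi80: float
    background_mean: float
    cu_volumetric: float
    cu_suv: float
    tbr_mean: float
    suv_max: float
    v_mtv_abs_cm3: Optional[float] = None
    dice_mtv60_ce: Optional[float] = None
    dice_t2_mtv60: Optional[float] = None
    dice_t2_ce: Optional[float] = None
    jaccard_mtv60_ce: Optional[float] = None
    jaccard_t2_mtv60: Optional[float] = None
    jaccard_t2_ce: Optional[float] = None
    labels: Mapping[str, str] = field(default_factory=dict)
    thresholds_used: Mapping[str, tuple] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("labels", "thresholds_used") and v is not None
        }
        out.update(self.labels)
        return out


def lesion_record(
    volume: SuvVolume,
    compartments: CompartmentSet,
    background: BackgroundRoi | float,
    subject_id: str = "",
    ce_mask: Optional[BinaryMask] = None,
    t2_mask: Optional[BinaryMask] = None,
    labels: Optional[Mapping[str, str]] = None,
) -> LesionRecord:
    """Assemble the full biomarker record for one lesion.

    Overlap indices are only populated for the mask pairs actually supplied;
    absent MRI masks leave the fields as None rather than zero.
    """
    cu_vol, cu_suv = cu_ratios(compartments, volume)
    bg = background.mean_suv if isinstance(background, BackgroundRoi) else background
    record = LesionRecord(
        subject_id=subject_id,
        v_mtv60_cm3=mask_volume_cm3(compartments.mtv60),
        v_roi60_cm3=mask_volume_cm3(compartments.roi60),
        v_roi80_cm3=mask_volume_cm3(compartments.roi80),
        suv_mean_roi60=mean_suv(volume, compartments.roi60),
        suv_mean_roi80=mean_suv(volume, compartments.roi80),
        background_mean=float(bg),
        cu_volumetric=cu_vol,
        cu_suv=cu_suv,
        tbr_mean=tbr_mean(compartments, volume, bg),
        suv_max=compartments.suv_max,
        labels=dict(labels or {}),
        thresholds_used=dict(compartments.thresholds_used),
    )
    if compartments.mtv_abs is not None:
        record.v_mtv_abs_cm3 = mask_volume_cm3(compartments.mtv_abs)
    if ce_mask is not None:
        record.dice_mtv60_ce = dice(compartments.mtv60, ce_mask)
        record.jaccard_mtv60_ce = jaccard(compartments.mtv60, ce_mask)
    if t2_mask is not None:
        record.dice_t2_mtv60 = dice(t2_mask, compartments.mtv60)
        record.jaccard_t2_mtv60 = jaccard(t2_mask, compartments.mtv60)
    if ce_mask is not None and t2_mask is not None:
        record.dice_t2_ce = dice(t2_mask, ce_mask)
        record.jaccard_t2_ce = jaccard(t2_mask, ce_mask)
    return record
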