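"""NIfTI volume/mask containers, geometry checks and the cohort manifest.

All downstream computation assumes images and masks are already co-registered:
geometry mismatches are hard errors, never silently resampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "SuvVolume",
    "BinaryMask",
    "CohortManifest",
    "GeometryError",
    "MASK_LABELS",
    "MOLECULAR_MARKERS",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "load_manifest",
]

#: vocabulary of mask roles the pipeline understands
MASK_LABELS = frozenset(
    {
        "lesion",
        "exclusion",
        "contrast_enhancing",
        "t2",
        "mtv60",
        "roi60",
        "roi80",
        "mtv_abs",
        "background",
    }
)

#: molecular marker columns recognised in a cohort manifest
MOLECULAR_MARKERS = ("IDH", "MGMT", "ATRX", "LOH1p19q")

#: relative tolerance on voxel spacing when comparing geometries
SPACING_RTOL = 1e-4


class GeometryError(ValueError):
    """Image/mask grids differ in shape, spacing or orientation."""


def _spacing_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


@dataclass
class SuvVolume:
    """A 3D grid of standardized-uptake values with its world geometry.

    ``values[i, j, k]`` is the SUV of the voxel whose world position is given
    by the NIfTI affine; ``spacing_mm`` / ``origin_mm`` / ``axis_codes`` are
    derived from the affine and cached for convenience.
    """

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.values.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if np.any(self.values < 0):
            warnings.warn("volume contains negative SUV values", stacklevel=3)
        if np.any(self.spacing_mm <= 0):
            raise ValueError(f"non-positive voxel spacing {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def spacing_mm(self) -> np.ndarray:
        return _spacing_from_affine(self.affine)

    @property
    def origin_mm(self) -> np.ndarray:
        return np.asarray(self.affine)[:3, 3]

    @property
    def axis_codes(self) -> tuple[str, str, str]:
        return nib.orientations.aff2axcodes(self.affine)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_geometry(self, other: "SuvVolume | BinaryMask") -> bool:
        if self.shape != other.shape:
            return False
        if self.axis_codes != other.axis_codes:
            return False
        return bool(
            np.allclose(self.spacing_mm, other.spacing_mm, rtol=SPACING_RTOL, atol=0)
        )

    def require_same_geometry(self, other: "SuvVolume | BinaryMask") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                "geometry mismatch: "
                f"shape {self.shape} spacing {np.round(self.spacing_mm, 6)} "
                f"codes {self.axis_codes} vs "
                f"shape {other.shape} spacing {np.round(other.spacing_mm, 6)} "
                f"codes {other.axis_codes}"
            )


@dataclass
class BinaryMask:
    """A {0,1} voxel mask sharing the geometry conventions of :class:`SuvVolume`."""

    values: np.ndarray
    affine: np.ndarray
    label: str = "lesion"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {arr.shape}")
        if arr.dtype != bool:  # strict {0,1} check, not a threshold
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(
                    f"mask is not binary: values {uniq[:10]} (strict 0/1 required)"
                )
            arr = arr.astype(bool)
        self.values = arr
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.label not in MASK_LABELS:
            raise ValueError(f"unknown mask label {self.label!r}; one of {sorted(MASK_LABELS)}")

    shape = SuvVolume.shape
    spacing_mm = SuvVolume.spacing_mm
    origin_mm = SuvVolume.origin_mm
    axis_codes = SuvVolume.axis_codes
    voxel_volume_mm3 = SuvVolume.voxel_volume_mm3
    same_geometry = SuvVolume.same_geometry
    require_same_geometry = SuvVolume.require_same_geometry

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def with_values(self, values: np.ndarray, label: Optional[str] = None) -> "BinaryMask":
        return BinaryMask(values, self.affine, label or self.label)


def read_volume(path: str | Path) -> SuvVolume:
    """Load a 3D SUV volume from a NIfTI file."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return SuvVolume(data, img.affine)


def read_mask(path: str | Path, label: str = "lesion") -> BinaryMask:
    """Load a binary mask; any value other than exactly 0 or 1 is rejected."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return BinaryMask(data, img.affine, label)


def write_volume(volume: SuvVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float64), volume.affine)
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), mask.affine)
    img.header.set_data_dtype(np.uint8)
    nib.save(img, str(path))


_LABEL_SYNONYMS = {
    "positive": "positive",
    "pos": "positive",
    "mutant": "positive",
    "mutated": "positive",
    "methylated": "positive",
    "negative": "negative",
    "neg": "negative",
    "wildtype": "negative",
    "wild-type": "negative",
    "wt": "negative",
    "unmethylated": "negative",
    "unknown": "unknown",
    "not applicable": "unknown",
    "na": "unknown",
    "n/a": "unknown",
    "": "unknown",
}


def _normalise_label(value: object, column: str, subject: str) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "unknown"
    key = str(value).strip().lower()
    if key in _LABEL_SYNONYMS:
        return _LABEL_SYNONYMS[key]
    raise ValueError(
        f"subject {subject}: unrecognised {column} label {value!r} "
        "(expected positive/negative/unknown)"
    )


_PATH_COLUMNS = (
    "image_path",
    "lesion_mask_path",
    "exclusion_mask_path",
    "ce_mask_path",
    "t2_mask_path",
    "background_mask_path",
)


@dataclass
class CohortManifest:
    """Validated table mapping subjects to image/mask files and molecular labels."""

    table: pd.DataFrame
    root: Path = field(default_factory=Path)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.table["subject_id"])

    def resolve(self, path: object) -> Optional[Path]:
        if path is None or (isinstance(path, float) and np.isnan(path)) or path == "":
            return None
        p = Path(str(path))
        return p if p.is_absolute() else self.root / p

    def iter_subjects(self) -> Iterator[pd.Series]:
        for _, row in self.table.iterrows():
            yield row


def load_manifest(path: str | Path) -> CohortManifest:
    """Load and validate a cohort manifest CSV.

    Required columns: ``subject_id``, ``image_path``, ``lesion_mask_path``.
    Molecular marker columns (IDH/MGMT/ATRX/LOH1p19q) are normalised to the
    positive/negative/unknown vocabulary; absent markers become ``unknown``.
    Referenced files must exist (relative paths resolve against the manifest's
    directory).
    """
    path = Path(path)
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    if len(table) == 0:
        raise ValueError(f"{path}: manifest contains no subjects")
    required = {"subject_id", "image_path", "lesion_mask_path"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing manifest columns {sorted(missing)}")
    dupes = table["subject_id"][table["subject_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"{path}: duplicate subject_id {sorted(set(dupes))}")

    root = path.parent
    manifest = CohortManifest(table, root)
    for col in _PATH_COLUMNS:
        if col not in table.columns:
            continue
        for subject, value in zip(table["subject_id"], table[col]):
            resolved = manifest.resolve(value)
            if resolved is not None and not resolved.exists():
                raise FileNotFoundError(
                    f"subject {subject}: {col} {resolved} does not exist"
                )
    for marker in MOLECULAR_MARKERS:
        if marker in table.columns:
            table[marker] = [
                _normalise_label(v, marker, s)
                for s, v in zip(table["subject_id"], table[marker])
            ]
        else:
            table[marker] = "unknown"
    return manifest
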