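"""Synthetic single-lesion FET-PET phantoms with analytic compartment volumes.

A lesion is modelled as a spherically symmetric uptake profile, piecewise
linear in the distance from the lesion centre, whose fraction-of-maximum
passes through fixed control points::

    fraction(0)   = 1.00        (peak)
    fraction(r80) = 0.80        -> central compartment boundary
    fraction(r75) = 0.75        -> 75-80% gap band boundary
    fraction(r60) = 0.60        -> peripheral compartment / lesion boundary
    fraction(1.3*r60) = background_suv / suv_max   (then flat background)

The radii are chosen so the three spherical shells have exactly the requested
band volumes, which gives every phantom a closed-form ground truth for the
compartment volumes and the volumetric CU (compartmental-uptake) ratio
v_peripheral / v_central.  Rendering evaluates ``suv_max * fraction(d)`` at
voxel centres, so on a noise-free phantom the image's own relative
isocontours coincide with the analytic spheres.

Cohort sampling draws per-subject CU ratios and central volumes log-normally,
calibrated so the two genotype groups reproduce the reported group medians
(volumetric CU ratio 7.84 vs 3.92; peripheral volume 5.33 vs 2.78 cm^3 at
n = 21 vs 31) and so the population AUC of the two CU distributions is 0.88.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterator, NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .volumes import BinaryMask, SuvVolume, write_mask, write_volume

__all__ = [
    "PhantomSpec",
    "CohortParams",
    "GroundTruth",
    "RadialProfile",
    "VesselSpec",
    "CohortSubject",
    "build_radial_profile",
    "render_phantom",
    "sample_cohort",
    "population_auc",
    "write_cohort",
    "DEFAULT_GRID_SHAPE",
    "DEFAULT_SPACING_MM",
]

#: default grid and PET reconstruction voxel size (mm)
DEFAULT_GRID_SHAPE = (96, 96, 64)
DEFAULT_SPACING_MM = (1.0, 1.0, 2.3)

_MM3_PER_CM3 = 1000.0


class VesselSpec(NamedTuple):
    """A spherical hot blob emulating a large blood vessel."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    suv: float


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one synthetic lesion.

    Volumes are in cm^3, lengths in mm, uptake in SUV units.  ``gap_fraction``
    sets the 75-80% band volume as a fraction of ``v_peripheral``.
    """

    v_central: float = 0.68
    v_peripheral: float = 5.33
    gap_fraction: float = 0.25
    suv_max: float = 3.0
    background_suv: float = 1.0
    noise_sd: float = 0.0
    vessel: Optional[VesselSpec] = None
    center_mm: Optional[tuple[float, float, float]] = None
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v_central <= 0 or self.v_peripheral <= 0:
            raise ValueError("band volumes must be positive")
        if not 0 < self.gap_fraction < 1:
            raise ValueError("gap_fraction must lie in (0, 1)")
        if self.background_suv < 0:
            raise ValueError("background_suv must be non-negative")
        if 0.6 * self.suv_max <= self.background_suv:
            raise ValueError(
                "0.6*suv_max must exceed background_suv so the 60% isocontour "
                f"excludes background (suv_max={self.suv_max}, "
                f"background={self.background_suv})"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be 3 positive reals")

    @property
    def resolved_center_mm(self) -> np.ndarray:
        """Lesion centre; defaults to the centre voxel's centre (on-lattice)."""
        if self.center_mm is not None:
            return np.asarray(self.center_mm, dtype=float)
        return (np.asarray(self.grid_shape) // 2) * np.asarray(self.spacing_mm)


@dataclass(frozen=True)
class GroundTruth:
    """Analytic compartment geometry of a phantom (radii mm, volumes cm^3)."""

    r80: float
    r75: float
    r60: float
    v_central: float
    v_gap: float
    v_peripheral: float
    v_mtv60: float
    volumetric_cu_true: float
    suv_cu_true: float


@dataclass(frozen=True)
class RadialProfile:
    """Piecewise-linear fraction-of-maximum uptake as a function of radius."""

    r80: float
    r75: float
    r60: float
    background_fraction: float

    @property
    def knots(self) -> tuple[np.ndarray, np.ndarray]:
        xs = np.array([0.0, self.r80, self.r75, self.r60, 1.3 * self.r60])
        ys = np.array([1.0, 0.80, 0.75, 0.60, self.background_fraction])
        return xs, ys

    def __call__(self, r: np.ndarray | float) -> np.ndarray:
        xs, ys = self.knots
        return np.interp(r, xs, ys)


def _sphere_radius(volume_mm3: float) -> float:
    return (3.0 * volume_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)


def build_radial_profile(spec: PhantomSpec) -> tuple[GroundTruth, RadialProfile]:
    """Solve the isocontour radii from the requested band volumes.

    The central compartment is the ball of radius r80, the gap band the shell
    (r80, r75], the peripheral compartment the shell (r75, r60]; each shell
    volume equals the corresponding spec volume exactly.
    """
    v_gap = spec.gap_fraction * spec.v_peripheral
    r80 = _sphere_radius(spec.v_central * _MM3_PER_CM3)
    r75 = (r80**3 + 3.0 * v_gap * _MM3_PER_CM3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    r60 = (r75**3 + 3.0 * spec.v_peripheral * _MM3_PER_CM3 / (4.0 * math.pi)) ** (
        1.0 / 3.0
    )
    center = spec.resolved_center_mm
    extent = np.asarray(spec.grid_shape) * np.asarray(spec.spacing_mm)
    margin = min(float(np.min(center)), float(np.min(extent - center)))
    if 1.3 * r60 > margin:
        raise ValueError(
            f"lesion support 1.3*r60 = {1.3 * r60:.1f} mm exceeds the distance "
            f"{margin:.1f} mm from the lesion centre to the grid boundary"
        )
    profile = RadialProfile(r80, r75, r60, spec.background_suv / spec.suv_max)

    def shell_mean(lo: float, hi: float) -> float:
        # profile is piecewise linear, so f(r)*r^2 is piecewise cubic and
        # Simpson's rule on each linear segment integrates it exactly
        knots = profile.knots[0]
        cuts = np.unique(np.concatenate([[lo, hi], knots[(knots > lo) & (knots < hi)]]))
        num = 0.0
        for a, b in zip(cuts[:-1], cuts[1:]):
            m = 0.5 * (a + b)
            num += (b - a) / 6.0 * (
                profile(a) * a**2 + 4.0 * profile(m) * m**2 + profile(b) * b**2
            )
        den = (hi**3 - lo**3) / 3.0
        return num / den

    suv_cu_true = shell_mean(r75, r60) / shell_mean(0.0, r80)
    truth = GroundTruth(
        r80=r80,
        r75=r75,
        r60=r60,
        v_central=spec.v_central,
        v_gap=v_gap,
        v_peripheral=spec.v_peripheral,
        v_mtv60=spec.v_central + v_gap + spec.v_peripheral,
        volumetric_cu_true=spec.v_peripheral / spec.v_central,
        suv_cu_true=suv_cu_true,
    )
    return truth, profile


def _default_affine(spec: PhantomSpec) -> np.ndarray:
    affine = np.diag([*spec.spacing_mm, 1.0]).astype(float)
    return affine


def _distance_grid(spec: PhantomSpec) -> np.ndarray:
    center = spec.resolved_center_mm
    axes = [
        np.arange(n, dtype=float) * s - c
        for n, s, c in zip(spec.grid_shape, spec.spacing_mm, center)
    ]
    return np.sqrt(
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )


def render_phantom(spec: PhantomSpec) -> tuple[SuvVolume, BinaryMask, GroundTruth]:
    """Render a phantom to a voxel grid (RAS, affine = diag(spacing)).

    Returns the SUV volume, the true lesion mask (voxel centres within r60)
    and the analytic ground truth.  Noise and vessel blobs are applied after
    the radial profile; the same seed always yields a bit-identical volume.
    """
    truth, profile = build_radial_profile(spec)
    center = spec.resolved_center_mm
    lo = center - 1.3 * truth.r60
    hi = center + 1.3 * truth.r60
    extent = np.asarray(spec.grid_shape) * np.asarray(spec.spacing_mm)
    if np.any(lo < -1e-9) or np.any(hi > extent + 1e-9):
        axis = int(np.argmax(np.maximum(-lo, hi - extent)))
        raise ValueError(
            f"lesion clipped by grid boundary along axis {axis}: "
            f"needs radius 1.3*r60 = {1.3 * truth.r60:.1f} mm around "
            f"centre {np.round(center, 1)} mm"
        )
    d = _distance_grid(spec)
    values = spec.suv_max * profile(d)
    if spec.vessel is not None:
        vc = np.asarray(spec.vessel.center_mm, dtype=float)
        axes = [
            np.arange(n, dtype=float) * s - c
            for n, s, c in zip(spec.grid_shape, spec.spacing_mm, vc)
        ]
        dv = np.sqrt(
            axes[0][:, None, None] ** 2
            + axes[1][None, :, None] ** 2
            + axes[2][None, None, :] ** 2
        )
        values = values + np.where(dv <= spec.vessel.radius_mm, spec.vessel.suv, 0.0)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
        np.clip(values, 0.0, None, out=values)
    affine = _default_affine(spec)
    volume = SuvVolume(values, affine)
    lesion = BinaryMask((d <= truth.r60).astype(np.uint8), affine, "lesion")
    return volume, lesion, truth


@dataclass(frozen=True)
class CohortParams:
    """Two-genotype cohort calibration.

    Defaults reproduce the reported clinical summaries: group sizes 21
    (IDH-mutant) vs 31 (wild-type), volumetric CU ratio medians 7.84 vs 3.92,
    peripheral-compartment volume medians 5.33 vs 2.78 cm^3, and a common
    log-SD chosen so the population AUC of the two log-normal CU distributions
    is 0.88 (sigma = ln2 / (sqrt(2) * Phi^-1(0.88)) ~ 0.4171).
    """

    n_mut: int = 21
    n_wt: int = 31
    log_median_cu_mut: float = math.log(7.84)
    log_median_cu_wt: float = math.log(3.92)
    sigma_log_cu: float = math.log(7.84 / 3.92) / (math.sqrt(2.0) * 1.1749867920660904)
    median_vc_mut: float = 5.33 / 7.84
    median_vc_wt: float = 2.78 / 3.92
    sigma_log_vc: float = 0.5
    suvmax_range: tuple[float, float] = (2.0, 4.0)
    background_suv: float = 1.0
    gap_fraction: float = 0.25
    noise_sd: float = 0.0
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mut < 2 or self.n_wt < 2:
            raise ValueError("group sizes must be at least 2")
        if self.sigma_log_cu <= 0 or self.sigma_log_vc <= 0:
            raise ValueError("log-SDs must be positive")
        if self.median_vc_mut <= 0 or self.median_vc_wt <= 0:
            raise ValueError("median central volumes must be positive")
        if not self.suvmax_range[0] < self.suvmax_range[1]:
            raise ValueError("suvmax_range must be an increasing interval")
        if self.suvmax_range[0] * 0.6 <= 1.0:
            raise ValueError(
                "suvmax_range lower bound (in multiples of background) must "
                "exceed 1/0.6 so every 60% isocontour clears background"
            )


class CohortSubject(NamedTuple):
    subject_id: str
    genotype: str  # "mutant" or "wildtype"
    spec: PhantomSpec
    truth: GroundTruth


def population_auc(params: CohortParams) -> float:
    """Closed-form AUC of the two log-normal CU distributions.

    For equal-variance log-normals the probability that a mutant draw exceeds
    a wild-type draw is Phi(delta_logmedian / (sqrt(2)*sigma)).
    """
    delta = params.log_median_cu_mut - params.log_median_cu_wt
    return float(stats.norm.cdf(delta / (math.sqrt(2.0) * params.sigma_log_cu)))


_MAX_REDRAWS = 200


def sample_cohort(params: CohortParams) -> list[CohortSubject]:
    """Draw a calibrated two-genotype cohort of phantom specs.

    Per subject the true volumetric CU ratio and the central volume are drawn
    log-normally with the group's log-median; the peripheral volume is their
    product, so group medians of CU and peripheral volume both match the
    calibration targets.  All draws come from a single seeded stream; specs
    violating phantom invariants (e.g. a lesion too large for the grid) are
    redrawn a bounded number of times.
    """
    rng = np.random.default_rng(params.seed)
    subjects: list[CohortSubject] = []
    # lesions sit in one hemisphere (as real gliomas do) so the mirrored
    # contralateral background region lands in lesion-free tissue: the centre
    # goes on the voxel-centre lattice at ~28% of the left-right extent, with
    # the other two coordinates at the grid-centre voxel.
    shape = np.asarray(params.grid_shape)
    spacing = np.asarray(params.spacing_mm)
    center_idx = shape // 2
    center_idx[0] = int(round(0.28 * shape[0]))
    center_mm = center_idx * spacing
    mid_lr = 0.5 * (shape[0] - 1) * spacing[0]
    lateral_offset = abs(mid_lr - center_mm[0])
    groups = [
        ("mutant", params.n_mut, params.log_median_cu_mut, params.median_vc_mut),
        ("wildtype", params.n_wt, params.log_median_cu_wt, params.median_vc_wt),
    ]
    idx = 0
    for genotype, n, log_med_cu, med_vc in groups:
        for _ in range(n):
            idx += 1
            spec = None
            for _attempt in range(_MAX_REDRAWS):
                cu = math.exp(log_med_cu + params.sigma_log_cu * rng.standard_normal())
                vc = math.exp(
                    math.log(med_vc) + params.sigma_log_vc * rng.standard_normal()
                )
                vp = cu * vc
                suv_max = params.background_suv * rng.uniform(*params.suvmax_range)
                try:
                    candidate = PhantomSpec(
                        v_central=vc,
                        v_peripheral=vp,
                        gap_fraction=params.gap_fraction,
                        suv_max=suv_max,
                        background_suv=params.background_suv,
                        noise_sd=params.noise_sd,
                        center_mm=tuple(center_mm),
                        grid_shape=params.grid_shape,
                        spacing_mm=params.spacing_mm,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                    truth_check, _ = build_radial_profile(candidate)
                    # mirrored background needs the lesion inside one hemisphere
                    if truth_check.r60 > lateral_offset:
                        continue
                except ValueError:
                    continue
                spec = candidate
                break
            if spec is None:
                raise RuntimeError(
                    f"could not draw a valid phantom spec after {_MAX_REDRAWS} tries"
                )
            truth, _ = build_radial_profile(spec)
            subjects.append(CohortSubject(f"sub-{idx:03d}", genotype, spec, truth))
    return subjects


def write_cohort(
    cohort: Sequence[CohortSubject], out_dir: str | Path
) -> Path:
    """Render every subject to NIfTI and write the manifest CSV.

    Returns the manifest path.  Manifest columns include the file paths, the
    IDH label (mutant -> positive) and the analytic ground truth per subject.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    rows = []
    for subject in cohort:
        volume, lesion, truth = render_phantom(subject.spec)
        image_name = f"{subject.subject_id}_suv.nii.gz"
        mask_name = f"{subject.subject_id}_lesion.nii.gz"
        try:
            write_volume(volume, out_dir / image_name)
            write_mask(lesion, out_dir / mask_name)
        except OSError as exc:  # pragma: no cover - depends on filesystem
            raise OSError(f"failed writing {subject.subject_id} to {out_dir}: {exc}")
        rows.append(
            {
                "subject_id": subject.subject_id,
                "image_path": image_name,
                "lesion_mask_path": mask_name,
                "IDH": "positive" if subject.genotype == "mutant" else "negative",
                "genotype": subject.genotype,
                "true_cu_volumetric": truth.volumetric_cu_true,
                "true_v_central_cm3": truth.v_central,
                "true_v_peripheral_cm3": truth.v_peripheral,
                "true_suv_cu": truth.suv_cu_true,
                "suv_max": subject.spec.suv_max,
                "seed": subject.spec.seed,
            }
        )
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return manifest_path
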