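# Methods

## The compartmental-uptake model

A glioma's FET uptake is summarised by splitting the lesion into relative
isocontour bands of its maximum SUV: a total volume MTV₆₀ (60–100% of
SUVmax), a peripheral compartment ROI₆₀ (60–75%) and a central compartment
ROI₈₀ (80–100%). The 75–80% band belongs to MTV₆₀ but to neither named
compartment. Band bounds are inclusive on both ends, so a voxel at exactly
0.75·SUVmax is peripheral and one at exactly 0.80·SUVmax is central — the
closed percentage ranges name their own endpoints. The compartmental-uptake
(CU) ratio is peripheral over central, either as a ratio of volumes
(volumetric CU) or of mean SUVs (SUV CU). Because every threshold is
relative to SUVmax, both CU ratios and all compartment masks are invariant
under any global positive rescaling of the image; the absolute-threshold
MTV (SUV ≥ k·background mean, default k = 1.8) is not, unless the background
rescales identically.

The reference maximum is the single hottest voxel of the target lesion,
taken after vessel exclusion (a flag restores the pre-exclusion reading). A
robust-peak option that pre-averages each voxel with its 26-neighbourhood is
available for noisy data and off by default. In multifocal masks the target
lesion is the largest 26-connected component; ties break by higher contained
SUVmax, then by lowest linear index, so the choice is deterministic. The
isocontour search region is the target mask dilated by 2 voxels
(configurable): the isocontours are PET-defined and should not be clipped by
the exact tightness of an anatomical mask.

The contralateral background is a 2-D region on the axial slice whose MTV₆₀
voxels have the highest mean uptake: the tumor's in-slice mask is mirrored
across the left-right mid-plane (axis identified from the NIfTI orientation
codes, overridable) and, if the mirror touches the tumor or leaves the grid,
shifted along that axis to the nearest valid position — increasing shift
magnitude, trying the direction away from the tumor first. "Similar size" is
implemented as exact equality of in-plane area, which the mirror preserves.
An empty central compartment is a hard error rather than a NaN, because
every downstream biomarker divides by its statistics; an empty peripheral
compartment is a warning at segmentation time and an error when a CU ratio
is requested.

## The synthetic phantom

Each phantom lesion is spherically symmetric with a piecewise-linear
fraction-of-maximum profile through (0, 1.00), (r₈₀, 0.80), (r₇₅, 0.75),
(r₆₀, 0.60), decaying linearly to the background fraction at 1.3·r₆₀ and
flat beyond. The radii are solved from the requested band volumes
(v_central, the 75–80% gap band as `gap_fraction · v_peripheral`, and
v_peripheral), so the ground-truth volumetric CU ratio
v_peripheral/v_central is exact by construction. Voxels take the value
`suv_max · profile(distance to centre)`, evaluated at voxel centres with no
anti-aliasing; this makes the image's own relative isocontours coincide with
the analytic spheres, the far field equal the background SUV, and the
condition 0.6·suv_max > background guarantee that the 60% contour clears
the background. Optional additive Gaussian noise (seeded, bit-reproducible)
and an additive spherical "vessel" blob complete the model. The SUV CU ratio
implied by the default profile is ≈ 0.78, which sits in the range clinically
observed for FET-avid gliomas — a property of the profile shape, not a
calibrated quantity.

Deliberate simplifications: no brain anatomy, no scanner point-spread
function or partial-volume blur, single-lesion only, homogeneous background.
Passing tests therefore demonstrate the correctness of the segmentation and
statistics pipeline and the self-consistency of the calibration — not
robustness to anatomical heterogeneity, PSF-driven spill-over, or
mis-registration, which real data would add.

## Cohort calibration

The two-genotype cohort draws, per subject, the true volumetric CU ratio
log-normally around the group's median and the central volume log-normally
around its group median; the peripheral volume is their product. Defaults:

| parameter | value | rationale |
|---|---|---|
| n (mutant / wild-type) | 21 / 31 | study group sizes |
| CU medians | 7.84 / 3.92 | reported group medians |
| σ(log CU), shared | 0.41714 | `ln(7.84/3.92)/(√2·Φ⁻¹(0.88))`, so the population AUC of the two log-normal CU distributions is exactly the reported cohort AUC 0.88 (the reported IQRs imply a slightly different overlap; the AUC is the headline claim, so it anchors the calibration) |
| central-volume medians (cm³) | 5.33/7.84 ≈ 0.680 and 2.78/3.92 ≈ 0.709 | median(v_peripheral) = median(CU)·median(v_central) for independent log-normals, reproducing the reported peripheral-volume medians 5.33 / 2.78 cm³ |
| σ(log v_central) | 0.5 | free spread parameter; affects volume dispersion only, not medians |
| gap_fraction | 0.25 | the 75–80% band's size is unreported; configurable |
| suv_max | Uniform(2, 4) × background 1.0 | consistent with the TBR scale of FET gliomas (cutoffs near 2.7) |
| noise_sd | 0 | calibrated cohorts are rendered noise-free; noise is available per phantom |
| grid / spacing | 96×96×64 at 1.0×1.0×2.3 mm | the PET reconstruction voxel size |

Lesion centres sit on the voxel-centre lattice at ≈28% of the left-right
extent (other axes centred). Two reasons: a lateralised lesion leaves the
contralateral hemisphere free for the mirrored background region, as in real
anatomy; and an on-lattice centre makes the rendered maximum equal
`suv_max` exactly on noise-free phantoms. The latter matters: with an
off-lattice centre the hottest voxel under-reads the true peak by up to
`slope × half voxel diagonal`, all relative thresholds shift down with it,
and the central compartment inflates by ~25% at median lesion sizes —
a genuine partial-volume-like effect, but one that would have to be modelled,
not accidentally included. Draws whose lesion would clip the grid or cross
the mid-plane (< 0.5% of subjects at the default calibration) are redrawn
from the same stream, slightly truncating the upper volume tail.

Voxelization is the remaining measurement error: counting voxel centres
inside a sphere of radius r mis-estimates its volume by a surface term of
order (spacing/r), largest along the 2.3 mm axis. At the default calibration
this leaves the measured volumetric CU ratio within a few percent of truth
for median lesions (r₈₀ ≈ 5.5 mm) and worse for the smallest central
compartments — the recovery tests therefore track group medians over 20
seeded cohorts (1040 rendered lesions), not individual subjects, and the
study report records the measured-over-true CU ratio explicitly.

## Statistics

The AUC is the Mann–Whitney estimator with ties counted ½; its variance
comes from the DeLong placement values (sample variances of the per-positive
and per-negative placements), and the 95% CI is Wald on the AUC scale,
clipped to [0, 1] — the CI dialect is documented rather than matched to any
particular commercial implementation. Score direction is auto-detected so
AUC ≥ 0.5 and recorded (`greater`: score ≥ threshold ⇒ positive; `less`:
≤). Paired AUCs on the same subjects are compared with the DeLong
covariance of the placement vectors and a two-sided normal test.

Youden cutpoints scan midpoints between consecutive sorted unique scores
plus ±∞, maximise sensitivity + specificity − 1 under the stated direction,
and break ties toward the smallest threshold; the reported accuracy is
prevalence-dependent by design. Exact small-sample p-values (full
enumeration for the Mann–Whitney at n ≤ 12 without ties, all 2ⁿ sign
patterns for the signed-rank at n ≤ 12 — which also handles tied
|differences| — and all n! pairings for Spearman at n ≤ 8) switch to the
usual tie- and continuity-corrected normal/t approximations beyond those
sizes, chosen so every exact path stays desk-scale. One-tailed signed-rank
tests take the tail in the direction of the observed rank sum. Dunn post hoc
z-tests use pooled mid-ranks with tie correction and Holm–Šídák adjustment
(step-down `1 − (1−p)^(m−i)` with a running maximum). Logistic "predictive
accuracy" classifies at predicted probability 0.5 (the natural reading of a
0.5 cutoff for a fitted binary model); complete separation is detected
before fitting and flagged, with the separating rule's accuracy returned.

The genotyping experiment splits the labelled cohort stratified-randomly
into halves (exact per-class training counts are configurable, e.g. the
16/10 vs 15/11 split sizes of the reference study), fits the Youden
threshold on the training side only, and reports sensitivity, specificity
and accuracy of that frozen threshold on the held-out side, plus DeLong AUCs
for both sides and the whole cohort. Degenerate splits (a side missing a
class) are reshuffled with an incremented sub-seed, a bounded number of
times. Reference clinical thresholds (5.49 whole-cohort, 5.43 training, TBR
2.73) ship as named constants for annotation only and never drive decisions.
Quantiles everywhere are linear-interpolation (type 7); IQR is Q3 − Q1.

## Numerical and design choices

- Geometry: images and masks must agree in shape, orientation codes and
  spacing to 1e-4 relative; nothing is resampled, mismatches are errors.
  Masks are strict {0, 1} — a 0.5 voxel is rejected, not thresholded.
  Volumes are voxel count × voxel volume (from the affine determinant),
  reported in cm³ at full precision; rounding is a presentation concern.
- Band integrals of the radial profile (for the ground-truth SUV CU ratio)
  use Simpson's rule per linear segment, which is exact for the cubic
  integrand `linear(r)·r²`.
- Problem sizes in the validation suite — 20 seeded cohorts for the
  calibration recovery, 10 000 null simulations for the type-I check, 2 000
  bootstrap replicates against the DeLong SE, 100-instance brute-force
  oracle sweeps — were chosen to keep each check's Monte-Carlo error well
  inside its assertion band at desk scale.
- The cohort generator exposes every calibration constant; changing them
  changes the simulated "study", so the defaults are treated as fixed study
  conditions, not tuning knobs.

## Known limitations

- The phantom's monotone radial profile cannot produce disconnected or
  non-nested compartments (ring-enhancing or necrotic morphologies); the
  segmentation handles such images, but the generator never produces them.
- The absolute-threshold MTV depends on the mirrored-background mean, which
  on phantoms includes part of the contralateral profile tail; TBR inherits
  the same mild (<2%) background inflation.
- The SUV CU medians of the two genotype groups are not separately
  calibrated — the profile shape fixes them near 0.78 for every lesion, so
  group differences in SUV CU are much smaller than in the volumetric CU,
  qualitatively (not quantitatively) matching clinical behaviour.
- Kendall-style concordance statistics for matched pairs are not provided;
  matched comparisons report the standard signed-rank W.
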