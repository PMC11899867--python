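# Methods

## Depth slabs and ROIs

A volume is a (depth, rows, cols) grid with axial spacing in µm and
lateral spacing defaulting to 3000/304 ≈ 9.868 µm/px (a 3 × 3 mm field
sampled at 304 × 304 A-scans). The two analysis slabs are half-open
intervals in physical depth — superficial [0, 200) µm, deep
[200, 1000) µm — mapped to voxel indices by `floor(z / axial_spacing)`,
so the slabs partition the depth samples with no double-counted row.
The default en-face operator is the maximum-intensity projection, the
convention for OCTA flow signal; mean projection is available by flag and
is the operator the projection oracle tests exercise (it commutes with
affine intensity rescaling, which maximum does not for negative scale).

Quadrant ROIs split the frame at the middle column. Laterality decides
orientation: for a right eye (OD) in the standard en-face view the nasal
conjunctiva is taken on the right image side (configurable); OS mirrors
it. A limbus boundary, supplied as an (x, y) polyline, removes pixels on
the corneal side — the side facing away from the selected quadrant — by
per-row linear interpolation of the boundary column. There is no
automatic limbus detection; the geometry is always supplied.

## Enhancement and segmentation

Enhancement is CLAHE followed by a median filter. The CLAHE clip limit is
expressed as a multiple of the uniform histogram bin height (default 2.0,
the classic convention) and converted to scikit-image's fractional
`clip_limit` by dividing by the 256-bin count; the tile grid defaults to
8 × 8 and the median kernel to 3 px — conventional values for 304 × 304
OCTA frames, all exposed in `EnhanceParams` so sensitivity can be
studied. Output intensities are clipped back to the input bit-depth
range. Setting `clahe_clip=None` and `median_kernel=1` gives the exact
identity, which the tests rely on.

Otsu's threshold is computed from a 256-bin histogram of ROI pixels only:
background sclera or eyelid outside the ROI would bias a whole-frame
histogram. Because bin centres are affine in the bin index, the
between-class variance `w0·w1·(µ0−µ1)²` for a split after bin `k` is
proportional to `(m0·w1 − m1·w0)² / (w0·w1)` with integer class counts
`w` and integer index moments `m`; the implementation maximizes this with
exact integer arithmetic and takes the first maximum on ties. Ties are
real, not hypothetical: valley bins between two intensity modes are often
empty, giving exactly equal objective values, and floating-point
cumulative sums would resolve them arbitrarily. Binarization is strict
(`intensity > threshold`) and restricted to the ROI. Whether the raw or
the enhanced image is thresholded is a flag (default: enhanced, the order
of the processing chain). An externally edited ROI mask can replace the
constructed quadrant at any point, since every operation takes the ROI as
an argument.

## Vascular indices

The skeleton is the morphological thinning of the vessel mask
(scikit-image `skeletonize`), and its length is the connectivity-weighted
pair sum: 1 per 4-adjacent pair, √2 per diagonal pair. This is the
standard skeletonized-density construction for OCTA; in pixel units it
puts VLD near 0.17 px⁻¹ and VDI near 2 px at VD ≈ 0.34, the magnitudes
typical for conjunctival AS-OCTA, which is why the package reports pixel
units by default (µm conversions follow from `lateral_spacing`).

VD, VLD and VDI share numerators and denominators, so `VDI·VLD = VD`
holds to machine rounding; `compute_metrics` computes the three from
shared intermediates. Undefined values (VDI with a zero-length skeleton,
FD on an empty mask) are NaN sentinels with a warning, never silent
zeros, so degenerate frames can be excluded rather than imputed
downstream.

Box counting uses a grid anchored at the top-left of the ROI bounding
box, sizes defaulting to the dyadic sequence 2, 4, 8, … up to a quarter
of the smaller ROI span, and no grid-offset averaging — the simplest
defensible variant; FD is the negative OLS slope of log N on log e and
needs at least three sizes. FD is computed on the vessel mask, not the
skeleton (flag available); both choices are common and differ by a few
hundredths. One practical caveat encoded in the fixtures: box counts of a
short line saturate at box sizes comparable to the line length and bias
the slope low, so the analytic line fixture spans the full frame.

## Cohort statistics

Group comparisons fit a Gaussian identity-link GEE of a metric on group +
age + gender, clustered on subject (both eyes of one participant are one
cluster), with an exchangeable working correlation — the natural
structure for two fellow eyes — and robust sandwich covariance
(independence is available by flag; the sandwich keeps either choice
consistent). Confidence intervals use the normal multiplier 1.96, per GEE
asymptotics, not a t quantile. Missing metric rows are dropped, never
imputed. The Šidák correction `p_adj = 1 − (1 − p)^m` is applied per
metric with family size defaulting to the number of region × layer cells
tested (4); it is computed as `-expm1(m·log1p(−p))` to survive tiny p.
Activity is active iff CAS ≥ 3; the active-vs-inactive comparison reuses
the same GEE with the activity label as the contrast, restricted to
diseased eyes, and CAS-association slopes come from the same clustered
machinery with CAS as a continuous regressor. Categorical covariates are
dummy-coded against the alphabetically first level; a constant term
raises an error naming it.

Descriptive summaries report subject- and eye-level female percentages
separately (they differ whenever eye counts are unbalanced), sample SD
(ddof = 1, NaN for a single subject), a chi-square test for gender and a
t-test for age.

## Synthetic data

The image generator lays vessels in horizontal lanes: each centerline is
a curvature-bounded random walk (heading increments ~N(0, tortuosity),
mean-reverting) whose vertical wander reflects off its lane boundary, so
vessels never touch. This mirrors the near-parallel course of
conjunctival vessels within a single quadrant and — more importantly for
testing — keeps the ground-truth centerline length well defined at
study-like densities, where freely crossing networks fuse into blobs
whose "true" skeleton is ambiguous. Centerlines are stamped with disks of
per-vessel sampled caliber, the stamped mask gets one binary median pass
to remove rasterization bumps (that smoothed mask is the ground truth),
and the frame is rendered as vessel level 180 over background 40 with
Gaussian noise (SD 8 by default). `target_vd` derives the lane count from
the requested area fraction with a 7% rasterization-yield correction.
Defaults (47 vessels of 2.2 ± 0.3 px on 304 × 304) give VD ≈ 0.35,
VLD ≈ 0.13 px⁻¹, VDI ≈ 2.7 px, FD ≈ 1.77.

What the generator does not emulate: OCTA speckle and decorrelation
noise, motion and projection artifacts, branching topology, caliber
tapering, and crossing vessels. Passing end-to-end tests therefore shows
the processing chain is faithful to its own ground truth, not that it is
robust to device physics.

The volume generator places one independent network per depth slab,
constant through the slab's depth samples, so either projection mode
recovers it; overlapping slab specifications are rejected.

The cohort generator is decoupled from imaging: each subject gets group,
age ~ N(46.2, 10.8²) for cases vs N(32.7, 6.6²) for controls, gender
(female probability 0.41 / 0.38), and for cases a CAS drawn uniformly
from 0–6 (≈ 57% active under the CAS ≥ 3 rule, matching the ≈ 55%
active-eye share such cohorts show). Metric values per
group × region × layer cell are Gaussian with configurable means/SDs
(defaults at published AS-OCTA magnitudes, e.g. temporal-deep VD
0.344 ± 0.09 vs 0.296 ± 0.05), decomposed as
`mean + sd·(√ρ·z_subject + √(1−ρ)·z_eye)` so fellow eyes correlate at
`ρ` (default 0.5). `null_cohort_params` equalizes the groups (shared
means, ages, gender) and optionally injects a single-cell mean shift —
the configuration used for type-I error, coverage and slope-recovery
calibration.

## Verification problem sizes

The Monte-Carlo calibrations run 200 replicates at the study sample size
(29 + 21 subjects × 2 eyes): type-I error of the group test on null
cohorts (accepted range [0.02, 0.09] at α = 0.05), 95% CI coverage of an
injected 0.085 temporal-deep VD effect (≥ 90%), and ±2 SE recovery of a
−0.013 per-CAS-unit slope (≥ 90%). Oracle equivalences use exhaustive
search (Otsu over all 256 candidate splits in exact rational arithmetic),
double-loop grid scans (box counts) and per-pixel loops (slab means) on
small seeded inputs. End-to-end fidelity uses noise-free frames at
default density: segmentation Dice ≥ 0.9 and VD/VLD within 5% of the
ground-truth-mask values; observed values are ≈ 0.99 Dice and ≤ 3%
error, with the residual coming from the enhancement median interacting
with vessel boundaries.

## Known limitations

- The lane layout cannot produce crossing or branching vessels; FD tops
  out around 1.8 rather than the ~1.85 typical of real conjunctival
  networks.
- CLAHE's clip-limit mapping follows scikit-image's normalization; other
  implementations scale the limit differently, so thresholds are
  comparable only within this package.
- GEE robust errors are asymptotic; at very small cluster counts
  (< ~10 subjects per group) coverage degrades and no small-sample
  correction is applied.
- Box-count FD depends mildly (±0.01–0.05) on grid anchoring and
  mask-vs-skeleton choice; comparisons should hold these fixed.
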