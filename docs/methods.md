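# Methods

## Problem and pipeline overview

The mammillary bodies (MBs) are paired hypothalamic nuclei of roughly
20–80 mm³ each, depending on age. `mamvol` measures their left and
right volumes from a T1-weighted 3D MR volume by multi-atlas
segmentation and places the result on normative growth curves. The
pipeline runs in the order: isotropic resampling → linear registration
of each atlas to the subject → deformable refinement → nearest-neighbor
label propagation → strict majority-vote fusion → volumetry →
statistical modeling.

All geometry is RAS world millimetres; voxel indices are 0-based and a
voxel's world position is its center. Resampled grids are anchored at
the original first-voxel center, so repeated resampling is
reproducible. Out-of-field samples take the image's background
intensity (the median of its corner voxels) for intensities and 0 for
labels.

## Isotropic resampling

Every volume is resampled to a 0.5 × 0.5 × 0.5 mm grid before any
volumetric step. The interpolation kernel is trilinear for intensities
and nearest-neighbor for labels; trilinear is exact on affine intensity
ramps, and nearest keeps the label value set intact. At 0.5 mm one
voxel is 0.125 mm³, so a ~24 mm³ MB spans ~190 voxels — enough for
stable counting statistics.

## Linear registration

The linear stage estimates 9 parameters (3 rotations, 3 anisotropic
scales, 3 translations; rotation/scale about the fixed image's world
center so they decouple from the translation). The similarity measure
is the sum of squared differences between *local-phase features*: each
image is band-pass filtered along each axis with a one-sided log-Gabor
transfer function (default wavelength 8 voxels, bandwidth parameter
σ = 0.65), giving a complex quadrature response `q` per axis, which is
normalized as `q / (|q| + 0.05·mean|q|)`. Phase is unchanged by
`a·I + b` intensity transforms, so the registration is invariant to
global intensity rescaling and offset — a property the test suite
asserts for gains in [0.5, 2].

Translation is initialized by phase correlation (sub-voxel via a
parabolic fit around the correlation peak). The 9 parameters are then
refined by trust-region Gauss–Newton (`scipy.optimize.least_squares`)
on the feature residuals, coarse-to-fine over a 3-level pyramid
(4 → 2 → 1 mm by default). Evaluation is restricted to the 12 000
highest-energy feature voxels per level to bound cost. On 64³ phantoms
this recovers known translations to ~1e-4 mm and isotropic scales to
~0.5 %, well inside the package's acceptance bounds (0.25 mm, 1 %).

Flat images and non-overlapping fields of view raise explicit errors;
a silent identity is never returned.

## Deformable registration

The deformable stage minimizes the variational energy

    E(u) = Σ_x (F(x) − M(x + u(x)))² + α Σ_x ‖∇u(x)‖²

by explicit gradient descent — force term
`(F − M∘φ)·∇(M∘φ) + α·Δu` — with a backtracking line search (the step
is halved on any energy increase, up to 12 times) over a
multiresolution pyramid. Backtracking makes the recorded per-level
energy history non-increasing *by construction*, which the tests
assert. Images are normalized to zero mean / unit SD before the energy
is computed, making α (default 0.1) a unitless data/smoothness
trade-off. The update step is parameterized in voxels of the current
level (default 0.25) and adapts upward (×1.3) after accepted steps.

Two numerical details matter:

* The moving image is sampled with *edge-clamped* interpolation inside
  the energy. A constant out-of-field fill makes the energy
  discontinuous in `u` wherever the grid ends in tissue (any ε
  displacement at the last voxel blends toward the fill value), which
  stalls the line search at zero displacement. Edge clamping keeps the
  energy continuous.
* Displacement fields are resampled between pyramid levels with the
  same origin-anchored convention as images, interpolating the mm
  offsets directly.

In the segmentation pipeline the deformable stage is not run globally:
after linear alignment, a region of interest around the
linearly-propagated MB labels (dilated by 8 mm) is cropped and refined
at the full 0.5 mm resolution, seeded with a locally estimated
translation (phase correlation of the crop). The MBs occupy a few
hundred voxels, so full-resolution refinement is affordable exactly
where it matters; the global registration problem would cost ~50× more
at 0.5 mm for no benefit to the MB labels. The resulting field is
embedded in a zero field on the subject grid; the discontinuity at the
crop edge never touches propagated voxels because atlas labels exist
only inside the crop.

## Label propagation and fusion

Atlas labels are carried onto the subject grid by nearest-neighbor
sampling through the composed mapping `x ↦ A(x + u(x))` (deformable
correction, then the linear transform into atlas space). Labels are
propagated from their native atlas grid: resampling them to 0.5 mm
first was evaluated and rejected, because order-0 resampling shifts
label boundaries by ~¼ source voxel relative to the trilinearly
resampled intensities and measurably degrades fused accuracy.

Fusion is a per-voxel *strict* majority vote: a label must win more
than half of the usable propagated maps, otherwise the voxel is
background (e.g. votes 1-1-2-2-0 → background). Strict majority is
conservative and fully specified for three-label votes; the test suite
checks it against exhaustive enumeration of all 3⁵ five-atlas vote
patterns. Atlases whose registration fails are excluded and shrink the
vote denominator, recorded in the result's QC flags; fewer than three
usable atlases is a hard failure. QC also flags empty or
non-6-connected fused labels.

Volumes are label count × voxel volume, exactly. ICV is the volume of
a supplied binary brain mask in cm³; the mask's provenance is the
caller's responsibility.

## Synthetic data

**Phantoms.** A 64³ × 1.0 mm grid holds an ellipsoidal head (semiaxes
24 × 28 × 22 mm) with a few internal structures for registration
contrast (paired ventricle-like cavities, a brainstem-like blob) and
two MB ellipsoids with semiaxes 2.5 × 1.5 × 1.5 mm (analytic volume
4/3·π·2.5·1.5² ≈ 23.56 mm³) placed ±3 mm off the midline; label 1 is
the anatomical left (negative R side). The default size keeps
end-to-end tests around half a minute per subject while the 0.5 mm
analysis grid still resolves the MBs. Tissue intensities are arbitrary
units loosely mimicking T1 contrast; Gaussian noise (default SD 2, ~2 %
of tissue intensity) and a smooth multiplicative bias field (default
±5 %) are added. No MR physics is simulated — no k-space, no partial
volume beyond rasterization, no cortical anatomy — so passing tests
demonstrate correctness of the geometry/statistics machinery, not
performance on clinical scans.

**Population variation.** Atlas sets and subjects are the base phantom
warped by a random similarity jitter (default ±3°, ±3 % scale,
±1.5 mm) composed with a smooth random displacement field (Gaussian
correlation length 8 mm, peak amplitude 2 mm, regenerated with reduced
amplitude until the Jacobian determinant of id+u is positive
everywhere). Ground-truth labels of warped phantoms are rasterized
*analytically* — the generating transform is applied to the voxel
centers and tested against the original ellipsoids — so evaluation is
not polluted by double nearest-neighbor quantization.

**Cohorts.** Cohort tables are drawn from the published normative
equations used as generating means: total volume
68.61 + 6.53·age − 0.19·age² mm³ (age in years, 6–24),
ICV-corrected volume 0.059 + 2.52×10⁻³·age − 7.349×10⁻⁵·age²
(mm³ per cm³), neonatal slope 0.51 mm³/week of postmenstrual age at
scan with a +0.75 mm³ male offset, and the left/right split inverting
left = −0.31542 + 1.00702·right. Defaults mirror the published samples
(256 neonates, 156 male; 250 children, 166 male). Choices the sources
leave open, fixed here once:

* The neonatal intercept is not published; default 4.0 mm³ puts
  term-age total volume near 25 mm³, consistent in magnitude with the
  child curve (~101 mm³ at age 6).
* Per-subject residual SDs are not published; they are free generator
  parameters (defaults 2 mm³ neonatal, 12 mm³ child, 0.008 corrected)
  surfaced in `CohortSpec`, never treated as "true".
* The left/right split adds an antisymmetric perturbation
  ±d, d ~ N(0, residual_sd/4), preserving the total exactly and
  vanishing in the noiseless case so coefficient recovery is exact.
* Negative generated volumes are resampled, not truncated, keeping the
  generating mean unbiased.
* Gestational age at birth is drawn consistently with age at scan
  (birth before scan, prematurity flag = ga < 37 wk); subjects scanned
  before 37 weeks are necessarily preterm.

## Statistical models

All fits are ordinary least squares with coefficient t-tests (n−p df),
via statsmodels. Sex is coded male = 1; ages are *not* centered, so
fitted coefficients are directly comparable with the published
equations. `residual_sd = √(SSR/(n−p))` drives normative z-scores
`z = (observed − predicted)/residual_sd`, with percentiles from the
standard normal; ages outside the fitted range are flagged as
extrapolation, not refused. The laterality "comparison" is a paired
t-test on (left − right) plus an OLS of the difference on age and sex;
no specific test is mandated by the sources, and the paired t is the
standard choice for within-subject pairs.

"Corrected" volume is total MB (mm³) divided by ICV (cm³): this is the
only unit pairing under which the corrected curve's intercept (0.059)
is commensurate with raw volumes (~80 mm³) and ICVs (~1500 cm³).

The vertex of the fitted raw quadratic is 6.53/(2·0.19) ≈ 17.18 years
and of the corrected quadratic ≈ 17.15 years. The narrative
descriptions accompanying the published curves place the peaks earlier
(≈15 y raw, ≈12 y corrected); the package reports the analytic vertex
of whichever curve it fits and does not adjust toward either narrative
value. The stratified left-right comparison above/below 50 mm³ is
descriptive only.

## Problem sizes and runtime

Defaults were chosen so the full test suite and the acceptance script
each run in minutes on a single CPU: 64³ phantoms, 5-atlas sets, 3
held-out subjects per evaluation, 200 replicates for calibration
checks (type-I error of the null prematurity coefficient; coefficient
bias < 3·SE at the published sample sizes). Coefficient-recovery
checks use noiseless cohorts, where OLS is exact to numerical
precision.

## Known limitations

* Registration accuracy is validated on phantoms with strong MB
  contrast; real neonatal T1 contrast is far poorer, and the reported
  Dice (~0.85) should not be read as clinical performance.
* The linear stage assumes rough initial overlap (phase correlation
  has a half-field capture range) and axis-aligned quadrature filters;
  large rotations (>~15°) are out of scope.
* The deformable model is small-deformation (no diffeomorphic
  guarantee for the *estimated* field, although generated synthetic
  fields are fold-free by construction).
* Mutual-information metrics, weighted/STAPLE fusion, atlas selection
  and skull stripping are deliberately not implemented.
* Normative curves are parametric OLS with homoscedastic residuals; no
  GAMLSS-style age-varying variance.
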