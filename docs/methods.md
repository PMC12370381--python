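# Methods

This note documents the models, conventions and numerical choices behind
`srsqa`, in the order data flows through the package.

## Structure model and rasterization

Structures are stacks of closed planar polygons on CT slices, the
representation used by RT Structure Sets.  Volume reconstruction follows a
**slab model**: the contour at slice position `z` governs the half-open
slab `[z − h/2, z + h/2)`, where `h` is the structure's slice spacing, and
the first/last contours are extended half a slab beyond their plane
(**end-capping**, no taper).  There is no interslice interpolation.
Multi-ring slices combine by the even-odd rule, so annular shells are
representable.

A voxel's occupancy fraction is the proportion of its sub-sample points
contained in-plane by the polygon of the point's slab (boundary points
count as inside, resolved via `shapely` predicates).  Supersampling
factors per axis are configurable; the structure default refines in-plane
sampling to ≤ 0.2 mm sub-pixels with 4 z sub-samples per voxel, and the
dose-sampling scheme mirrors common TPS practice: CT voxels larger than
1 mm³ are split into equal sub-voxels until each is below 1 mm³, then into
mini-voxels at least 27× smaller than the dose voxel.

Two properties follow from the construction and are exercised by tests:

* the occupancy volume equals the sub-sample fraction sum times the voxel
  volume to machine precision, and
* over uniformly random sub-voxel placements the slab estimator is
  **unbiased**: the expected volume equals the exact slab-solid volume (a
  Poisson-summation argument; empirically the signed mean error of fifty
  3-mm spheres is ≈ 0 ± 0.7%).

The cost of the convention is a heavy error tail for structures only a
couple of slices thick: a 3-mm sphere centred midway between 1-mm slices
presents two ~1.41-mm contours and nothing else — the polar caps beyond
the end-capped extent are unrecoverable from the contour stack, giving a
worst-case volume deficit of ~11%.  No generic convention can do better
from the same information: fitting a sphere through adjacent contour radii
recovers analytic spheres exactly, but that is shape-specific knowledge a
contour-based pipeline should not assume, so we keep the generic slab
model and report the tail as a known limitation.

Circle contours for analytic spheres use 64 vertices at the slice-position
radius `√(R² − (z − c_z)²)` (as a clinician would draw on the slice
image).  An inscribed 64-gon carries an area deficit of
`1 − (64/2π)·sin(2π/64) ≈ 0.157%`, which is the dominant bias for
diameters ≥ 7 mm; the vertex count is configurable where finer fidelity is
needed.

## Dose model

The radial model is `dose(r) = bath + (100 − bath)·2^−(r−R)/g`, capped at
140% in the interior: 100% at the target surface, halving every `g` mm
(default 3 mm — "50% within a few mm"), rising toward a realistic hot spot
in the centre, with an optional far-field bath.  Every isodose level of
the isotropic model is a sphere with radius `r_L = R + g·log₂(100/L)`, so
V100/V50/V25 and the gradient index have closed forms.  The model is
deliberately *not* flat inside the target: a flat 100% plateau makes the
set {dose ≥ 100%} degenerate under any interpolating reconstruction and
V100 unmeasurable.

Clinical-like lesions perturb a sphere with degree-2/3 spherical
harmonics (amplitude 8% of radius, seeded), scaled so the maximum axial
diameter equals the nominal label.  The per-lesion dose radius is the
0.97-coverage quantile of the surface (guaranteeing ≥ 95% prescription
coverage after discretization), the falloff grows with size
(`g = 3 + 0.25·R_dose` mm, keeping GI in the clinically typical ~7 → ~3
range from 6 to 30-mm lesions), mild per-axis anisotropy (±5%) breaks
exact sphericity, and lesions combine by voxelwise maximum plus a smooth
3% Gaussian bath (σ = 60 mm).  Placement enforces that any other lesion
contributes < 1% inside a target's evaluation shell, so per-target
measurements are isolated by construction.

## Dose reconstruction at sample points

Dose values live at dose-grid voxel centres; volume measurement needs dose
at mini-voxel centres.  Three reconstructions are supported, and the
choice matters more than any other numerical option in the package:

* **trilinear** — the reconstructed level set of a convex isodose surface
  with curvature κ is displaced inward by ≈ κh²/8 for grid spacing h.  For
  a 1.5-mm-radius 100% isodose on a 1-mm grid that is a ~17% volume
  deficit.  This erosion is exactly the kind of error a typical TPS DVH
  engine exhibits, so the **study pipeline defaults to trilinear**: the
  dose-grid sensitivity it measures (ratios falling below 1 for small
  isodose volumes, recovering toward 1 with size, following a power law)
  is the physically expected behaviour.
* **tricubic B-spline** — reproduces local curvature; V100 of 3-mm targets
  is recovered with ~0.5% mean and ~3% worst-case error on a 1-mm grid.
  The **validation pipeline defaults to tricubic**, playing the role of
  the accurate reference implementation against which closed forms are
  checked.
* **nearest voxel** — unbiased but noisy (±tens of % for the smallest
  targets); kept for sensitivity analyses.

Isodose thresholds are inclusive (≥), and `V30Gy` ("dose greater than the
prescription") is implemented as ≥ 100% so it coincides with V100
semantics.  DVHs are cumulative with 0.1% bins; `D95` interpolates
linearly within bins; a dose exactly on a bin edge counts into the upper
bin (tolerance 10⁻⁶ of a bin).

## Discretization study semantics

* **DG perturbation** re-samples the analytic dose model at the voxel
  centres of a coarser lattice sharing the reference origin — the
  synthetic analogue of a TPS recalculation.  (For imported dose with no
  analytic model, resampling the fine grid is the fallback and is an
  approximation.)
* **ST perturbation** re-slices the CT lattice (common origin, in-plane
  resolution kept); target contours are regenerated from their analytic
  shapes at the new slice positions, and all mini-voxel sampling inherits
  the coarser z resolution.  Dose is unchanged, so the ST effect flows
  through structure discretization and DVH sampling only.

Statistics: Spearman ρ of (reference volume, ratio) pairs with exact
permutation p-values for n ≤ 9; power-law fits `y = a·x^b + c` by
multi-start nonlinear least squares (b initialized on a grid in [−3,
−0.05], a and c by linear solve per start, best SSE kept; constant data
short-circuits to a = 0 with NRMSE defined as 0); NRMSE is the RMSE
normalized by the range of the ratios; two-sided Wilcoxon signed-rank
tests (exact for ≤ 25 nonzero differences, all-zero differences reported
as p = 1); paired effect size `d = mean/sd` of differences with required
sample size `(z₁₋α/₂ + z_power)²/d²` inflated by the signed-rank relative
efficiency (÷0.955) and rounded up.  No multiple-testing correction is
applied; p-values are reported raw.  One master seed drives every
stochastic draw through `SeedSequence` spawning.

## What the generators do and do not emulate

The synthetic cohort reproduces the *structure* of a clinical SRS dataset
— lesion size groups, steep per-lesion falloff, multi-lesion geometry,
evaluation shells, prescription normalization — with exact analytic
ground truth.  It does not emulate MLC/arc fluence, tissue heterogeneity,
CT noise, contouring variability, or organ-at-risk anatomy; real plans
also produce rougher dose surfaces than the smooth radial model.  Passing
tests therefore demonstrate the correctness and discretization behaviour
of the *measurement pipeline*, not the dosimetric accuracy of any TPS on
real patients; on clinical data the same pipeline would be applied to
imported DICOM dose and structures.

## Problem sizes

The bundled validation runs 50 spheres per diameter in {3, 7, 10, 15, 20}
mm (250 targets) and the study cohort 15 cases (~30 lesions) at ST 1 mm
and DG {1, 2} mm — sizes chosen to keep the full reproduction run in the
minutes range on a single CPU while leaving per-group sample sizes
comparable to a pilot-study cohort.  Larger lists of diameters, STs and
DGs are configuration, not code changes.

## Known limitations

* The slab/end-capping convention's heavy error tail for ≤ 2-slice
  structures (above) — worst-case ~11% volume deficit at 3 mm.
* Closed-form isodose volumes exist only for the isotropic radial model;
  anisotropic lesions are validated against Monte-Carlo/quadrature
  oracles instead.
* `reslice_structure` for imported polygon stacks copies the nearest
  original contour rather than interpolating between planes.
* DICOM support covers geometry, contours and dose needed for QA round
  trips, not full RT-plan semantics (no MLC sequences, no registration
  objects).
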