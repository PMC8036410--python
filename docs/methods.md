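# Methods

This note documents the models, estimators and design choices behind
spheromorph, and what the synthetic validation does and does not show.

## 2D morphometrics

The 2D read-outs operate on the maximum-intensity projection of a
single-channel stack (the standard per-well acquisition: one field, a
handful of z-slices, combined by maximum projection).  Segmentation is a
global Otsu threshold — the spheroid is dark on a bright background in
transmitted light, bright on dark in fluorescence, so object polarity is an
explicit option rather than something inferred from the image — followed by
largest-8-connected-component selection and hole filling.  Compact
aggregates are well served by this; the module deliberately does not handle
multiple spheroids per field.

Descriptors, for area `S` (mm²) and perimeter `P` (mm):

| quantity | formula | value for a circle |
|---|---|---|
| projected radius | `R = sqrt(S/π)` | r |
| projected volume | `V = (4/3)πR³` | true sphere volume |
| circularity | `Cir = 4πS/P²` | 1 |
| sphericity index | `SI = sqrt(Cir)` | 1 |
| roundness | `RI = 4S/(πL²)`, L = major axis of the second-moment ellipse | 1 |
| solidity | `S / area(convex hull)` | 1 |

The sphericity index is sometimes written without the radical (`SI = Cir`).
Both conventions normalise to 1 for a circle; this package computes
`SI = sqrt(Cir)` — the form consistent with the standard definition of
sphericity as the square root of circularity — and always reports `Cir`
alongside, so either convention is recoverable from the output.

**Perimeter estimator.**  Perimeter is the length of the 0.5 iso-contour of
the Gaussian-smoothed (σ = 1 px) mask, extracted by marching squares.
Naive boundary-pixel counting overestimates a disk's perimeter by ~5%, and
even the 4-direction Crofton estimator — accurate to 0.5% on disks — is
biased −5.5% on grid-aligned straight edges, which would push a square's
circularity from π/4 to ~0.88.  The smoothed-contour estimator measures
within 1% on disks (r = 50–100 px), axis-aligned and rotated squares, and
2:1 ellipses alike.  Dimensionless indices are stored raw (rasterization
can push them a fraction of a percent above 1) and clipped to 1 only in
exported records.

2D measurements require (near-)square pixels; anisotropic projections are
rejected rather than silently mis-measured.

## 3D segmentation pipeline

Input stacks are `(z, y, x)` with z the optical/gravitational axis (plate
bottom at low z) and caller-supplied voxel spacing — TIFF tags are not
trusted, and the default (2.0, 1.3, 1.3) µm matches a typical light-sheet
z-step/pixel-size combination.

1. **Isotropic resampling** — trilinear interpolation onto a lattice at the
   finest input pitch (never downsampling by default).  Foreground volume
   is conserved to <2% on phantoms.
2. **Noise estimation** — σ is the median absolute deviation of the
   residuals of a 3D Laplacian kernel (6·center − 6-neighbour sum), scaled
   by 1/(0.6745·√42) so pure Gaussian noise returns σ.  The median makes
   the estimate robust to the sparse large residuals at object edges; a
   Poisson noise component is absorbed into the effective σ rather than
   modelled explicitly.  Accuracy is ~±5% on phantoms; the estimate scales
   linearly with intensity.
3. **Non-local-means denoising** with filter parameter `h = 0.8 σ`, patch
   size 3³, search window 7³ (all exposed in `SegmentationParams`).  On
   phantoms this cuts background noise >2× while shifting the mean <0.01%.
4. **Otsu-centred hysteresis thresholding.**  The Otsu threshold `T`
   maximises between-class variance over a 256-bin histogram — identical
   to a brute-force intraclass-variance scan.  When several splits tie
   exactly (every split across an empty-bin gap between two well-separated
   modes attains the same criterion), the *middle* of the tie plateau is
   returned: the plateau ends hug one of the modes, which would corrupt
   thresholds derived multiplicatively from `T`.  Hysteresis keeps voxels
   ≥ `0.8 T` that are 26-connected to a voxel ≥ `1.2 T`.  The factors are
   multiplicative — hence invariant to intensity rescaling — and symmetric
   about `T`; they are the package's operationalisation of initialising the
   dual thresholds around the Otsu estimate, and are exposed as parameters.
5. **Cleanup** — largest 26-connected component, internal cavities filled.
   Compact aggregates have no true internal voids, and a dye-dark core must
   not produce a hollow mask; filling is therefore the default and the
   measured "real volume" includes any enclosed cavity.

**Object-presence guard.**  Plain Otsu + hysteresis segments *something* in
any image, including pure noise (a half-density random field percolates
into one giant 26-connected component).  The pipeline therefore requires
the Otsu class-mean separation on the denoised volume to exceed 3× the
estimated raw noise σ — the same detectability floor the phantom generator
enforces — and raises `EmptySegmentationError` otherwise, as it does when
the largest component falls below `min_component_voxels` (default 1000).

## 3D descriptors

* **Volume** — foreground voxel count × voxel volume.
* **Surface** — area of the marching-cubes mesh at the 0.5 iso-level of
  the padded, Gaussian-smoothed (σ = 1 voxel) mask.  Counting exposed voxel
  faces overestimates a sphere's surface by >30% (staircase bias), which
  would destroy the sphericity descriptor; the smoothed mesh is within
  0.5% on spheres and 3% on 2:1 ellipsoids.
* **Equivalent ellipsoid** — semi-axes `aᵢ = sqrt(5 λᵢ)` from the
  eigenvalues of the voxel-position covariance (physical units, plus a
  `spacing²/12` per-axis term for the finite voxel extent).  This is the
  unique solid ellipsoid with the same second central moments; a bounding
  or fitted-surface ellipsoid would give slightly different eccentricities
  for non-ellipsoidal shapes.
* **Eccentricities** `e1 = sqrt(1 − c²/a²) ≥ e2 = sqrt(1 − c²/b²)`; 0 for
  a sphere, → 1 under flattening.
* **Sphericity** `36π V²/A³` — kept in exactly this form (it is the cube
  of the Wadell sphericity `π^(1/3)(6V)^(2/3)/A`); both normalise to 1 for
  a sphere, so the choice only affects how fast the value falls below 1.
* **Roundness** `6V/(πL³)` with `L = 2a`.  The variant with π in the
  numerator (`6πV/L³`) gives π² for a sphere, contradicting the defining
  normalisation "roundness = 1 for a perfect sphere"; the π-in-denominator
  form is the one that satisfies it, and is what this package computes.
* **Thickness / diameter** — occupied z-extent (the flat bottom rests on
  the plate, which defines z; no re-orientation search is performed), and
  the maximum Feret diameter of the top-view projection via the convex
  hull of projected pixel centers in physical coordinates.

Eccentricity is a steep function of near-equal axes
(`e1 = sqrt(1 − c²/a²)` has infinite slope at a = c), so on a noisy
*sphere* a 0.5% axis error already reads as e1 ≈ 0.1; e1/e2 are accurate
to ±0.03 once the object is genuinely anisotropic, which the recovery
suite checks on random ellipsoids.

## Synthetic phantoms

`PhantomSpec` rasterises spheres, ellipsoids (optionally rotated),
hemispheres and flat-bottomed oblate caps (upper half of an oblate
spheroid) at arbitrary, possibly anisotropic, spacing.  Intensities follow
the two gray-level structures of real light-sheet stacks: *bivariate*
(background + homogeneous object) and *trivariate* (background + bright
peripheral rim + dimmer core, emulating the higher cell density of
peripheral layers in older aggregates; rim thickness is a fraction of the
normalised ellipsoidal radius).  Noise is additive Gaussian from a seeded
generator; identical spec + seed ⇒ bit-identical stacks.  Default levels
(background 30, object 600, σ 95) put the object 6σ above background;
specs with contrast below 3σ are rejected as undetectable by design.

Ground truth is computed analytically, never from the rasterized mask:
ellipsoid volume `4/3·πabc`, half-shapes `2/3·πa²c`; oblate surfaces in
closed form, triaxial via the Thomsen approximation (max error ~1.1%, well
inside the 3% surface tolerance); moment-equivalent axes of a half-shape
use `var_z = 19c²/320` (so the equivalent c-axis is `sqrt(95/320)·c ≈
0.545c`); extents of rotated ellipsoids via the support function
`2·sqrt(uᵀRD²Rᵀu)`.  Rasterization volume error is <1% for min axis
≥ 25 voxels.

What the phantoms do **not** emulate: light-sheet stripe artifacts,
depth-dependent attenuation, the microscope PSF, refractive-index mismatch
after clearing, and cell-scale texture.  Passing the recovery suite
therefore demonstrates the correctness of the geometry/estimator chain and
its robustness to additive noise and the rim/core structure — not
robustness to every optical artifact of real acquisitions.

## Death and viability read-outs

PI-positive pixels are those inside the bright-field mask at or above a
threshold chosen by policy: Otsu on the in-mask values (default), a fixed
value, or an in-mask quantile.  The Otsu estimate is only trusted when the
in-mask distribution is genuinely bimodal (class-mean separation > 3 robust
σ of the in-mask values); a homogeneous signal — dye-free spheroid, or dye
covering everything — falls back to a floor of background median + 3 robust
background σ, so those two limits report 0 and 1 rather than an arbitrary
half-split.  Summed PI intensity subtracts the background median (median PI
outside the BF mask) without clipping, so zero-mean noise cancels and the
intensity ratio is invariant to a constant camera offset; subtraction can
be disabled.  Viability is the exact count formula `100·live/(live+dead)`.

## Problem sizes used in the validation suite

Tests size their phantoms to exercise every code path at meaningful
resolution: recovery phantoms have full axes of 40–120 voxels at
(2.0, 1.3, 1.3) µm spacing (≈130³ grids after isotropic resampling); the
overestimation phantoms (hemisphere r = 500 µm, 1300 µm cap) are sampled at
5 µm isotropic, which resolves their smallest dimension with >60 voxels.
Descriptor accuracy is unchanged at finer sampling; these sizes keep each
pipeline run at a few seconds.

## Known limitations

* Thickness assumes the flat face is exactly plate-aligned; a tilted
  sample would need a re-orientation step that is deliberately out of
  scope.
* The moment-based ellipsoid is one of several reasonable axis
  definitions; eccentricities of strongly non-ellipsoidal shapes depend on
  this choice.
* 2D metrics require square pixels.
* Multi-spheroid wells, time-lapse tracking, dose–response fitting and
  statistical testing are out of scope; results are exported as tidy CSV
  for downstream tools.
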