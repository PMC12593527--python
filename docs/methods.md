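# Methods

This note documents the models inside `pmpscan`, the defaults and why they
were chosen, and what the synthetic studies do and do not demonstrate about
physical scanners.

## Scene and imaging model

Both devices are ideal pinholes.  World units are mm, right-handed, with
the scene near the origin; the camera sits at `(0, 0, L)` looking straight
down and the projector at baseline distance `D` along +x, pitched so its
axis passes through the scene center (triangulation angle `atan(D/L)`).
Image coordinates are 0-based with pixel centers on integers, u rightward,
v downward.  The reference rig is: camera 20 mm focal length, 36 × 24 mm
sensor, 1138 × 489 px (note the strongly anisotropic 31.6 × 49.1 µm
pixels); projector 1920 × 1080 px behind a 20 mm / 12.8 × 7.2 mm panel,
giving a ~0.69 m-wide illuminated field at the 1 m stand-off — wide enough
to cover the benchmark objects; `D = 400 mm`, `L = 1000 mm`.

Rendering is single-bounce Lambertian ray casting (vectorized
Möller–Trumbore with an AABB pre-test; no global illumination):

```
raw = gain · (ambient + albedo · pattern(u_p, v_p) · max(0, n̂·l̂))
```

with a shadow ray toward the projector, bilinear sampling of the pattern
raster at the hit's projector pixel, k×k supersampling (default 2×2),
per-pixel Gaussian defocus with thin-lens circle of confusion
`c = aperture·f·|z − z_f| / (z·(z_f − f))` (σ = c/2, approximated by
blending fixed blur levels), clamping at 1.0 with a bloom stage that adds
back the Gaussian-blurred clipped excess, optional Gaussian sensor noise,
and 8-bit quantization.  Every random stream derives from the scene seed,
so identical configurations produce bitwise-identical captures.

Photometric defaults: ambient 0.05, albedo 0.90, saturation 1.0.  The
aperture default (50 mm) is chosen so that scans ±100 mm from the focus
distance degrade visibly (≈1.8 px blur), driving the distance study;
calibration imagery is rendered in focus (aperture 0), as calibration
frames are in practice.  Bloom defaults (radius 18 px, strength 1.5) are
calibrated once so that a 2× over-exposed capture exhibits the halo
artifact — excess floating points near the silhouette — that strong light
produces in real systems; unsaturated captures are unaffected by the bloom
stage.  The light-intensity study runs with sensor noise σ = 0.01 (~2.5
gray levels, a typical camera noise floor) so weak light degrades through
a shrinking signal-to-noise ratio; the noise default elsewhere is 0.

## Patterns and phase recovery

A scan projects N = 12 phase-shifted fringes (16 periods across the 1920 px
panel, 120 px/period), 4 period-aligned gray-code frames (orders k₁) and 5
half-period-shifted frames (orders k₂).  The fringe carries a −π phase
offset so that each fringe peak is centered on a k₁ band: with that
alignment the three-branch unwrap

```
Φ = φ + 2π k₂         φ ≤ −π/2
    φ + 2π k₁         −π/2 < φ < π/2
    φ + 2π k₂ − 2π    φ ≥ π/2
```

holds *identically* — k₁ transitions coincide with the φ wrap and are only
consulted far from it, k₂ transitions sit half a period away.  Without the
offset, the middle branch would need an order map with 2^m + 1 values,
which m period-aligned code frames cannot supply.  The wrapped phase uses a
quadrant-aware two-argument arctangent with range (−π, π]; a half-range
arctan could not feed the ±π/2 branch switching.  Gray frames are binarized
against the per-pixel DC level from the PSP stack, which makes the
threshold immune to albedo and shading; codeword→order is an explicit
lookup table built from the reflected-gray sequence.  Ties at exact stripe
boundaries fall to the lower codeword; the branch rule absorbs the
residual half-period ambiguity.

Pixels are kept when fringe modulation B ≥ 0.05 (rejects shadow and
background) and DC < 0.98 (rejects saturation), and when their unwrapped
phase agrees within π with a majority of 4-neighbors.

## Calibration

The board is a bright plane (albedo 0.95) with a 9 × 11 grid of dark dots
(2.5 mm diameter, 16 mm pitch, albedo 0.12) plus four 5 mm fiducials in an
asymmetric "L" that resolves orientation under any rotation.  Twenty poses
span camera distances ≈780–1080 mm with tilts to ±22°.  Detection proceeds
in two passes: connected-component centroids on a locally
background-normalized image, grid-ordering via the fiducial constellation
and an iteratively refined homography; then a per-dot model fit.  The fit
is decisive for accuracy: at this rig a 2.5 mm dot spans only ~1.6 × 1.0
px, where plain intensity centroids pixel-lock at the 0.05 px level.  The
model fixes each dot's pixel-space ellipse from the board homography's
local Jacobian and the known physical radius, and fits only center,
amplitude and background against a high-supersampling re-render of the
dot's window (32×32 subsamples, removing the coverage staircase of the
full frame).  Mean center error is ≈0.012 px.

Projection matrices come from Hartley-normalized DLT over all poses
jointly (board poses are known in the virtual world, so the world points
are exact) followed by Levenberg–Marquardt refinement of the 11 free
entries (a34 = 1).  The projector never sees the board; each detected dot
center is mapped to a projector pixel through the absolute phase of
vertical and horizontal fringe scans of the pose, sampled at the sub-pixel
center by a modulation-weighted local plane fit of the phase-derived
coordinate map.  Degenerate inputs (coplanar world points, <6
correspondences) raise rather than returning garbage.  Lens distortion is
zero throughout (the renderer emits none); the interfaces accept
distortion coefficients but never estimate them.

## Reconstruction

The primary geometry path solves, per valid pixel, the 3×3 system formed
by two camera rows and the projector-column row of the two projection
matrices; systems whose determinant falls below `row-norm product / 1e10`
are rejected as degenerate.  The reference-plane height mapping
`h = L·Δφ / (2π f₀ D + Δφ)` is kept as a secondary, didactic mode with
`f₀ = 0.172 lp/mm` as its default fringe frequency; it is not used by the
benchmarks.  Outlier removal is neighborhood-relative: a point is dropped
when its mean distance to its 8 nearest neighbors exceeds 2.5× the median
of that statistic over those neighbors.  A global mean + 2σ cut was tried
first and rejected: it deletes legitimately sparse foreshortened flanks of
curved bodies wholesale.

## Evaluation protocol

MAE is the mean absolute point-to-surface distance of the full filtered
cloud against the full ground-truth mesh (exact point-triangle distances,
not sampled).  HD/MDTA are set-to-set statistics and therefore sensitive
to *coverage*, not only error: at this rig the camera's pixel footprint is
1.6 × 2.5 mm on a fronto-parallel surface and several-fold larger on
steeply inclined faces, so gaps between pixel samples — not reconstruction
error — would dominate a naive symmetric Hausdorff distance.  The
benchmark therefore evaluates HD/MDTA over the **scannable surface**:
ground truth is sampled densely (10 points/mm² for the benchmark) and
restricted to points that face and are unoccluded to both devices with a
camera-incidence margin cos ≥ 0.35 (pixel footprint within ~3× nominal)
and projector margin cos ≥ 0.2, then eroded by 5 mm (~2 pixel footprints)
at the boundary of that region, since edge pixels mixing two surfaces are
inherently unmeasurable; the reconstructed cloud is cropped by applying
the same test to each point's closest-surface foot point.  CMAE collapses
cloud points within ±1.5 mm of a section plane through the object centroid
(snapped to the nearest populated camera row) to a median height profile
and compares it with vertical-ray ground truth on the same abscissa grid.
DSC voxelizes both interiors on a shared grid (default 1 mm) by
vertical-ray crossing parity.  ICP is point-to-point with the closed-form
SVD update, max 100 iterations, tolerance 1e−6 mm, optional trimming.
HD/MDTA are reported symmetric (max/mean over both directions), with the
directed variants exposed.

## Benchmark fixtures and study layouts

The frustum ("regular trapezoid") defaults to 120 × 120 mm base,
60 × 60 mm top, 80 mm height — tall enough for section analyses at
z = 20 and 70 mm.  The torso stand-in is a superellipsoid-remapped
icosphere (exponent 2/2.5 cross-sections, 500 × 320 × 200 mm) with its
back compressed to rest near the couch plane; it is smooth, watertight and
bilaterally symmetric, but carries none of the anatomical detail (folds,
breasts, posture) of a CT-derived body, so study results characterize the
measurement chain, not anatomy-specific effects.  The distance study moves
the *object* along the optical axis under the fixed calibrated rig (900,
950, 1000, 1050, 1100 mm).  The viewpoint study lays the body along the
baseline axis, where the lateral ±45° views are exact mirror images with
respect to the rig, and tips it 65° for the foot-of-couch view.  The
intensity study scans at gains 0.5 / 1 / 2.

## Problem sizes and limitations

The benchmarks run at the full 1138 × 489 camera resolution; fast test
paths use a resolution-scaled camera (same optics) and a coarser torso
tessellation (icosphere subdivision 2, ~25 mm facets) — adequate because
ground truth is always the same mesh that was rendered.  Passing synthetic
studies demonstrate the correctness and numerical behavior of the
pattern/decode/calibrate/triangulate chain under a faithful but simplified
image model; they do not capture inter-reflections, subsurface scattering,
projector defocus, gamma nonlinearity, lens distortion or calibration
drift, all of which degrade physical systems.  Phase-error compensation
and spatial or multi-wavelength unwrapping are out of scope by design.
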