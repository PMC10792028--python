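# Methods

This note documents the models implemented in `texsurf`, the parameters
that matter, the numerical choices, and what the synthetic phantom does
and does not establish.

## Texture features

**Gabor bank.** A kernel is a real cosine carrier of wavelength λ along
orientation θ under an anisotropic Gaussian envelope with along-carrier
standard deviation σ and cross-carrier standard deviation σ/γ, DC
corrected to zero mean, with support the smallest odd square covering ±3
of the larger σ. The response is the magnitude of the 2D convolution with
edge replication, computed slice-wise even on 3D volumes. Defaults: θ ∈
{0°, 45°, 90°}, λ = 8 px, σ ∈ {1, 2} px, γ = 0.25 — a bank of six
filters tuned to parenchymal texture at CT resolution. The γ convention
(cross-σ = σ/γ, kernels elongated along the stripes, as in skimage and
OpenCV) is this package's explicit choice; the parameterisation is
otherwise standard. Convolution uses FFTs on an edge-padded image; the
test suite pins it against direct spatial convolution at 1e-6 relative.

Note a consequence of the fixed bank that matters at small image sizes:
the widest kernel spans 49 px, so any strong region boundary "blazes" a
band of comparable width in the wide-envelope maps. Structures whose
half-width is below ~2 kernel widths are effectively all boundary in
those maps.

**Windowed GLCM.** For every pixel, grey-level pairs at the four standard
offsets (0°/45°/90°/135°, Chebyshev length `step`, default 1) are
accumulated over the surrounding (2r+1)² window (default r = 3), clipped
at image borders, symmetrised and normalised. Grey levels are linear
min–max bins (default 32). Features: contrast Σp(i−j)², entropy −Σp ln p,
homogeneity Σp/(1+|i−j|), energy Σp², correlation
Σp(i−μᵢ)(j−μⱼ)/(σᵢσⱼ) (0 when σᵢσⱼ = 0). Windows with no valid pair
(possible only when `step` exceeds the clipped window) take the
constant-window values (energy = homogeneity = 1, others 0). The kernel
is a numba routine; a naive Python implementation and skimage's
co-occurrence matrix serve as oracles in the tests.

## Probabilistic seeding

P_in (see README) is a Gaussian KDE over the feature values inside the
seed disc, evaluated at every pixel; P_tex sums it over the bank, with
the bandwidth σ resolved per map. Two modes:

- `fixed`: a user σ.
- `contour_std` (default): σ = std of the map inside the disc, floored at
  `sigma_floor_fraction` (default 0.30) of the map's value range and at
  machine ε.

The floor is the one genuinely consequential choice here. Feature maps
whose dynamic range is dominated by localised extremes (region-edge blaze)
combine a tiny in-contour std with large benign spatial variation; an
unfloored bandwidth then makes the KDE nearly a delta mixture, and the
window-similarity criterion (window mean within `similarity_factor` = 0.5
of the in-contour probability std) degenerates to selecting nothing. A
floor of 0.3 of the range saturates such maps — they contribute an almost
constant probability and neither select nor veto — while maps whose
in-contour spread is genuinely representative stay discriminative. The
criterion itself follows the half-std similarity rule exactly, including
the degenerate zero-std fallback (tiles matching the contour mean within
1e-9).

For large slices the KDE is tabulated on an 8192-knot grid spanning the
value range ±4σ and linearly interpolated (error ~1e-7 of the peak); the
exact O(N·|V|) evaluation is used below 2²¹ pairwise terms and in all
oracle comparisons.

Slice ranges: Mode A processes the inclusive interval [n_s−r, n_s+r],
Mode B [n_s, n_s+r] with optional propagation of the anchor contour every
k slices; only every m-th slice participates. Each processed slice uses
the contour nearest in z (ties to the lower index). Seed discs are always
force-included on their own slices: a user-marked region is trusted even
when the window criterion would reject its tiles.

## Level-set evolution

Sign convention: φ > 0 inside; F > 0 expands. φ is initialised as the
signed Euclidean distance to the start-region boundary (voxel units, zero
level half a voxel outside the outermost seed voxels) and clamped to ±5
voxels throughout — a narrow-band-like guard that removes the need for
reinitialisation.

Discretisation: explicit Euler; Godunov upwind gradient for the data term
(for F > 0, descending backward and ascending forward slopes — note this
is the mirror of the common textbook form because the inside is positive
here); central differences for the mean curvature κ = div(∇φ/|∇φ|) with
an η = 1e-8 denominator guard and κ clamped to ±1; replicated boundary
conditions. Time step

    dt = 1 / ( α·max|D| / 0.9  +  (1−α)·2·d / 0.45 ),

the harmonic combination of an advective Courant bound (0.9) and the
parabolic diffusion limit (0.45) in d dimensions. With the defaults
(α = 0.0125, ε = 750) the raw product α·D reaches ≈ 9, so the front moves
≈ 0.4 voxel/iteration where tissue matches and the typical run converges
in 100–150 iterations on the phantom — the regime in which the default α
balances curvature against the raw data term. An optional
`normalize_data` mode divides D by ε and clamps at ±4 for users who want
data and curvature on commensurate scales; with the default α it is far
slower and is off by default.

The 2D texture model applies the same update with in-plane stencils only,
so slices evolve independently; its data term is the binary
θ-deviation test (θ = 4, v = 2) over per-slice z-scored Gabor + GLCM
features, with statistics taken over the slice's start regions (features
with zero seed std deviate whenever the value differs from the mean).

Convergence follows the object-voxel-count rule: every j = 10 iterations
the count is compared with the previous checkpoint; a change of at most
0.5% of the estimated target volume (the start-region voxel count, floor
50 voxels) stops the run. The hard cap defaults to 200 iterations.

Pipeline detail: with slice spacing m the start regions are plates on
every m-th slice, and a voxel exactly midway between two plates is a
stationary point of the upwind update (all one-sided and central
differences vanish). The pipeline therefore closes the start mask along z
(structure length m+1) before initialising φ; the seeding output itself
is left untouched.

## Metrics

DC, VOE and RVD come from exact voxel counts. Surface voxels are object
voxels with a background 6-neighbour, the volume border counting as
background. Distances are Euclidean between voxel centers scaled by the
spacing; MSD averages both directed nearest-surface distance lists; HD95
is the 95th percentile of the pooled symmetric multiset with linear
interpolation at rank 0.95(n−1). Pooled-symmetric is the common
convention in segmentation challenges; max-of-directed percentiles would
differ slightly and is not used.

## The phantom

`generate_phantom` builds a deterministic CT-like volume: ellipsoidal
targets filled with an oriented cosine grating around −800 HU
(amplitude 350), a background grating of orthogonal orientation around
+200 HU (amplitude 50), bright vessel-like cylinders (−100 HU) clipped to
the target interiors, and additive Gaussian noise (σ = 20 HU). Default
shape 40×256×256 with two side-by-side targets; suggested seeds are
radius-8 discs at each target's center slice and at ±60% of its axial
extent.

Three design points are deliberate and load-bearing:

- **Intensity placement.** The target swing (±350, clipped speckle ±2σ)
  stays inside the default tolerance band around T ≈ −800, the background
  (≥ ~+50 HU) stays outside it, and vessels (−100 HU) sit inside it — so
  the 3D model keeps intrapulmonary clutter, as reference lung masks do.
- **Speckle.** Both gratings are amplitude-modulated by a smooth 3D
  random gain (clipped at ±2σ, correlation ≈ 2 px). Without it the
  texture is so homogeneous that a seed contour is unrepresentative of
  its own region and the window-similarity criterion selects nothing;
  real parenchyma has exactly this stationary small-scale variability.
  The gain varies along z so its extremes are compact blobs the evolving
  surface can wrap around, not columns.
- **Scale.** Targets are wide relative to the 49-px kernel footprint.
  The certificate `separability_ratio` renders both textures full-frame
  (so the region-edge blaze cannot contaminate the comparison) and
  requires the matched-orientation filters to respond ≥3× more strongly
  on their own texture; specs failing it are rejected.

`degrade_phantom` burns a background-like sphere at elevated intensity
into a target without touching the ground truth, for graceful-degradation
tests.

What passing phantom tests show: that the seeding criterion, the PDE
solver and the metrics do what the model says under textures whose
statistics the method assumes. What they do not show: performance on real
parenchyma (broadband texture, anisotropic spacing, pathology,
partial-volume boundaries), robustness of the fixed filter bank across
scanners, or the operator effort on real data.

## Problem sizes used in the tests

The end-to-end checks run the default 40×256×256 phantom (≈2.6 M voxels,
five slice spacings, ~110–130 iterations each); per-slice seeding checks
use a 288² single-target slice; oracle comparisons use ≤16³ random
arrays; the curvature-flow law is verified on radius-10 spheres/circles
in 28-wide grids. These sizes keep every structure several kernel
footprints wide, which is the regime the method is designed for.

## Known limitations

- The window criterion is geometry-limited near region boundaries: a
  band roughly one kernel footprint wide is never selected, so very small
  targets seed only at their core (the level set recovers the rest).
- No reinitialisation: φ is a clamped approximate distance only near the
  zero level; curvature far from the surface is not meaningful (harmless
  because updates vanish on the clamp plateau).
- The 2D texture model inherits the paper-default α only nominally; with
  binary ±2 data it needs a larger α (e.g. 0.5) to act, which the tests
  use explicitly.
- DICOM reading covers plain single-frame CT series with uniform slice
  gaps (1% tolerance, median-gap fallback with a warning); enhanced
  multi-frame objects and RT structure sets are out of scope — evaluation
  accepts pre-rasterised masks only.
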