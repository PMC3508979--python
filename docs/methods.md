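# Methods

This note documents the models and procedures implemented in `mtubesim`,
the parameter choices that matter, what the synthetic data emulate (and
do not), and the numerical decisions taken where the design was open.

## Conditional growth model

A microtubule is an ordered 3D polyline of points spaced exactly
`step_um` = 0.2 µm apart, nucleated at the centrosome. The model is
conditional: growth happens inside a `CellGeometry` (3D cell and nucleus
masks plus the centrosome voxel), and the filament may only occupy the
cytosol (cell AND NOT nucleus). A continuous position p maps to the voxel
`floor(p / voxel_size)` per axis; coordinates are in µm, voxel indices
0-based in (x, y, z) order with arrays stored `[z, y, x]`.

Rules, in the order applied at each step:

1. **Length sampling.** Desired lengths are i.i.d. Erlang with shape
   k (integer, default 2) and rate k/μ, so the mean is exactly μ and the
   distribution has a single free parameter once k is fixed. Draws are
   rounded to the nearest positive step multiple so the bookkeeping below
   can match lengths exactly. k is not a published constant; k = 2 gives a
   unimodal length distribution with coefficient of variation 1/√2 ≈ 0.7,
   consistent with the broad spread of realized lengths in the frequency
   plots this model family produces. It is configurable
   (`GrowthParams.erlang_shape_k`).
2. **First step.** The initial direction is uniform on the unit sphere,
   rejection-resampled (up to 1000 draws) until the first step lands in
   the cytosol. No distribution is prescribed for this step by the model;
   uniform is the maximum-entropy choice and matches the radial appearance
   of real asters.
3. **Free steps.** The next direction lies on the lateral surface of the
   cone of aperture 2α about the previous direction: the dot product with
   the previous direction equals the collinearity cos α *exactly*, the
   azimuth is uniform. Higher cos α = straighter filaments.
4. **Boundary rebound.** If the cone step would exit the cytosol, the
   collinearity requirement is relaxed but the turn is still confined to a
   cone of half-angle α_local = 63.9° (cos 0.44). Fifty candidate
   directions are drawn uniformly over that solid cone; among the
   candidates whose step stays cytosolic, the one whose straight one-step
   continuation also stays inside is preferred, and ties resolve to the
   most collinear. If no candidate stays inside, the filament terminates.
   The preference for clear, minimally-deflected candidates implements
   "relax as little as possible": it makes boundary encounters behave like
   cortical gliding (the filament bends along the surface) rather than
   diffuse reflection. With unbiased candidate selection the curvature
   rule below fires so often in 1.2–1.6 µm flat cells that mean lengths
   beyond ~20 µm become ungenerable at cos α = 0.97, which would make most
   of the default parameter grid empty — empirically untenable for a model
   whose published grid spans μ up to 45 µm.
5. **Global curvature rule.** After every step, all C(w,2) unordered
   pairs of step directions in the trailing window of w = 30 steps
   (about 6 µm) are examined; if more than 3 pairs subtend an angle
   greater than α_global = 120°, the filament terminates. This is the
   "no curling back" filter: at cos α = 0.97 the direction random-walks
   ~14° per step, and sustained turns that would loop the filament
   produce exactly such >120° pairs. The count is maintained
   incrementally (add/evict dot products against the window), which is
   algebraically identical to re-counting the full window each step.

**Exact-length generation.** `generate_distribution` sorts the sampled
lengths longest-first and grows each one, storing the partial filament of
every failed attempt keyed by its realized step count; a later desired
length is served from storage when available. After 100 failed attempts
for a single length the parameters are declared ungenerable (a
`RuntimeError` with the literal message "input parameters cannot be
generated"). This guarantees the realized length multiset equals the
sampled one on success — the input parameters *are* the output
parameters, which is what makes library grid points trustworthy labels.

Termination is not an error but a working part of the algorithm: at the
curliest grid setting (cos α = 0.97) even unconstrained filaments fail
the curvature rule more often than not over long lengths, and the
retry-with-storage loop is what turns frequent cheap failures into
exact-length successes. Parameter combinations for which
even retries fail (long μ at low collinearity in very flat cells) are
recorded as declared failures and excluded from libraries; the validation
experiment works on the surviving grid points.

The single-attempt grower exists twice: a readable pure-Python reference
(`grow_microtubule`) and a numba-compiled kernel used by
`generate_distribution` (identical rules; ~100× faster, which is what
makes per-cell library generation interactive). Both are exercised by the
test suite; determinism is guaranteed by threading one seeded generator
through all sampling and seeding the compiled kernel from it.

## Geometry reconstruction

The 2D data are slices at half the cell height, z = Z/2. The bottom
footprint is recovered by thresholding the (background-subtracted) cell
image above zero, keeping the largest connected component and filling
holes. The 3D shape tapers from that footprint to an inner ellipse whose
centroid, orientation and axis ratio come from the footprint's second
moments and whose area is A(Z); slice k (z = k·0.2 µm) is the
signed-distance-transform interpolation between footprint and ellipse
whose area matches A(z) = 2⁻ᶻ·Area within 1 % (bisection over the mixing
weight; area is monotone in it). z is measured in µm: at the grid heights
1.2–1.6 µm the top slice keeps 33–44 % of the bottom area, matching
visible tapering, whereas slice-index units would collapse the top to
under 1 %. Slices are additionally intersected with their predecessor so
tapering (weakly decreasing areas, nested shapes) holds exactly rather
than only up to interpolation error.

Field images are segmented by nucleus-seeded watershed: nuclei are
detected in the nuclear channel (Otsu after smoothing), and the inverted
smoothed tubulin channel is flooded within the support of any tubulin
signal. Each basin is one cell; the nucleus mask is the seed within it.

The centrosome's (x, y) is the argmax of the 25 px mean-filtered tubulin
image over the vicinity of the nucleus — the nucleus dilated by 25 px
(the smoothing scale), intersected with the cell footprint — with
row-major tie-breaking. Its z is predicted by a linear regression on
(max intensity, mean intensity, intensity at (x, y)); the training data
for those coefficients come from 3D reference stacks and are supplied via
configuration. Without a model the central slice is used, consistent with
data acquired at half the cell height. A centrosome landing inside the
nucleus (e.g. the default nucleus-centroid initial guess) is relocated to
the nearest cytosolic voxel laterally within the central slice, i.e.
flush against the nuclear envelope in the imaging plane.

## Optical model

Rasterization adds one count to the voxel containing each polyline point,
so the volume total equals the number of points — intensity before optics
is exactly the amount of polymer in voxel units. The PSF is the Gaussian
confocal approximation with σ_lateral = 0.21 λ/NA and
σ_axial = 0.75 λ n/NA² (n = 1.515), defaults NA = 1.4 and λ = 565 nm
(Alexa555): σ_xy ≈ 0.085 µm, σ_z ≈ 0.33 µm. Kernels are truncated at 3σ
and normalized to unit sum; explicit σ overrides can mimic any externally
computed PSF, and recorded pinhole metadata does not alter the Gaussian
model. Convolution is same-size with zero padding; for flat cells the
axial kernel (11 slices at 3σ) exceeds the 6–8 slice stack, which is fine
because everything outside the stack is dark. The result is multiplied by
the single-microtubule intensity (estimated from the mode of nonzero
intensities in the outer 20 % of the cell where single filaments
dominate, or supplied as configuration; 1 for synthetic-only work, making
bed and library images intensity-consistent by construction). 8-bit
quantization is available but off by default; feature extraction runs on
float images.

## Features and matching

The per-image summary is a fixed 29-vector computed on the central slice
within the cell mask:

* 13 Haralick features of the within-mask gray-level co-occurrence matrix
  (distance 1, symmetric, averaged over the 4 directions, 64 gray levels
  by linear min–max binning of in-mask intensities). The GLCM is built
  in-house because co-occurrence must be restricted to pixel pairs both
  inside the mask; it reproduces `skimage.feature.graycomatrix` exactly on
  rectangular masks.
* Prewitt edge features: a 4-bin gradient-magnitude histogram with fixed
  relative edges spanning [0, 4·mean magnitude], the first and second
  circular resultants of the magnitude-weighted gradient-direction
  distribution, the edge-pixel fraction (magnitude above the in-mask
  mean) and the total gradient magnitude. Histogram bins anchored to the
  mean rather than the maximum stay well populated and do not jitter with
  the noisy per-image extreme; the circular resultants condense the
  direction histogram into its anisotropy content. A raw many-bin variant
  anchored at the per-image maximum was rejected at design time: most of
  its bins are quasi-degenerate, and under the equal-weight normalized
  distance every quasi-degenerate dimension contributes a full standard
  deviation of pure noise to each comparison, swamping the informative
  features.
* Total, mean and variance of in-mask intensity.
* Object/skeleton morphology of the image thresholded at its in-mask
  mean: object count, covered-area fraction, total skeleton length and
  mean object area. These carry most of the information that separates
  mean length from count at fixed total polymer: few long filaments make
  sparse, elongated, high-skeleton objects, many short ones make dense
  granular texture. The legacy feature sets this vector stands in for
  include exactly such object-level statistics, and without them the
  mean-length estimate is close to uninformative.
* The intensity-weighted mean distance of in-mask fluorescence to the
  centrosome (x, y), normalized by the maximum in-mask distance.

Matching z-scores every feature by the mean and standard deviation over
the query cell's own library entries (sample SD, ddof 1; the query never
influences the statistics), skips zero-variance features, and returns the
entry minimizing the Euclidean norm in z-space, ties to the smallest
entry id. Estimates are grid values only — no interpolation between grid
points.

## Synthetic data and what it does (not) show

`FixtureSpec` builds a superellipse cell footprint (default semi-axes
19 × 14 µm, exponent 2.5 — a ~38 × 28 µm spread cultured cell) with an
offset elliptical nucleus (6.5 × 5 µm, offset 3 µm), extruded through the
production tapering code at 0.2 µm lateral pixels (one growth step = one
pixel) and 0.2 µm z-steps; heights follow the parameter grid
(1.2–1.6 µm → 6–8 slices). The centrosome sits against the nuclear edge
in the central slice. Geometry construction is fully deterministic.

The emulation covers: a convex-ish tapering cell containing a nucleus, a
centrosome-anchored radial filament pattern, confocal blur, and the
intensity scale of 8-bit acquisitions. It does **not** emulate detector
or photon noise (the optical model adds none), background staining
gradients, cell-to-cell shape variability, non-centrosomal nucleation, or
microtubule dynamics over time. Passing the closed-loop tests therefore
shows the estimator is consistent for the model itself — images from the
model's own distribution are mapped back to their parameters — not that
real-microscope noise sources are handled.

`validation_experiment` mirrors the simulation-validation protocol: one
validation bed (base seed s₀) and N = 5 test libraries (test library i at
base seed s₀ + i·|grid|, so per-entry seeds never collide) on one
geometry; every bed image is matched into each test library; recovery
error is reported as per-parameter MAPE with the SD of per-image absolute
percentage errors (the ± spread is per-image, one of the two readings the
protocol allows). Grid points declared ungenerable are excluded on both
sides; at the default reduced grid (4 counts × 4 lengths ×
2 collinearities × height 1.2 µm) the cos α = 0.97 column with μ ≥ 20 µm
drops out, leaving ~20 of 32 points. Problem sizes throughout (reduced
grid, ~194 × 144 × 6 voxel geometry, 5 libraries) were chosen so the
whole experiment runs in seconds while every rung of each parameter is
still represented.

On this reduced grid a single wrong rung costs 25–100 % error for one
image, so single-digit MAPEs mean matching returns the exact generating
grid point for the large majority of queries. Collinearity MAPE is
bounded near zero by construction: only two candidates ~2.7 % apart
exist.

## Statistics

* MAPE: 100·mean(|est − true|/|true|); errors on zero truths are
  undefined and rejected.
* Coefficient of variation: sample SD over mean.
* Hotelling's T²: two-sample with pooled covariance;
  p from F = T²(n−p−1)/(p(n−2)) on (p, n−p−1) df. Cross-checked against
  an independent matrix-formula evaluation and `pingouin`.
* Box's M: standard χ² approximation with Box's scale factor,
  df = (k−1)p(p+1)/2; null p-values verified approximately uniform.
* Pairwise comparison: for each group pair (sorted names, so argument
  order is irrelevant), 100 seeded subsamples of 35 cells per group drawn
  without replacement (per-(pair, repeat) seeds derived from the master
  seed via `SeedSequence`); the pair's p is the minimum over repeats
  × repeats × number of pairs, clipped at 1. Multiplying before or after
  the minimum is the same operation, so the two readings of "minimum
  p-values after Bonferroni correction" coincide. The reported T² is from
  the repeat attaining the minimum.
* Clustering: average-linkage (UPGMA, configurable) agglomeration of the
  pairwise T² matrix used directly as a dissimilarity (it is not a metric;
  no repair is attempted), emitted as Newick.
* PCA: mean-centred SVD; first two scores and variance fractions; signs
  fixed by making each component's largest-magnitude loading positive.

## Known limitations

* The growth model is static: no dynamic instability, no non-centrosomal
  nucleation, no interaction between filaments.
* A(z) is a fixed empirical decay; cells whose area profile deviates from
  2⁻ᶻ will get biased 3D reconstructions.
* Centrosome-z regression coefficients must be supplied; the central-slice
  fallback is only correct for data acquired at half height.
* Very flat cells make long, curly filaments (low cos α, large μ)
  ungenerable; the affected grid points are reported as declared failures
  rather than silently approximated.
* The estimator returns grid values only; its resolution is the grid
  spacing, and MAPE figures are grid-dependent for that reason.
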