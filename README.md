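# mtubesim

Generative modelling of 3D microtubule distributions in single cells, and
indirect estimation of the model's parameters from a single 2D
fluorescence slice.

## The problem

The microtubule cytoskeleton of an interphase cell is a set of polymer
filaments nucleated at the centrosome and confined to the cytosol. Its
architecture is summarized well by a handful of numbers — how many
microtubules a cell has (*n*), how long they are on average (*μ*), and how
straight they grow (the collinearity cos α) — but none of these can be
read off a fluorescence image directly: individual filaments blur into
texture at confocal resolution. `mtubesim` takes the simulation-based
(indirect) route: simulate images of microtubule distributions whose
parameters you *do* know, conditioned on the query cell's own shape,
nucleus and centrosome, and report the parameters of the synthetic image
that looks most like the real one. The package is aimed at quantitative
cell biologists and image-analysis researchers who want per-cell parameter
estimates from routine 2D tubulin/DNA stains, and at modellers who need a
conditional generative model of filament patterns to build on.

## The model

* **Geometry.** From a 2D slice taken at half the cell height (z = Z/2),
  the cell's bottom footprint is recovered by thresholding; the 3D shape is
  rebuilt by distance-transform interpolation between that footprint and a
  small inner ellipse so that slice areas follow the empirical decay
  A(z) = 2⁻ᶻ·Area (z in µm). The nucleus is extruded the same way; the
  centrosome is the brightest smoothed spot near the nucleus.
* **Growth.** Each microtubule is a polyline of 0.2 µm steps starting at
  the centrosome. Lengths are Erlang-distributed with mean μ (shape k = 2
  by default). Each free step lies on the surface of a cone of aperture 2α
  around the previous direction (cos α is the collinearity). At the
  cell/nuclear boundary the collinearity requirement is relaxed within a
  local cone of half-angle α_local = 63.9°; if no allowed direction stays
  cytosolic, or if more than 3 direction pairs within a trailing 30-step
  window exceed α_global = 120°, the filament terminates. A
  retry-with-storage loop guarantees the realized length multiset equals
  the sampled one, or declares the parameters ungenerable after 100
  attempts.
* **Imaging.** Rasterized counts (one per step) are convolved with a
  Gaussian confocal PSF (NA 1.4, Alexa555 emission; σ_xy = 0.21 λ/NA,
  σ_z = 0.75 λ n/NA²) and scaled by the single-microtubule intensity.
* **Matching.** For each query cell a library of synthetic images is
  generated over a parameter grid (the default grid is 10 counts × 9 mean
  lengths × 3 collinearities × 3 heights = 810 images). A 29-dimensional
  feature vector (Haralick texture, Prewitt edge statistics, intensity,
  object/skeleton morphology, centrosome-referenced distance) is computed
  for the central slice of every library image and for the query; the
  estimate is the grid point minimizing the normalized (per-feature
  z-scored) Euclidean distance.
* **Statistics.** Populations of per-cell estimates are compared on the
  bivariate (n, μ) distribution: Box's M for covariance homogeneity,
  pairwise two-sample Hotelling's T² on balanced subsamples (35 cells,
  100 repeats) with two-level Bonferroni correction, hierarchical
  clustering of the T² matrix, PCA summaries, coefficients of variation,
  and correlations of polymerized tubulin (n·μ) with image totals.

## Worked example

`python examples/grow_and_render.py` grows a distribution and images it:

```
grew 150 microtubules from the centrosome (123, 91, 3)
realized lengths: mean 18.3 um (target mu = 20.0), min 1.0, max 85.0
raw volume holds 13838 counts (= total polyline points, one per 0.2 um step)
central slice (194 x 144 px): total intensity 1629, peak 34.7 at the centrosome
```

The realized mean tracks μ because the generator realizes the sampled
Erlang lengths exactly; the bright peak is the centrosome, where all 150
filaments originate. `python examples/validation_experiment.py` then
checks recovery accuracy end to end — images generated at known
parameters are matched into independently seeded libraries:

```
         n_mape  mu_mape  collinearity_mape
library
1          6.15     9.85               0.48
2          3.12     7.58               0.37
```

i.e. the number of microtubules is recovered with ~3–6 % mean absolute
percentage error and the mean length with ~8–10 %, on a coarse grid where
a single wrong rung costs 25–100 % error — so most queries recover the
exact generating grid point. See `examples/estimate_parameters.py` for
the single-cell estimation workflow and `examples/compare_populations.py`
for the population statistics.

A thin CLI mirrors the library for shell use:
`mtubesim geometry|library|estimate|compare|validate --help`.

## Layout

```
src/mtubesim/
  geometry.py   segmentation, 3D morphology, centrosome localisation
  growth.py     the conditional growth model (+ compiled fast path)
  imaging.py    rasterization, PSF, optical model
  library.py    parameter grids, per-cell library build/save/load
  matching.py   features, normalized distance, nearest-image estimation
  stats.py      MAPE, CV, Hotelling T², Box's M, trees, PCA, correlations
  fixtures.py   synthetic geometries and the validation experiment
  cli.py        thin click wrapper
docs/methods.md  model assumptions, parameter choices, limitations
examples/        one narrative script per capability
```
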