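"""Closed-loop indirect estimation: recover known growth parameters.

Generates a query image at known parameters (n = 250, mu = 20 µm), builds
a small per-cell library spanning a 3 x 3 parameter grid on the same
geometry, and matches the query's features against the library.  The
estimate is the grid point of the nearest synthetic image.
"""

import numpy as np

from mtubesim import (
    FixtureSpec,
    GrowthParams,
    LibraryConfig,
    ParameterGrid,
    apply_optics,
    build_library,
    central_slice,
    generate_distribution,
    make_psf,
    match,
    render,
)
from mtubesim.fixtures import bottom_masks
from mtubesim.geometry import Mask2D
from mtubesim.library import _geometry_for_height
from mtubesim.matching import compute_features

spec = FixtureSpec()
cell2d, nuc2d = bottom_masks(spec)
grid = ParameterGrid(
    n_values=(150, 250, 350),
    mu_values=(10.0, 20.0, 30.0),
    collinearity_values=(0.9961,),
    height_values=(1.2,),
)
cfg = LibraryConfig(grid=grid, base_seed=100)
library = build_library(cell2d, nuc2d, grid, 100, cfg)
print(f"library: {len(library.entries)} synthetic images on the cell's geometry")

# query generated with an independent seed at (n=250, mu=20)
geom = _geometry_for_height(cell2d, nuc2d, 1.2, spec.z_step_um, None)
mts = generate_distribution(
    geom, GrowthParams(n=250, mu_um=20.0, collinearity=0.9961),
    np.random.default_rng(777),
)
psf = make_psf(voxel_size_um=spec.voxel_size_um, z_step_um=spec.z_step_um)
query_img = central_slice(apply_optics(render(mts, geom), psf))
mask = Mask2D(geom.cell.voxels[geom.cell.n_slices // 2], spec.voxel_size_um)
query = compute_features(query_img, mask, geom.centrosome[:2])

result = match(query, library)
print(f"true parameters:      n = 250, mu = 20.0 um, cos(alpha) = 0.9961")
print(f"estimated parameters: n = {result.n}, mu = {result.mu_um} um, "
      f"cos(alpha) = {result.collinearity}")
print(f"normalized feature distance to the winning entry: {result.distance:.2f}")
# The estimator returns grid values only, so a recovery is either exact or
# lands on a neighboring rung; across many seeds roughly nine in ten
# queries come back within one grid increment (see
# examples/validation_experiment.py for the aggregate error rates).
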