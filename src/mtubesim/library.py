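"""Per-cell libraries of synthetic images over a parameter grid.

Indirect estimation needs, for every query cell, a library of synthetic
images generated on that cell's own geometry across all combinations of
the model parameters.  The default grid is the published one: 10 counts ×
9 mean lengths × 3 collinearities × 3 heights = 810 images per cell.
Each entry records the generating parameters, the per-entry seed and the
central-slice feature vector; per-feature mean/sd over entries provide the
normalization statistics for matching.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import geometry as geo
from . import imaging
from .growth import GrowthParams, generate_distribution
from .matching import FEATURE_NAMES, compute_features

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterGrid",
    "LibraryConfig",
    "LibraryEntry",
    "LibraryIndex",
    "default_grid",
    "reduced_grid",
    "build_library",
    "save_library",
    "load_library",
]

SCHEMA_VERSION = 1


@dataclass
class ParameterGrid:
    """Cartesian grid over (n, mu, collinearity, height)."""

    n_values: tuple[int, ...]
    mu_values: tuple[float, ...]
    collinearity_values: tuple[float, ...]
    height_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (
            self.n_values
            and self.mu_values
            and self.collinearity_values
            and self.height_values
        ):
            raise ValueError("all grid value lists must be nonempty")

    def __len__(self) -> int:
        return (
            len(self.n_values)
            * len(self.mu_values)
            * len(self.collinearity_values)
            * len(self.height_values)
        )

    def combinations(self):
        """Yield (height, n, mu, collinearity) in deterministic order."""
        yield from product(
            self.height_values,
            self.n_values,
            self.mu_values,
            self.collinearity_values,
        )


def default_grid() -> ParameterGrid:
    """The published parameter grid: 810 combinations."""
    return ParameterGrid(
        n_values=(5, 50, 100, 150, 200, 250, 300, 350, 400, 450),
        mu_values=(5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0),
        collinearity_values=(0.97000, 0.98466, 0.99610),
        height_values=(1.2, 1.4, 1.6),
    )


def reduced_grid() -> ParameterGrid:
    """A 32-point grid for desk-scale validation experiments."""
    return ParameterGrid(
        n_values=(50, 150, 250, 350),
        mu_values=(10.0, 20.0, 30.0, 40.0),
        collinearity_values=(0.97, 0.9961),
        height_values=(1.2,),
    )


@dataclass
class LibraryConfig:
    """Configuration shared by library generation and end-to-end estimation."""

    grid: ParameterGrid = field(default_factory=default_grid)
    base_seed: int = 0
    z_step_um: float = 0.2
    step_um: float = 0.2
    erlang_shape_k: int = 2
    single_mt_intensity: float = 1.0
    quantize_8bit: bool = False
    psf_sigma_override_um: tuple[float, float, float] | None = None
    numerical_aperture: float = 1.4
    emission_wavelength_nm: float = 565.0
    store_images: bool = False
    max_failure_fraction: float = 0.5


@dataclass
class LibraryEntry:
    """One grid point: generating parameters, seed and central-slice features."""

    params: GrowthParams
    height_um: float
    features: np.ndarray
    seed: int
    image: np.ndarray | None = None  # optional central slice, for saving
    image_path: str | None = None


@dataclass
class LibraryIndex:
    """All surviving entries of one cell's library plus normalization stats."""

    entries: list[LibraryEntry]
    norm_stats: tuple[np.ndarray, np.ndarray]  # per-feature mean, sd (ddof=1)
    feature_names: tuple[str, ...] = FEATURE_NAMES
    failures: list[dict] = field(default_factory=list)

    def feature_matrix(self) -> np.ndarray:
        return np.stack([e.features for e in self.entries])


def _compute_norm_stats(feats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = feats.mean(axis=0)
    sd = feats.std(axis=0, ddof=1) if len(feats) > 1 else np.zeros(feats.shape[1])
    return mean, sd


def _geometry_for_height(
    bottom_cell: geo.Mask2D,
    bottom_nucleus: geo.Mask2D,
    height_um: float,
    z_step_um: float,
    centrosome_xy: tuple[int, int] | None,
) -> geo.CellGeometry:
    cell3d = geo.build_volume(bottom_cell, height_um, z_step_um, "cell")
    nuc3d = geo.build_volume(bottom_nucleus, height_um, z_step_um, "nucleus")
    nuc3d = geo.Mask3D(
        nuc3d.voxels & cell3d.voxels, nuc3d.pixel_size_um, nuc3d.z_step_um
    )
    if centrosome_xy is None:
        ys, xs = np.nonzero(bottom_nucleus.voxels)
        centrosome_xy = (int(round(xs.mean())), int(round(ys.mean())))
    z_mid = cell3d.n_slices // 2
    # keep the centrosome in the imaging plane: relocate a non-cytosolic
    # guess laterally within the central slice (right at the nuclear edge)
    cyt2d = cell3d.voxels[z_mid] & ~nuc3d.voxels[z_mid]
    x, y = centrosome_xy
    if not cyt2d[y, x]:
        _, (iy, ix) = ndimage.distance_transform_edt(
            ~cyt2d, return_indices=True
        )
        y, x = int(iy[y, x]), int(ix[y, x])
    return geo.assemble_geometry(cell3d, nuc3d, (x, y, z_mid))


def build_library(
    bottom_cell: geo.Mask2D,
    bottom_nucleus: geo.Mask2D,
    grid: ParameterGrid,
    base_seed: int,
    cfg: LibraryConfig | None = None,
    centrosome_xy: tuple[int, int] | None = None,
) -> LibraryIndex:
    """Generate the synthetic-image library for one cell geometry.

    The 3D geometry is built once per height; each grid combination gets
    the deterministic seed ``base_seed + entry_index`` so generation is
    reproducible and order-independent.  Grid points whose parameters
    cannot be generated inside the geometry are logged as failures and
    excluded from the index; more than ``max_failure_fraction`` failures
    aborts (the geometry cannot support the grid).
    """
    cfg = cfg or LibraryConfig(grid=grid, base_seed=base_seed)
    psf = imaging.make_psf(
        cfg.numerical_aperture,
        cfg.emission_wavelength_nm,
        bottom_cell.pixel_size_um,
        cfg.z_step_um,
        cfg.psf_sigma_override_um,
    )
    geoms: dict[float, geo.CellGeometry] = {}
    for h in grid.height_values:
        geoms[h] = _geometry_for_height(
            bottom_cell, bottom_nucleus, h, cfg.z_step_um, centrosome_xy
        )

    entries: list[LibraryEntry] = []
    failures: list[dict] = []
    for idx, (h, n, mu, ca) in enumerate(grid.combinations()):
        g = geoms[h]
        params = GrowthParams(
            n=n, mu_um=mu, collinearity=ca,
            erlang_shape_k=cfg.erlang_shape_k, step_um=cfg.step_um,
        )
        seed = base_seed + idx
        rng = np.random.default_rng(seed)
        try:
            mts = generate_distribution(g, params, rng)
        except RuntimeError as exc:
            failures.append(
                {"height": h, "n": n, "mu": mu, "collinearity": ca,
                 "seed": seed, "error": str(exc)}
            )
            continue
        vol = imaging.render(mts, g)
        vol = imaging.apply_optics(
            vol, psf, cfg.single_mt_intensity, cfg.quantize_8bit
        )
        sl = imaging.central_slice(vol)
        mask_mid = geo.Mask2D(
            g.cell.voxels[g.cell.n_slices // 2], g.voxel_size_um
        )
        feats = compute_features(sl, mask_mid, g.centrosome[:2])
        entries.append(
            LibraryEntry(
                params=params,
                height_um=h,
                features=feats.values,
                seed=seed,
                image=sl.pixels if cfg.store_images else None,
            )
        )
    if len(failures) > cfg.max_failure_fraction * len(grid):
        raise RuntimeError(
            f"{len(failures)}/{len(grid)} grid points failed; "
            "geometry cannot support the grid"
        )
    if failures:
        logger.warning("%d grid points could not be generated", len(failures))
    feats = np.stack([e.features for e in entries])
    return LibraryIndex(entries=entries, norm_stats=_compute_norm_stats(feats),
                        failures=failures)


def save_library(index: LibraryIndex, path: str | Path) -> None:
    """Persist a library: JSON index + norm stats, CSV features, TIFF images."""
    import tifffile

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    records = []
    for i, e in enumerate(index.entries):
        image_path = None
        if e.image is not None:
            image_path = f"images/entry_{i:05d}.tif"
            (path / "images").mkdir(exist_ok=True)
            tifffile.imwrite(path / image_path, e.image.astype(np.float32))
        records.append(
            {
                "entry_id": i,
                "n": e.params.n,
                "mu_um": e.params.mu_um,
                "collinearity": e.params.collinearity,
                "erlang_shape_k": e.params.erlang_shape_k,
                "step_um": e.params.step_um,
                "height_um": e.height_um,
                "seed": e.seed,
                "image_path": image_path,
            }
        )
    mean, sd = index.norm_stats
    meta = {
        "schema_version": SCHEMA_VERSION,
        "feature_names": list(index.feature_names),
        "norm_mean": mean.tolist(),
        "norm_sd": sd.tolist(),
        "entries": records,
        "failures": index.failures,
    }
    (path / "index.json").write_text(json.dumps(meta, indent=1))
    df = pd.DataFrame(index.feature_matrix(), columns=list(index.feature_names))
    df.insert(0, "entry_id", range(len(index.entries)))
    df.to_csv(path / "features.csv", index=False)


def load_library(path: str | Path) -> LibraryIndex:
    """Load a saved library; exact round-trip of features, params and stats."""
    path = Path(path)
    meta = json.loads((path / "index.json").read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"library schema version {meta.get('schema_version')} "
            f"incompatible with code version {SCHEMA_VERSION}"
        )
    df = pd.read_csv(path / "features.csv")
    names = tuple(meta["feature_names"])
    entries = []
    for rec in meta["entries"]:
        image = None
        if rec["image_path"] is not None:
            import tifffile

            img_file = path / rec["image_path"]
            if not img_file.exists():
                raise FileNotFoundError(f"missing library image: {img_file}")
            image = tifffile.imread(img_file).astype(float)
        feats = df.loc[df.entry_id == rec["entry_id"], list(names)].to_numpy()[0]
        entries.append(
            LibraryEntry(
                params=GrowthParams(
                    n=rec["n"],
                    mu_um=rec["mu_um"],
                    collinearity=rec["collinearity"],
                    erlang_shape_k=rec["erlang_shape_k"],
                    step_um=rec["step_um"],
                ),
                height_um=rec["height_um"],
                features=feats,
                seed=rec["seed"],
                image=image,
                image_path=rec["image_path"],
            )
        )
    return LibraryIndex(
        entries=entries,
        norm_stats=(np.array(meta["norm_mean"]), np.array(meta["norm_sd"])),
        feature_names=names,
        failures=meta["failures"],
    )
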