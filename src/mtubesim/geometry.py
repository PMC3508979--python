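"""Cell geometry: segmentation, approximate 3D morphology from a single slice,
and centrosome localisation.

Adherent cultured cells are flat (1-2 µm tall) and taper from a broad bottom
footprint to a small apex above the nucleus.  A single in-focus 2D slice taken
at half the cell height carries enough out-of-focus light to recover the bottom
footprint by thresholding; the 3D shape is then reconstructed by interpolating,
slice by slice, between that footprint and a small inner ellipse so that the
slice areas follow the empirical exponential decay ``A(z) = 2^(-z) * Area``
(z in µm above the bottom slice).

Conventions
-----------
2D arrays are indexed ``[row (y), col (x)]``; 3D volumes ``[z, y, x]``.
Point tuples are ``(x, y)`` or ``(x, y, z)`` in 0-based voxel indices.
Continuous positions are in µm; a position maps to the voxel ``floor(p / size)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, segmentation
from skimage.draw import ellipse as draw_ellipse
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "Image2D",
    "Mask2D",
    "Mask3D",
    "CellGeometry",
    "CentrosomeZModel",
    "segment_field",
    "bottom_shape",
    "area_profile",
    "interpolate_shape",
    "build_volume",
    "detect_centrosome_xy",
    "estimate_centrosome_z",
    "assemble_geometry",
]


@dataclass
class Image2D:
    """A single-channel 2D fluorescence image with physical pixel size."""

    pixels: np.ndarray
    pixel_size_um: float = 0.2

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("Image2D requires a 2D array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("intensities must be finite and nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class Mask2D:
    """Binary 2D mask with physical pixel size."""

    voxels: np.ndarray
    pixel_size_um: float = 0.2

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 2:
            raise ValueError("Mask2D requires a 2D array")

    @property
    def area_px(self) -> int:
        return int(self.voxels.sum())


@dataclass
class Mask3D:
    """Binary 3D mask, ``voxels[z, y, x]``, with anisotropic voxel size."""

    voxels: np.ndarray
    pixel_size_um: float = 0.2
    z_step_um: float = 0.2

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("Mask3D requires a 3D array")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def slice_areas(self) -> np.ndarray:
        return self.voxels.sum(axis=(1, 2))


@dataclass
class CellGeometry:
    """3D cell and nuclear masks plus the centrosome, the context for growth.

    The centrosome is the microtubule organising centre: every simulated
    filament is nucleated there.  ``height_um`` is the symbol Z; the imaging
    plane of the 2D data sits at z = Z/2.
    """

    cell: Mask3D
    nucleus: Mask3D
    centrosome: tuple[int, int, int]  # (x, y, z)
    voxel_size_um: float
    height_um: float

    def __post_init__(self) -> None:
        if self.cell.voxels.shape != self.nucleus.voxels.shape:
            raise ValueError("cell and nucleus masks must share a shape")
        if np.any(self.nucleus.voxels & ~self.cell.voxels):
            raise ValueError("nucleus must be contained in the cell")
        x, y, z = self.centrosome
        if not self.cytosol[z, y, x]:
            raise ValueError("centrosome must lie in the cytosol")

    @property
    def cytosol(self) -> np.ndarray:
        return self.cell.voxels & ~self.nucleus.voxels

    @property
    def z_step_um(self) -> float:
        return self.cell.z_step_um

    def centrosome_position_um(self) -> np.ndarray:
        """Continuous centrosome position (µm) at the voxel centre, (x, y, z)."""
        x, y, z = self.centrosome
        s, h = self.voxel_size_um, self.cell.z_step_um
        return np.array([(x + 0.5) * s, (y + 0.5) * s, (z + 0.5) * h])


@dataclass
class CentrosomeZModel:
    """Linear-regression model for the centrosome z slice.

    Predictors: max in-cell intensity, mean in-cell intensity, and the
    intensity at the detected (x, y) position.  Coefficients come from
    training on 3D reference stacks and are supplied through configuration.
    """

    coefficients: tuple[float, float, float, float]  # intercept + 3 slopes

    def __post_init__(self) -> None:
        if len(self.coefficients) != 4 or not np.all(np.isfinite(self.coefficients)):
            raise ValueError("need 4 finite coefficients")


def segment_field(tubulin: Image2D, nuclei: Image2D) -> list[tuple[Mask2D, Mask2D]]:
    """Segment a field image into single cells by nucleus-seeded watershed.

    The nuclear channel provides one seed per nucleus; the watershed floods
    the (inverted, smoothed) tubulin channel so each basin is one cell.
    Returns one ``(cell, nucleus)`` mask pair per seed; regions are disjoint
    and each nucleus lies inside its own cell region.
    """
    if tubulin.shape != nuclei.shape:
        raise ValueError("channels must share a shape")
    if tubulin.pixel_size_um != nuclei.pixel_size_um:
        raise ValueError("channels must share a pixel size")

    nuc = ndimage.uniform_filter(nuclei.pixels, size=5)
    nuc_mask = nuc > _auto_threshold(nuc)
    lab, n_lab = ndimage.label(nuc_mask)
    if n_lab:
        sizes = ndimage.sum_labels(nuc_mask, lab, index=np.arange(1, n_lab + 1))
        nuc_mask = np.isin(lab, 1 + np.nonzero(sizes >= 9)[0])
    seeds, n_seeds = ndimage.label(nuc_mask)
    if n_seeds == 0:
        warnings.warn("no nuclei detected; returning empty segmentation")
        return []

    tub = ndimage.uniform_filter(tubulin.pixels, size=5)
    # cell support: any tubulin signal at all (cytoplasm is dim but nonzero)
    foreground = (tubulin.pixels > 0) | nuc_mask
    foreground = ndimage.binary_fill_holes(foreground)
    labels = segmentation.watershed(-tub, markers=seeds, mask=foreground)

    out: list[tuple[Mask2D, Mask2D]] = []
    for lab in range(1, n_seeds + 1):
        region = labels == lab
        if not region.any():
            continue
        out.append(
            (
                Mask2D(region, tubulin.pixel_size_um),
                Mask2D(region & (seeds == lab), tubulin.pixel_size_um),
            )
        )
    return out


def _auto_threshold(img: np.ndarray) -> float:
    """Otsu threshold, falling back to 0 for near-binary or empty images."""
    vals = img[img > 0]
    if vals.size == 0 or np.ptp(vals) == 0:
        return 0.0
    return float(threshold_otsu(img))


def bottom_shape(tubulin_cell: Image2D, threshold: float = 0.0) -> Mask2D:
    """Recover the bottom footprint of a segmented cell by thresholding.

    Out-of-focus light from the bottom of the cell is visible in the central
    slice, so pixels above the (default zero) background threshold outline
    the bottom shape.  The largest connected component is kept, holes filled.
    """
    raw = tubulin_cell.pixels > threshold
    if not raw.any():
        raise ValueError("empty cell: no pixels above threshold")
    labels, n = ndimage.label(raw)
    if n > 1:
        sizes = ndimage.sum_labels(raw, labels, index=np.arange(1, n + 1))
        raw = labels == (1 + int(np.argmax(sizes)))
    filled = ndimage.binary_fill_holes(raw)
    return Mask2D(filled, tubulin_cell.pixel_size_um)


def area_profile(bottom_area_px: float, z_um: float) -> float:
    """Slice area (px) at height ``z_um`` above the bottom: ``2^(-z) * Area``."""
    if bottom_area_px <= 0:
        raise ValueError("bottom area must be positive")
    if z_um < 0:
        raise ValueError("z must be nonnegative")
    return float(2.0 ** (-z_um) * bottom_area_px)


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance map, negative inside the mask."""
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return outside - inside


def interpolate_shape(
    bottom: Mask2D, top: Mask2D, target_area_px: float, tol: float = 0.01
) -> Mask2D:
    """Interpolate between two nested masks to a target pixel area.

    A convex combination of the two signed distance transforms is thresholded
    at zero; the mixing weight t is found by bisection (area is monotone in t)
    until the area matches ``target_area_px`` within ``tol`` (relative).
    t = 0 returns ``bottom`` exactly, t = 1 returns ``top`` exactly.
    """
    a_bot, a_top = bottom.area_px, top.area_px
    if not (a_top <= target_area_px <= a_bot):
        raise ValueError(
            f"target area {target_area_px} outside [{a_top}, {a_bot}]"
        )
    if target_area_px == a_bot:
        return Mask2D(bottom.voxels.copy(), bottom.pixel_size_um)
    if target_area_px == a_top:
        return Mask2D(top.voxels.copy(), top.pixel_size_um)

    sd_bot = _signed_distance(bottom.voxels)
    sd_top = _signed_distance(top.voxels)

    def mask_at(t: float) -> np.ndarray:
        return ((1.0 - t) * sd_bot + t * sd_top) < 0

    lo, hi = 0.0, 1.0
    best = mask_at(0.5)
    for _ in range(60):
        t = 0.5 * (lo + hi)
        m = mask_at(t)
        area = m.sum()
        if abs(area - target_area_px) <= tol * target_area_px:
            best = m
            break
        if area > target_area_px:
            lo = t
        else:
            hi = t
        best = m
    return Mask2D(best, bottom.pixel_size_um)


def _inner_ellipse(bottom: Mask2D, area_px: float) -> Mask2D:
    """Ellipse with the bottom shape's centroid, orientation and axis ratio,
    scaled to ``area_px`` and clipped to the bottom mask."""
    props = measure.regionprops(bottom.voxels.astype(np.uint8))[0]
    cy, cx = props.centroid
    major = max(props.axis_major_length, 2.0)
    minor = max(props.axis_minor_length, 2.0)
    ratio = minor / major
    # pi * a * b = area with b = ratio * a
    a = np.sqrt(area_px / (np.pi * ratio))
    b = ratio * a
    canvas = np.zeros_like(bottom.voxels)
    # regionprops orientation: angle between major axis and the row (y) axis
    rr, cc = draw_ellipse(
        cy, cx, b, a, shape=canvas.shape, rotation=-props.orientation
    )
    canvas[rr, cc] = True
    canvas &= bottom.voxels
    if not canvas.any():
        # degenerate tiny ellipse: fall back to the pixel nearest the centroid
        canvas[int(round(cy)), int(round(cx))] = True
        canvas &= bottom.voxels
    return Mask2D(canvas, bottom.pixel_size_um)


def build_volume(
    bottom: Mask2D,
    height_um: float,
    z_step_um: float = 0.2,
    channel: str = "cell",
) -> Mask3D:
    """Extrude a bottom footprint into a tapering 3D mask.

    Slice k (z = k * z_step) is the distance-transform interpolation between
    the bottom shape and an inner ellipse (same centroid, orientation and
    axis ratio; area = A(height)), with slice areas following
    ``A(z) = 2^(-z) * Area``.  Slices are nested, so areas weakly decrease.
    """
    if channel not in ("cell", "nucleus"):
        raise ValueError("channel must be 'cell' or 'nucleus'")
    n_slices = round(height_um / z_step_um)
    if n_slices < 1 or abs(n_slices * z_step_um - height_um) > 1e-9:
        raise ValueError("height must be a positive multiple of the z step")

    a_bot = bottom.area_px
    top_area = area_profile(a_bot, height_um)
    if top_area < 1.0:
        raise ValueError("area profile drops below one pixel; height too large")
    if n_slices == 1:
        return Mask3D(bottom.voxels[None], bottom.pixel_size_um, z_step_um)

    top = _inner_ellipse(bottom, top_area)
    slices = np.empty((n_slices,) + bottom.voxels.shape, dtype=bool)
    prev = bottom.voxels
    for k in range(n_slices):
        target = max(area_profile(a_bot, k * z_step_um), top.area_px)
        target = min(target, a_bot)
        m = interpolate_shape(bottom, top, target).voxels
        m &= prev  # enforce tapering (nesting) exactly
        slices[k] = m
        prev = m
    return Mask3D(slices, bottom.pixel_size_um, z_step_um)


def detect_centrosome_xy(
    tubulin_cell: Image2D,
    nucleus: Mask2D,
    smooth_px: int = 25,
    vicinity_px: int = 25,
) -> tuple[int, int]:
    """Locate the centrosome (x, y) as the brightest smoothed pixel near the
    nucleus.

    The tubulin channel is mean-filtered with a ``smooth_px`` square window
    and the argmax is taken over the vicinity region: the nucleus dilated by
    ``vicinity_px`` pixels, intersected with the cell footprint.  Ties break
    to the first pixel in row-major order.
    """
    if not nucleus.voxels.any():
        raise ValueError("empty nucleus mask")
    cell = bottom_shape(tubulin_cell).voxels
    vicinity = morphology.dilation(
        nucleus.voxels, morphology.disk(vicinity_px)
    ) & cell
    if not vicinity.any():
        raise ValueError("vicinity region is empty")
    smoothed = ndimage.uniform_filter(tubulin_cell.pixels, size=smooth_px)
    masked = np.where(vicinity, smoothed, -np.inf)
    flat = int(np.argmax(masked))  # first occurrence, row-major
    y, x = np.unravel_index(flat, masked.shape)
    return int(x), int(y)


def estimate_centrosome_z(
    tubulin_cell: Image2D,
    xy: tuple[int, int],
    model: CentrosomeZModel | None,
    n_slices: int,
) -> int:
    """Estimate the centrosome z slice index from 2D intensity statistics.

    Uses the linear model on (max intensity, mean intensity, intensity at the
    centrosome (x, y)); the prediction is rounded and clipped into range.
    Without a model the central slice is returned, matching data acquired at
    half the cell height.
    """
    if n_slices < 1:
        raise ValueError("need at least one slice")
    if model is None:
        return n_slices // 2
    x, y = xy
    c0, c1, c2, c3 = model.coefficients
    px = tubulin_cell.pixels
    pred = c0 + c1 * px.max() + c2 * px.mean() + c3 * px[y, x]
    return int(np.clip(round(pred), 0, n_slices - 1))


def assemble_geometry(
    cell: Mask3D, nucleus: Mask3D, centrosome: tuple[int, int, int]
) -> CellGeometry:
    """Validate masks and centrosome into a :class:`CellGeometry`.

    A centrosome falling inside the nucleus or outside the cell is moved to
    the nearest cytosolic voxel (Euclidean distance in µm, logged).
    """
    if np.any(nucleus.voxels & ~cell.voxels):
        raise ValueError("nucleus must be contained in the cell")
    cytosol = cell.voxels & ~nucleus.voxels
    if not cytosol.any():
        raise ValueError("empty cytosol")
    x, y, z = centrosome
    in_bounds = (
        0 <= z < cytosol.shape[0]
        and 0 <= y < cytosol.shape[1]
        and 0 <= x < cytosol.shape[2]
    )
    if not (in_bounds and cytosol[z, y, x]):
        sampling = (cell.z_step_um, cell.pixel_size_um, cell.pixel_size_um)
        _, (iz, iy, ix) = ndimage.distance_transform_edt(
            ~cytosol, sampling=sampling, return_indices=True
        )
        zc = int(np.clip(z, 0, cytosol.shape[0] - 1))
        yc = int(np.clip(y, 0, cytosol.shape[1] - 1))
        xc = int(np.clip(x, 0, cytosol.shape[2] - 1))
        z2, y2, x2 = int(iz[zc, yc, xc]), int(iy[zc, yc, xc]), int(ix[zc, yc, xc])
        logger.info(
            "centrosome %s not cytosolic; relocated to %s", (x, y, z), (x2, y2, z2)
        )
        x, y, z = x2, y2, z2
    height_um = cell.z_step_um * cell.n_slices
    return CellGeometry(
        cell=cell,
        nucleus=nucleus,
        centrosome=(x, y, z),
        voxel_size_um=cell.pixel_size_um,
        height_um=height_um,
    )
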