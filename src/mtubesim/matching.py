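"""2D image features and indirect parameter estimation by library matching.

The estimator never fits the growth model directly: it compares a numeric
summary (feature vector) of the query slice against the summaries of a
per-cell library of synthetic images spanning a parameter grid, and reports
the grid point of the nearest library image under the normalized Euclidean
distance (per-feature z-scoring by the library's own statistics).

The feature vector (35 values, fixed order) comprises:

* 13 Haralick texture features from a within-mask gray-level co-occurrence
  matrix (distance 1, average of the 4 directions, 64 gray levels);
* edge features from the Prewitt operator: a 4-bin normalized histogram of
  gradient magnitude with fixed relative bin edges (spanning zero to four
  times the mean in-mask magnitude, so every bin is well populated and the
  edges do not jitter with the noisy per-image maximum), the first and
  second circular resultants of the magnitude-weighted gradient-direction
  distribution (anisotropy summaries of the direction histogram), the
  edge-pixel fraction (pixels above the mean in-mask magnitude) and the
  total gradient magnitude;
* total, mean and variance of in-mask intensity;
* object/skeleton morphology of the image thresholded at its in-mask mean
  intensity: object count, covered-area fraction, total skeleton length and
  mean object area — the filament-structure statistics that carry most of
  the information about mean filament length;
* the intensity-weighted mean distance to the centrosome (x, y), normalized
  by the maximum in-mask distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import ndimage

from .geometry import Image2D, Mask2D

if TYPE_CHECKING:  # pragma: no cover
    from .library import LibraryIndex

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "HARALICK_NAMES",
    "masked_glcm",
    "compute_features",
    "normalized_distance",
    "match",
    "MatchResult",
    "estimate_cell",
]

N_GRAY_LEVELS = 64
_EPS = 1e-12

HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "info_correlation_1",
    "info_correlation_2",
)

FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"haralick_{n}" for n in HARALICK_NAMES)
    + tuple(f"grad_mag_hist_{i}" for i in range(4))
    + ("grad_dir_resultant_1", "grad_dir_resultant_2")
    + ("edge_fraction", "total_gradient")
    + ("total_intensity", "mean_intensity", "var_intensity")
    + ("obj_count", "obj_coverage", "skeleton_length", "obj_area_mean")
    + ("centrosome_distance",)
)


@dataclass
class FeatureVector:
    """Fixed-order named feature values."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("values must match the feature-name list")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("features must be finite")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


@dataclass
class MatchResult:
    """Parameter estimate from the nearest library image."""

    n: int
    mu_um: float
    collinearity: float
    height_um: float
    distance: float
    entry_id: int


def _quantize(img: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Linear min-max quantization of in-mask intensities to integer levels;
    out-of-mask pixels are marked -1."""
    out = np.full(img.shape, -1, dtype=np.int64)
    vals = img[mask]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        q = np.floor((img - lo) / (hi - lo) * levels).astype(np.int64)
        out[mask] = np.clip(q[mask], 0, levels - 1)
    else:
        out[mask] = 0
    return out


def masked_glcm(
    img: np.ndarray, mask: np.ndarray, levels: int = N_GRAY_LEVELS
) -> np.ndarray:
    """Symmetric gray-level co-occurrence matrix restricted to a mask.

    Distance-1 offsets in the 4 standard directions (E, S, SE, SW); only
    pixel pairs with both members inside the mask are counted.  Returns the
    normalized average of the four per-direction matrices.
    """
    q = _quantize(img, mask, levels)
    acc = np.zeros((levels, levels))
    offsets = ((0, 1), (1, 0), (1, 1), (1, -1))
    for dy, dx in offsets:
        h, w = q.shape
        y0, y1 = max(0, -dy), min(h, h - dy)
        x0, x1 = max(0, -dx), min(w, w - dx)
        a = q[y0:y1, x0:x1]
        b = q[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
        valid = (a >= 0) & (b >= 0)
        if not valid.any():
            continue
        pairs = a[valid] * levels + b[valid]
        counts = np.bincount(pairs, minlength=levels * levels).reshape(
            levels, levels
        ).astype(float)
        counts = counts + counts.T  # symmetric
        if counts.sum() > 0:
            acc += counts / counts.sum()
    return acc / len(offsets)


def haralick_features(glcm: np.ndarray) -> np.ndarray:
    """The 13 classic texture features of a normalized co-occurrence matrix."""
    p = glcm / max(glcm.sum(), _EPS)
    ng = p.shape[0]
    i = np.arange(ng, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sd_x = math.sqrt(max(((i - mu_x) ** 2 * px).sum(), 0.0))
    sd_y = math.sqrt(max(((i - mu_y) ** 2 * py).sum(), 0.0))

    ii, jj = np.meshgrid(i, i, indexing="ij")
    # p_{x+y} and p_{x-y}
    psum = np.bincount((ii + jj).astype(int).ravel(), weights=p.ravel(),
                       minlength=2 * ng - 1)
    pdiff = np.bincount(np.abs(ii - jj).astype(int).ravel(), weights=p.ravel(),
                        minlength=ng)
    k_sum = np.arange(2 * ng - 1, dtype=float)
    k_diff = np.arange(ng, dtype=float)

    asm = (p**2).sum()
    contrast = (k_diff**2 * pdiff).sum()
    if sd_x > 0 and sd_y > 0:
        correlation = ((ii * jj * p).sum() - mu_x * mu_y) / (sd_x * sd_y)
    else:
        correlation = 0.0
    variance = ((ii - mu_x) ** 2 * p).sum()
    idm = (p / (1.0 + (ii - jj) ** 2)).sum()
    sum_avg = (k_sum * psum).sum()
    sum_var = ((k_sum - sum_avg) ** 2 * psum).sum()
    sum_ent = -(psum * np.log(psum + _EPS)).sum()
    entropy = -(p * np.log(p + _EPS)).sum()
    diff_avg = (k_diff * pdiff).sum()
    diff_var = ((k_diff - diff_avg) ** 2 * pdiff).sum()
    diff_ent = -(pdiff * np.log(pdiff + _EPS)).sum()

    hxy = entropy
    pxy = np.outer(px, py)
    hxy1 = -(p * np.log(pxy + _EPS)).sum()
    hxy2 = -(pxy * np.log(pxy + _EPS)).sum()
    hx = -(px * np.log(px + _EPS)).sum()
    hy = -(py * np.log(py + _EPS)).sum()
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))

    return np.array([
        asm, contrast, correlation, variance, idm, sum_avg, sum_var,
        sum_ent, entropy, diff_var, diff_ent, imc1, imc2,
    ])


def _edge_features(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Prewitt gradient-magnitude histogram, direction anisotropy and
    summary statistics within the mask.

    A flat image yields all magnitude-histogram mass in the first bin and
    zero resultants, fraction and total.
    """
    gx = ndimage.prewitt(img, axis=1, mode="nearest")
    gy = ndimage.prewitt(img, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)[mask]
    theta = np.arctan2(gy, gx)[mask]

    mean_mag = float(mag.mean())
    if mean_mag > 0:
        mag_hist, _ = np.histogram(
            np.minimum(mag, 4.0 * mean_mag * (1 - 1e-12)),
            bins=4,
            range=(0.0, 4.0 * mean_mag),
        )
        mag_hist = mag_hist / mag_hist.sum()
        w = mag / mag.sum()
        z1 = (w * np.exp(1j * theta)).sum()
        z2 = (w * np.exp(2j * theta)).sum()
        resultants = np.array([np.abs(z1), np.abs(z2)])
        edge_fraction = float((mag > mean_mag).mean())
    else:
        mag_hist = np.zeros(4)
        mag_hist[0] = 1.0
        resultants = np.zeros(2)
        edge_fraction = 0.0
    return np.concatenate(
        [mag_hist, resultants, [edge_fraction, float(mag.sum())]]
    )


def _object_features(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Filament-morphology statistics of the image binarized at its in-mask
    mean intensity: object count, coverage fraction, total skeleton length
    and mean object area.  A constant image yields all zeros."""
    from skimage.morphology import skeletonize

    thr = img[mask].mean()
    binary = (img > thr) & mask
    if not binary.any():
        return np.zeros(4)
    _, n_obj = ndimage.label(binary)
    area = int(binary.sum())
    skel = int(skeletonize(binary).sum())
    return np.array([n_obj, area / mask.sum(), skel, area / n_obj])


def compute_features(
    img: Image2D, mask: Mask2D, centrosome_xy: tuple[int, int]
) -> FeatureVector:
    """Compute the full 29-feature vector of a slice within a cell mask."""
    m = mask.voxels
    if not m.any():
        raise ValueError("empty mask")
    px = img.pixels

    texture = haralick_features(masked_glcm(px, m))
    edges = _edge_features(px, m)

    vals = px[m]
    intensity = np.array([vals.sum(), vals.mean(), vals.var()])
    objects = _object_features(px, m)

    cx, cy = centrosome_xy
    yy, xx = np.nonzero(m)
    d = np.hypot(xx - cx, yy - cy)
    d_max = d.max()
    w = px[m]
    total = w.sum()
    mean_d = (w * d).sum() / total if total > 0 else d.mean()
    centro = np.array([mean_d / d_max if d_max > 0 else 0.0])

    return FeatureVector(
        np.concatenate([texture, edges, intensity, objects, centro])
    )


def normalized_distance(
    a: FeatureVector, b: FeatureVector, norm_stats: tuple[np.ndarray, np.ndarray]
) -> float:
    """Normalized Euclidean distance: z-score each feature by the library
    standard deviation, then take the Euclidean norm.  Features whose
    library standard deviation is zero carry no information and are skipped.
    """
    if a.names != b.names:
        raise ValueError("feature vectors have mismatched names")
    _, sd = norm_stats
    valid = sd > 0
    diff = (a.values[valid] - b.values[valid]) / sd[valid]
    return float(np.sqrt((diff**2).sum()))


def match(query: FeatureVector, lib: "LibraryIndex") -> MatchResult:
    """Nearest-library-image parameter estimate.

    Distances are computed against every library entry; ties break to the
    smallest entry id.  The winning entry's generation parameters are the
    estimate.
    """
    if len(lib.entries) == 0:
        raise ValueError("empty library")
    feats = lib.feature_matrix()
    mean, sd = lib.norm_stats
    valid = sd > 0
    z = (feats[:, valid] - query.values[valid]) / sd[valid]
    dists = np.sqrt((z**2).sum(axis=1))
    best = int(np.argmin(dists))  # first minimum = smallest entry id
    e = lib.entries[best]
    return MatchResult(
        n=e.params.n,
        mu_um=e.params.mu_um,
        collinearity=e.params.collinearity,
        height_um=e.height_um,
        distance=float(dists[best]),
        entry_id=best,
    )


def estimate_cell(tubulin: Image2D, nuclei: Image2D, cfg) -> MatchResult:
    """End-to-end estimation for one field: segment, build the per-cell
    library, and match the query's central-slice features.

    ``cfg`` is a :class:`mtubesim.library.LibraryConfig`.  The largest
    segmented cell is analysed.  The query's own feature values never enter
    the library normalization statistics.
    """
    from . import geometry as geo
    from .library import build_library

    cells = geo.segment_field(tubulin, nuclei)
    if not cells:
        raise ValueError("no cells segmented from the field")
    cell2d, nuc2d = max(cells, key=lambda cn: cn[0].area_px)

    tub_cell = Image2D(
        np.where(cell2d.voxels, tubulin.pixels, 0.0), tubulin.pixel_size_um
    )
    bottom_cell = geo.bottom_shape(tub_cell)
    nuc_cell = Image2D(
        np.where(nuc2d.voxels, nuclei.pixels, 0.0), nuclei.pixel_size_um
    )
    bottom_nuc = geo.bottom_shape(nuc_cell)
    centrosome_xy = geo.detect_centrosome_xy(tub_cell, bottom_nuc)

    lib = build_library(
        bottom_cell, bottom_nuc, cfg.grid, cfg.base_seed, cfg,
        centrosome_xy=centrosome_xy,
    )
    query = compute_features(tub_cell, cell2d, centrosome_xy)
    return match(query, lib)
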