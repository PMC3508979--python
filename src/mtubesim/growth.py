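"""Conditional growth model for microtubule distributions.

Microtubules are modelled as 3D polylines of fixed 0.2 µm steps, all
nucleated at the centrosome and confined to the cytosol (cell minus
nucleus).  Each free step lands on the lateral surface of a cone around
the previous direction whose aperture is set by the collinearity cos(α):
higher collinearity means straighter filaments.  Lengths are drawn from an
Erlang distribution with mean mu (a single free parameter besides the
shape), and two termination rules keep the filaments realistic:

* local rebound rule — when a cone step would leave the cytosol, the
  collinearity requirement is relaxed and candidate directions are drawn
  inside a wider cone of half-angle α_local (63.9°, cos 0.44); if no
  candidate stays inside, growth terminates;
* global curvature rule — if within a trailing window of 30 steps more
  than 3 pairwise step-direction angles exceed α_global (120°), growth
  terminates.

The distribution generator guarantees that the realized length multiset
equals the sampled one by retrying failed filaments (storing off-length
partials for reuse) up to 100 times before declaring the parameters
ungenerable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .geometry import CellGeometry

__all__ = [
    "GrowthParams",
    "Microtubule",
    "GrowthFailure",
    "sample_lengths",
    "step_direction",
    "window_check",
    "grow_microtubule",
    "generate_distribution",
]

_FIRST_DIR_ATTEMPTS = 1000


@dataclass
class GrowthParams:
    """Parameters of the growth model.

    ``n``, ``mu_um`` and ``collinearity`` are the three estimated
    parameters; the remainder are model constants.
    """

    n: int
    mu_um: float
    collinearity: float
    erlang_shape_k: int = 2
    step_um: float = 0.2
    cos_alpha_local: float = 0.44  # alpha_local = 63.9 degrees
    alpha_global_deg: float = 120.0
    window_steps: int = 30
    max_bad_pairs: int = 3
    max_retries: int = 100
    rebound_candidates: int = 50

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        if self.mu_um <= 0:
            raise ValueError("mu_um must be positive")
        if not (0 < self.collinearity <= 1):
            raise ValueError("collinearity must be in (0, 1]")
        if self.erlang_shape_k < 1:
            raise ValueError("erlang_shape_k must be >= 1")
        if self.step_um <= 0:
            raise ValueError("step_um must be positive")


@dataclass
class Microtubule:
    """Ordered polyline of 3D points (µm), consecutive points one step apart."""

    points: np.ndarray  # (m, 3) float, columns (x, y, z)
    step_um: float = 0.2

    @property
    def length_um(self) -> float:
        return (len(self.points) - 1) * self.step_um

    @property
    def n_steps(self) -> int:
        return len(self.points) - 1


@dataclass
class GrowthFailure:
    """Early termination: the partial filament and its realized length."""

    partial: Microtubule

    @property
    def realized_length_um(self) -> float:
        return self.partial.length_um


def sample_lengths(
    n: int, mu_um: float, k: int, rng: np.random.Generator, step_um: float = 0.2
) -> list[float]:
    """Draw n microtubule lengths from Erlang(shape k, mean mu).

    The Erlang (integer-shape gamma) has a single free parameter once the
    shape is fixed; rate = k / mu gives mean exactly mu.  Each draw is
    rounded to the nearest positive multiple of the step length so that the
    generator's desired-length bookkeeping is exact.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n == 0:
        return []
    raw = rng.gamma(shape=k, scale=mu_um / k, size=n)
    steps = np.maximum(1, np.rint(raw / step_um).astype(int))
    return [float(s * step_um) for s in steps]


def _orthonormal_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane perpendicular to unit vector d."""
    # pick the coordinate axis least aligned with d for stability
    a = np.zeros(3)
    a[np.argmin(np.abs(d))] = 1.0
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def step_direction(
    prev_dir: np.ndarray, cos_alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """Next step direction on the lateral surface of the collinearity cone.

    The returned unit vector makes an angle arccos(cos_alpha) with
    ``prev_dir`` exactly; the azimuth around the cone axis is uniform.
    """
    d = np.asarray(prev_dir, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("previous direction must be nonzero")
    if not (0 < cos_alpha <= 1):
        raise ValueError("cos_alpha must be in (0, 1]")
    d = d / norm
    if cos_alpha == 1.0:
        return d
    e1, e2 = _orthonormal_basis(d)
    sin_alpha = math.sqrt(1.0 - cos_alpha * cos_alpha)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    v = cos_alpha * d + sin_alpha * (math.cos(phi) * e1 + math.sin(phi) * e2)
    return v / np.linalg.norm(v)


def _cone_solid_direction(
    d: np.ndarray, cos_half_angle: float, rng: np.random.Generator
) -> np.ndarray:
    """Direction uniform over the solid cone of given half-angle about d."""
    cos_t = rng.uniform(cos_half_angle, 1.0)
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    phi = rng.uniform(0.0, 2.0 * math.pi)
    e1, e2 = _orthonormal_basis(d)
    return cos_t * d + sin_t * (math.cos(phi) * e1 + math.sin(phi) * e2)


def window_check(
    step_dirs: np.ndarray | list,
    alpha_global_deg: float = 120.0,
    max_bad_pairs: int = 3,
) -> bool:
    """Global curvature rule on a window of step directions.

    True (continue growing) iff at most ``max_bad_pairs`` unordered pairs of
    directions in the window make an angle greater than ``alpha_global_deg``.
    """
    dirs = np.atleast_2d(np.asarray(step_dirs, dtype=float))
    if len(dirs) < 2:
        return True
    cos_g = math.cos(math.radians(alpha_global_deg))
    gram = dirs @ dirs.T
    bad = int(np.count_nonzero(gram < cos_g)) // 2  # symmetric, diag excluded
    return bad <= max_bad_pairs


class _Grower:
    """Reusable growth machinery bound to one geometry (precomputed masks)."""

    def __init__(self, geom: CellGeometry, params: GrowthParams):
        self.params = params
        self.cytosol = geom.cytosol
        self.nz, self.ny, self.nx = self.cytosol.shape
        self.sxy = geom.voxel_size_um
        self.sz = geom.cell.z_step_um
        self.origin = geom.centrosome_position_um()
        cx, cy, cz = geom.centrosome
        if not self.cytosol[cz, cy, cx]:
            raise ValueError("centrosome is not cytosolic")
        self.cos_g = math.cos(math.radians(params.alpha_global_deg))

    def inside(self, p: np.ndarray) -> bool:
        ix = int(p[0] // self.sxy)
        iy = int(p[1] // self.sxy)
        iz = int(p[2] // self.sz)
        if 0 <= ix < self.nx and 0 <= iy < self.ny and 0 <= iz < self.nz:
            return bool(self.cytosol[iz, iy, ix])
        return False

    def grow(
        self, target_steps: int, rng: np.random.Generator
    ) -> Microtubule | GrowthFailure:
        prm = self.params
        step = prm.step_um
        points = np.empty((target_steps + 1, 3))
        points[0] = self.origin

        # first step: uniform on the sphere, rejected against the cytosol
        d = None
        for _ in range(_FIRST_DIR_ATTEMPTS):
            v = rng.normal(size=3)
            nv = np.linalg.norm(v)
            if nv == 0:
                continue
            v /= nv
            p1 = points[0] + step * v
            if self.inside(p1):
                d = v
                points[1] = p1
                break
        if d is None:
            return GrowthFailure(Microtubule(points[:1].copy(), step))

        w = prm.window_steps
        window = np.empty((w, 3))
        window[0] = d
        m = 1  # directions currently in the window
        n_pts = 2

        while n_pts <= target_steps:
            v = step_direction(d, prm.collinearity, rng)
            p_next = points[n_pts - 1] + step * v
            if not self.inside(p_next):
                # boundary rebound: relax collinearity as little as possible.
                # Among uniform candidates in the alpha_local cone that stay
                # cytosolic, prefer ones whose straight continuation also
                # stays inside (avoids surface trapping), then the most
                # collinear with the previous direction.
                p_cur = points[n_pts - 1]
                v = None
                best_key = (False, -2.0)
                for _ in range(prm.rebound_candidates):
                    cand = _cone_solid_direction(d, prm.cos_alpha_local, rng)
                    p_cand = p_cur + step * cand
                    if not self.inside(p_cand):
                        continue
                    key = (self.inside(p_cand + step * cand), float(cand @ d))
                    if key > best_key:
                        best_key, v = key, cand
                if v is None:
                    return GrowthFailure(Microtubule(points[:n_pts].copy(), step))
                p_next = p_cur + step * v
            points[n_pts] = p_next
            n_pts += 1
            if m == w:
                window[:-1] = window[1:]
                window[-1] = v
            else:
                window[m] = v
                m += 1
            d = v
            if n_pts > target_steps:
                break  # reached the desired length; no further growth to police
            gram = window[:m] @ window[:m].T
            bad = int(np.count_nonzero(gram < self.cos_g)) // 2
            if bad > prm.max_bad_pairs:
                return GrowthFailure(Microtubule(points[:n_pts].copy(), step))
        return Microtubule(points, step)


@njit(cache=True)
def _nb_seed(seed: int) -> None:  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def _nb_grow(
    cyt,  # uint8 (z, y, x)
    sxy: float,
    sz: float,
    ox: float,
    oy: float,
    oz: float,
    target_steps: int,
    step: float,
    cos_a: float,
    cos_local: float,
    cos_g: float,
    wsize: int,
    max_bad: int,
    n_cand: int,
    pts,  # (target_steps + 1, 3) float64 output
) -> int:
    """Compiled single-attempt growth; returns the number of points placed.

    Mirrors the reference implementation in :class:`_Grower` exactly:
    uniform-sphere first step, cone-surface free steps, minimal-relaxation
    rebound inside the alpha_local cone, and the incremental trailing-window
    curvature rule.
    """
    nz, ny, nx = cyt.shape
    pts[0, 0] = ox
    pts[0, 1] = oy
    pts[0, 2] = oz

    dx = dy = dz = 0.0
    px = py = pz = 0.0
    found = False
    for _ in range(1000):
        vx = np.random.normal()
        vy = np.random.normal()
        vz = np.random.normal()
        nv = math.sqrt(vx * vx + vy * vy + vz * vz)
        if nv == 0.0:
            continue
        vx /= nv
        vy /= nv
        vz /= nv
        px = ox + step * vx
        py = oy + step * vy
        pz = oz + step * vz
        ix = int(math.floor(px / sxy))
        iy = int(math.floor(py / sxy))
        iz = int(math.floor(pz / sz))
        if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz and cyt[iz, iy, ix]:
            found = True
            dx, dy, dz = vx, vy, vz
            break
    if not found:
        return 1
    pts[1, 0] = px
    pts[1, 1] = py
    pts[1, 2] = pz

    window = np.empty((wsize, 3))
    window[0, 0] = dx
    window[0, 1] = dy
    window[0, 2] = dz
    m = 1
    bad = 0
    n_pts = 2
    sin_a = math.sqrt(max(0.0, 1.0 - cos_a * cos_a))

    while n_pts <= target_steps:
        # orthonormal basis perpendicular to d (axis least aligned with d)
        ax, ay, az = abs(dx), abs(dy), abs(dz)
        if ax <= ay and ax <= az:
            e1x, e1y, e1z = 0.0, dz, -dy
        elif ay <= az:
            e1x, e1y, e1z = -dz, 0.0, dx
        else:
            e1x, e1y, e1z = dy, -dx, 0.0
        n1 = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
        e1x /= n1
        e1y /= n1
        e1z /= n1
        e2x = dy * e1z - dz * e1y
        e2y = dz * e1x - dx * e1z
        e2z = dx * e1y - dy * e1x

        phi = np.random.uniform(0.0, 2.0 * math.pi)
        cp, sp = math.cos(phi), math.sin(phi)
        vx = cos_a * dx + sin_a * (cp * e1x + sp * e2x)
        vy = cos_a * dy + sin_a * (cp * e1y + sp * e2y)
        vz = cos_a * dz + sin_a * (cp * e1z + sp * e2z)
        nv = math.sqrt(vx * vx + vy * vy + vz * vz)
        vx /= nv
        vy /= nv
        vz /= nv

        cx = pts[n_pts - 1, 0]
        cy = pts[n_pts - 1, 1]
        cz = pts[n_pts - 1, 2]
        px = cx + step * vx
        py = cy + step * vy
        pz = cz + step * vz
        ix = int(math.floor(px / sxy))
        iy = int(math.floor(py / sxy))
        iz = int(math.floor(pz / sz))
        inside = (
            0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz and cyt[iz, iy, ix]
        )
        if not inside:
            best_dot = -2.0
            best_clear = False
            ok = False
            bvx = bvy = bvz = 0.0
            for _ in range(n_cand):
                cos_t = np.random.uniform(cos_local, 1.0)
                sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
                phi = np.random.uniform(0.0, 2.0 * math.pi)
                cp, sp = math.cos(phi), math.sin(phi)
                wx = cos_t * dx + sin_t * (cp * e1x + sp * e2x)
                wy = cos_t * dy + sin_t * (cp * e1y + sp * e2y)
                wz = cos_t * dz + sin_t * (cp * e1z + sp * e2z)
                nw = math.sqrt(wx * wx + wy * wy + wz * wz)
                wx /= nw
                wy /= nw
                wz /= nw
                qx = cx + step * wx
                qy = cy + step * wy
                qz = cz + step * wz
                jx = int(math.floor(qx / sxy))
                jy = int(math.floor(qy / sxy))
                jz = int(math.floor(qz / sz))
                if not (
                    0 <= jx < nx and 0 <= jy < ny and 0 <= jz < nz
                    and cyt[jz, jy, jx]
                ):
                    continue
                kx = int(math.floor((qx + step * wx) / sxy))
                ky = int(math.floor((qy + step * wy) / sxy))
                kz = int(math.floor((qz + step * wz) / sz))
                clear = (
                    0 <= kx < nx and 0 <= ky < ny and 0 <= kz < nz
                    and cyt[kz, ky, kx]
                )
                dot = wx * dx + wy * dy + wz * dz
                if (clear and not best_clear) or (
                    clear == best_clear and dot > best_dot
                ):
                    best_clear = clear
                    best_dot = dot
                    bvx, bvy, bvz = wx, wy, wz
                    ok = True
            if not ok:
                return n_pts
            vx, vy, vz = bvx, bvy, bvz
            px = cx + step * vx
            py = cy + step * vy
            pz = cz + step * vz

        pts[n_pts, 0] = px
        pts[n_pts, 1] = py
        pts[n_pts, 2] = pz
        n_pts += 1

        # trailing-window bad-pair count, maintained incrementally
        if m == wsize:
            for i in range(1, m):
                if (
                    window[0, 0] * window[i, 0]
                    + window[0, 1] * window[i, 1]
                    + window[0, 2] * window[i, 2]
                ) < cos_g:
                    bad -= 1
            for i in range(m - 1):
                window[i, 0] = window[i + 1, 0]
                window[i, 1] = window[i + 1, 1]
                window[i, 2] = window[i + 1, 2]
            m -= 1
        for i in range(m):
            if (
                window[i, 0] * vx + window[i, 1] * vy + window[i, 2] * vz
            ) < cos_g:
                bad += 1
        window[m, 0] = vx
        window[m, 1] = vy
        window[m, 2] = vz
        m += 1
        dx, dy, dz = vx, vy, vz
        if n_pts > target_steps:
            break  # reached the desired length; nothing further to police
        if bad > max_bad:
            return n_pts
    return n_pts


def grow_microtubule(
    geom: CellGeometry,
    params: GrowthParams,
    target_length_um: float,
    rng: np.random.Generator,
) -> Microtubule | GrowthFailure:
    """Grow one microtubule of the desired length inside the geometry.

    Starts at the centrosome with a uniformly random in-cytosol first step;
    subsequent steps follow the collinearity cone, with boundary rebounds
    and the global curvature rule as described in the module docstring.
    Returns the full polyline on success or :class:`GrowthFailure` with the
    partial filament on early termination.
    """
    target_steps = round(target_length_um / params.step_um)
    if target_steps < 1 or abs(target_steps * params.step_um - target_length_um) > 1e-9:
        raise ValueError("target length must be a positive multiple of the step")
    return _Grower(geom, params).grow(target_steps, rng)


def generate_distribution(
    geom: CellGeometry, params: GrowthParams, rng: np.random.Generator
) -> list[Microtubule]:
    """Generate a full microtubule distribution with exact length bookkeeping.

    Samples n desired lengths, sorts them longest first, and grows each one;
    partial filaments from failed attempts are stored by realized length and
    reused whenever a later desired length matches.  After 100 failed
    attempts for a single length the parameters are declared ungenerable.
    """
    lengths = sample_lengths(
        params.n, params.mu_um, params.erlang_shape_k, rng, params.step_um
    )
    desired_steps = sorted(
        (round(l / params.step_um) for l in lengths), reverse=True
    )
    if not desired_steps:
        return []
    grower = _Grower(geom, params)  # validates geometry/centrosome
    cyt = grower.cytosol.astype(np.uint8)
    ox, oy, oz = grower.origin
    cos_g = grower.cos_g
    _nb_seed(int(rng.integers(0, 2**31 - 1)))
    storage: dict[int, list[Microtubule]] = {}
    out: list[Microtubule] = []
    for steps in desired_steps:
        bucket = storage.get(steps)
        if bucket:
            out.append(bucket.pop())
            continue
        for _ in range(params.max_retries):
            pts = np.empty((steps + 1, 3))
            n_pts = _nb_grow(
                cyt, grower.sxy, grower.sz, ox, oy, oz, steps,
                params.step_um, params.collinearity, params.cos_alpha_local,
                cos_g, params.window_steps, params.max_bad_pairs,
                params.rebound_candidates, pts,
            )
            if n_pts == steps + 1:
                out.append(Microtubule(pts, params.step_um))
                break
            if n_pts >= 2:
                storage.setdefault(n_pts - 1, []).append(
                    Microtubule(pts[:n_pts].copy(), params.step_um)
                )
        else:
            raise RuntimeError("input parameters cannot be generated")
    return out
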