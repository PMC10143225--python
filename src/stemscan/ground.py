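"""Ground classification and above-ground-height (AGH) normalisation.

Three complementary ground treatments are provided:

* :func:`octree_ground_segment` — voxelise the cloud and take, in each
  occupied XY column, the points of the lowest occupied voxel as ground.
* :func:`csf_ground_segment` — a cloth simulation filter: the cloud is
  inverted vertically and a particle cloth is dropped onto the inverted
  surface under gravity with rigidity constraints; points near the settled
  cloth are ground.
* :func:`percentile_ground_height` — a scalar fallback for subplots where
  dense understory hides the ground: the height below which the lowest
  fraction (default 2%) of points lie.

AGH is defined relative to a digital terrain model (DTM), a regular XY grid
of terrain heights built from the ground points (lowest ground point per
cell, nearest-neighbour fill for empty cells, nearest-cell lookup).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter
from scipy.spatial import cKDTree

from .io import PointCloud

__all__ = [
    "DTM",
    "GroundModel",
    "ClothParams",
    "octree_ground_segment",
    "csf_ground_segment",
    "percentile_ground_height",
    "dtm_from_ground",
]


@dataclass
class DTM:
    """Regular-grid terrain model; heights indexed [iy, ix]."""

    origin: np.ndarray          # (x0, y0) of the lower-left cell corner
    spacing: float              # cell edge, metres
    heights: np.ndarray         # (ny, nx) terrain z, metres

    def height_at(self, xy) -> np.ndarray:
        """Terrain height at XY positions via nearest-cell lookup."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        ix = np.clip(
            ((xy[:, 0] - self.origin[0]) / self.spacing).astype(int),
            0, self.heights.shape[1] - 1,
        )
        iy = np.clip(
            ((xy[:, 1] - self.origin[1]) / self.spacing).astype(int),
            0, self.heights.shape[0] - 1,
        )
        return self.heights[iy, ix]


@dataclass
class GroundModel:
    """Per-point ground labels plus the terrain surface for AGH queries."""

    ground_mask: np.ndarray              # True where the point is ground
    dtm: DTM | None
    fallback_ground_z: float | None = None
    converged: bool = True               # CSF iteration-budget flag

    def agh(self, cloud_or_xyz) -> np.ndarray:
        """Above-ground height of points: z minus local terrain height."""
        xyz = (
            cloud_or_xyz.xyz
            if isinstance(cloud_or_xyz, PointCloud)
            else np.atleast_2d(np.asarray(cloud_or_xyz, dtype=float))
        )
        if self.dtm is not None:
            return xyz[:, 2] - self.dtm.height_at(xyz[:, :2])
        if self.fallback_ground_z is None:
            raise ValueError("ground model has neither DTM nor fallback height")
        return xyz[:, 2] - self.fallback_ground_z


@dataclass
class ClothParams:
    """Cloth simulation filter parameters.

    Defaults follow common practice for decimetre-scale understory work:
    0.24 m grid, 0.03 m classification threshold, 0.6 s time step, rigidity 3
    (three constraint passes per step), 1000-iteration budget.
    """

    grid_resolution: float = 0.24
    class_threshold: float = 0.03
    time_step: float = 0.6
    iterations: int = 1000
    rigidity: int = 3
    gravity: float = 0.5            # m s^-2; per-step fall = gravity * dt^2
    convergence_tol: float = 0.005  # m; stop when max displacement is below

    def __post_init__(self) -> None:
        if self.grid_resolution <= 0:
            raise ValueError("grid_resolution must be positive")
        if self.rigidity < 0:
            raise ValueError("rigidity must be >= 0")


# ---------------------------------------------------------------------------


def _voxel_indices(xyz: np.ndarray, edge: float, origin: np.ndarray) -> np.ndarray:
    return np.floor((xyz - origin) / edge + 1e-9).astype(np.int64)


def octree_ground_segment(cloud: PointCloud, voxel_edge: float = 0.10) -> GroundModel:
    """Octree-style ground layer: label the lowest occupied voxel per XY
    column as ground, everything above as vegetation.

    The voxel grid is anchored at the cloud's minimum corner. Columns that
    contain only canopy still contribute a "ground" voxel — a documented
    consequence of the rule, not an error.
    """
    if len(cloud) == 0:
        raise ValueError("cannot segment ground from an empty cloud")
    origin = cloud.xyz.min(axis=0)
    idx = _voxel_indices(cloud.xyz, voxel_edge, origin)
    # lowest occupied z-index per XY column
    cols, inverse = np.unique(idx[:, :2], axis=0, return_inverse=True)
    min_iz = np.full(len(cols), np.iinfo(np.int64).max)
    np.minimum.at(min_iz, inverse, idx[:, 2])
    ground_mask = idx[:, 2] == min_iz[inverse]
    dtm = dtm_from_ground(cloud.xyz[ground_mask])
    return GroundModel(ground_mask=ground_mask, dtm=dtm)


def percentile_ground_height(cloud: PointCloud, lower_fraction: float = 0.02) -> float:
    """Height below which *lower_fraction* of the points lie (order
    statistic: the ceil(f*n)-th smallest z). Fallback ground height for
    stems whose footprint is hidden by understory."""
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    z = np.sort(cloud.z)
    k = max(int(math.ceil(lower_fraction * len(z))), 1) - 1
    return float(z[k])


def dtm_from_ground(
    ground_xyz: np.ndarray,
    grid_spacing: float = 0.5,
    bounds: tuple | None = None,
) -> DTM:
    """Grid the ground points into a terrain model: lowest ground z per
    cell, empty cells filled from the nearest non-empty cell.

    *bounds*, when given, is ((xmin, ymin), (xmax, ymax)) and lets the DTM
    cover the full cloud footprint rather than just the ground extent.
    """
    ground_xyz = np.asarray(ground_xyz, dtype=float).reshape(-1, 3)
    if len(ground_xyz) == 0:
        raise ValueError("no ground points; supply fallback_ground_z instead")
    if bounds is None:
        lo = ground_xyz[:, :2].min(axis=0)
        hi = ground_xyz[:, :2].max(axis=0)
    else:
        lo = np.asarray(bounds[0], dtype=float)
        hi = np.asarray(bounds[1], dtype=float)
    nx = max(int(math.ceil((hi[0] - lo[0]) / grid_spacing)), 1)
    ny = max(int(math.ceil((hi[1] - lo[1]) / grid_spacing)), 1)
    ix = np.clip(((ground_xyz[:, 0] - lo[0]) / grid_spacing).astype(int), 0, nx - 1)
    iy = np.clip(((ground_xyz[:, 1] - lo[1]) / grid_spacing).astype(int), 0, ny - 1)
    heights = np.full((ny, nx), np.inf)
    np.minimum.at(heights, (iy, ix), ground_xyz[:, 2])
    empty = ~np.isfinite(heights)
    if empty.any():
        filled_iy, filled_ix = np.nonzero(~empty)
        empty_iy, empty_ix = np.nonzero(empty)
        tree = cKDTree(np.column_stack([filled_ix, filled_iy]))
        _, nearest = tree.query(np.column_stack([empty_ix, empty_iy]))
        heights[empty_iy, empty_ix] = heights[filled_iy[nearest], filled_ix[nearest]]
    return DTM(origin=lo.copy(), spacing=grid_spacing, heights=heights)


# ---------------------------------------------------------------------------
# cloth simulation filter


def csf_ground_segment(
    cloud: PointCloud, params: ClothParams | None = None
) -> GroundModel:
    """Cloth simulation filter ground classification.

    The cloud is inverted (z -> -z) so the former ground becomes the upper
    envelope; a particle cloth initialised above it falls under gravity.
    Particles pin permanently where they meet the inverted surface
    (per-cell highest inverted point), and each time step applies
    ``rigidity`` internal-constraint passes that pull neighbouring particle
    heights together so the cloth bridges gaps. Iteration stops when the
    maximum per-step displacement drops below the convergence tolerance or
    the budget is exhausted (flagged on the result). A point is ground when
    its height is within ``class_threshold`` of the bilinearly interpolated
    settled cloth.
    """
    if params is None:
        params = ClothParams()
    if len(cloud) == 0:
        raise ValueError("cannot segment ground from an empty cloud")

    res = params.grid_resolution
    inv_z = -cloud.z
    lo = cloud.xy.min(axis=0) - res
    hi = cloud.xy.max(axis=0) + res
    nx = max(int(math.ceil((hi[0] - lo[0]) / res)) + 1, 2)
    ny = max(int(math.ceil((hi[1] - lo[1]) / res)) + 1, 2)

    # Collision height per particle: highest inverted point (= lowest
    # original z) near the particle centre. Sampled on a 4x finer subgrid
    # so sloped terrain is probed at the particle position rather than the
    # minimum over the whole 0.24 m cell, which would bias the cloth low.
    sub = 4
    sres = res / sub
    snx, sny = nx * sub, ny * sub
    six = np.clip(((cloud.xy[:, 0] - lo[0]) / sres).astype(int), 0, snx - 1)
    siy = np.clip(((cloud.xy[:, 1] - lo[1]) / sres).astype(int), 0, sny - 1)
    hcv_sub = np.full((sny, snx), -np.inf)
    np.maximum.at(hcv_sub, (siy, six), inv_z)
    empty = ~np.isfinite(hcv_sub)
    if empty.any():
        fy, fx = np.nonzero(~empty)
        ey, ex = np.nonzero(empty)
        tree = cKDTree(np.column_stack([fx, fy]))
        _, nearest = tree.query(np.column_stack([ex, ey]))
        hcv_sub[ey, ex] = hcv_sub[fy[nearest], fx[nearest]]
    # particle (iy, ix) sits at the cell centre -> collision height over a
    # 3x3 subcell neighbourhood of its containing subcell, so sparse ground
    # sampling cannot leave a particle colliding on vegetation alone
    hcv_sub = maximum_filter(hcv_sub, size=3, mode="nearest")
    pix = np.clip(((np.arange(nx) + 0.5) * res / sres).astype(int), 0, snx - 1)
    piy = np.clip(((np.arange(ny) + 0.5) * res / sres).astype(int), 0, sny - 1)
    hcv = hcv_sub[np.ix_(piy, pix)]

    fall = params.gravity * params.time_step ** 2
    cloth = np.full((ny, nx), inv_z.max() + 2 * fall)
    prev = cloth.copy()
    movable = np.ones((ny, nx), dtype=bool)
    converged = False

    for _ in range(params.iterations):
        before = cloth.copy()
        # Verlet gravity step for movable particles
        new = np.where(movable, 2 * cloth - prev + (-fall), cloth)
        prev = cloth
        cloth = new
        # collision: pin at the inverted surface
        hit = movable & (cloth <= hcv)
        cloth[hit] = hcv[hit]
        movable[hit] = False
        # rigidity: neighbour-constraint passes
        for _pass in range(params.rigidity):
            up = np.roll(cloth, 1, axis=0)
            down = np.roll(cloth, -1, axis=0)
            left = np.roll(cloth, 1, axis=1)
            right = np.roll(cloth, -1, axis=1)
            up[0, :] = cloth[0, :]
            down[-1, :] = cloth[-1, :]
            left[:, 0] = cloth[:, 0]
            right[:, -1] = cloth[:, -1]
            mean_nb = (up + down + left + right) / 4.0
            cloth = np.where(movable, cloth + 0.5 * (mean_nb - cloth), cloth)
            hit = movable & (cloth <= hcv)
            cloth[hit] = hcv[hit]
            movable[hit] = False
        if np.max(np.abs(cloth - before)) < params.convergence_tol:
            converged = True
            break

    # classify against the bilinearly interpolated cloth, back in z-up space;
    # particles sit at cell centres, hence the half-cell shift
    cloth_z = -cloth
    gx = (cloud.xy[:, 0] - lo[0]) / res - 0.5
    gy = (cloud.xy[:, 1] - lo[1]) / res - 0.5
    x0 = np.clip(np.floor(gx).astype(int), 0, nx - 2)
    y0 = np.clip(np.floor(gy).astype(int), 0, ny - 2)
    tx = np.clip(gx - x0, 0.0, 1.0)
    ty = np.clip(gy - y0, 0.0, 1.0)
    h = (
        cloth_z[y0, x0] * (1 - tx) * (1 - ty)
        + cloth_z[y0, x0 + 1] * tx * (1 - ty)
        + cloth_z[y0 + 1, x0] * (1 - tx) * ty
        + cloth_z[y0 + 1, x0 + 1] * tx * ty
    )
    ground_mask = np.abs(cloud.z - h) <= params.class_threshold
    dtm = (
        dtm_from_ground(cloud.xyz[ground_mask]) if ground_mask.any() else None
    )
    return GroundModel(ground_mask=ground_mask, dtm=dtm, converged=converged)
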