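"""Stem segmentation, base position, and DBH estimation.

Stems are isolated from the vegetation points by a voxel region-growing
scheme seeded on a PCA verticality descriptor, their base position is the
component-wise median of the basal point band (robust to basal sweep), and
DBH is a geometric least-squares circle fit through the 1.3 m AGH slice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .ground import GroundModel
from .io import PointCloud

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationParams",
    "StemSegment",
    "StemRecord",
    "segment_stems",
    "refine_segment",
    "stem_base_position",
    "fit_dbh",
    "fit_circle_kasa",
    "fit_circle_geometric",
]


@dataclass
class SegmentationParams:
    """Voxel region-growing parameters.

    ``descriptor_threshold`` applies to a verticality-weighted linearity
    descriptor in [0, 1]: lambda1 / (lambda1+lambda2+lambda3) of the local
    PCA over the k nearest occupied-voxel centroids, weighted by the
    absolute vertical component of the first eigenvector. High values mark
    vertical line-like structure, i.e. stems.
    """

    voxel_edge: float = 0.05
    descriptor_threshold: float = 0.70
    iterations: int = 5
    min_voxels_per_element: int = 100
    min_agh: float = 0.5
    knn: int = 10
    #: z is divided by this factor in the neighbour metric, so descriptor
    #: neighbourhoods elongate vertically and follow stem surfaces rather
    #: than wrapping around them; PCA runs on unscaled coordinates.
    vertical_stretch: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.descriptor_threshold <= 1:
            raise ValueError("descriptor_threshold must be in (0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class StemSegment:
    stem_id: int
    point_indices: np.ndarray   # indices into the vegetation cloud
    voxel_count: int


@dataclass
class StemRecord:
    """Measurements for one stem at 1.3 m above ground height."""

    stem_id: int
    base_xy: np.ndarray | None = None
    ground_z_at_base: float | None = None
    dbh_cm: float | None = None
    circle_center_xy: np.ndarray | None = None
    fit_rms_residual: float | None = None
    n_slice_points: int = 0
    arc_coverage_deg: float | None = None
    capture_status: str = "captured"
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# segmentation


def _voxelize(xyz: np.ndarray, edge: float):
    origin = xyz.min(axis=0)
    idx = np.floor((xyz - origin) / edge + 1e-9).astype(np.int64)
    keys, inverse = np.unique(idx, axis=0, return_inverse=True)
    centroids = np.zeros((len(keys), 3))
    counts = np.bincount(inverse, minlength=len(keys)).astype(float)
    for d in range(3):
        centroids[:, d] = np.bincount(inverse, weights=xyz[:, d]) / counts
    return keys, inverse, centroids


_NEIGHBOR_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=np.int64,
)


def _pca_descriptor(
    centroids: np.ndarray, knn: int, vertical_stretch: float = 3.0
) -> np.ndarray:
    """Verticality-weighted linearity per occupied voxel.

    Neighbours are the k nearest occupied-voxel centroids under a metric
    with z compressed by ``vertical_stretch``; the PCA itself uses the
    original coordinates. On a vertical stem surface the neighbourhood is a
    vertical strip (descriptor near 1); on ground or leafy understory it is
    flat or isotropic (descriptor near 0)."""
    n = len(centroids)
    k = min(knn, n)
    scaled = centroids.copy()
    scaled[:, 2] /= max(vertical_stretch, 1e-9)
    tree = cKDTree(scaled)
    _, nbrs = tree.query(scaled, k=k)
    if nbrs.ndim == 1:
        nbrs = nbrs[:, None]
    pts = centroids[nbrs]                       # (n, k, 3)
    mean = pts.mean(axis=1, keepdims=True)
    centered = pts - mean
    cov = np.einsum("nki,nkj->nij", centered, centered) / max(k - 1, 1)
    evals, evecs = np.linalg.eigh(cov)          # ascending
    total = evals.sum(axis=1)
    ok = total > 1e-12
    linearity = np.zeros(n)
    linearity[ok] = evals[ok, 2] / total[ok]
    verticality = np.abs(evecs[:, 2, 2])        # |z of the largest eigenvector|
    desc = linearity * verticality
    return desc


def segment_stems(
    vegetation: PointCloud,
    ground: GroundModel,
    params: SegmentationParams | None = None,
) -> list[StemSegment]:
    """Identify individual stems among the vegetation points.

    The vegetation is voxelised; voxels whose PCA descriptor exceeds the
    threshold and whose centroid lies above ``min_agh`` seed 26-connected
    components, which then grow for ``iterations`` dilation passes over
    adjacent unassigned voxels. Components with fewer than
    ``min_voxels_per_element`` voxels are discarded. Returns disjoint
    segments carrying point memberships; an empty list when no seeds exist.
    """
    if params is None:
        params = SegmentationParams()
    if len(vegetation) == 0:
        return []
    keys, inverse, centroids = _voxelize(vegetation.xyz, params.voxel_edge)
    desc = _pca_descriptor(centroids, params.knn, params.vertical_stretch)
    agh = ground.agh(centroids)
    seeds = (desc >= params.descriptor_threshold) & (agh >= params.min_agh)
    if not seeds.any():
        logger.info("segment_stems: no seed voxels found")
        return []

    key_to_idx = {tuple(k): i for i, k in enumerate(keys)}
    assignment = np.full(len(keys), -1, dtype=np.int64)

    # connected components of seed voxels (26-connectivity)
    comp = 0
    for i in np.nonzero(seeds)[0]:
        if assignment[i] >= 0:
            continue
        stack = [i]
        assignment[i] = comp
        while stack:
            j = stack.pop()
            for off in _NEIGHBOR_OFFSETS:
                nb = key_to_idx.get(tuple(keys[j] + off))
                if nb is not None and seeds[nb] and assignment[nb] < 0:
                    assignment[nb] = comp
                    stack.append(nb)
        comp += 1

    # growth passes: unassigned voxels adjacent to a segment join it
    for _ in range(params.iterations):
        joins = {}
        for i in np.nonzero(assignment < 0)[0]:
            best = -1
            for off in _NEIGHBOR_OFFSETS:
                nb = key_to_idx.get(tuple(keys[i] + off))
                if nb is not None and assignment[nb] >= 0:
                    if best < 0 or assignment[nb] < best:
                        best = assignment[nb]
            if best >= 0:
                joins[i] = best
        if not joins:
            break
        for i, c in joins.items():
            assignment[i] = c

    segments = []
    sid = 0
    for c in range(comp):
        vox_mask = assignment == c
        nvox = int(vox_mask.sum())
        if nvox < params.min_voxels_per_element:
            continue
        pt_mask = vox_mask[inverse]
        segments.append(
            StemSegment(
                stem_id=sid,
                point_indices=np.nonzero(pt_mask)[0],
                voxel_count=nvox,
            )
        )
        sid += 1
    return segments


def refine_segment(
    vegetation: PointCloud,
    merged: StemSegment,
    ground: GroundModel,
    voxel_edge: float = 0.02,
    params: SegmentationParams | None = None,
) -> list[StemSegment]:
    """Re-segment a suspected multi-stem element at a finer voxel edge.

    Runs the same seed-and-grow algorithm on the member points only;
    returned segments carry indices into the original vegetation cloud.
    """
    if len(merged.point_indices) == 0:
        return []
    if params is None:
        params = SegmentationParams()
    fine = SegmentationParams(
        voxel_edge=voxel_edge,
        descriptor_threshold=params.descriptor_threshold,
        iterations=params.iterations,
        min_voxels_per_element=params.min_voxels_per_element,
        min_agh=params.min_agh,
        knn=params.knn,
        vertical_stretch=params.vertical_stretch,
    )
    sub = vegetation.select(merged.point_indices)
    out = segment_stems(sub, ground, fine)
    for seg in out:
        seg.point_indices = merged.point_indices[seg.point_indices]
    return out


# ---------------------------------------------------------------------------
# base position


def _lower_median(values: np.ndarray) -> float:
    v = np.sort(values)
    return float(v[(len(v) - 1) // 2])


def stem_base_position(
    vegetation: PointCloud,
    segment: StemSegment,
    ground: GroundModel,
    band: tuple[float, float] = (0.0, 1.0),
) -> tuple[np.ndarray, float, list]:
    """Stem base = component-wise (lower) median XY of the basal point band
    (0 < AGH <= 1 m by default), which tolerates basal sweep. Returns
    (base_xy, ground_z_at_base, flags); when the band is empty it falls
    back to the lowest 10% of member points by AGH, flagged.
    """
    flags = []
    pts = vegetation.xyz[segment.point_indices]
    agh = ground.agh(pts)
    mask = (agh > band[0]) & (agh <= band[1])
    if not mask.any():
        flags.append("base_band_empty")
        order = np.argsort(agh)
        n = max(int(math.ceil(0.1 * len(pts))), 1)
        mask = np.zeros(len(pts), dtype=bool)
        mask[order[:n]] = True
    sel = pts[mask]
    base_xy = np.array([_lower_median(sel[:, 0]), _lower_median(sel[:, 1])])
    if ground.dtm is not None:
        ground_z = float(ground.dtm.height_at(base_xy[None, :])[0])
    else:
        ground_z = float(ground.fallback_ground_z)
    return base_xy, ground_z, flags


# ---------------------------------------------------------------------------
# circle fitting


def fit_circle_kasa(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kasa) least-squares circle: solve the linear system for
    x^2 + y^2 = 2 a x + 2 b y + c. Used to initialise the geometric fit."""
    x, y = xy[:, 0], xy[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones(len(xy))])
    b = x ** 2 + y ** 2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r = math.sqrt(max(c + cx ** 2 + cy ** 2, 0.0))
    return np.array([cx, cy]), r


def fit_circle_geometric(
    xy: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, float, float, bool]:
    """Geometric least-squares circle minimising sum (||p - c|| - r)^2 by
    Gauss-Newton from the Kasa solution.

    Returns (center, radius, rms_residual, converged). On non-convergence
    the best iterate so far is returned with ``converged`` False.
    """
    center, r = fit_circle_kasa(xy)
    params = np.array([center[0], center[1], r])
    converged = False
    for _ in range(max_iter):
        d = xy - params[:2]
        dist = np.hypot(d[:, 0], d[:, 1])
        dist = np.maximum(dist, 1e-12)
        resid = dist - params[2]
        J = np.column_stack([-d[:, 0] / dist, -d[:, 1] / dist, -np.ones(len(xy))])
        step, *_ = np.linalg.lstsq(J, -resid, rcond=None)
        params = params + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    d = xy - params[:2]
    resid = np.hypot(d[:, 0], d[:, 1]) - params[2]
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return params[:2].copy(), float(abs(params[2])), rms, converged


def _arc_coverage_deg(xy: np.ndarray, center: np.ndarray) -> float:
    """Angular span of points around the fitted centre, from the largest
    angular gap (360 minus it)."""
    ang = np.sort(np.arctan2(xy[:, 1] - center[1], xy[:, 0] - center[0]))
    gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * math.pi]]))
    return math.degrees(2 * math.pi - gaps.max())


def fit_dbh(
    vegetation: PointCloud,
    segment: StemSegment,
    ground: GroundModel,
    slice_center_agh: float = 1.3,
    slice_half_thickness: float = 0.05,
    min_slice_points: int = 5,
) -> StemRecord:
    """Estimate DBH: take the point slice at 1.3 m AGH (+- half thickness),
    project to XY, and fit a geometric least-squares circle; DBH = 2r.

    With fewer than ``min_slice_points`` slice points the stem is marked
    ``failed_other`` and carries no DBH. Arc coverage and slice point count
    are recorded so downstream analysis can flag single-face captures.
    """
    rec = StemRecord(stem_id=segment.stem_id)
    rec.base_xy, rec.ground_z_at_base, rec.flags = stem_base_position(
        vegetation, segment, ground
    )
    pts = vegetation.xyz[segment.point_indices]
    agh = ground.agh(pts)
    mask = np.abs(agh - slice_center_agh) <= slice_half_thickness
    rec.n_slice_points = int(mask.sum())
    if rec.n_slice_points < min_slice_points:
        rec.capture_status = "failed_other"
        rec.flags.append("too_few_slice_points")
        return rec
    xy = pts[mask][:, :2]
    center, r, rms, converged = fit_circle_geometric(xy)
    if not converged:
        rec.flags.append("circle_fit_not_converged")
        center, r = fit_circle_kasa(xy)
        d = xy - center
        rms = float(np.sqrt(np.mean((np.hypot(d[:, 0], d[:, 1]) - r) ** 2)))
    rec.circle_center_xy = center
    rec.dbh_cm = 200.0 * r
    rec.fit_rms_residual = rms
    rec.arc_coverage_deg = _arc_coverage_deg(xy, center)
    return rec
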