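"""Stem proximity and per-stem understory vegetation metrics.

A stem's proximity is the XY distance to the next closest stem in the plot;
stems closer than a device's duplicate-capture radius risk misaligned
duplicate faces during continuous capture. Understory around each stem is
summarised inside a device-specific circular subplot (sensor range minus
the 1 m operator standoff) as voxel-column cover and volume: in each 10 mm
column the highest occupied voxel and everything beneath it counts as
filled, because upper foliage occludes what lies below it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .ground import ClothParams, GroundModel, csf_ground_segment
from .io import PointCloud, crop_radial
from .stems import StemRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DeviceProfile",
    "DEVICE_PROFILES",
    "VegetationMetrics",
    "nearest_stem_distance",
    "nearest_neighbor_distances",
    "within_duplicate_range",
    "understory_metrics",
]

UNDERSTORY_TOP_AGH = 1.3  # metres; understory is everything below sensor height


@dataclass(frozen=True)
class DeviceProfile:
    """RGB-D device capture geometry.

    ``subplot_radius`` is the sensor's maximum depth range minus the 1 m
    standoff the operator keeps from the stem face, i.e. the area the
    sensor can see while a stem is captured.
    """

    name: str
    sensor_max_range: float
    duplicate_capture_radius: float
    subplot_radius: float

    def __post_init__(self) -> None:
        if self.duplicate_capture_radius <= 0:
            raise ValueError("duplicate_capture_radius must be positive")
        if not math.isclose(self.subplot_radius, self.sensor_max_range - 1.0):
            raise ValueError("subplot_radius must equal sensor_max_range - 1 m")


#: Built-in device profiles: range / duplicate radius / subplot radius (m).
DEVICE_PROFILES = {
    "kinect": DeviceProfile("kinect", 3.0, 2.0, 2.0),
    "zed": DeviceProfile("zed", 3.5, 2.5, 2.5),
    "ipad": DeviceProfile("ipad", 5.5, 4.5, 4.5),
}


@dataclass
class VegetationMetrics:
    stem_id: int
    subplot_radius: float
    cover_pct: float
    volume_pct: float
    volume_m3: float
    filled_voxels: int
    voxel_edge: float
    flags: list


# ---------------------------------------------------------------------------


def nearest_neighbor_distances(xy: np.ndarray) -> np.ndarray:
    """Distance from each position to its nearest other position."""
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    if len(xy) < 2:
        raise ValueError("need at least two positions")
    diff = xy[:, None, :] - xy[None, :, :]
    d = np.hypot(diff[..., 0], diff[..., 1])
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def nearest_stem_distance(stems: list[StemRecord]) -> dict[int, float | None]:
    """Per-stem distance to the next closest stem base in the plot.

    Stems without a base position get None; with a single stem the metric
    is undefined for it (None, logged).
    """
    located = [s for s in stems if s.base_xy is not None]
    out: dict[int, float | None] = {s.stem_id: None for s in stems}
    if len(located) < 2:
        logger.warning("nearest_stem_distance: fewer than two located stems")
        return out
    xy = np.array([s.base_xy for s in located])
    d = nearest_neighbor_distances(xy)
    for s, dist in zip(located, d):
        out[s.stem_id] = float(dist)
    return out


def within_duplicate_range(distance: float, device: DeviceProfile) -> bool:
    """True when the next-closest stem sits within the device's duplicate
    capture radius (boundary inclusive)."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return distance <= device.duplicate_capture_radius


# ---------------------------------------------------------------------------


def understory_metrics(
    cloud: PointCloud,
    stem: StemRecord,
    device: DeviceProfile,
    ground: GroundModel,
    voxel_edge: float = 0.01,
    csf_params: ClothParams | None = None,
    stem_margin: float = 0.05,
) -> VegetationMetrics:
    """Understory cover and volume in the device subplot around *stem*.

    Pipeline: radial crop at the stem base; keep points at most 1.3 m AGH;
    cloth-simulation-filter out the ground; strip the target stem (points
    within fitted radius + ``stem_margin`` of the base axis); voxelise at
    ``voxel_edge`` on a grid anchored at the subplot bounding box with z
    measured from the per-column terrain height; apply the column-fill rule.

    cover_pct is the share of subplot columns containing at least one
    vegetation point; volume_pct normalises the filled-voxel count by the
    subplot's 0-1.3 m column capacity.
    """
    if voxel_edge <= 0:
        raise ValueError("voxel_edge must be positive")
    if stem.base_xy is None:
        raise ValueError("stem has no base position")
    flags: list = []
    radius = device.subplot_radius
    sub = crop_radial(cloud, stem.base_xy, radius)

    # keep understory band only
    if len(sub):
        agh = ground.agh(sub)
        sub = sub.select(agh <= UNDERSTORY_TOP_AGH)

    # remove ground with the cloth simulation filter
    if len(sub):
        try:
            gm = csf_ground_segment(sub, csf_params or ClothParams())
            sub = sub.select(~gm.ground_mask)
        except ValueError:
            pass

    # remove the target stem
    if len(sub):
        r_stem = (stem.dbh_cm or 0.0) / 200.0 + stem_margin
        d = np.hypot(
            sub.xy[:, 0] - stem.base_xy[0], sub.xy[:, 1] - stem.base_xy[1]
        )
        sub = sub.select(d > r_stem)

    # voxel-column accounting over the subplot circle
    anchor = np.asarray(stem.base_xy, dtype=float) - radius
    n_side = int(math.ceil(2 * radius / voxel_edge))
    capacity_per_column = int(math.ceil(UNDERSTORY_TOP_AGH / voxel_edge))

    # columns whose centre lies inside the subplot circle
    centers = anchor[0] + (np.arange(n_side) + 0.5) * voxel_edge
    cy = anchor[1] + (np.arange(n_side) + 0.5) * voxel_edge
    inside = (
        (centers[None, :] - stem.base_xy[0]) ** 2
        + (cy[:, None] - stem.base_xy[1]) ** 2
    ) <= radius ** 2
    total_columns = int(inside.sum())
    if total_columns == 0:
        return VegetationMetrics(
            stem.stem_id, radius, 0.0, 0.0, 0.0, 0, voxel_edge, ["empty_subplot"]
        )

    filled = 0
    occupied_columns = 0
    if len(sub):
        ix = np.floor((sub.xy[:, 0] - anchor[0]) / voxel_edge).astype(np.int64)
        iy = np.floor((sub.xy[:, 1] - anchor[1]) / voxel_edge).astype(np.int64)
        keep = (ix >= 0) & (ix < n_side) & (iy >= 0) & (iy < n_side)
        keep &= inside[iy.clip(0, n_side - 1), ix.clip(0, n_side - 1)]
        if keep.any():
            ix, iy = ix[keep], iy[keep]
            # z index measured from the terrain height of the point's column
            col_x = anchor[0] + (ix + 0.5) * voxel_edge
            col_y = anchor[1] + (iy + 0.5) * voxel_edge
            if ground.dtm is not None:
                terrain = ground.dtm.height_at(np.column_stack([col_x, col_y]))
            else:
                terrain = np.full(len(ix), ground.fallback_ground_z, dtype=float)
            # boundary convention: a return exactly on a voxel boundary
            # belongs to the voxel beneath it (ceil - 1), so an analytic
            # surface at k * voxel_edge fills exactly k layers
            v = (sub.z[keep] - terrain) / voxel_edge
            iz = np.ceil(v - 1e-9).astype(np.int64) - 1
            iz = np.clip(iz, 0, capacity_per_column - 1)
            col_key = iy * n_side + ix
            uniq, inv = np.unique(col_key, return_inverse=True)
            top = np.full(len(uniq), -1, dtype=np.int64)
            np.maximum.at(top, inv, iz)
            occupied_columns = len(uniq)
            filled = int((top + 1).sum())   # column-fill rule

    if len(sub) == 0:
        flags.append("no_vegetation_points")

    volume_m3 = filled * voxel_edge ** 3
    volume_pct = 100.0 * filled / (total_columns * capacity_per_column)
    cover_pct = 100.0 * occupied_columns / total_columns
    return VegetationMetrics(
        stem_id=stem.stem_id,
        subplot_radius=radius,
        cover_pct=cover_pct,
        volume_pct=volume_pct,
        volume_m3=volume_m3,
        filled_voxels=filled,
        voxel_edge=voxel_edge,
        flags=flags,
    )
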