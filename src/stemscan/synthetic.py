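"""Synthetic forest-plot point clouds with exact ground truth.

The generator emulates the structure of terrestrial RGB-D / TLS captures of
forest plots: a smooth low-relief ground surface, tapered (optionally swept
and leaning) stem cylinders sampled on their surface, low understory
vegetation patches (boxes, ellipsoids, hemispheres below 1.3 m), and the
characteristic RGB-D capture artifacts — duplicated stem faces offset by
SLAM misalignment, accumulated positional drift along the capture path, and
signed radial backscatter displacement of stem-edge pixels.

Every scene records its truth (stem bases, true DBH, nearest-stem
distances, terrain function, analytic understory volume) so each pipeline
stage has a recoverable answer. Generation is fully deterministic in the
config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .io import PointCloud

__all__ = [
    "StemSpec",
    "PatchSpec",
    "ArtifactSpec",
    "SceneConfig",
    "SyntheticScene",
    "generate_scene",
    "apply_artifacts",
    "analytic_understory_volume_oracle",
    "sample_patch_points",
    "GROUND_LABEL",
    "UNDERSTORY_LABEL",
    "STEM_LABEL_OFFSET",
]

GROUND_LABEL = 0
UNDERSTORY_LABEL = 1
STEM_LABEL_OFFSET = 2  # stem i carries label STEM_LABEL_OFFSET + i

BREAST_HEIGHT = 1.3  # metres AGH at which DBH is defined
STANDOFF = 1.0       # metres the operator keeps from the stem face


@dataclass
class StemSpec:
    """One stem: a tapered cylinder, optionally swept and leaning.

    ``dbh_true`` is the diameter (cm) at 1.3 m above the terrain at the
    base; ``taper_rate`` is cm of diameter lost per metre of height;
    ``sweep_offset`` displaces the axis laterally by that many metres at
    1.3 m (linear in height); ``angular_coverage`` < 360 leaves only one
    face of the stem sampled, the small-stem RGB-D failure mode.
    """

    base_xy: tuple = (0.0, 0.0)
    dbh_true: float = 30.0           # centimetres
    height: float = 3.0              # metres
    taper_rate: float = 1.0          # cm diameter per m height
    sweep_offset: float = 0.0        # metres at breast height
    lean_deg: float = 0.0
    surface_noise_sd: float = 0.0    # metres, radial
    angular_coverage: float = 360.0  # degrees

    def __post_init__(self) -> None:
        if self.dbh_true <= 0:
            raise ValueError("dbh_true must be positive")
        if not 0 < self.angular_coverage <= 360:
            raise ValueError("angular_coverage must be in (0, 360]")

    def radius_at(self, h: float) -> float:
        """Stem radius (m) at height h above base terrain."""
        diam_cm = self.dbh_true + self.taper_rate * (BREAST_HEIGHT - h)
        return max(diam_cm / 200.0, 0.002)

    @property
    def base_radius(self) -> float:
        return self.radius_at(0.0)


@dataclass
class PatchSpec:
    """An understory vegetation patch (everything below 1.3 m AGH).

    ``extent`` is the full extent per axis in metres: a box spans
    center +- extent/2 in XY rising from the ground to extent_z; ellipsoids
    and hemispheres use semi-axes extent_x/2, extent_y/2 with vertical
    semi-axis extent_z (resting on the ground). Heights are capped at
    ``max_height``.
    """

    shape: str = "box"               # box | ellipsoid | hemisphere
    center_xy: tuple = (0.0, 0.0)
    extent: tuple = (1.0, 1.0, 0.5)
    max_height: float = 1.3
    point_density: float = 2000.0    # interior points per m^3
    #: jittered-grid spacing of points on the patch's upper surface; dense
    #: top returns dominate real shrub captures and are what the
    #: column-fill volume rule responds to. None disables.
    surface_point_spacing: float | None = 0.005

    def __post_init__(self) -> None:
        if self.shape not in ("box", "ellipsoid", "hemisphere"):
            raise ValueError(f"unknown patch shape {self.shape!r}")
        if self.max_height > 1.3 + 1e-9:
            raise ValueError("understory patches must stay at or below 1.3 m")
        if any(e <= 0 for e in self.extent):
            raise ValueError("patch extent must be strictly positive")

    def top_height(self, x, y):
        """Analytic top height (AGH) of the patch above positions (x, y);
        NaN where the column misses the patch footprint."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        cx, cy = self.center_xy
        ex, ey, ez = self.extent
        if self.shape == "box":
            inside = (np.abs(x - cx) <= ex / 2) & (np.abs(y - cy) <= ey / 2)
            top = np.where(inside, min(ez, self.max_height), np.nan)
        else:
            # ellipsoid and hemisphere: upper half-spheroid resting on the
            # ground (the full ellipsoid's lower half is buried)
            u = ((x - cx) / (ex / 2)) ** 2 + ((y - cy) / (ey / 2)) ** 2
            with np.errstate(invalid="ignore"):
                top = np.where(u <= 1.0, ez * np.sqrt(np.maximum(1 - u, 0)), np.nan)
            top = np.minimum(top, self.max_height)
        return top

    def volume_bbox(self):
        cx, cy = self.center_xy
        ex, ey, ez = self.extent
        return (cx - ex / 2, cy - ey / 2, 0.0), (cx + ex / 2, cy + ey / 2, min(ez, self.max_height))

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        """Membership test for points with z measured as AGH."""
        top = self.top_height(xyz[:, 0], xyz[:, 1])
        ok = ~np.isnan(top) & (xyz[:, 2] >= 0) & (xyz[:, 2] <= top)
        return ok


@dataclass
class ArtifactSpec:
    """RGB-D capture artifact model.

    duplicate_offset / duplicate_fraction: a re-observed arc of each stem
    within another capture position's sensor range is copied and rigidly
    shifted in XY. drift_rate: metres of accumulated translation per metre
    of simulated capture path. backscatter_bias: signed radial displacement
    (positive = outward, inflating fitted diameters) applied to
    backscatter_fraction of each stem's points, emulating mixed depth
    pixels at stem silhouettes.
    """

    duplicate_offset: float = 0.0
    duplicate_fraction: float = 0.25
    drift_rate: float = 0.002
    backscatter_bias: float = 0.0
    backscatter_fraction: float = 0.0
    sensor_range: float = 3.0
    sensor_height: float = 1.3

    def __post_init__(self) -> None:
        if self.sensor_range <= 0:
            raise ValueError("sensor_range must be positive")
        for name in ("duplicate_fraction", "backscatter_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SceneConfig:
    plot_radius: float = 12.0
    ground_relief_amplitude: float = 0.15
    ground_point_spacing: float = 0.05
    ground_noise_sd: float = 0.005
    point_spacing: float = 0.01      # stem surface sampling spacing
    stems: list = field(default_factory=list)
    understory_patches: list = field(default_factory=list)
    artifact: ArtifactSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plot_radius <= 0:
            raise ValueError("plot_radius must be positive")
        if self.ground_point_spacing <= 0:
            raise ValueError("ground_point_spacing must be positive")
        self.stems = [
            s if isinstance(s, StemSpec) else StemSpec(**s) for s in self.stems
        ]
        self.understory_patches = [
            p if isinstance(p, PatchSpec) else PatchSpec(**p)
            for p in self.understory_patches
        ]
        if self.artifact is not None and not isinstance(self.artifact, ArtifactSpec):
            self.artifact = ArtifactSpec(**self.artifact)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SceneConfig":
        return cls(**yaml.safe_load(text))


@dataclass
class SyntheticScene:
    """A generated plot and its exact ground truth.

    ``cloud`` carries a ``label`` attribute (0 ground, 1 understory,
    2+i stem i). ``truth_stems`` holds one dict per stem with base_xy,
    dbh_true (cm) and nearest_stem_distance_true (m). Understory-volume
    truth comes from :meth:`true_understory_volume`, which rasterises the
    analytic patch shapes with the same column-fill rule the pipeline uses
    — independent of point sampling.
    """

    cloud: PointCloud
    config: SceneConfig
    truth_stems: list
    terrain: object                 # callable (x, y) -> terrain z

    def true_ground_height(self, x, y):
        return self.terrain(x, y)

    def stem_axis_xy(self, index: int, h) -> np.ndarray:
        """XY of stem *index*'s axis at height h above its base terrain."""
        spec = self.config.stems[index]
        return _axis_xy(spec, self._stem_dirs[index], h)

    def capture_position(self, index: int) -> np.ndarray:
        return _capture_position(self.config.stems[index])

    def true_understory_volume(
        self, stem_index: int, subplot_radius: float, voxel_edge: float = 0.01
    ) -> float:
        base = np.asarray(self.config.stems[stem_index].base_xy)
        return analytic_understory_volume_oracle(
            self.config.understory_patches, base, subplot_radius, voxel_edge
        )

    # populated by generate_scene; (lean_vec, sweep_vec) per stem
    _stem_dirs: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# terrain


def _make_terrain(amplitude: float, seed: int):
    """Smooth low-frequency relief: a seeded sum of three sinusoids,
    scaled so the combined amplitude is roughly the requested one."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 7]))
    k = 3
    wavelengths = rng.uniform(5.0, 15.0, size=k)
    azimuths = rng.uniform(0, 2 * math.pi, size=k)
    phases = rng.uniform(0, 2 * math.pi, size=k)
    weights = rng.uniform(0.5, 1.0, size=k)
    weights *= amplitude / weights.sum() if weights.sum() else 0.0

    def terrain(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = np.zeros(np.broadcast(x, y).shape)
        for i in range(k):
            kx = 2 * math.pi / wavelengths[i] * math.cos(azimuths[i])
            ky = 2 * math.pi / wavelengths[i] * math.sin(azimuths[i])
            z = z + weights[i] * np.sin(kx * x + ky * y + phases[i])
        return z

    return terrain


# ---------------------------------------------------------------------------
# stem geometry helpers


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 1e-12 else np.array([1.0, 0.0])


def _capture_position(spec: StemSpec) -> np.ndarray:
    """Operator standoff position: 1 m from the stem face, on the side of
    the plot centre (stems are approached from the plot interior)."""
    base = np.asarray(spec.base_xy, dtype=float)
    toward_centre = _unit(-base)
    return base + toward_centre * (spec.base_radius + STANDOFF)


def _axis_xy(spec: StemSpec, dirs: tuple, h) -> np.ndarray:
    """Axis XY at heights *h* above the base terrain; always (n, 2)."""
    lean_vec, sweep_vec = dirs
    h = np.atleast_1d(np.asarray(h, dtype=float))
    base = np.asarray(spec.base_xy, dtype=float)
    lean = math.tan(math.radians(spec.lean_deg))
    return (
        base[None, :]
        + np.outer(h, lean_vec) * lean
        + np.outer(h / BREAST_HEIGHT, sweep_vec) * spec.sweep_offset
    )


def _sample_stem_surface(
    spec: StemSpec, dirs: tuple, z_base: float, spacing: float, rng
):
    """Rings of surface points up the (tapered, swept, leaning) axis.

    The sampled arc is centred on the azimuth facing the plot origin — the
    face an operator approaching from the interior would see first.
    """
    base = np.asarray(spec.base_xy, dtype=float)
    phi_c = math.atan2(-base[1], -base[0]) if np.any(base) else 0.0
    cov = math.radians(spec.angular_coverage)
    heights = np.arange(0.0, spec.height + 1e-9, spacing)
    pts = []
    for h in heights:
        r = spec.radius_at(h)
        n_theta = max(int(round(cov * r / spacing)), 3)
        theta = phi_c - cov / 2 + (np.arange(n_theta) + 0.5) * cov / n_theta
        axis = _axis_xy(spec, dirs, np.array([h]))[0]
        rr = r
        if spec.surface_noise_sd > 0:
            rr = r + rng.normal(0.0, spec.surface_noise_sd, size=n_theta)
        x = axis[0] + rr * np.cos(theta)
        y = axis[1] + rr * np.sin(theta)
        z = np.full(n_theta, z_base + h)
        pts.append(np.column_stack([x, y, z]))
    return np.vstack(pts)


# ---------------------------------------------------------------------------
# understory sampling and the analytic volume oracle


def sample_patch_points(patch: PatchSpec, rng, terrain=None) -> np.ndarray:
    """Sample a patch: uniform-density interior points by rejection, plus a
    jittered grid of points on the analytic upper surface. z is AGH plus
    the terrain height when a terrain function is given."""
    (x0, y0, z0), (x1, y1, z1) = patch.volume_bbox()
    bbox_vol = (x1 - x0) * (y1 - y0) * (z1 - z0)
    n_target = max(int(round(patch.point_density * bbox_vol)), 1)
    cand = np.column_stack([
        rng.uniform(x0, x1, n_target),
        rng.uniform(y0, y1, n_target),
        rng.uniform(z0, z1, n_target),
    ])
    parts = [cand[patch.contains(cand)]]
    if patch.surface_point_spacing:
        s = patch.surface_point_spacing
        sx = np.arange(x0 + s / 2, x1, s)
        sy = np.arange(y0 + s / 2, y1, s)
        gx, gy = np.meshgrid(sx, sy)
        gx = gx.ravel() + rng.uniform(-s / 3, s / 3, gx.size)
        gy = gy.ravel() + rng.uniform(-s / 3, s / 3, gy.size)
        top = patch.top_height(gx, gy)
        ok = ~np.isnan(top) & (top > 0)
        parts.append(np.column_stack([gx[ok], gy[ok], top[ok]]))
    pts = np.vstack(parts)
    if terrain is not None and len(pts):
        pts[:, 2] += terrain(pts[:, 0], pts[:, 1])
    return pts


def analytic_understory_volume_oracle(
    patches: list,
    subplot_center_xy,
    subplot_radius: float,
    voxel_edge: float,
) -> float:
    """Column-fill volume of the analytic patch shapes, in m^3.

    Rasterises the shapes onto the same voxel grid the pipeline uses
    (anchored at the subplot bounding box, columns whose centres fall
    inside the circle): per column the highest voxel whose centre lies
    inside any shape is found, and it plus all voxels beneath it count as
    filled. Heights are above-ground heights, so terrain relief cancels.
    """
    if voxel_edge <= 0:
        raise ValueError("voxel_edge must be positive")
    if not patches:
        return 0.0
    center = np.asarray(subplot_center_xy, dtype=float)
    anchor = center - subplot_radius
    n_side = int(math.ceil(2 * subplot_radius / voxel_edge))
    cx = anchor[0] + (np.arange(n_side) + 0.5) * voxel_edge
    cy = anchor[1] + (np.arange(n_side) + 0.5) * voxel_edge
    X, Y = np.meshgrid(cx, cy)
    inside = (X - center[0]) ** 2 + (Y - center[1]) ** 2 <= subplot_radius ** 2
    top = np.full(X.shape, np.nan)
    for patch in patches:
        t = patch.top_height(X, Y)
        top = np.where(np.isnan(top), t, np.where(np.isnan(t), top, np.maximum(top, t)))
    top = np.where(inside, top, np.nan)
    valid = ~np.isnan(top)
    if not valid.any():
        return 0.0
    # highest voxel whose centre (i + 0.5) * edge is at or below the top
    i_max = np.floor(top[valid] / voxel_edge - 0.5 + 1e-12).astype(np.int64)
    cap = int(math.ceil(BREAST_HEIGHT / voxel_edge))
    filled = np.clip(i_max + 1, 0, cap).sum()
    return float(filled) * voxel_edge ** 3


# ---------------------------------------------------------------------------
# scene generation


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Generate the plot: ground disk + stem surfaces + understory patches.

    Rejects configs whose stem axes at ground level are closer than the sum
    of their base radii. Output is byte-identical for identical configs.
    """
    # overlap validation
    for i in range(len(config.stems)):
        for j in range(i + 1, len(config.stems)):
            a, b = config.stems[i], config.stems[j]
            d = math.dist(a.base_xy, b.base_xy)
            if d < a.base_radius + b.base_radius:
                raise ValueError(
                    f"stems {i} and {j} overlap: base distance {d:.3f} m < "
                    f"sum of radii {a.base_radius + b.base_radius:.3f} m"
                )

    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, 11])
    )
    terrain = _make_terrain(config.ground_relief_amplitude, config.seed)

    clouds = []
    labels = []

    # ground disk on a jittered grid
    s = config.ground_point_spacing
    R = config.plot_radius
    coords = np.arange(-R, R + s / 2, s)
    gx, gy = np.meshgrid(coords, coords)
    gx = gx.ravel()
    gy = gy.ravel()
    keep = gx ** 2 + gy ** 2 <= R ** 2
    gx, gy = gx[keep], gy[keep]
    gx = gx + rng.uniform(-s / 3, s / 3, gx.shape)
    gy = gy + rng.uniform(-s / 3, s / 3, gy.shape)
    gz = terrain(gx, gy)
    if config.ground_noise_sd > 0:
        gz = gz + rng.normal(0.0, config.ground_noise_sd, gz.shape)
    clouds.append(np.column_stack([gx, gy, gz]))
    labels.append(np.full(len(gx), GROUND_LABEL, dtype=np.int64))

    # stems
    stem_dirs = []
    for i, spec in enumerate(config.stems):
        lean_az = rng.uniform(0, 2 * math.pi)
        sweep_az = rng.uniform(0, 2 * math.pi)
        dirs = (
            np.array([math.cos(lean_az), math.sin(lean_az)]),
            np.array([math.cos(sweep_az), math.sin(sweep_az)]),
        )
        stem_dirs.append(dirs)
        z_base = float(terrain(*spec.base_xy))
        pts = _sample_stem_surface(spec, dirs, z_base, config.point_spacing, rng)
        clouds.append(pts)
        labels.append(np.full(len(pts), STEM_LABEL_OFFSET + i, dtype=np.int64))

    # understory
    for patch in config.understory_patches:
        pts = sample_patch_points(patch, rng, terrain)
        if len(pts):
            clouds.append(pts)
            labels.append(np.full(len(pts), UNDERSTORY_LABEL, dtype=np.int64))

    cloud = PointCloud(
        np.vstack(clouds), {"label": np.concatenate(labels)}
    )

    # truth
    bases = np.array([s_.base_xy for s_ in config.stems], dtype=float)
    truth = []
    if len(bases) >= 2:
        diff = bases[:, None, :] - bases[None, :, :]
        dmat = np.hypot(diff[..., 0], diff[..., 1])
        np.fill_diagonal(dmat, np.inf)
        nearest = dmat.min(axis=1)
    else:
        nearest = [None] * len(bases)
    for i, spec in enumerate(config.stems):
        truth.append(
            {
                "stem_id": i,
                "base_xy": np.asarray(spec.base_xy, dtype=float),
                "dbh_true_cm": spec.dbh_true,
                "nearest_stem_distance_true": (
                    float(nearest[i]) if nearest[i] is not None else None
                ),
            }
        )

    scene = SyntheticScene(
        cloud=cloud, config=config, truth_stems=truth, terrain=terrain
    )
    scene._stem_dirs = stem_dirs
    return scene


# ---------------------------------------------------------------------------
# artifacts


def apply_artifacts(scene: SyntheticScene, artifact: ArtifactSpec) -> SyntheticScene:
    """Return a copy of the scene with RGB-D capture artifacts applied.

    (a) Any stem within ``sensor_range`` of another stem's capture position
    has a ``duplicate_fraction`` arc of its points (the arc facing that
    capture position) copied and shifted rigidly by ``duplicate_offset``.
    (b) ``backscatter_fraction`` of each stem's points are displaced
    radially by ``backscatter_bias`` (positive = outward). During a
    circumnavigation every azimuth passes through the sensor silhouette, so
    edge pixels are drawn uniformly over the stem surface.
    (c) All points accumulate a rigid translation growing with the
    simulated capture-path length (stem to stem at 1 m standoff, one loop
    per stem), applied per 30-degree observation sector.
    """
    config = scene.config
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, 13])
    )
    xyz = scene.cloud.xyz.copy()
    label = scene.cloud.attributes["label"].copy()
    n_stems = len(config.stems)
    captures = [_capture_position(s) for s in config.stems]
    bases = [np.asarray(s.base_xy, dtype=float) for s in config.stems]

    extra_pts = []
    extra_labels = []

    # (b) backscatter on the original stem points (before duplication so
    # duplicated faces inherit the displacement, as re-observed pixels do)
    for i, spec in enumerate(config.stems):
        frac = artifact.backscatter_fraction
        if frac <= 0 or artifact.backscatter_bias == 0:
            # still draw to keep the random stream aligned across configs
            sel_draw = rng.random(int((label == STEM_LABEL_OFFSET + i).sum()))
            continue
        mask = label == STEM_LABEL_OFFSET + i
        idx = np.nonzero(mask)[0]
        draws = rng.random(len(idx))
        chosen = idx[draws < frac]
        if len(chosen) == 0:
            continue
        h = xyz[chosen, 2] - scene.terrain(*bases[i])
        axis = _axis_xy(spec, scene._stem_dirs[i], h)
        radial = xyz[chosen, :2] - axis
        norms = np.hypot(radial[:, 0], radial[:, 1])
        norms = np.maximum(norms, 1e-9)
        xyz[chosen, 0] += radial[:, 0] / norms * artifact.backscatter_bias
        xyz[chosen, 1] += radial[:, 1] / norms * artifact.backscatter_bias

    # (a) duplicate faces
    for i, spec in enumerate(config.stems):
        observer = None
        for j in range(n_stems):
            if j == i:
                continue
            if (
                np.linalg.norm(captures[j] - bases[i]) - spec.base_radius
                <= artifact.sensor_range
            ):
                observer = j
                break
        if observer is None or artifact.duplicate_fraction <= 0:
            continue
        mask = label == STEM_LABEL_OFFSET + i
        pts = xyz[mask]
        az = np.arctan2(
            pts[:, 1] - bases[i][1], pts[:, 0] - bases[i][0]
        )
        toward = captures[observer] - bases[i]
        az_c = math.atan2(toward[1], toward[0])
        half = math.pi * artifact.duplicate_fraction
        delta = np.angle(np.exp(1j * (az - az_c)))
        arc = np.abs(delta) <= half
        if not arc.any():
            continue
        shift_dir = rng.uniform(0, 2 * math.pi)
        shift = artifact.duplicate_offset * np.array(
            [math.cos(shift_dir), math.sin(shift_dir), 0.0]
        )
        dup = pts[arc] + shift
        extra_pts.append(dup)
        extra_labels.append(np.full(len(dup), STEM_LABEL_OFFSET + i, dtype=np.int64))

    if extra_pts:
        dup_flag = np.concatenate(
            [np.zeros(len(xyz), dtype=np.int64)]
            + [np.ones(len(p), dtype=np.int64) for p in extra_pts]
        )
        xyz = np.vstack([xyz] + extra_pts)
        label = np.concatenate([label] + extra_labels)
    else:
        dup_flag = np.zeros(len(xyz), dtype=np.int64)

    # (c) drift along the capture path
    if artifact.drift_rate > 0 and n_stems:
        order = _path_order(bases)
        cum = np.zeros(n_stems)
        loops = np.zeros(n_stems)
        dist = 0.0
        prev = captures[order[0]]
        for k, i in enumerate(order):
            dist += float(np.linalg.norm(captures[i] - prev))
            cum[i] = dist
            loops[i] = 2 * math.pi * (config.stems[i].base_radius + STANDOFF)
            dist += loops[i]
            prev = captures[i]
        drift_az = rng.uniform(0, 2 * math.pi)
        drift_dir = np.array([math.cos(drift_az), math.sin(drift_az), 0.0])

        # stem points drift per 30-degree sector of their observation loop
        for i, spec in enumerate(config.stems):
            mask = label == STEM_LABEL_OFFSET + i
            if not mask.any():
                continue
            pts = xyz[mask]
            az = np.arctan2(pts[:, 1] - bases[i][1], pts[:, 0] - bases[i][0])
            sector = np.floor(((az + math.pi) / (2 * math.pi)) * 12).astype(int)
            sector = np.clip(sector, 0, 11)
            path_at = cum[i] + (sector + 0.5) / 12.0 * loops[i]
            xyz[mask] = pts + np.outer(
                artifact.drift_rate * path_at, drift_dir
            )
        # ground / understory points inherit the drift of the nearest stem
        other = (label == GROUND_LABEL) | (label == UNDERSTORY_LABEL)
        if other.any():
            base_arr = np.array(bases)
            d = np.linalg.norm(
                xyz[other, None, :2] - base_arr[None, :, :2], axis=2
            )
            nearest = np.argmin(d, axis=1)
            mid = cum[nearest] + 0.5 * loops[nearest]
            xyz[other] = xyz[other] + np.outer(
                artifact.drift_rate * mid, drift_dir
            )

    cloud = PointCloud(xyz, {"label": label, "duplicate": dup_flag})
    out = SyntheticScene(
        cloud=cloud,
        config=config,
        truth_stems=scene.truth_stems,
        terrain=scene.terrain,
    )
    out._stem_dirs = scene._stem_dirs
    return out


def _path_order(bases: list) -> list:
    """Greedy nearest-neighbour visiting order starting at stem 0."""
    n = len(bases)
    remaining = set(range(1, n))
    order = [0]
    while remaining:
        last = bases[order[-1]]
        nxt = min(remaining, key=lambda j: float(np.linalg.norm(bases[j] - last)))
        order.append(nxt)
        remaining.remove(nxt)
    return order
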