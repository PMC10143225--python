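"""Point-cloud and stem-table input/output.

Coordinates are always metres, z-up, in an arbitrary local frame. Supported
cloud formats: ASCII / binary-little-endian PLY, LAS 1.2-1.4 (point record
formats 0-3, uncompressed), and delimited XYZ text. Stem tables are plain CSV.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PointCloud",
    "FormatError",
    "read_cloud",
    "write_cloud",
    "crop_radial",
    "read_stem_table",
    "write_stem_table",
    "STEM_TABLE_COLUMNS",
]

#: Column names of the stem table CSV.
STEM_TABLE_COLUMNS = [
    "plot_id",
    "stem_id",
    "base_x",
    "base_y",
    "dbh_cm",
    "device",
    "capture_status",
]

CAPTURE_STATUSES = {"captured", "failed_tracking", "failed_other"}


class FormatError(ValueError):
    """Raised when a cloud file does not parse under its declared format."""


@dataclass
class PointCloud:
    """Unordered 3D points (metres) with optional per-point attributes.

    Attributes are parallel arrays keyed by name (e.g. ``label``,
    ``intensity``, ``source``); each must have one entry per point.
    """

    xyz: np.ndarray
    attributes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("point coordinates must be finite")
        for name, arr in list(self.attributes.items()):
            arr = np.asarray(arr)
            if arr.shape[0] != len(self):
                raise ValueError(
                    f"attribute {name!r} has length {arr.shape[0]}, "
                    f"expected {len(self)}"
                )
            self.attributes[name] = arr

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def xy(self) -> np.ndarray:
        return self.xyz[:, :2]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def select(self, mask_or_index) -> "PointCloud":
        """New cloud with the given boolean mask / index array applied,
        preserving point order and all attributes."""
        return PointCloud(
            self.xyz[mask_or_index],
            {k: v[mask_or_index] for k, v in self.attributes.items()},
        )

    def concat(self, other: "PointCloud") -> "PointCloud":
        attrs = {}
        for k in self.attributes:
            if k in other.attributes:
                attrs[k] = np.concatenate(
                    [self.attributes[k], other.attributes[k]]
                )
        return PointCloud(np.vstack([self.xyz, other.xyz]), attrs)

    @classmethod
    def empty(cls) -> "PointCloud":
        return cls(np.empty((0, 3)))


# ---------------------------------------------------------------------------
# format detection


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("ply", "las"):
        return suffix
    if suffix in ("xyz", "txt", "csv", "asc", "pts"):
        return "xyz"
    raise FormatError(f"cannot infer point-cloud format from {path.name!r}")


def read_cloud(path, format: str | None = None) -> PointCloud:
    """Read a point cloud from *path* (``ply``, ``las`` or ``xyz``).

    Unknown per-point attributes are ignored with a logged warning. An empty
    file yields an empty cloud, not an error.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "las":
        return _read_las(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise FormatError(f"unsupported format {fmt!r}")


def write_cloud(cloud: PointCloud, path, format: str | None = None) -> None:
    """Write *cloud* to *path*. PLY is written as ASCII, LAS as version 1.2
    point format 0. Attributes a format cannot hold are dropped with a
    warning; coordinates are never dropped."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "ply":
        _write_ply(cloud, path)
    elif fmt == "las":
        _write_las(cloud, path)
    elif fmt == "xyz":
        _write_xyz(cloud, path)
    else:
        raise FormatError(f"unsupported format {fmt!r}")


# ---------------------------------------------------------------------------
# XYZ text


def _read_xyz(path: Path) -> PointCloud:
    text = path.read_text()
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        try:
            vals = [float(v) for v in parts[:3]]
        except ValueError:
            if rows:
                raise FormatError(
                    f"{path.name}:{lineno}: non-numeric row {line!r}"
                )
            continue  # header line
        if len(vals) < 3:
            raise FormatError(f"{path.name}:{lineno}: fewer than 3 columns")
        rows.append(vals)
    if not rows:
        return PointCloud.empty()
    return PointCloud(np.asarray(rows))


def _write_xyz(cloud: PointCloud, path: Path) -> None:
    if cloud.attributes:
        logger.warning("XYZ format drops attributes: %s", sorted(cloud.attributes))
    np.savetxt(path, cloud.xyz, fmt="%.6f")


# ---------------------------------------------------------------------------
# PLY

_PLY_TYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}

#: PLY vertex properties (besides x/y/z) that map onto cloud attributes.
_PLY_ATTRS = {"intensity", "label", "source", "classification", "scalar_label"}


def _read_ply(path: Path) -> PointCloud:
    raw = path.read_bytes()
    if not raw:
        return PointCloud.empty()
    if not raw.startswith(b"ply"):
        raise FormatError(f"{path.name}: missing 'ply' magic")
    end = raw.find(b"end_header")
    if end < 0:
        raise FormatError(f"{path.name}: missing 'end_header'")
    header = raw[:end].decode("ascii", errors="replace").splitlines()
    body = raw[end:]
    body = body[body.index(b"\n") + 1:]

    fmt = None
    elements: list[tuple[str, int, list[tuple[str, str]]]] = []
    for line in header[1:]:
        tokens = line.split()
        if not tokens or tokens[0] == "comment":
            continue
        if tokens[0] == "format":
            if len(tokens) < 2 or tokens[1] not in (
                "ascii", "binary_little_endian"
            ):
                raise FormatError(
                    f"{path.name}: unsupported PLY format line {line!r}"
                )
            fmt = tokens[1]
        elif tokens[0] == "element":
            if len(tokens) != 3:
                raise FormatError(f"{path.name}: malformed element line {line!r}")
            elements.append((tokens[1], int(tokens[2]), []))
        elif tokens[0] == "property":
            if not elements:
                raise FormatError(f"{path.name}: property before element")
            if tokens[1] == "list":
                elements[-1][2].append(("__list__", " ".join(tokens[2:])))
            else:
                if tokens[1] not in _PLY_TYPES:
                    raise FormatError(
                        f"{path.name}: unknown property type {tokens[1]!r}"
                    )
                elements[-1][2].append((tokens[-1], _PLY_TYPES[tokens[1]]))
    if fmt is None:
        raise FormatError(f"{path.name}: missing 'format' line")
    if not elements:
        raise FormatError(f"{path.name}: no elements declared")
    name, count, props = elements[0]
    if name != "vertex":
        raise FormatError(f"{path.name}: first element is {name!r}, not vertex")
    if any(p == "__list__" for p, _ in props):
        raise FormatError(f"{path.name}: list properties in vertex element")
    prop_names = [p for p, _ in props]
    for c in "xyz":
        if c not in prop_names:
            raise FormatError(f"{path.name}: vertex element lacks property {c!r}")
    if count == 0:
        return PointCloud.empty()

    if fmt == "ascii":
        lines = body.decode("ascii").splitlines()[:count]
        data = np.array([[float(v) for v in ln.split()] for ln in lines])
        cols = {p: data[:, i] for i, (p, _) in enumerate(props)}
    else:
        dtype = np.dtype([(p, "<" + t) for p, t in props])
        data = np.frombuffer(body, dtype=dtype, count=count)
        cols = {p: data[p] for p, _ in props}

    xyz = np.column_stack([cols["x"], cols["y"], cols["z"]])
    attrs = {}
    for p in prop_names:
        if p in ("x", "y", "z"):
            continue
        if p in _PLY_ATTRS:
            attrs[p.replace("scalar_", "")] = np.array(cols[p])
        else:
            logger.warning("%s: ignoring vertex property %r", path.name, p)
    return PointCloud(xyz, attrs)


def _write_ply(cloud: PointCloud, path: Path) -> None:
    attrs = {}
    for k, v in cloud.attributes.items():
        if k in _PLY_ATTRS:
            attrs[k] = v
        else:
            logger.warning("PLY write drops attribute %r", k)
    lines = ["ply", "format ascii 1.0", f"element vertex {len(cloud)}"]
    for c in "xyz":
        lines.append(f"property double {c}")
    for k, v in attrs.items():
        ptype = "double" if np.issubdtype(np.asarray(v).dtype, np.floating) else "int"
        lines.append(f"property {ptype} {k}")
    lines.append("end_header")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        cols = [cloud.xyz]
        fmts = ["%.6f"] * 3
        for v in attrs.values():
            cols.append(np.asarray(v).reshape(-1, 1))
            fmts.append(
                "%.6f" if np.issubdtype(np.asarray(v).dtype, np.floating) else "%d"
            )
        if len(cloud):
            np.savetxt(fh, np.column_stack(cols), fmt=" ".join(fmts))


# ---------------------------------------------------------------------------
# LAS (uncompressed). Header layout per the ASPRS LAS 1.2-1.4 specifications.

_LAS_POINT_DTYPES = {
    0: np.dtype([("X", "<i4"), ("Y", "<i4"), ("Z", "<i4"),
                 ("intensity", "<u2"), ("flags", "u1"),
                 ("classification", "u1"), ("scan_angle", "i1"),
                 ("user_data", "u1"), ("point_source_id", "<u2")]),
}
_LAS_POINT_DTYPES[1] = np.dtype(_LAS_POINT_DTYPES[0].descr + [("gps_time", "<f8")])
_LAS_POINT_DTYPES[2] = np.dtype(
    _LAS_POINT_DTYPES[0].descr
    + [("red", "<u2"), ("green", "<u2"), ("blue", "<u2")]
)
_LAS_POINT_DTYPES[3] = np.dtype(
    _LAS_POINT_DTYPES[1].descr
    + [("red", "<u2"), ("green", "<u2"), ("blue", "<u2")]
)


def _read_las(path: Path) -> PointCloud:
    raw = path.read_bytes()
    if not raw:
        return PointCloud.empty()
    if raw[:4] != b"LASF":
        raise FormatError(f"{path.name}: missing 'LASF' signature")
    if len(raw) < 227:
        raise FormatError(f"{path.name}: truncated LAS header")
    ver_major, ver_minor = raw[24], raw[25]
    if ver_major != 1 or ver_minor not in (2, 3, 4):
        raise FormatError(
            f"{path.name}: unsupported LAS version {ver_major}.{ver_minor}"
        )
    (offset_to_points,) = struct.unpack_from("<I", raw, 96)
    point_format = raw[104]
    if point_format not in _LAS_POINT_DTYPES:
        raise FormatError(
            f"{path.name}: unsupported point data format {point_format}"
        )
    (record_len,) = struct.unpack_from("<H", raw, 105)
    (n_points,) = struct.unpack_from("<I", raw, 107)
    scale = struct.unpack_from("<3d", raw, 131)
    offset = struct.unpack_from("<3d", raw, 155)
    if ver_minor == 4 and n_points == 0:
        (n_points,) = struct.unpack_from("<Q", raw, 247)
    if n_points == 0:
        return PointCloud.empty()
    dtype = _LAS_POINT_DTYPES[point_format]
    if record_len < dtype.itemsize:
        raise FormatError(
            f"{path.name}: point record length {record_len} shorter than "
            f"format {point_format} minimum {dtype.itemsize}"
        )
    if record_len > dtype.itemsize:
        # extra bytes per record: pad and ignore
        dtype = np.dtype(dtype.descr + [("__pad__", f"V{record_len - dtype.itemsize}")])
    data = np.frombuffer(raw, dtype=dtype, count=n_points, offset=offset_to_points)
    xyz = np.column_stack([
        data["X"] * scale[0] + offset[0],
        data["Y"] * scale[1] + offset[1],
        data["Z"] * scale[2] + offset[2],
    ])
    attrs = {
        "intensity": np.array(data["intensity"]),
        "classification": np.array(data["classification"]),
    }
    return PointCloud(xyz, attrs)


def _write_las(cloud: PointCloud, path: Path) -> None:
    n = len(cloud)
    scale = np.array([0.001, 0.001, 0.001])
    offset = cloud.xyz.min(axis=0) if n else np.zeros(3)
    header = bytearray(227)
    header[0:4] = b"LASF"
    header[24] = 1
    header[25] = 2
    header[90:94] = struct.pack("<HH", 1, 2023)  # day-of-year, year
    struct.pack_into("<H", header, 94, 227)      # header size
    struct.pack_into("<I", header, 96, 227)      # offset to point data
    struct.pack_into("<I", header, 100, 0)       # number of VLRs
    header[104] = 0                              # point data format
    struct.pack_into("<H", header, 105, _LAS_POINT_DTYPES[0].itemsize)
    struct.pack_into("<I", header, 107, n)
    struct.pack_into("<3d", header, 131, *scale)
    struct.pack_into("<3d", header, 155, *offset)
    if n:
        mx, mn = cloud.xyz.max(axis=0), cloud.xyz.min(axis=0)
    else:
        mx = mn = np.zeros(3)
    struct.pack_into("<6d", header, 179, mx[0], mn[0], mx[1], mn[1], mx[2], mn[2])

    rec = np.zeros(n, dtype=_LAS_POINT_DTYPES[0])
    scaled = np.round((cloud.xyz - offset) / scale)
    rec["X"], rec["Y"], rec["Z"] = scaled[:, 0], scaled[:, 1], scaled[:, 2]
    if "intensity" in cloud.attributes:
        rec["intensity"] = np.clip(cloud.attributes["intensity"], 0, 65535)
    if "classification" in cloud.attributes:
        rec["classification"] = np.clip(cloud.attributes["classification"], 0, 255)
    dropped = set(cloud.attributes) - {"intensity", "classification"}
    if dropped:
        logger.warning("LAS write drops attributes: %s", sorted(dropped))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(rec.tobytes())


# ---------------------------------------------------------------------------
# geometry helpers


def crop_radial(cloud: PointCloud, center_xy, radius: float) -> PointCloud:
    """Points with horizontal distance <= *radius* of *center_xy*
    (boundary inclusive); retains point order and attributes."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center_xy, dtype=float).reshape(2)
    d2 = np.sum((cloud.xy - center) ** 2, axis=1)
    return cloud.select(d2 <= radius * radius + 1e-12)


# ---------------------------------------------------------------------------
# stem tables


def read_stem_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(STEM_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"stem table missing columns: {sorted(missing)}")
    bad = df[(df["capture_status"] == "captured") & ~(df["dbh_cm"] > 0)]
    if len(bad):
        raise FormatError(
            f"captured stems with non-positive dbh_cm: {bad['stem_id'].tolist()}"
        )
    unknown = set(df["capture_status"].unique()) - CAPTURE_STATUSES
    if unknown:
        raise FormatError(f"unknown capture_status values: {sorted(unknown)}")
    return df


def write_stem_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in STEM_TABLE_COLUMNS if c in df.columns])
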