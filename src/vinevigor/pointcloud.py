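"""Point-cloud handling and voxel-based apparent volumes.

A mobile terrestrial LiDAR rig (two stacked line scanners, one pass per row
side) yields a 3D point cloud per elementary plot.  Apparent canopy and
pruning-wood volumes are derived by voxelizing the scene and counting the
voxels hit by at least one return:

    V_i = N_v,i * s

with ``N_v,i`` the number of occupied ("vine") voxels attributed to plant i
and ``s`` the voxel volume in litres (10-mm voxels for summer canopy scenes,
5-mm voxels for winter wood scenes).  Pruning-wood volume is the difference
of the before- and after-pruning apparent volumes, which also cancels the
contribution of trellis wires present in both scans.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SENSORS = ("lower", "upper")
SIDES = ("north", "south")

#: heights (m) of the two scanners above ground; overlap is split at their midpoint
DEFAULT_SENSOR_HEIGHTS = (0.8, 1.5)


@dataclass
class PointCloud:
    """Returns of one scene pass, with optional per-point annotations.

    Parameters
    ----------
    points : (n, 3) float array
        x along-row, y across-row, z height, all in metres.
    sensor, side, label : (n,) str arrays, optional
        Per-point sensor ("lower"/"upper"), row side ("north"/"south") and
        simulator bookkeeping label (e.g. "soil", "wire", "canopy").
    plot_id : str, optional
    """

    points: np.ndarray
    sensor: np.ndarray | None = None
    side: np.ndarray | None = None
    label: np.ndarray | None = None
    plot_id: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        self.points = pts
        for name in ("sensor", "side", "label"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != (len(pts),):
                    raise ValueError(f"{name} must have one entry per point")
                setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.points)

    def subset(self, mask: np.ndarray) -> "PointCloud":
        """Return the sub-cloud selected by a boolean mask, keeping annotations."""
        mask = np.asarray(mask)
        return PointCloud(
            self.points[mask],
            None if self.sensor is None else self.sensor[mask],
            None if self.side is None else self.side[mask],
            None if self.label is None else self.label[mask],
            self.plot_id,
        )

    def split_sensor_side(self) -> dict[tuple[str, str], "PointCloud"]:
        """Split into the four (sensor, side) sub-clouds."""
        if self.sensor is None or self.side is None:
            raise ValueError("cloud has no sensor/side annotations to split on")
        out = {}
        for sen in SENSORS:
            for sd in SIDES:
                out[(sen, sd)] = self.subset((self.sensor == sen) & (self.side == sd))
        return out

    @staticmethod
    def concatenate(clouds: Sequence["PointCloud"]) -> "PointCloud":
        clouds = list(clouds)
        if not clouds:
            return PointCloud(np.empty((0, 3)))

        def cat(name):
            arrs = [getattr(c, name) for c in clouds]
            if any(a is None for a in arrs):
                return None
            return np.concatenate(arrs)

        return PointCloud(
            np.vstack([c.points for c in clouds]),
            cat("sensor"), cat("side"), cat("label"),
            clouds[0].plot_id,
        )


@dataclass
class VoxelGrid:
    """Set of occupied voxels on a regular grid anchored at ``origin``.

    Cells are half-open: a point p falls in the voxel with index
    floor((p - origin) / s) per axis, so every point maps to exactly one cell.
    """

    origin: tuple[float, float, float]
    s: float
    occupied: np.ndarray  # (m, 3) int64, unique rows

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("voxel edge s must be positive")
        occ = np.asarray(self.occupied, dtype=np.int64)
        if occ.size == 0:
            occ = occ.reshape(0, 3)
        if occ.ndim != 2 or occ.shape[1] != 3:
            raise ValueError("occupied must be an (m, 3) index array")
        self.occupied = np.unique(occ, axis=0)
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def n_occupied(self) -> int:
        return len(self.occupied)

    @property
    def volume_liters(self) -> float:
        """|occupied| * s^3, converted from m^3 to litres."""
        return self.n_occupied * self.s**3 * 1000.0

    def centers(self) -> np.ndarray:
        """(m, 3) array of cell-centre coordinates in metres."""
        return np.asarray(self.origin) + (self.occupied + 0.5) * self.s

    def _check_compatible(self, other: "VoxelGrid") -> None:
        if not np.isclose(self.s, other.s, rtol=0, atol=1e-12):
            raise ValueError("voxel sizes differ")
        if not np.allclose(self.origin, other.origin, rtol=0, atol=1e-9):
            raise ValueError("grid origins differ")

    def union(self, other: "VoxelGrid") -> "VoxelGrid":
        self._check_compatible(other)
        return VoxelGrid(self.origin, self.s,
                         np.vstack([self.occupied, other.occupied]))


@dataclass
class PlantVolumeRecord:
    genotype: str
    block: int
    plot_id: str
    plant_index: int
    season: str
    trait: str  # "canopy" or "wood"
    volume_liters: float

    def __post_init__(self) -> None:
        if self.volume_liters < 0:
            raise ValueError("apparent volume must be >= 0")

    def to_dict(self) -> dict:
        return {
            "genotype": self.genotype, "block": self.block, "plot": self.plot_id,
            "plant": self.plant_index, "season": self.season, "trait": self.trait,
            "volume_L": self.volume_liters,
        }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.csv")


def load_point_cloud(path, fmt: str = "auto") -> PointCloud:
    """Load a point cloud from whitespace XYZ text or LAS.

    XYZ files are three whitespace-separated columns (x y z, metres); an
    optional sidecar ``<name>.meta.csv`` carries per-point sensor, side and
    plot annotations.  LAS support requires the optional ``laspy`` package.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        fmt = "las" if path.suffix.lower() == ".las" else "xyz"
    if fmt == "xyz":
        return _load_xyz(path)
    if fmt == "las":
        return _load_las(path)
    raise ValueError(f"unknown point-cloud format {fmt!r}")


def _load_xyz(path: Path) -> PointCloud:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from exc
    if not rows:
        logger.warning("point cloud file %s is empty", path)
        return PointCloud(np.empty((0, 3)))
    pts = np.asarray(rows)
    sensor = side = label = None
    plot_id = None
    meta = _sidecar_path(path)
    if meta.exists():
        df = pd.read_csv(meta)
        if len(df) != len(pts):
            raise ValueError(f"{meta}: {len(df)} rows for {len(pts)} points")
        if "sensor" in df:
            sensor = df["sensor"].to_numpy(dtype=str)
        if "side" in df:
            side = df["side"].to_numpy(dtype=str)
        if "label" in df:
            label = df["label"].to_numpy(dtype=str)
        if "plot_id" in df and len(df):
            plot_id = str(df["plot_id"].iloc[0])
    return PointCloud(pts, sensor, side, label, plot_id)


def _load_las(path: Path) -> PointCloud:
    try:
        import laspy
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "LAS support requires the optional 'laspy' package; "
            "use whitespace XYZ instead") from exc
    las = laspy.read(path)
    pts = np.column_stack([las.x, las.y, las.z]).astype(float)
    return PointCloud(pts)


def write_point_cloud(cloud: PointCloud, path, fmt: str = "auto") -> Path:
    """Write as XYZ text (plus sidecar CSV when annotated) or LAS (point format 0)."""
    path = Path(path)
    if fmt == "auto":
        fmt = "las" if path.suffix.lower() == ".las" else "xyz"
    if fmt == "xyz":
        np.savetxt(path, cloud.points, fmt="%.6f")
        if cloud.sensor is not None or cloud.side is not None or cloud.label is not None:
            with open(_sidecar_path(path), "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["point_id", "sensor", "side", "label", "plot_id"])
                n = len(cloud)
                sen = cloud.sensor if cloud.sensor is not None else [""] * n
                sd = cloud.side if cloud.side is not None else [""] * n
                lab = cloud.label if cloud.label is not None else [""] * n
                for i in range(n):
                    writer.writerow([i, sen[i], sd[i], lab[i], cloud.plot_id or ""])
        return path
    if fmt == "las":
        try:
            import laspy
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "LAS support requires the optional 'laspy' package") from exc
        header = laspy.LasHeader(point_format=0, version="1.2")
        header.scales = (0.0001, 0.0001, 0.0001)
        las = laspy.LasData(header)
        las.x, las.y, las.z = cloud.points.T
        las.write(path)
        return path
    raise ValueError(f"unknown point-cloud format {fmt!r}")


# ---------------------------------------------------------------------------
# Scene filtering and voxelization
# ---------------------------------------------------------------------------

def filter_scene(
    cloud: PointCloud,
    soil_margin: float = 0.05,
    y_halfwidth: float = 0.85,
    wire_masks: Sequence[tuple[float, float]] | None = None,
    sensor_heights: tuple[float, float] = DEFAULT_SENSOR_HEIGHTS,
) -> PointCloud:
    """Remove soil, background and the overlap between the two scanners.

    Points at or below ``soil_margin`` above the registered ground plane are
    dropped, as are points beyond ``y_halfwidth`` across-row (background and
    neighbouring rows) and any configured wire z-bands.  When the cloud is
    annotated with sensors, each scanner keeps only its exclusive vertical
    band, split at the midpoint between the scanner heights, so no z-band
    retains returns from both instruments.
    """
    z = cloud.points[:, 2]
    keep = (z > soil_margin) & (np.abs(cloud.points[:, 1]) <= y_halfwidth)
    if wire_masks:
        for zlo, zhi in wire_masks:
            keep &= ~((z >= zlo) & (z <= zhi))
    if cloud.sensor is not None:
        split = 0.5 * (sensor_heights[0] + sensor_heights[1])
        keep &= np.where(cloud.sensor == "lower", z < split, z >= split)
    out = cloud.subset(keep)
    if len(out) == 0 and len(cloud) > 0:
        warnings.warn(f"all {len(cloud)} points removed by scene filtering")
    return out


def voxelize(
    cloud: PointCloud,
    s: float,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    min_hits: int = 1,
) -> VoxelGrid:
    """Classify half-open grid cells as "vine" when they contain >= min_hits returns."""
    if s <= 0:
        raise ValueError("voxel edge s must be positive")
    if min_hits < 1:
        raise ValueError("min_hits must be >= 1")
    if len(cloud) == 0:
        return VoxelGrid(origin, s, np.empty((0, 3), dtype=np.int64))
    idx = np.floor((cloud.points - np.asarray(origin)) / s).astype(np.int64)
    if min_hits == 1:
        occ = np.unique(idx, axis=0)
    else:
        occ, counts = np.unique(idx, axis=0, return_counts=True)
        occ = occ[counts >= min_hits]
    return VoxelGrid(origin, s, occ)


def split_plant_zones(
    grid: VoxelGrid,
    plot_extent: tuple[float, float],
    n_plants: int,
) -> np.ndarray:
    """Attribute occupied voxels to plants by equal along-row zones.

    The plot's along-row extent is divided into ``n_plants`` equal half-open
    segments and each voxel is assigned by its cell-centre x.  Centres falling
    outside the extent go to the nearest end zone (with a warning).  Returns
    the per-plant occupied counts, which always sum to the total.
    """
    x_start, x_end = plot_extent
    if x_end <= x_start:
        raise ValueError("plot extent must have x_end > x_start")
    if n_plants not in (1, 2, 3):
        raise ValueError("n_plants must be 1, 2 or 3")
    counts = np.zeros(n_plants, dtype=np.int64)
    if grid.n_occupied == 0:
        return counts
    x = grid.centers()[:, 0]
    if np.any((x < x_start) | (x >= x_end)):
        warnings.warn("voxel centres outside the plot extent assigned to end zones")
    width = (x_end - x_start) / n_plants
    zone = np.clip(np.floor((x - x_start) / width).astype(int), 0, n_plants - 1)
    for k in range(n_plants):
        counts[k] = int(np.sum(zone == k))
    return counts


def combine_sensor_side_grids(
    grids: Mapping[tuple[str, str], VoxelGrid],
    side_combine: str = "union",
) -> tuple[float, VoxelGrid | None]:
    """Merge the four (sensor, side) voxel grids into one per-plant count.

    Per side, the lower and upper scanner grids are pooled (their occupied
    sets, which are disjoint after overlap removal, are united).  The two row
    sides are then combined:

    - ``union``:  voxel-set union in the shared grid (default);
    - ``sum``:    side counts added;
    - ``mean``:   side counts averaged.

    Returns (combined count, combined grid) -- the grid is None for the
    count-only modes ``sum`` and ``mean``.
    """
    per_side: dict[str, VoxelGrid] = {}
    for (sensor, side), grid in grids.items():
        per_side[side] = grid if side not in per_side else per_side[side].union(grid)
    sides = list(per_side.values())
    if not sides:
        raise ValueError("no grids supplied")
    if side_combine == "union":
        merged = sides[0]
        for g in sides[1:]:
            merged = merged.union(g)
        return float(merged.n_occupied), merged
    if side_combine == "sum":
        return float(sum(g.n_occupied for g in sides)), None
    if side_combine == "mean":
        return float(np.mean([g.n_occupied for g in sides])), None
    raise ValueError(f"unknown side_combine {side_combine!r}")


def apparent_volume(
    grids: Mapping[tuple[str, str], VoxelGrid],
    side_combine: str = "union",
    *,
    genotype: str = "",
    block: int = 1,
    plot_id: str = "",
    plant_index: int = 1,
    season: str = "summer",
    trait: str = "canopy",
) -> PlantVolumeRecord:
    """Per-plant apparent volume V = N_v * s (litres) from (sensor, side) grids."""
    s_values = {round(g.s, 12) for g in grids.values()}
    if len(s_values) > 1:
        raise ValueError("all grids must share the same voxel size")
    s = next(iter(grids.values())).s
    count, _ = combine_sensor_side_grids(grids, side_combine)
    return PlantVolumeRecord(genotype, block, plot_id, plant_index, season, trait,
                             count * s**3 * 1000.0)


def pruning_wood_volume(
    before: VoxelGrid,
    after: VoxelGrid,
    *,
    genotype: str = "",
    block: int = 1,
    plot_id: str = "",
    plant_index: int = 1,
    season: str = "winter",
) -> PlantVolumeRecord:
    """Wood removed at pruning: (N_before - N_after) * s, floored at zero.

    Both grids must use the same (5-mm) voxel size and origin so that wires
    and permanent wood present in both scans cancel exactly.
    """
    if not np.isclose(before.s, after.s, rtol=0, atol=1e-12):
        raise ValueError("before/after grids must share the same voxel size")
    before._check_compatible(after)
    diff = before.n_occupied - after.n_occupied
    if diff < 0:
        warnings.warn(
            f"negative pruning-wood voxel difference ({diff}); flooring at 0")
        diff = 0
    return PlantVolumeRecord(genotype, block, plot_id, plant_index, season, "wood",
                             diff * before.s**3 * 1000.0)


def pruning_wood_volume_from_counts(n_before: int, n_after: int, s: float) -> float:
    """Count-level variant of :func:`pruning_wood_volume`, returning litres."""
    diff = n_before - n_after
    if diff < 0:
        warnings.warn(
            f"negative pruning-wood voxel difference ({diff}); flooring at 0")
        diff = 0
    return diff * s**3 * 1000.0


def volume_records_to_frame(records: Iterable[PlantVolumeRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records])
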