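"""Canopy trait extraction from single-sector laser-scan point clouds.

A top-down line scanner sweeps each sector (a 65 cm x 40/60 cm plot) and
returns a dense point cloud in millimetre coordinates, z measured upward
from the platform ground plane.  This module turns one such cloud into
canopy traits:

* **3D leaf area** — the area of the triangulated canopy surface,
  independent of leaf orientation (reported in cm^2);
* **projected area** — the ground-cover area of the canopy's vertical
  projection, akin to leaf area index when divided by ground area;
* **plant height** — a robust upper quantile of point heights above the
  pot rim (cm);
* **leaf angle** — the area-weighted mean angle between triangle surface
  normals and the vertical (degrees; 0 deg = flat leaf).

Meshing is a 2.5D Delaunay triangulation over the xy-projection: a
single-viewpoint nadir scan is single-valued in xy, so the Delaunay
triangles tile the sampled footprint without overlap.  Triangles with any
3D edge longer than ``max_edge_mm`` are pruned; this is what prevents the
mesh from bridging between separate leaves or between canopy layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .errors import CalibrationError, ConfigurationError

__all__ = [
    "PointCloud",
    "CalibrationFrame",
    "TriangleMesh",
    "CanopyTraits",
    "TraitConfig",
    "sensor_to_platform",
    "filter_pot_height",
    "mesh_point_cloud",
    "leaf_area_3d",
    "projected_area",
    "plant_height",
    "leaf_angle",
    "extract_traits",
    "bin_sectors",
]

MM2_PER_CM2 = 100.0
MM_PER_CM = 10.0

#: quality flags attached to CanopyTraits
FLAG_OK = "ok"
FLAG_LOW_POINTS = "low_points"


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return np.empty((0, 3), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (N, 3) array of x, y, z in mm")
    return pts


@dataclass
class PointCloud:
    """One sector scan: xyz points (mm), z up from the platform ground plane."""

    sector_id: str
    timestamp: datetime
    points: np.ndarray  # (N, 3) float, mm

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        if self.timestamp.tzinfo is None:
            self.timestamp = self.timestamp.replace(tzinfo=timezone.utc)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]


@dataclass(frozen=True)
class CalibrationFrame:
    """Scanner calibration distances (all mm).

    ``d_ground`` is the sensor-to-ground distance, ``d_target`` the
    sensor-to-barcode-target distance and ``target_height`` the physical
    height of that target; the three must agree to within ``tolerance_mm``
    or the frame is rejected.  ``pot_height`` is the cutoff below which
    returns (pot rim, soil, mulch) are excluded from trait computation.
    """

    d_ground: float
    d_target: float
    target_height: float
    pot_height: float = 0.0
    tolerance_mm: float = 5.0

    def validate(self) -> None:
        if not (self.d_ground > self.d_target > 0):
            raise CalibrationError(
                f"require d_ground > d_target > 0, got {self.d_ground}, {self.d_target}"
            )
        if self.pot_height < 0:
            raise CalibrationError(f"pot_height must be >= 0, got {self.pot_height}")
        residual = self.d_ground - self.d_target - self.target_height
        if abs(residual) > self.tolerance_mm:
            raise CalibrationError(
                "inconsistent calibration frame: "
                f"d_ground - d_target = {self.d_ground - self.d_target:.2f} mm but "
                f"target_height = {self.target_height:.2f} mm "
                f"(residual {residual:.2f} mm > tolerance {self.tolerance_mm} mm)"
            )


class TriangleMesh:
    """Triangulated canopy surface with per-triangle areas and unit normals.

    Degenerate (zero-area) triangles are dropped on construction.  When the
    mesh comes from :func:`mesh_point_cloud` it keeps a handle to the
    underlying Delaunay triangulation, which lets :func:`projected_area`
    rasterise occupancy with a single vectorised point-location query.
    """

    def __init__(
        self,
        vertices: np.ndarray,
        triangles: np.ndarray,
        _delaunay: Delaunay | None = None,
        _retained: np.ndarray | None = None,
    ) -> None:
        self.vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
        tri = np.asarray(triangles, dtype=np.intp).reshape(-1, 3)
        if tri.size and (tri.min() < 0 or tri.max() >= len(self.vertices)):
            raise ValueError("triangle index out of range")
        areas, normals = _triangle_areas_normals(self.vertices, tri)
        keep = areas > 0.0
        self.triangles = tri[keep]
        self.areas = areas[keep]  # mm^2
        self.normals = normals[keep]  # unit vectors
        self._delaunay = _delaunay
        if _delaunay is not None:
            retained = np.zeros(len(_delaunay.simplices), dtype=bool)
            if _retained is not None:
                retained[_retained[keep]] = True
            self._retained_simplices = retained
        else:
            self._retained_simplices = None

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def is_empty(self) -> bool:
        return self.n_triangles == 0

    def total_area_mm2(self) -> float:
        return float(self.areas.sum())

    @classmethod
    def empty(cls) -> "TriangleMesh":
        return cls(np.empty((0, 3)), np.empty((0, 3), dtype=np.intp))


def _triangle_areas_normals(vertices: np.ndarray, tri: np.ndarray):
    if tri.size == 0:
        return np.empty(0), np.empty((0, 3))
    a = vertices[tri[:, 0]]
    cross = np.cross(vertices[tri[:, 1]] - a, vertices[tri[:, 2]] - a)
    norm = np.linalg.norm(cross, axis=1)
    areas = 0.5 * norm
    with np.errstate(invalid="ignore", divide="ignore"):
        normals = cross / norm[:, None]
    normals[norm == 0] = 0.0
    return areas, normals


@dataclass
class CanopyTraits:
    """Per-sector, per-scan canopy traits."""

    sector_id: str
    timestamp: datetime
    leaf_area_3d_cm2: float
    projected_area_cm2: float
    height_cm: float
    leaf_angle_deg: float  # NaN when undefined (no mesh)
    n_points: int
    quality_flag: str = FLAG_OK

    def as_record(self) -> dict:
        return {
            "sector_id": self.sector_id,
            "timestamp": self.timestamp.isoformat(),
            "leaf_area_3d_cm2": self.leaf_area_3d_cm2,
            "projected_area_cm2": self.projected_area_cm2,
            "height_cm": self.height_cm,
            "leaf_angle_deg": self.leaf_angle_deg,
            "n_points": self.n_points,
            "quality_flag": self.quality_flag,
        }


@dataclass(frozen=True)
class TraitConfig:
    """Tunable parameters of the trait-extraction chain.

    ``max_edge_mm`` defaults to four times the 0.8 mm scan pitch; longer
    edges only arise from gaps between leaves or occlusion cliffs, never
    from a contiguous sampled surface tilted less than ~75 deg.
    """

    max_edge_mm: float = 3.2
    raster_mm: float = 0.8
    height_percentile: float = 0.995
    min_points: int = 50


def sensor_to_platform(
    raw: np.ndarray,
    frame: CalibrationFrame,
    sector_id: str = "",
    timestamp: datetime | None = None,
) -> PointCloud:
    """Convert per-pixel sensor distances into platform-frame heights.

    ``raw`` is an (N, 3) array of ``(x_mm, y_mm, d_plant_mm)`` where
    ``d_plant`` is the measured sensor-to-surface distance.  Heights are
    ``z = d_ground - d_plant``; returns that would land below the ground
    plane (z < 0, spurious long ranges) are dropped.
    """
    frame.validate()
    raw = np.asarray(raw, dtype=float).reshape(-1, 3)
    z = frame.d_ground - raw[:, 2]
    keep = z >= 0.0
    pts = np.column_stack([raw[keep, 0], raw[keep, 1], z[keep]])
    return PointCloud(
        sector_id=sector_id,
        timestamp=timestamp or datetime.now(timezone.utc),
        points=pts,
    )


def filter_pot_height(cloud: PointCloud, frame: CalibrationFrame) -> PointCloud:
    """Drop returns at or below the pot-height cutoff (pot, soil, mulch)."""
    keep = cloud.z > frame.pot_height
    return replace(cloud, points=cloud.points[keep])


def mesh_point_cloud(cloud: PointCloud, max_edge_mm: float = 3.2) -> TriangleMesh:
    """Triangulate a single-viewpoint cloud into a 2.5D surface mesh.

    Delaunay triangulation over the xy-projection, then pruning of every
    triangle with any 3D edge longer than ``max_edge_mm``.  Fewer than
    three non-collinear points yield an empty mesh.
    """
    pts = cloud.points
    if len(pts) < 3:
        return TriangleMesh.empty()
    try:
        dela = Delaunay(pts[:, :2])
    except QhullError:
        return TriangleMesh.empty()  # collinear or otherwise degenerate in xy
    simplices = dela.simplices
    if simplices.size == 0:
        return TriangleMesh.empty()
    a = pts[simplices[:, 0]]
    b = pts[simplices[:, 1]]
    c = pts[simplices[:, 2]]
    max_edge_sq = max(
        0.0, max_edge_mm
    ) ** 2
    edge_ok = (
        (((b - a) ** 2).sum(axis=1) <= max_edge_sq)
        & (((c - b) ** 2).sum(axis=1) <= max_edge_sq)
        & (((a - c) ** 2).sum(axis=1) <= max_edge_sq)
    )
    keep_idx = np.flatnonzero(edge_ok)
    return TriangleMesh(
        pts, simplices[keep_idx], _delaunay=dela, _retained=keep_idx
    )


def leaf_area_3d(mesh: TriangleMesh) -> float:
    """Total retained triangle area in cm^2 (0 for an empty mesh)."""
    return mesh.total_area_mm2() / MM2_PER_CM2


def _raster_grid(bounds, raster_mm: float):
    """Cell-centre coordinates of a raster covering ``bounds`` (xy)."""
    (xmin, ymin), (xmax, ymax) = bounds
    nx = max(1, int(math.ceil((xmax - xmin) / raster_mm)))
    ny = max(1, int(math.ceil((ymax - ymin) / raster_mm)))
    cx = xmin + (np.arange(nx) + 0.5) * raster_mm
    cy = ymin + (np.arange(ny) + 0.5) * raster_mm
    return cx, cy


def projected_area(mesh: TriangleMesh, raster_mm: float = 0.8) -> float:
    """Ground-cover area (cm^2) of the mesh's vertical projection.

    Occupancy is rasterised on a ``raster_mm`` grid and the *union* of
    triangle footprints is counted, so stacked canopy layers are not
    double-counted — this is what makes the quantity akin to ground cover
    (and, per ground area, to LAI).
    """
    if raster_mm <= 0:
        raise ValueError("raster_mm must be > 0")
    if mesh.is_empty():
        return 0.0
    used = np.unique(mesh.triangles.ravel())
    xy = mesh.vertices[used][:, :2]
    bounds = (xy.min(axis=0), xy.max(axis=0))
    cx, cy = _raster_grid(bounds, raster_mm)
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    centres = np.column_stack([gx.ravel(), gy.ravel()])
    if mesh._delaunay is not None:
        simp = mesh._delaunay.find_simplex(centres)
        occupied = (simp >= 0) & mesh._retained_simplices[np.where(simp >= 0, simp, 0)]
        n_occ = int(np.count_nonzero(occupied))
    else:
        n_occ = _count_covered(centres, mesh)
    return n_occ * raster_mm * raster_mm / MM2_PER_CM2


def _count_covered(centres: np.ndarray, mesh: TriangleMesh) -> int:
    """Count raster centres covered by >= 1 triangle (STRtree point query)."""
    import shapely

    tri_xy = mesh.vertices[mesh.triangles][:, :, :2]
    polys = shapely.polygons(tri_xy)
    tree = shapely.STRtree(polys)
    pts = shapely.points(centres)
    pairs = tree.query(pts, predicate="intersects")
    return int(np.unique(pairs[0]).size)


def plant_height(
    cloud: PointCloud, frame: CalibrationFrame, percentile: float = 0.995
) -> float:
    """Robust plant height (cm) above the pot rim.

    Uses the given quantile of z (default 99.5th percentile; 1.0 = max) so
    single stray high returns do not inflate the estimate.  Expects a
    pot-height-filtered cloud; returns 0 when empty.
    """
    if len(cloud) == 0:
        return 0.0
    zq = float(np.quantile(cloud.z, percentile))
    return max(0.0, zq - frame.pot_height) / MM_PER_CM


def leaf_angle(mesh: TriangleMesh) -> float:
    """Area-weighted mean angle (deg) between surface normals and vertical.

    The sign of a surface normal is ambiguous, so angles are folded into
    [0 deg, 90 deg]; 0 deg means a horizontal (flat) leaf surface.  Returns
    NaN for an empty mesh — undefined, deliberately distinct from 0.
    """
    if mesh.is_empty():
        return float("nan")
    cos_v = np.clip(np.abs(mesh.normals[:, 2]), 0.0, 1.0)
    angles = np.degrees(np.arccos(cos_v))
    return float(np.average(angles, weights=mesh.areas))


def extract_traits(
    cloud: PointCloud,
    frame: CalibrationFrame,
    config: TraitConfig | None = None,
) -> CanopyTraits:
    """Full trait chain: pot filter -> mesh -> area/height/angle.

    Clouds with fewer than ``config.min_points`` canopy points yield
    all-zero traits with a ``low_points`` quality flag instead of an error,
    so platform-scale batch runs never abort on an empty sector.
    """
    config = config or TraitConfig()
    frame.validate()
    canopy = filter_pot_height(cloud, frame)
    n = len(canopy)
    if n < config.min_points:
        return CanopyTraits(
            sector_id=cloud.sector_id,
            timestamp=cloud.timestamp,
            leaf_area_3d_cm2=0.0,
            projected_area_cm2=0.0,
            height_cm=0.0,
            leaf_angle_deg=float("nan"),
            n_points=n,
            quality_flag=FLAG_LOW_POINTS,
        )
    mesh = mesh_point_cloud(canopy, max_edge_mm=config.max_edge_mm)
    return CanopyTraits(
        sector_id=cloud.sector_id,
        timestamp=cloud.timestamp,
        leaf_area_3d_cm2=leaf_area_3d(mesh),
        projected_area_cm2=projected_area(mesh, raster_mm=config.raster_mm),
        height_cm=plant_height(canopy, frame, percentile=config.height_percentile),
        leaf_angle_deg=leaf_angle(mesh),
        n_points=n,
        quality_flag=FLAG_OK,
    )


def bin_sectors(
    stream: PointCloud,
    sector_layout: Sequence[tuple[str, float, float]],
    barcode_positions: Iterable[float] | None = None,
) -> list[PointCloud]:
    """Split a scan-lane cloud into per-sector clouds by y coordinate.

    ``sector_layout`` is a list of ``(sector_id, y_start, y_end)`` with
    half-open intervals [y_start, y_end) in lane coordinates; intervals
    must not overlap.  Points falling in inter-sector gaps are dropped.
    When ``barcode_positions`` are given (physical markers along the lane,
    nominally every 5 m), each output cloud's y is re-zeroed to the start
    of the barcode block containing it, mirroring the scanner's position
    reset at every barcode.
    """
    layout = sorted(sector_layout, key=lambda s: s[1])
    for sid, y0, y1 in layout:
        if y1 <= y0:
            raise ConfigurationError(f"sector {sid!r}: empty interval [{y0}, {y1})")
    for (ida, _, enda), (idb, startb, _) in zip(layout, layout[1:]):
        if startb < enda:
            raise ConfigurationError(f"sectors {ida!r} and {idb!r} overlap in y")

    barcodes = np.sort(np.asarray(list(barcode_positions or []), dtype=float))
    y = stream.y
    clouds: list[PointCloud] = []
    for sid, y0, y1 in layout:
        mask = (y >= y0) & (y < y1)
        pts = stream.points[mask].copy()
        if barcodes.size and len(pts):
            idx = np.searchsorted(barcodes, pts[:, 1], side="right") - 1
            block_start = np.where(idx >= 0, barcodes[np.clip(idx, 0, None)], 0.0)
            pts[:, 1] = pts[:, 1] - block_start
        clouds.append(
            PointCloud(sector_id=sid, timestamp=stream.timestamp, points=pts)
        )
    return clouds
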