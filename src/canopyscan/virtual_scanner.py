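"""Virtual laser scanner: synthetic canopies with known ground truth.

No public dataset of platform scans exists, so every geometry operation is
validated against parametric scenes whose traits are known analytically.
A :class:`SectorScene` is a set of plants, each a list of
:class:`LeafPatch` surfaces (planar polygons, arched strap leaves for
cereals, elliptical leaflets for legumes).  :func:`render_scan` images a
scene the way the real sensor does: a vertical ray is cast at every node
of a 0.8 x 0.8 mm grid, only the *highest* surface intersection is kept
(single top-down perspective, so lower layers are occluded), z is
quantised to 0.2 mm, and wind adds seeded Gaussian xy jitter.

The module also synthesises the platform's other two data streams:
load-cell weight traces (diurnal transpiration + irrigation/drainage
steps + scale noise) and 30-min weather records, so the lysimetry and
environment modules can be tested end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd

from .scan_geometry import MM2_PER_CM2, MM_PER_CM, CanopyTraits, PointCloud

__all__ = [
    "LeafPatch",
    "SectorScene",
    "ScanConfig",
    "planar_leaf",
    "strap_leaf",
    "elliptical_leaflet",
    "build_scene",
    "render_scan",
    "scene_truth",
    "synthesize_env_series",
    "synthesize_weight_trace",
]

#: xy jitter standard deviation per unit wind speed (mm per m s^-1)
WIND_JITTER_MM_PER_MS = 0.5

SPECIES_ARCHETYPES = ("planar", "cereal", "legume")


@dataclass
class LeafPatch:
    """One leaf surface: a fine triangle mesh plus its analytic truth.

    ``area_cm2`` and ``angle_deg`` are exact for the parametric surface
    (the facet mesh is only used for ray casting and rasterisation).
    """

    kind: str
    vertices: np.ndarray  # (n, 3) mm
    faces: np.ndarray  # (m, 3) int
    area_cm2: float
    angle_deg: float

    def top_z(self) -> float:
        return float(self.vertices[:, 2].max())

    def facet_xyz(self) -> np.ndarray:
        """(m, 3, 3) array of facet corner coordinates."""
        return self.vertices[self.faces]


def _rot_x(deg: float) -> np.ndarray:
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_z(deg: float) -> np.ndarray:
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def planar_leaf(
    centre,
    width_mm: float,
    length_mm: float,
    tilt_deg: float = 0.0,
    azimuth_deg: float = 0.0,
) -> LeafPatch:
    """Flat rectangular leaf blade, tilted about its own width axis."""
    w, l = width_mm / 2.0, length_mm / 2.0
    local = np.array(
        [[-w, -l, 0.0], [w, -l, 0.0], [w, l, 0.0], [-w, l, 0.0]]
    )
    verts = local @ _rot_x(tilt_deg).T @ _rot_z(azimuth_deg).T + np.asarray(centre, float)
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    return LeafPatch(
        kind="planar",
        vertices=verts,
        faces=faces,
        area_cm2=width_mm * length_mm / MM2_PER_CM2,
        angle_deg=abs(tilt_deg),
    )


def elliptical_leaflet(
    centre,
    width_mm: float,
    length_mm: float,
    tilt_deg: float = 0.0,
    azimuth_deg: float = 0.0,
    n_segments: int = 48,
) -> LeafPatch:
    """Flat elliptical leaflet (legume archetype), meshed as a fan."""
    t = np.linspace(0.0, 2 * math.pi, n_segments, endpoint=False)
    ring = np.column_stack(
        [0.5 * width_mm * np.cos(t), 0.5 * length_mm * np.sin(t), np.zeros_like(t)]
    )
    local = np.vstack([[0.0, 0.0, 0.0], ring])
    verts = local @ _rot_x(tilt_deg).T @ _rot_z(azimuth_deg).T + np.asarray(centre, float)
    idx = np.arange(1, n_segments + 1)
    faces = np.column_stack([np.zeros_like(idx), idx, np.roll(idx, -1)])
    # analytic area of the inscribed polygon fan, not of the ideal ellipse:
    # the rendered surface IS the fan, so truth must match what is imaged
    poly_area = 0.5 * n_segments * math.sin(2 * math.pi / n_segments) * (
        0.5 * width_mm
    ) * (0.5 * length_mm)
    return LeafPatch(
        kind="legume",
        vertices=verts,
        faces=faces,
        area_cm2=poly_area / MM2_PER_CM2,
        angle_deg=abs(tilt_deg),
    )


def strap_leaf(
    anchor,
    width_mm: float,
    arc_radius_mm: float,
    base_inclination_deg: float = 50.0,
    azimuth_deg: float = 0.0,
    n_segments: int = 24,
) -> LeafPatch:
    """Arched strap leaf (cereal archetype): a circular-arc ribbon.

    The centreline rises from ``anchor`` at ``base_inclination_deg`` above
    horizontal and flattens to horizontal at the tip, following a circular
    arc of radius ``arc_radius_mm`` in a vertical plane.  The ribbon width
    stays horizontal and perpendicular to the travel direction, so the
    surface is ruled and its area is exactly arc_length x width, and the
    area-weighted mean surface angle is exactly half the base inclination
    (inclination decreases linearly in arc length).
    """
    phi0 = math.radians(base_inclination_deg)
    if not 0.0 < phi0 < math.radians(80.0):
        raise ValueError("base inclination must be in (0, 80) degrees")
    phis = np.linspace(phi0, 0.0, n_segments + 1)
    run = arc_radius_mm * (np.sin(phi0) - np.sin(phis))  # horizontal advance
    rise = arc_radius_mm * (np.cos(phis) - np.cos(phi0))  # height gain
    half_w = width_mm / 2.0
    left = np.column_stack([np.full_like(run, -half_w), run, rise])
    right = np.column_stack([np.full_like(run, half_w), run, rise])
    local = np.vstack([left, right])
    verts = local @ _rot_z(azimuth_deg).T + np.asarray(anchor, float)
    n = n_segments + 1
    i = np.arange(n_segments)
    faces = np.vstack(
        [
            np.column_stack([i, i + 1, i + n]),
            np.column_stack([i + 1, i + n + 1, i + n]),
        ]
    )
    # chord-based area of the faceted ribbon (matches what is rendered);
    # converges to R*phi0*width as n_segments grows
    seg = np.sqrt(np.diff(run) ** 2 + np.diff(rise) ** 2).sum()
    return LeafPatch(
        kind="cereal",
        vertices=verts,
        faces=faces,
        area_cm2=seg * width_mm / MM2_PER_CM2,
        angle_deg=math.degrees(phi0) / 2.0,
    )


@dataclass
class SectorScene:
    """A sector's worth of plants with exact, recomputable ground truth."""

    sector_id: str
    plants: list[list[LeafPatch]]
    width_mm: float = 650.0
    length_mm: float = 400.0
    pot_centres: list[tuple[float, float]] = field(default_factory=list)
    pot_radius_mm: float = 135.0
    pot_rim_mm: float = 150.0

    @property
    def patches(self) -> list[LeafPatch]:
        return [p for plant in self.plants for p in plant]

    @property
    def ground_area_m2(self) -> float:
        return self.width_mm * self.length_mm / 1e6

    @property
    def density_per_m2(self) -> float:
        return len(self.plants) / self.ground_area_m2

    def total_area_cm2(self) -> float:
        return float(sum(p.area_cm2 for p in self.patches))


@dataclass(frozen=True)
class ScanConfig:
    """Scanner geometry and noise model.

    Defaults mirror the platform sensor: 0.8 mm grid pitch in x and y,
    0.2 mm height quantisation, a 650 mm scan width and 400 mm (or 600 mm)
    sector length, 1000 mm maximum height.
    """

    pitch_x: float = 0.8
    pitch_y: float = 0.8
    z_quantum: float = 0.2
    width_mm: float = 650.0
    length_mm: float = 400.0
    max_height_mm: float = 1000.0
    jitter_mm_per_ms: float = WIND_JITTER_MM_PER_MS
    seed: int = 0

    def __post_init__(self):
        if self.pitch_x <= 0 or self.pitch_y <= 0 or self.z_quantum <= 0:
            raise ValueError("pitches and z_quantum must be > 0")


def build_scene(
    density_per_m2: float = 16.0,
    species: str = "cereal",
    leaf_area_cm2: float = 40.0,
    leaves_per_plant: int = 4,
    width_mm: float = 650.0,
    length_mm: float = 400.0,
    base_height_mm: float = 260.0,
    arrangement: str = "natural",
    seed: int = 0,
    sector_id: str = "S01",
) -> SectorScene:
    """Build a reproducible synthetic sector.

    ``density_per_m2`` fixes the plant count (rounded to the sector's
    ground area; 16 m^-2 is a typical cereal field density, 24-32 m^-2 a
    legume one).  ``leaf_area_cm2`` is the nominal area of one leaf;
    individual leaves vary +/-20% around it.  ``arrangement``:

    * ``"spaced"`` — every leaf confined to its own grid cell so xy
      footprints are disjoint (single-layer canopy, for recovery tests);
    * ``"natural"`` — leaves radiate from each plant's crown and may
      overlap neighbours (field-like, occlusion expected).
    """
    if density_per_m2 <= 0:
        raise ValueError("density must be > 0")
    if species not in SPECIES_ARCHETYPES:
        raise ValueError(f"unknown species archetype {species!r}")
    rng = np.random.default_rng(seed)
    area_m2 = width_mm * length_mm / 1e6
    n_plants = max(1, round(density_per_m2 * area_m2))
    n_leaves = n_plants * leaves_per_plant

    plants: list[list[LeafPatch]] = []
    if arrangement == "spaced":
        cells = _disjoint_cells(n_leaves, width_mm, length_mm, leaf_area_cm2, rng)
        k = 0
        for _ in range(n_plants):
            leaves = []
            for _ in range(leaves_per_plant):
                leaves.append(
                    _make_cell_leaf(species, cells[k], leaf_area_cm2, base_height_mm, rng)
                )
                k += 1
            plants.append(leaves)
        pot_centres = []
    elif arrangement == "natural":
        centres = _plant_grid(n_plants, width_mm, length_mm, rng)
        for cx, cy in centres:
            leaves = []
            for j in range(leaves_per_plant):
                az = 360.0 * j / leaves_per_plant + rng.uniform(-20, 20)
                leaves.append(
                    _make_radiating_leaf(
                        species, (cx, cy), az, leaf_area_cm2, base_height_mm, rng
                    )
                )
            plants.append(leaves)
        pot_centres = centres
    else:
        raise ValueError(f"unknown arrangement {arrangement!r}")

    return SectorScene(
        sector_id=sector_id,
        plants=plants,
        width_mm=width_mm,
        length_mm=length_mm,
        pot_centres=pot_centres,
    )


def _plant_grid(n: int, width: float, length: float, rng) -> list[tuple[float, float]]:
    ncol = int(math.ceil(math.sqrt(n * width / length)))
    nrow = int(math.ceil(n / ncol))
    xs = np.linspace(width / (2 * ncol), width - width / (2 * ncol), ncol)
    ys = np.linspace(length / (2 * nrow), length - length / (2 * nrow), nrow)
    pts = [(x, y) for y in ys for x in xs][:n]
    return [
        (x + rng.uniform(-8, 8), y + rng.uniform(-8, 8)) for x, y in pts
    ]


def _disjoint_cells(n: int, width: float, length: float, leaf_area: float, rng):
    """Rectangular cells sized so one leaf always fits, with clear gaps.

    A strap leaf of nominal area A (max 1.2 A after size jitter) runs at
    most ~1.9 sqrt(A_mm2) along its azimuth; cells are 2.0 sqrt(A) long
    and 1.5 sqrt(A) wide (plus padding), and leaf azimuths are kept close
    to the cell long axis, so footprints of neighbouring cells never
    touch (gaps exceed the 3.2 mm mesh edge cutoff by construction).
    """
    s = math.sqrt(1.2 * leaf_area * MM2_PER_CM2)
    cell_x = 2.0 * s + 12.0
    cell_y = 1.5 * s + 12.0
    ncol = max(1, int(width // cell_x))
    nrow = max(1, int(length // cell_y))
    if ncol * nrow < n:
        raise ValueError(
            f"cannot place {n} disjoint leaves of {leaf_area} cm^2 "
            f"in a {width} x {length} mm sector"
        )
    xs = np.linspace(cell_x / 2, width - cell_x / 2, ncol)
    ys = np.linspace(cell_y / 2, length - cell_y / 2, nrow)
    cells = [(x, y) for y in ys for x in xs]
    order = rng.permutation(len(cells))[:n]
    return [(cells[i][0], cells[i][1], cell_x, cell_y) for i in order]


def _make_cell_leaf(species, cell, leaf_area, base_z, rng) -> LeafPatch:
    """One leaf confined to its rectangular cell (single-layer scenes)."""
    cx, cy, cell_x, cell_y = cell
    area = leaf_area * rng.uniform(0.8, 1.2)
    z = base_z + rng.uniform(0.0, 60.0)
    az = rng.uniform(-10.0, 10.0)  # near the cell long axis
    if species == "cereal":
        width = math.sqrt(area * MM2_PER_CM2 / 3.0)  # 1:3 blade
        incl = rng.uniform(20.0, 55.0)
        radius = 3.0 * width / math.radians(incl)  # arc length = 3*width
        ax = cx - cell_x / 2.0 + 6.0  # anchored at the cell edge, runs +x
        return strap_leaf(
            (ax, cy, z), width, radius, base_inclination_deg=incl,
            azimuth_deg=az - 90.0,
        )
    tilt = rng.uniform(0.0, 45.0)
    if species == "legume":
        width = math.sqrt(4.0 * area * MM2_PER_CM2 / (math.pi * 1.5))
        return elliptical_leaflet(
            (cx, cy, z), 1.5 * width, width, tilt_deg=tilt, azimuth_deg=az
        )
    side = math.sqrt(area * MM2_PER_CM2)
    return planar_leaf((cx, cy, z), side, side, tilt_deg=tilt, azimuth_deg=az)


def _make_radiating_leaf(species, crown, azimuth, leaf_area, base_z, rng) -> LeafPatch:
    area = leaf_area * rng.uniform(0.8, 1.2)
    z = base_z + rng.uniform(0.0, 120.0)
    if species == "cereal":
        width = math.sqrt(area * MM2_PER_CM2 / 3.0)
        incl = rng.uniform(25.0, 55.0)
        radius = 3.0 * width / math.radians(incl)
        return strap_leaf(
            (crown[0], crown[1], z), width, radius,
            base_inclination_deg=incl, azimuth_deg=azimuth - 90.0,
        )
    tilt = rng.uniform(5.0, 45.0)
    reach = rng.uniform(30.0, 90.0)
    cx = crown[0] + reach * math.cos(math.radians(azimuth))
    cy = crown[1] + reach * math.sin(math.radians(azimuth))
    if species == "legume":
        width = math.sqrt(4.0 * area * MM2_PER_CM2 / (math.pi * 1.5))
        return elliptical_leaflet((cx, cy, z), width, 1.5 * width, tilt, azimuth)
    side = math.sqrt(area * MM2_PER_CM2)
    return planar_leaf((cx, cy, z), side, side, tilt, azimuth)


def render_scan(
    scene: SectorScene,
    config: ScanConfig | None = None,
    wind_ms: float = 0.0,
    timestamp: datetime | None = None,
    include_ground: bool = True,
) -> PointCloud:
    """Image a scene as the nadir line scanner would.

    One vertical ray per grid node (inclusive endpoints, so an L mm span
    at pitch p yields floor(L/p)+1 samples); only the highest intersection
    is recorded.  Ground and pot-rim returns are included at their true
    heights unless ``include_ground`` is False.  Wind displaces each
    recorded point in xy by seeded Gaussian jitter with
    sd = ``config.jitter_mm_per_ms`` x wind.
    """
    config = config or ScanConfig()
    nx = int(math.floor(config.width_mm / config.pitch_x)) + 1
    ny = int(math.floor(config.length_mm / config.pitch_y)) + 1
    gx = np.arange(nx) * config.pitch_x
    gy = np.arange(ny) * config.pitch_y

    zbuf = np.zeros((nx, ny))  # ground plane
    for cx, cy in scene.pot_centres:
        ix = (gx[:, None] - cx) ** 2 + (gy[None, :] - cy) ** 2 <= scene.pot_radius_mm**2
        zbuf[ix] = np.maximum(zbuf[ix], scene.pot_rim_mm)
    ground_top = zbuf.max()

    for patch in scene.patches:
        _splat_patch(zbuf, gx, gy, patch, config)

    zbuf = np.minimum(zbuf, config.max_height_mm)
    zq = np.round(zbuf / config.z_quantum) * config.z_quantum
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zq.ravel()])
    if not include_ground:
        pts = pts[zbuf.ravel() > ground_top + 1e-9]

    if wind_ms > 0:
        rng = np.random.default_rng(config.seed)
        pts[:, :2] += rng.normal(
            0.0, config.jitter_mm_per_ms * wind_ms, size=(len(pts), 2)
        )

    return PointCloud(
        sector_id=scene.sector_id,
        timestamp=timestamp or datetime(2024, 1, 1, tzinfo=timezone.utc),
        points=pts,
    )


def _splat_patch(zbuf, gx, gy, patch: LeafPatch, config: ScanConfig) -> None:
    """Depth-buffer a patch: per facet, interpolate z at covered grid nodes."""
    tris = patch.facet_xyz()
    for tri in tris:
        x0, x1 = tri[:, 0].min(), tri[:, 0].max()
        y0, y1 = tri[:, 1].min(), tri[:, 1].max()
        # 1e-9 guards against FP error when a facet edge lands exactly on a node
        i0 = max(0, int(math.ceil(x0 / config.pitch_x - 1e-9)))
        i1 = min(len(gx) - 1, int(math.floor(x1 / config.pitch_x + 1e-9)))
        j0 = max(0, int(math.ceil(y0 / config.pitch_y - 1e-9)))
        j1 = min(len(gy) - 1, int(math.floor(y1 / config.pitch_y + 1e-9)))
        if i1 < i0 or j1 < j0:
            continue
        px = gx[i0 : i1 + 1]
        py = gy[j0 : j1 + 1]
        qx, qy = np.meshgrid(px, py, indexing="ij")
        a, b, c = tri[0, :2], tri[1, :2], tri[2, :2]
        det = (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
        if abs(det) < 1e-12:
            continue
        l1 = ((qx - a[0]) * (c[1] - a[1]) - (qy - a[1]) * (c[0] - a[0])) / det
        l2 = ((b[0] - a[0]) * (qy - a[1]) - (b[1] - a[1]) * (qx - a[0])) / det
        l0 = 1.0 - l1 - l2
        eps = -1e-9
        inside = (l0 >= eps) & (l1 >= eps) & (l2 >= eps)
        if not inside.any():
            continue
        z = l0 * tri[0, 2] + l1 * tri[1, 2] + l2 * tri[2, 2]
        sub = zbuf[i0 : i1 + 1, j0 : j1 + 1]
        np.maximum(sub, np.where(inside, z, -np.inf), out=sub)


def scene_truth(
    scene: SectorScene,
    pot_height_mm: float = 0.0,
    raster_mm: float = 0.2,
    include_projected: bool = True,
    timestamp: datetime | None = None,
) -> CanopyTraits:
    """Analytic ground-truth traits of a scene (recomputed, never cached).

    Area and mean angle come from the patches' exact parametric values;
    projected area is the union of facet footprints rasterised at
    ``raster_mm`` (0.2 mm default — fine enough that raster error is
    negligible against the 0.8 mm scan pitch).
    """
    patches = scene.patches
    ts = timestamp or datetime(2024, 1, 1, tzinfo=timezone.utc)
    if not patches:
        return CanopyTraits(scene.sector_id, ts, 0.0, 0.0, 0.0, float("nan"), 0)
    total = sum(p.area_cm2 for p in patches)
    angle = sum(p.area_cm2 * p.angle_deg for p in patches) / total
    height = max(0.0, max(p.top_z() for p in patches) - pot_height_mm) / MM_PER_CM
    proj = _projected_truth(patches, raster_mm) if include_projected else float("nan")
    return CanopyTraits(
        sector_id=scene.sector_id,
        timestamp=ts,
        leaf_area_3d_cm2=total,
        projected_area_cm2=proj,
        height_cm=height,
        leaf_angle_deg=angle,
        n_points=0,
    )


def _projected_truth(patches: list[LeafPatch], raster_mm: float) -> float:
    tris = np.vstack([p.facet_xyz() for p in patches])  # (m, 3, 3)
    xy = tris[:, :, :2]
    xmin, ymin = xy.reshape(-1, 2).min(axis=0)
    xmax, ymax = xy.reshape(-1, 2).max(axis=0)
    nx = max(1, int(math.ceil((xmax - xmin) / raster_mm)))
    ny = max(1, int(math.ceil((ymax - ymin) / raster_mm)))
    occ = np.zeros((nx, ny), dtype=bool)
    for tri in xy:
        _fill_triangle(occ, tri, xmin, ymin, raster_mm)
    return occ.sum() * raster_mm * raster_mm / MM2_PER_CM2


def _fill_triangle(occ, tri, xmin, ymin, pitch):
    i0 = max(0, int((tri[:, 0].min() - xmin) / pitch - 1))
    i1 = min(occ.shape[0] - 1, int((tri[:, 0].max() - xmin) / pitch + 1))
    j0 = max(0, int((tri[:, 1].min() - ymin) / pitch - 1))
    j1 = min(occ.shape[1] - 1, int((tri[:, 1].max() - ymin) / pitch + 1))
    if i1 < i0 or j1 < j0:
        return
    cx = xmin + (np.arange(i0, i1 + 1) + 0.5) * pitch
    cy = ymin + (np.arange(j0, j1 + 1) + 0.5) * pitch
    qx, qy = np.meshgrid(cx, cy, indexing="ij")
    a, b, c = tri
    det = (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
    if abs(det) < 1e-12:
        return
    l1 = ((qx - a[0]) * (c[1] - a[1]) - (qy - a[1]) * (c[0] - a[0])) / det
    l2 = ((b[0] - a[0]) * (qy - a[1]) - (b[1] - a[1]) * (qx - a[0])) / det
    inside = (l1 >= 0) & (l2 >= 0) & (l1 + l2 <= 1.0)
    occ[i0 : i1 + 1, j0 : j1 + 1] |= inside


# ---------------------------------------------------------------------------
# synthetic platform data streams: weather and load-cell traces
# ---------------------------------------------------------------------------

def synthesize_env_series(
    start: datetime,
    n_days: int = 1,
    cadence_min: int = 30,
    t_min_c: float = 22.0,
    t_max_c: float = 38.0,
    rh_min_pct: float = 25.0,
    rh_max_pct: float = 85.0,
    wind_mean_ms: float = 1.2,
    wind_gust_ms: float = 2.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Semi-arid weather records at 30-min cadence.

    Temperature follows a sinusoid peaking at 14:00, relative humidity
    moves inversely, and wind is calm at night with gusty afternoons
    (half-Gaussian gusts on top of a diurnal mean).  Columns:
    timestamp, temp_c, rh_pct, wind_ms, light, rain_mm.
    """
    rng = np.random.default_rng(seed)
    if start.tzinfo is None:
        start = start.replace(tzinfo=timezone.utc)
    n = int(n_days * 24 * 60 / cadence_min)
    ts = pd.date_range(start, periods=n, freq=f"{cadence_min}min")
    hour = ts.hour + ts.minute / 60.0
    phase = np.cos(2 * np.pi * (hour - 14.0) / 24.0)
    temp = (t_min_c + t_max_c) / 2.0 + (t_max_c - t_min_c) / 2.0 * phase
    rh = (rh_min_pct + rh_max_pct) / 2.0 - (rh_max_pct - rh_min_pct) / 2.0 * phase
    diurnal = np.clip(phase, 0.0, None)
    wind = wind_mean_ms * diurnal + np.abs(
        rng.normal(0.0, wind_gust_ms / 2.0, size=n)
    ) * diurnal
    light = 1000.0 * np.clip(np.cos(2 * np.pi * (hour - 12.0) / 24.0), 0.0, None)
    return pd.DataFrame(
        {
            "timestamp": ts,
            "temp_c": temp,
            "rh_pct": np.clip(rh, 0.0, 100.0),
            "wind_ms": wind,
            "light": light,
            "rain_mm": 0.0,
        }
    )


def _diurnal_loss_weights(hour: np.ndarray) -> np.ndarray:
    """Relative transpiration intensity over the day (daylight bell)."""
    w = np.clip(np.sin(np.pi * (hour - 6.0) / 12.0), 0.0, None) ** 2
    return w


def synthesize_weight_trace(
    start: datetime,
    n_days: int = 1,
    sector_id: str = "S01",
    start_weight_g: float = 12000.0,
    daily_transpiration_g: float = 150.0,
    irrigation_events: list[tuple[float, float]] | None = None,
    noise_sd_g: float = 10.0,
    cadence_s: int = 60,
    rate_profile: pd.Series | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Load-cell trace = diurnal water loss + watering steps + scale noise.

    ``irrigation_events`` is a list of ``(hours_from_start, grams)`` —
    positive for irrigation, negative for drainage; each is applied as a
    step.  If ``rate_profile`` (g h^-1, indexed by hour start) is given it
    overrides the default daylight-bell loss profile.  Readings carry iid
    Gaussian noise of ``noise_sd_g`` (hourly integration then reaches the
    0.1 g precision regime of the platform scales).

    Returns the raw trace (timestamp, sector_id, weight_g) and the true
    cumulative loss sampled at each reading (the generator's oracle).
    """
    rng = np.random.default_rng(seed)
    if start.tzinfo is None:
        start = start.replace(tzinfo=timezone.utc)
    n = int(n_days * 24 * 3600 / cadence_s)
    ts = pd.date_range(start, periods=n, freq=f"{cadence_s}s")
    hours_from_start = (ts - ts[0]).total_seconds() / 3600.0
    hour_of_day = ts.hour + ts.minute / 60.0 + ts.second / 3600.0

    if rate_profile is not None:
        prof = rate_profile.reindex(
            pd.date_range(start, periods=int(n_days * 24), freq="1h")
        ).ffill().bfill()
        inst_rate = prof.to_numpy()[
            np.minimum((hours_from_start).astype(int), len(prof) - 1)
        ]  # g h^-1, piecewise constant per hour
        loss = np.concatenate([[0.0], np.cumsum(inst_rate[:-1] * cadence_s / 3600.0)])
    else:
        w = _diurnal_loss_weights(hour_of_day.to_numpy())
        daily_norm = _diurnal_loss_weights(np.linspace(0, 24, 24 * 60, endpoint=False)).mean()
        inst = daily_transpiration_g / 24.0 * w / daily_norm  # g h^-1
        loss = np.concatenate([[0.0], np.cumsum(inst[:-1] * cadence_s / 3600.0)])

    steps = np.zeros(n)
    for at_h, grams in irrigation_events or []:
        steps[hours_from_start >= at_h] += grams

    weight = start_weight_g - loss + steps + rng.normal(0.0, noise_sd_g, size=n)
    trace = pd.DataFrame(
        {"timestamp": ts, "sector_id": sector_id, "weight_g": weight}
    )
    truth = pd.Series(loss, index=ts, name="true_cumulative_loss_g")
    return trace, truth
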