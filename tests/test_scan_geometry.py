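"""Unit and property tests for point-cloud trait extraction."""

import math

import numpy as np
import pytest

from canopyscan.errors import CalibrationError, ConfigurationError
from canopyscan.scan_geometry import (
    CalibrationFrame,
    TraitConfig,
    TriangleMesh,
    bin_sectors,
    extract_traits,
    filter_pot_height,
    leaf_angle,
    leaf_area_3d,
    mesh_point_cloud,
    plant_height,
    projected_area,
    sensor_to_platform,
)

from conftest import grid_plate_cloud, make_cloud


class TestSensorToPlatform:
    def test_height_is_ground_minus_plant_distance(self, frame):
        raw = np.array([[10.0, 20.0, 1500.0], [10.0, 20.8, 2000.0]])
        cloud = sensor_to_platform(raw, frame)
        assert cloud.z.tolist() == [500.0, 0.0]  # ground return retained at z=0

    def test_below_ground_returns_dropped(self, frame):
        raw = np.array([[0.0, 0.0, 2100.0], [0.0, 0.8, 1900.0]])
        cloud = sensor_to_platform(raw, frame)
        assert len(cloud) == 1 and cloud.z[0] == 100.0

    def test_inconsistent_frame_rejected(self):
        bad = CalibrationFrame(d_ground=2000, d_target=1700, target_height=290)
        with pytest.raises(CalibrationError):
            sensor_to_platform(np.zeros((1, 3)), bad)

    def test_frame_tolerance_allows_small_residual(self):
        CalibrationFrame(2000, 1710, 287.0, tolerance_mm=5.0).validate()


class TestPotHeightFilter:
    def test_strictly_above_cutoff(self, frame):
        cloud = make_cloud([[0, 0, 100], [0, 1, 200], [0, 2, 300]])
        out = filter_pot_height(cloud, frame)
        assert out.z.tolist() == [300.0]
        assert out.sector_id == cloud.sector_id and out.timestamp == cloud.timestamp

    def test_zero_cutoff_is_identity_for_positive_z(self, frame_no_pot):
        cloud = make_cloud([[0, 0, 1], [1, 0, 2]])
        assert len(filter_pot_height(cloud, frame_no_pot)) == 2

    def test_empty_cloud(self, frame):
        assert len(filter_pot_height(make_cloud(np.empty((0, 3))), frame)) == 0


class TestMeshing:
    def test_square_splits_into_two_triangles(self):
        cloud = make_cloud([[0, 0, 0], [10, 0, 0], [0, 10, 0], [10, 10, 0]])
        mesh = mesh_point_cloud(cloud, max_edge_mm=20.0)
        assert mesh.n_triangles == 2
        assert mesh.total_area_mm2() == pytest.approx(100.0)

    def test_edge_cutoff_prevents_bridging(self):
        sq = [[0, 0, 0], [10, 0, 0], [0, 10, 0], [10, 10, 0]]
        far = [[x, y + 60, z] for x, y, z in sq]  # 50 mm gap in y
        mesh = mesh_point_cloud(make_cloud(sq + far), max_edge_mm=20.0)
        assert mesh.n_triangles == 4
        assert mesh.total_area_mm2() == pytest.approx(200.0)

    def test_regular_grid_triangle_count_and_area(self):
        # oracle: an (n-1)x(n-1) cell grid triangulates into 2*(n-1)^2 cells
        cloud = grid_plate_cloud(80.0, pitch=0.8, z0=0.0)
        n = int(round(80 / 0.8)) + 1
        mesh = mesh_point_cloud(cloud, max_edge_mm=3.2)
        assert mesh.n_triangles == 2 * (n - 1) ** 2
        assert mesh.total_area_mm2() == pytest.approx(6400.0, rel=0.005)

    def test_degenerate_inputs_give_empty_mesh(self):
        assert mesh_point_cloud(make_cloud([[0, 0, 0], [1, 1, 1]])).is_empty()
        collinear = make_cloud([[i, 0.0, 0.0] for i in range(5)])
        assert mesh_point_cloud(collinear).is_empty()


class TestLeafArea:
    def test_horizontal_plate(self):
        mesh = mesh_point_cloud(grid_plate_cloud(100.0), max_edge_mm=3.2)
        assert leaf_area_3d(mesh) == pytest.approx(100.0, rel=0.02)

    @pytest.mark.parametrize("tilt", [15.0, 30.0, 45.0, 60.0])
    def test_orientation_invariance(self, tilt):
        # the sampled surface area is exactly 100 cm^2 at every tilt
        mesh = mesh_point_cloud(grid_plate_cloud(100.0, tilt_deg=tilt), max_edge_mm=3.2)
        assert leaf_area_3d(mesh) == pytest.approx(100.0, rel=0.02)

    def test_empty_mesh_is_zero(self):
        assert leaf_area_3d(TriangleMesh.empty()) == 0.0

    def test_convergence_with_grid_pitch(self):
        # smooth dome z = 15 cos(pi x/160) cos(pi y/160) over an 80x80 plate;
        # oracle: quadrature of sqrt(1 + zx^2 + zy^2) on a 0.05 mm grid
        L, A = 80.0, 15.0
        k = math.pi / (2 * L)

        def z(x, y):
            return A * np.cos(k * x) * np.cos(k * y)

        h = 0.05
        xs = np.arange(0, L, h) + h / 2
        xx, yy = np.meshgrid(xs, xs, indexing="ij")
        zx = -A * k * np.sin(k * xx) * np.cos(k * yy)
        zy = -A * k * np.cos(k * xx) * np.sin(k * yy)
        true_area = float(np.sqrt(1 + zx**2 + zy**2).sum() * h * h)

        errors = []
        for pitch in (3.2, 1.6, 0.8):
            n = int(round(L / pitch)) + 1
            g = np.arange(n) * pitch
            gx, gy = np.meshgrid(g, g, indexing="ij")
            cloud = make_cloud(
                np.column_stack([gx.ravel(), gy.ravel(), z(gx, gy).ravel()])
            )
            mesh = mesh_point_cloud(cloud, max_edge_mm=4 * pitch)
            errors.append(abs(mesh.total_area_mm2() - true_area))
        assert errors[0] > errors[1] > errors[2]


class TestProjectedArea:
    def test_horizontal_plate_projection_equals_surface(self):
        mesh = mesh_point_cloud(grid_plate_cloud(100.0), max_edge_mm=3.2)
        assert projected_area(mesh) == pytest.approx(100.0, rel=0.02)

    def test_tilted_plate_projects_by_cosine(self):
        mesh = mesh_point_cloud(grid_plate_cloud(100.0, tilt_deg=60.0), max_edge_mm=3.2)
        assert projected_area(mesh) == pytest.approx(50.0, rel=0.03)

    def test_union_not_sum_for_stacked_plates(self):
        # two coincident horizontal plates, meshed by hand: 3D area doubles,
        # projection does not
        v = np.array(
            [[0, 0, 0], [100, 0, 0], [0, 100, 0], [100, 100, 0],
             [0, 0, 50], [100, 0, 50], [0, 100, 50], [100, 100, 50]],
            dtype=float,
        )
        t = np.array([[0, 1, 3], [0, 3, 2], [4, 5, 7], [4, 7, 6]])
        mesh = TriangleMesh(v, t)
        assert leaf_area_3d(mesh) == pytest.approx(200.0)
        assert projected_area(mesh, raster_mm=0.8) == pytest.approx(100.0, rel=0.02)

    def test_projection_never_exceeds_3d_area(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            pts = rng.uniform(0, 40, size=(300, 2))
            zs = 5 * np.sin(pts[:, 0] / 6.0) + rng.uniform(0, 2, size=300)
            cloud = make_cloud(np.column_stack([pts, zs + 300]))
            mesh = mesh_point_cloud(cloud, max_edge_mm=12.0)
            if not mesh.is_empty():
                assert projected_area(mesh, 0.5) <= leaf_area_3d(mesh) * 1.005


class TestPlantHeight:
    def test_uniform_height(self, frame):
        cloud = make_cloud([[0, 0, 500], [1, 0, 500], [2, 0, 500]])
        assert plant_height(cloud, frame) == pytest.approx(30.0)

    def test_stray_high_return_rejected_by_quantile(self, frame):
        # oracle: 99.5th percentile of 1000 points at 500 + one at 900
        z = np.full(1001, 500.0)
        z[-1] = 900.0
        pts = np.column_stack([np.arange(1001) * 0.8, np.zeros(1001), z])
        est = plant_height(make_cloud(pts), frame, percentile=0.995)
        assert est == pytest.approx(30.0, abs=0.1)

    def test_empty_cloud_is_zero(self, frame):
        assert plant_height(make_cloud(np.empty((0, 3))), frame) == 0.0


class TestLeafAngle:
    def test_horizontal_plate_is_flat(self):
        mesh = mesh_point_cloud(grid_plate_cloud(50.0), max_edge_mm=3.2)
        assert leaf_angle(mesh) == pytest.approx(0.0, abs=1e-9)

    def test_tilted_plate_angle(self):
        mesh = mesh_point_cloud(grid_plate_cloud(50.0, tilt_deg=45.0), max_edge_mm=3.2)
        assert leaf_angle(mesh) == pytest.approx(45.0, abs=2.0)

    def test_area_weighted_mean_of_two_plates(self):
        # equal-area plates at 30 and 60 degrees, meshed by hand
        def plate(tilt, y0):
            t = math.radians(tilt)
            return np.array(
                [[0, y0, 0], [10, y0, 0],
                 [0, y0 + 10 * math.cos(t), 10 * math.sin(t)],
                 [10, y0 + 10 * math.cos(t), 10 * math.sin(t)]]
            )

        v = np.vstack([plate(30, 0), plate(60, 100)])
        t = np.array([[0, 1, 3], [0, 3, 2], [4, 5, 7], [4, 7, 6]])
        assert leaf_angle(TriangleMesh(v, t)) == pytest.approx(45.0, abs=2.0)

    def test_empty_mesh_is_undefined_not_zero(self):
        assert math.isnan(leaf_angle(TriangleMesh.empty()))


class TestExtractTraits:
    def test_plate_sector_composition(self, frame):
        cloud = grid_plate_cloud(100.0, z0=500.0)
        traits = extract_traits(cloud, frame, TraitConfig(height_percentile=1.0))
        assert traits.leaf_area_3d_cm2 == pytest.approx(100.0, rel=0.02)
        assert traits.projected_area_cm2 == pytest.approx(100.0, rel=0.02)
        assert traits.height_cm == pytest.approx(30.0)
        assert traits.leaf_angle_deg == pytest.approx(0.0, abs=1e-9)
        assert traits.quality_flag == "ok"
        assert traits.projected_area_cm2 <= traits.leaf_area_3d_cm2 * 1.005

    def test_all_points_below_pot_height_flagged(self, frame):
        cloud = grid_plate_cloud(20.0, z0=100.0)
        traits = extract_traits(cloud, frame)
        assert traits.leaf_area_3d_cm2 == 0.0
        assert traits.height_cm == 0.0
        assert math.isnan(traits.leaf_angle_deg)
        assert traits.quality_flag == "low_points"

    def test_min_points_threshold(self, frame):
        cloud = make_cloud([[0, 0, 500], [5, 0, 501], [0, 5, 502]])
        traits = extract_traits(cloud, frame, TraitConfig(min_points=50))
        assert traits.quality_flag == "low_points"


class TestBinSectors:
    layout = [("A", 0.0, 400.0), ("B", 400.0, 800.0)]

    def test_assignment_and_gap_drop(self):
        stream = make_cloud([[0, 100, 5], [0, 450, 5], [0, 800, 5]])
        clouds = bin_sectors(stream, self.layout)
        assert [len(c) for c in clouds] == [1, 1]
        assert clouds[0].sector_id == "A" and clouds[1].sector_id == "B"

    def test_empty_lane_gives_all_sectors_empty(self):
        clouds = bin_sectors(make_cloud(np.empty((0, 3))), self.layout)
        assert len(clouds) == 2 and all(len(c) == 0 for c in clouds)

    def test_barcode_position_reset(self):
        layout = [("A", 0, 5000.0), ("B", 5000.0, 10000.0)]
        stream = make_cloud([[0, 5100.0, 5]])
        clouds = bin_sectors(stream, layout, barcode_positions=[0.0, 5000.0])
        assert clouds[1].y.tolist() == [100.0]

    def test_counts_conserve(self):
        rng = np.random.default_rng(3)
        pts = np.column_stack(
            [rng.uniform(0, 10, 500), rng.uniform(-50, 900, 500), rng.uniform(0, 5, 500)]
        )
        stream = make_cloud(pts)
        clouds = bin_sectors(stream, self.layout)
        assigned = sum(len(c) for c in clouds)
        dropped = int(((pts[:, 1] < 0) | (pts[:, 1] >= 800)).sum())
        assert assigned + dropped == 500

    def test_overlapping_layout_rejected(self):
        with pytest.raises(ConfigurationError):
            bin_sectors(make_cloud(np.empty((0, 3))), [("A", 0, 500), ("B", 400, 800)])
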