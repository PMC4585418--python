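from datetime import datetime, timezone

import numpy as np
import pytest

from canopyscan.scan_geometry import CalibrationFrame, PointCloud

T0 = datetime(2024, 3, 1, 10, 0, tzinfo=timezone.utc)


@pytest.fixture
def frame():
    """A consistent calibration frame: 2000 - 1710 = 290 mm target height."""
    return CalibrationFrame(
        d_ground=2000.0, d_target=1710.0, target_height=290.0, pot_height=200.0
    )


@pytest.fixture
def frame_no_pot():
    return CalibrationFrame(
        d_ground=2000.0, d_target=1710.0, target_height=290.0, pot_height=0.0
    )


def make_cloud(points, sector_id="S01", timestamp=T0) -> PointCloud:
    return PointCloud(sector_id=sector_id, timestamp=timestamp, points=np.asarray(points, float))


def grid_plate_cloud(
    side_mm: float,
    pitch: float = 0.8,
    z0: float = 300.0,
    tilt_deg: float = 0.0,
    origin=(0.0, 0.0),
) -> PointCloud:
    """Sample a square plate on a regular grid, optionally tilted about x.

    The grid is applied in the plate's own plane, so the sampled surface
    area is exactly side^2 regardless of tilt (points are then rotated
    into the world frame).
    """
    n = int(round(side_mm / pitch)) + 1
    u = np.arange(n) * pitch
    uu, vv = np.meshgrid(u, u, indexing="ij")
    x = uu + origin[0]
    t = np.radians(tilt_deg)
    y = vv * np.cos(t) + origin[1]
    z = z0 + vv * np.sin(t)
    return make_cloud(np.column_stack([x.ravel(), y.ravel(), z.ravel()]))
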