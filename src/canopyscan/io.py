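"""File formats: PLY/XYZ point clouds and the pipeline's CSV tables.

Point clouds travel as ascii PLY (vertex elements with float x, y, z in
mm; handled by trimesh) or as XYZ CSV with columns x_mm, y_mm, z_mm.
Tabular data are plain CSV with ISO 8601 UTC timestamps:

* weights:  timestamp, sector_id, weight_g
* weather:  timestamp, temp_c, rh_pct, wind_ms, light, rain_mm
* traits:   sector_id, timestamp, leaf_area_3d_cm2, projected_area_cm2,
            height_cm, leaf_angle_deg, n_points, quality_flag
"""

from __future__ import annotations

from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import trimesh
import yaml

from .scan_geometry import CanopyTraits, PointCloud

__all__ = [
    "read_point_cloud",
    "write_point_cloud",
    "traits_to_frame",
    "write_traits_csv",
    "read_traits_csv",
    "read_weights_csv",
    "read_env_csv",
    "load_yaml_config",
]

TRAIT_COLUMNS = [
    "sector_id",
    "timestamp",
    "leaf_area_3d_cm2",
    "projected_area_cm2",
    "height_cm",
    "leaf_angle_deg",
    "n_points",
    "quality_flag",
]


def read_point_cloud(
    path: str | Path,
    sector_id: str | None = None,
    timestamp: datetime | None = None,
) -> PointCloud:
    """Load a sector scan from ascii PLY or XYZ CSV.

    Sector id and timestamp default to the file stem parsed as
    ``<sector>_<ISO timestamp>`` when possible, else the stem and now.
    """
    path = Path(path)
    if path.suffix.lower() == ".ply":
        loaded = trimesh.load(str(path), process=False)
        pts = np.asarray(loaded.vertices, dtype=float)
    else:
        df = pd.read_csv(path)
        cols = [c for c in ("x_mm", "y_mm", "z_mm") if c in df.columns] or list(
            df.columns[:3]
        )
        pts = df[cols].to_numpy(dtype=float)
    sid, ts = _parse_stem(path.stem)
    return PointCloud(
        sector_id=sector_id or sid,
        timestamp=timestamp or ts,
        points=pts,
    )


def _parse_stem(stem: str):
    if "_" in stem:
        sid, _, rest = stem.partition("_")
        try:
            return sid, datetime.fromisoformat(rest.replace("T", "T"))
        except ValueError:
            pass
    return stem, datetime.now(timezone.utc)


def write_point_cloud(cloud: PointCloud, path: str | Path) -> None:
    """Write a cloud as ascii PLY or XYZ CSV, by extension."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        pc = trimesh.PointCloud(cloud.points)
        path.write_bytes(pc.export(file_type="ply", encoding="ascii"))
    else:
        pd.DataFrame(cloud.points, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
            path, index=False
        )


def traits_to_frame(traits: Iterable[CanopyTraits]) -> pd.DataFrame:
    df = pd.DataFrame([t.as_record() for t in traits], columns=TRAIT_COLUMNS)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def write_traits_csv(traits: Iterable[CanopyTraits], path: str | Path) -> None:
    df = traits_to_frame(traits)
    df["timestamp"] = df["timestamp"].map(lambda t: t.isoformat())
    df.to_csv(path, index=False)


def read_traits_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def read_weights_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df[["timestamp", "sector_id", "weight_g"]]


def read_env_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return data
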