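"""End-to-end orchestration: simulate -> traits -> filter -> join.

:func:`run_pipeline` drives one full analysis from a :class:`RunConfig`:
either reading point clouds / weight / weather files or generating a
synthetic study, then extracting canopy traits, applying the wind
filter, converting weights to transpiration and joining everything into
the hourly analysis table.  Every output is stamped with the config hash
and seed; record counts are logged and conserved at every filter.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import environment as envmod
from . import io as cio
from . import lysimetry as lys
from .errors import ConfigurationError
from .scan_geometry import CalibrationFrame, TraitConfig, extract_traits
from .virtual_scanner import (
    ScanConfig,
    build_scene,
    render_scan,
    scene_truth,
    synthesize_env_series,
    synthesize_weight_trace,
)

__all__ = ["RunConfig", "run_pipeline", "simulate_conductance_study"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one pipeline run (CLI flags override config keys)."""

    out_dir: str = "canopyscan_out"
    seed: int = 0
    # input files; None means synthesise
    clouds_dir: str | None = None
    weights_csv: str | None = None
    env_csv: str | None = None
    # synthetic study shape
    n_sectors: int = 6
    n_days: int = 1
    scans_per_day: int = 12
    species: str = "cereal"
    density_per_m2: float = 16.0
    leaf_area_cm2: float = 30.0
    daily_transpiration_g: float = 150.0
    start: str = "2024-03-01T00:00:00+00:00"
    # module parameters
    pot_height_mm: float = 200.0
    d_ground_mm: float = 2000.0
    d_target_mm: float = 1710.0
    target_height_mm: float = 290.0
    max_edge_mm: float = 3.2
    raster_mm: float = 0.8
    height_percentile: float = 0.995
    min_points: int = 50
    wind_threshold_ms: float = 2.0
    step_threshold_g: float = 50.0
    rate_threshold_g_per_h: float = 200.0
    sowing: str | None = None

    def frame(self) -> CalibrationFrame:
        return CalibrationFrame(
            d_ground=self.d_ground_mm,
            d_target=self.d_target_mm,
            target_height=self.target_height_mm,
            pot_height=self.pot_height_mm,
        )

    def trait_config(self) -> TraitConfig:
        return TraitConfig(
            max_edge_mm=self.max_edge_mm,
            raster_mm=self.raster_mm,
            height_percentile=self.height_percentile,
            min_points=self.min_points,
        )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(data) - known
        if extra:
            raise ConfigurationError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)


def _synthesize_scans(cfg: RunConfig) -> list:
    """Render one scan per sector per scan slot across the study days."""
    start = datetime.fromisoformat(cfg.start)
    scan_cfg = ScanConfig(seed=cfg.seed)
    clouds = []
    rng = np.random.default_rng(cfg.seed)
    for s in range(cfg.n_sectors):
        sector_id = f"S{s + 1:02d}"
        scene_seed = int(rng.integers(0, 2**31))
        for d in range(cfg.n_days):
            for k in range(cfg.scans_per_day):
                t = start + timedelta(days=d, hours=6 + 12 * k / cfg.scans_per_day)
                growth = 1.0 + 0.1 * (d + k / cfg.scans_per_day)  # slow growth
                scene = build_scene(
                    density_per_m2=cfg.density_per_m2,
                    species=cfg.species,
                    leaf_area_cm2=cfg.leaf_area_cm2 * growth,
                    arrangement="natural",
                    base_height_mm=cfg.pot_height_mm + 60.0,
                    seed=scene_seed,
                    sector_id=sector_id,
                )
                clouds.append(
                    render_scan(
                        scene, scan_cfg, wind_ms=0.0, timestamp=t, include_ground=False
                    )
                )
    return clouds


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and write all outputs under ``out_dir``.

    Returns a manifest dict (also written as JSON) with the config hash,
    seed and per-stage record counts.  Any stage failure removes partial
    outputs and re-raises with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    try:
        _run_stages(config, out, written, manifest)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise type(exc)(f"pipeline failed: {exc}") from exc
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _run_stages(config: RunConfig, out: Path, written: list[Path], manifest: dict):
    start = datetime.fromisoformat(config.start)

    # --- inputs -----------------------------------------------------------
    if config.clouds_dir:
        clouds = [
            cio.read_point_cloud(p)
            for p in sorted(Path(config.clouds_dir).glob("*"))
            if p.suffix.lower() in (".ply", ".csv", ".xyz")
        ]
    else:
        clouds = _synthesize_scans(config)
    manifest["stages"]["scans"] = {"n_clouds": len(clouds)}
    log.info("stage=scans n=%d", len(clouds))

    if config.env_csv:
        env = cio.read_env_csv(config.env_csv)
    else:
        env = synthesize_env_series(start, n_days=config.n_days + 1, seed=config.seed)

    if config.weights_csv:
        weights_raw = cio.read_weights_csv(config.weights_csv)
    else:
        frames = []
        for s in range(config.n_sectors):
            trace, _ = synthesize_weight_trace(
                start,
                n_days=config.n_days + 1,
                sector_id=f"S{s + 1:02d}",
                daily_transpiration_g=config.daily_transpiration_g,
                cadence_s=60,
                noise_sd_g=1.3,
                seed=config.seed + 1000 + s,
            )
            frames.append(trace)
        weights_raw = pd.concat(frames, ignore_index=True)
    manifest["stages"]["weights"] = {"n_readings": len(weights_raw)}

    # --- traits -----------------------------------------------------------
    frame = config.frame()
    tcfg = config.trait_config()
    traits = [extract_traits(c, frame, tcfg) for c in clouds]
    traits_df = cio.traits_to_frame(traits)
    p = out / "traits.csv"
    cio.write_traits_csv(traits, p)
    written.append(p)
    manifest["stages"]["traits"] = {
        "n_scans": len(traits_df),
        "n_low_quality": int((traits_df["quality_flag"] != "ok").sum()),
    }
    log.info("stage=traits n=%d", len(traits_df))

    # --- wind filter --------------------------------------------------------
    kept, rejected = envmod.wind_filter(
        traits_df, env, threshold_ms=config.wind_threshold_ms
    )
    assert len(kept) + len(rejected) == len(traits_df)
    manifest["stages"]["wind_filter"] = {
        "n_in": len(traits_df),
        "n_retained": len(kept),
        "n_removed": len(rejected),
    }
    log.info(
        "stage=wind_filter in=%d retained=%d removed=%d",
        len(traits_df), len(kept), len(rejected),
    )

    # --- transpiration ------------------------------------------------------
    hourly_frames, event_rows = [], []
    for sid, grp in weights_raw.groupby("sector_id"):
        hourly = lys.integrate_hourly(grp)
        events = lys.detect_events(
            hourly, config.step_threshold_g, config.rate_threshold_g_per_h
        )
        for ev in events:
            event_rows.append(
                {
                    "sector_id": sid,
                    "kind": ev.kind,
                    "start": ev.start,
                    "end": ev.end,
                    "magnitude_g": ev.magnitude_g,
                }
            )
        hourly_frames.append(hourly.reset_index())
    hourly_all = pd.concat(hourly_frames, ignore_index=True)
    events_df = pd.DataFrame(
        event_rows, columns=["sector_id", "kind", "start", "end", "magnitude_g"]
    )
    p = out / "events.csv"
    events_df.to_csv(p, index=False)
    written.append(p)
    manifest["stages"]["events"] = {"n_events": len(events_df)}

    # --- join ---------------------------------------------------------------
    table = envmod.sync_join(
        kept,
        hourly_all,
        env,
        sowing=config.sowing,
        wind_threshold_ms=config.wind_threshold_ms,
        step_threshold_g=config.step_threshold_g,
        rate_threshold_g_per_h=config.rate_threshold_g_per_h,
    )
    p = out / "analysis_table.csv"
    table.to_csv(p, index=False)
    written.append(p)
    manifest["stages"]["join"] = {
        "n_rows": len(table),
        "n_sectors": table["sector_id"].nunique(),
    }
    log.info("stage=join rows=%d", len(table))


# ---------------------------------------------------------------------------
# synthetic canopy-conductance study (VPD-response archetypes)
# ---------------------------------------------------------------------------

def simulate_conductance_study(
    start: datetime,
    n_days: int = 5,
    genotypes: dict | None = None,
    leaf_area_cm2: float = 2000.0,
    daily_growth_cm2: float = 60.0,
    trait_noise_cm2: float = 20.0,
    scale_noise_sd_g: float = 1.3,
    seed: int = 0,
) -> dict:
    """Synthesise a two-archetype VPD-response study, end to end.

    Each genotype archetype transpires at
    ``rate = light x min(slope_per_kpa x VPD, cap)`` (mg cm^-2 min^-1);
    a VPD-sensitive archetype caps its rate above a VPD breakpoint (a
    water-saving stomatal trait), an insensitive one keeps rising
    (``cap = inf``).  Returns per-sector weight traces, scan-time leaf
    area observations, the weather series, and the injected truth —
    everything the joined-table pipeline needs to try to recover the cap.

    ``genotypes`` maps label -> dict(slope_per_kpa, cap_mg_cm2_min,
    n_sectors).
    """
    if genotypes is None:
        genotypes = {
            "sensitive": {"slope_per_kpa": 0.028, "cap_mg_cm2_min": 0.055, "n_sectors": 3},
            "insensitive": {"slope_per_kpa": 0.028, "cap_mg_cm2_min": np.inf, "n_sectors": 3},
        }
    if start.tzinfo is None:
        start = start.replace(tzinfo=timezone.utc)
    rng = np.random.default_rng(seed)
    env = synthesize_env_series(start, n_days=n_days + 1, seed=seed)
    env_vpd = envmod.vpd(env["temp_c"], env["rh_pct"])
    hours = pd.date_range(start, periods=(n_days + 1) * 24, freq="1h")
    # hourly VPD and light factor at hour midpoints
    mid = hours + pd.Timedelta(minutes=30)
    idx = np.searchsorted(env["timestamp"].to_numpy(), mid.to_numpy(), side="right") - 1
    idx = np.clip(idx, 0, len(env) - 1)
    vpd_h = np.asarray(env_vpd)[idx]
    # stomatal opening gate: closed at night, fully open through midday
    # (trapezoid: ramps 07-10 and 16-19), so the midday rate expresses the
    # genotype's cap rather than the light curve
    hod = mid.hour + mid.minute / 60.0
    light_h = np.interp(hod, [0, 7, 10, 16, 19, 24], [0, 0, 1, 1, 0, 0])

    out = {"env": env, "sectors": {}, "truth": {"genotypes": genotypes}}
    sector_n = 0
    for label, gp in genotypes.items():
        for r in range(gp["n_sectors"]):
            sector_n += 1
            sid = f"{label[:3].upper()}{r + 1:02d}"
            la0 = leaf_area_cm2 * rng.uniform(0.9, 1.1)
            la_h = la0 + daily_growth_cm2 * (
                (hours - hours[0]).total_seconds() / 86400.0
            )
            rate_h = light_h * np.minimum(
                gp["slope_per_kpa"] * vpd_h, gp["cap_mg_cm2_min"]
            )  # mg cm^-2 min^-1
            loss_g_per_h = rate_h * la_h * 60.0 / 1000.0
            profile = pd.Series(loss_g_per_h, index=hours)
            trace, truth_loss = synthesize_weight_trace(
                start,
                n_days=n_days + 1,
                sector_id=sid,
                rate_profile=profile,
                noise_sd_g=scale_noise_sd_g,
                cadence_s=60,
                seed=int(rng.integers(0, 2**31)),
            )
            # scan-time leaf area observations, 12 per day, daylight hours
            scan_times = pd.DatetimeIndex(
                [
                    start + timedelta(days=d, hours=6 + k)
                    for d in range(n_days + 1)
                    for k in range(12)
                ]
            )
            la_obs = np.interp(
                scan_times.asi8, hours.asi8, la_h
            ) + rng.normal(0.0, trait_noise_cm2, size=len(scan_times))
            traits = pd.DataFrame(
                {
                    "sector_id": sid,
                    "timestamp": scan_times,
                    "leaf_area_3d_cm2": la_obs,
                }
            )
            out["sectors"][sid] = {
                "genotype": label,
                "weights": trace,
                "traits": traits,
                "true_rate_mg_cm2_min": pd.Series(rate_h, index=hours),
                "true_leaf_area_cm2": pd.Series(la_h, index=hours),
            }
    return out
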