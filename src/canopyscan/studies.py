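"""Reference synthetic studies exercising the whole chain end to end.

Each function here runs a self-contained, seeded study on the virtual
platform and returns the summary quantities a validation campaign would
report: trait-recovery errors on single-layer canopies, orientation
invariance across plate tilts, the occlusion-induced underestimation
slope, transpiration mass balance and event-detection quality, wind
degradation of area estimates, and recovery of an injected VPD-response
cap from the joined hourly table.  They are used by the test suite and
by the reproduction script, and are part of the public API so users can
rerun the same studies at other settings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd

from . import environment as envmod
from . import lysimetry as lys
from .scan_geometry import CalibrationFrame, TraitConfig, extract_traits
from .validation import fit_obs_vs_pred
from .pipeline import simulate_conductance_study
from .virtual_scanner import (
    ScanConfig,
    SectorScene,
    build_scene,
    planar_leaf,
    render_scan,
    scene_truth,
    synthesize_env_series,
    synthesize_weight_trace,
)

__all__ = [
    "DEFAULT_FRAME",
    "geometry_recovery_study",
    "tilt_invariance_study",
    "occlusion_study",
    "transpiration_recovery_study",
    "wind_degradation_study",
    "vpd_cap_recovery_study",
]

DEFAULT_FRAME = CalibrationFrame(
    d_ground=2000.0, d_target=1710.0, target_height=290.0, pot_height=200.0
)

T0 = datetime(2024, 3, 1, tzinfo=timezone.utc)


def geometry_recovery_study(
    n_sectors: int = 50,
    seed: int = 0,
    leaf_area_cm2: float = 150.0,
) -> pd.DataFrame:
    """Trait recovery on single-layer sectors at wind 0.

    Each sector holds four well-developed leaves (one per plant, 10
    plants/m^2 on a 650 x 600 mm sector) in disjoint cells, cycling
    through the three canopy archetypes.  Returns per-sector relative
    area error, absolute angle error (deg) and absolute height error
    (mm), against analytic truth.
    """
    cfg = ScanConfig(width_mm=650.0, length_mm=600.0)
    tcfg = TraitConfig(height_percentile=1.0)
    species = ("cereal", "legume", "planar")
    rows = []
    for i in range(n_sectors):
        sp = species[i % 3]
        scene = build_scene(
            density_per_m2=10.0, species=sp, leaf_area_cm2=leaf_area_cm2,
            leaves_per_plant=1, width_mm=650.0, length_mm=600.0,
            arrangement="spaced", base_height_mm=260.0, seed=seed + i,
            sector_id=f"R{i:02d}",
        )
        cloud = render_scan(scene, cfg, wind_ms=0.0, include_ground=False)
        est = extract_traits(cloud, DEFAULT_FRAME, tcfg)
        truth = scene_truth(scene, DEFAULT_FRAME.pot_height, include_projected=False)
        rows.append(
            {
                "sector_id": scene.sector_id,
                "species": sp,
                "area_rel_err": est.leaf_area_3d_cm2 / truth.leaf_area_3d_cm2 - 1.0,
                "angle_abs_err_deg": abs(est.leaf_angle_deg - truth.leaf_angle_deg),
                "height_abs_err_mm": abs(est.height_cm - truth.height_cm) * 10.0,
            }
        )
    return pd.DataFrame(rows)


def tilt_invariance_study(
    tilts_deg: tuple[float, ...] = (0.0, 15.0, 30.0, 45.0, 60.0),
) -> pd.DataFrame:
    """3D-area invariance and cosine projection across plate tilts.

    A 100 cm^2 plate (51.2 x 195.3125 mm, x-edges on the 0.8 mm grid) is
    tilted about its short axis and scanned; deterministic, no seed.
    """
    results = []
    for tilt in tilts_deg:
        leaf = planar_leaf((160.0, 165.0, 500.0), 51.2, 195.3125, tilt_deg=tilt)
        scene = SectorScene("TILT", [[leaf]], width_mm=320.0, length_mm=330.0)
        cloud = render_scan(
            scene, ScanConfig(width_mm=320.0, length_mm=330.0),
            include_ground=False,
        )
        est = extract_traits(cloud, DEFAULT_FRAME, TraitConfig())
        results.append(
            {
                "tilt_deg": tilt,
                "area_cm2": est.leaf_area_3d_cm2,
                "projected_cm2": est.projected_area_cm2,
                "expected_projected_cm2": 100.0 * math.cos(math.radians(tilt)),
            }
        )
    return pd.DataFrame(results)


def occlusion_study(n_scenes: int = 20, seed: int = 0) -> dict:
    """Estimated vs true area on dense, multi-layer field-like canopies.

    Scenes span species and leaf sizes at field density; the single
    top-down perspective cannot see overlapped tissue, so estimates are
    bounded by the truth and the fitted slope falls below 1.
    """
    rows = []
    for i in range(n_scenes):
        sp = ("cereal", "legume")[i % 2]
        scene = build_scene(
            density_per_m2=16.0, species=sp,
            leaf_area_cm2=30.0 + 10.0 * (i % 4),
            leaves_per_plant=5, arrangement="natural",
            base_height_mm=260.0, seed=seed + i,
        )
        cloud = render_scan(scene, ScanConfig(seed=seed + i), include_ground=False)
        est = extract_traits(cloud, DEFAULT_FRAME, TraitConfig())
        truth = scene_truth(scene, DEFAULT_FRAME.pot_height, include_projected=False)
        rows.append(
            {"species": sp, "true_cm2": truth.leaf_area_3d_cm2,
             "est_cm2": est.leaf_area_3d_cm2}
        )
    pairs = pd.DataFrame(rows)
    report = fit_obs_vs_pred(pairs["true_cm2"], pairs["est_cm2"])
    overshoot = float((pairs["est_cm2"] / pairs["true_cm2"] - 1.0).max())
    return {"pairs": pairs, "slope": report.pooled.slope,
            "r2": report.pooled.r2, "max_rel_overshoot": overshoot}


def transpiration_recovery_study(n_traces: int = 20, seed: int = 0) -> dict:
    """Mass balance, daily recovery and event detection on weight traces.

    Noise-free traces check the exact mass balance.  Noisy traces
    (second-cadence readings, 10 g scale noise, one 1000 g night-time
    irrigation) measure daily-total recovery and irrigation recall;
    precision counts spurious events across all traces.
    """
    # exact mass balance, no noise
    trace, _ = synthesize_weight_trace(
        T0, n_days=2, daily_transpiration_g=150.0, noise_sd_g=0.0,
        irrigation_events=[(22.0, 1000.0)], cadence_s=60, seed=seed,
    )
    hourly = lys.integrate_hourly(trace)
    events = lys.detect_events(hourly)
    transp = lys.compute_transpiration(hourly, events)
    residual = lys.mass_balance_residual(hourly, transp, events)

    daily_errors, detected, spurious = [], 0, 0
    for k in range(n_traces):
        t, _ = synthesize_weight_trace(
            T0, n_days=1, daily_transpiration_g=150.0, noise_sd_g=10.0,
            irrigation_events=[(22.0, 1000.0)], cadence_s=1, seed=seed + 100 + k,
        )
        h = lys.integrate_hourly(t)
        ev = lys.detect_events(h)
        tr = lys.compute_transpiration(h, ev)
        daily = tr["transpiration_g"].iloc[:23].sum()  # hours 0..22 of day 1
        daily_true = 150.0 * _diurnal_fraction_before(23.0)
        daily_errors.append(abs(daily - daily_true) / daily_true)
        irr = [e for e in ev if e.kind == "irrigation"]
        detected += len(irr) >= 1
        spurious += len(ev) - len(irr)
    return {
        "mass_balance_residual_g": float(residual),
        "mean_daily_rel_err": float(np.mean(daily_errors)),
        "max_daily_rel_err": float(max(daily_errors)),
        "recall": detected / n_traces,
        "precision": detected / max(1, detected + spurious),
    }


def _diurnal_fraction_before(hour: float) -> float:
    """Fraction of the daily loss profile accrued before ``hour``."""
    h = np.linspace(0, 24, 24 * 600, endpoint=False)
    w = np.clip(np.sin(np.pi * (h - 6.0) / 12.0), 0.0, None) ** 2
    return float(w[h < hour].sum() / w.sum())


def wind_degradation_study(
    winds_ms: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0),
    replicates: int = 100,
    seed: int = 0,
) -> dict:
    """Mean |area error| vs wind speed, and the payoff of the 2 m/s filter.

    Small two-leaf sectors are scanned at each wind level (seeded jitter);
    then a mixed-wind day (12 scans, half-hourly weather) is filtered at
    2 m/s and the mean error of retained scans compared with no filter.
    """
    cfg_kw = dict(width_mm=320.0, length_mm=330.0)
    tcfg = TraitConfig()
    mean_abs_err = {}
    for w in winds_ms:
        errs = []
        for r in range(replicates):
            scene = build_scene(
                density_per_m2=20.0, species="cereal", leaf_area_cm2=60.0,
                leaves_per_plant=1, arrangement="spaced",
                base_height_mm=260.0, seed=seed + r, **cfg_kw,
            )
            cloud = render_scan(
                scene, ScanConfig(seed=seed + 10_000 + r, **cfg_kw), wind_ms=w,
                include_ground=False,
            )
            est = extract_traits(cloud, DEFAULT_FRAME, tcfg)
            truth = scene_truth(scene, DEFAULT_FRAME.pot_height,
                                include_projected=False)
            errs.append(abs(est.leaf_area_3d_cm2 / truth.leaf_area_3d_cm2 - 1.0))
        mean_abs_err[w] = float(np.mean(errs))

    # mixed-wind day: reuse one scene, scan hourly with the day's wind
    env = synthesize_env_series(T0, n_days=1, seed=seed)
    scene = build_scene(
        density_per_m2=20.0, species="cereal", leaf_area_cm2=60.0,
        leaves_per_plant=1, arrangement="spaced", base_height_mm=260.0,
        seed=seed, **cfg_kw,
    )
    truth = scene_truth(scene, DEFAULT_FRAME.pot_height, include_projected=False)
    obs = []
    for k in range(12):
        ts = T0 + timedelta(hours=6 + k)
        rec = env.iloc[(env["timestamp"] - ts).abs().argmin()]
        cloud = render_scan(
            scene, ScanConfig(seed=seed + 500 + k, **cfg_kw),
            wind_ms=float(rec["wind_ms"]), timestamp=ts, include_ground=False,
        )
        est = extract_traits(cloud, DEFAULT_FRAME, tcfg)
        obs.append(
            {"timestamp": ts,
             "abs_rel_err": abs(est.leaf_area_3d_cm2 / truth.leaf_area_3d_cm2 - 1.0)}
        )
    obs = pd.DataFrame(obs)
    kept, _ = envmod.wind_filter(obs, env, threshold_ms=2.0)
    return {
        "mean_abs_err_by_wind": mean_abs_err,
        "unfiltered_day_err": float(obs["abs_rel_err"].mean()),
        "filtered_day_err": float(kept["abs_rel_err"].mean()),
        "n_retained": len(kept),
        "n_scans": len(obs),
    }


def vpd_cap_recovery_study(n_days: int = 20, seed: int = 0) -> dict:
    """Recover an injected midday transpiration-rate cap from the join.

    A VPD-sensitive archetype caps its rate at 0.055 mg cm^-2 min^-1 once
    demand passes the breakpoint; the study runs the full weights ->
    transpiration -> interpolated-leaf-area -> rate chain and estimates
    the cap as the median midday (11:00-15:00) rate of sensitive sectors
    on high-VPD hours.
    """
    study = simulate_conductance_study(T0, n_days=n_days, seed=seed)
    env = study["env"]
    genotypes = study["truth"]["genotypes"]
    cap = genotypes["sensitive"]["cap_mg_cm2_min"]
    slope = genotypes["sensitive"]["slope_per_kpa"]

    per_genotype_midday: dict[str, list[float]] = {g: [] for g in genotypes}
    for sid, sec in study["sectors"].items():
        hourly = lys.integrate_hourly(sec["weights"])
        table = envmod.sync_join(sec["traits"], hourly.reset_index(), env)
        hours = pd.DatetimeIndex(table["hour_start"])
        midday = table[
            hours.hour.isin([11, 12, 13, 14])
            & (table["vpd_kpa"] > 1.3 * cap / slope)
        ]
        per_genotype_midday[sec["genotype"]].extend(
            midday["rate_mg_cm2_min"].dropna().tolist()
        )
    recovered = float(np.median(per_genotype_midday["sensitive"]))
    insensitive = float(np.median(per_genotype_midday["insensitive"]))
    return {
        "true_cap": float(cap),
        "recovered_cap": recovered,
        "rel_err": abs(recovered - cap) / cap,
        "insensitive_midday_rate": insensitive,
    }
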