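"""Observed-vs-estimated leaf-area regression harness.

Destructive harvests are the classical reference for canopy leaf area;
the scanner's 3D leaf area is validated by regressing it against them.
Here the same harness runs on synthetic panels where the "observed" value
is the scene's analytic truth, so the slope (< 1 under occlusion: the
scanner sees one perspective and misses overlapped tissue) and R^2 are
measurable without field data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError
from .scan_geometry import CalibrationFrame, TraitConfig, extract_traits
from .virtual_scanner import ScanConfig, build_scene, render_scan, scene_truth

__all__ = ["GroupFit", "RegressionReport", "fit_obs_vs_pred", "run_validation"]


@dataclass(frozen=True)
class GroupFit:
    label: str
    slope: float
    intercept: float
    r2: float
    n: int


@dataclass
class RegressionReport:
    """Per-group and pooled OLS fits of estimated on observed leaf area."""

    pooled: GroupFit
    groups: dict[str, GroupFit] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        rows = [self.pooled] + list(self.groups.values())
        return pd.DataFrame(
            [
                {
                    "group": g.label,
                    "slope": g.slope,
                    "intercept": g.intercept,
                    "r2": g.r2,
                    "n": g.n,
                }
                for g in rows
            ]
        )


def _ols(x: np.ndarray, y: np.ndarray, label: str) -> GroupFit:
    if len(x) < 3:
        raise FitError(f"group {label!r}: need >= 3 pairs, got {len(x)}")
    if np.ptp(x) == 0:
        raise FitError(f"group {label!r}: observed values have zero variance")
    res = stats.linregress(x, y)
    return GroupFit(
        label=label,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n=len(x),
    )


def fit_obs_vs_pred(
    observed, estimated, groups=None
) -> RegressionReport:
    """OLS of estimated 3D leaf area on observed (reference) leaf area.

    A slope below 1 means the scan underestimates true area — the
    expected direction whenever leaves overlap, since a single top-down
    perspective cannot see occluded tissue.
    """
    x = np.asarray(observed, dtype=float)
    y = np.asarray(estimated, dtype=float)
    if x.shape != y.shape:
        raise ValueError("observed and estimated must have the same length")
    report = RegressionReport(pooled=_ols(x, y, "pooled"))
    if groups is not None:
        g = np.asarray(groups)
        for label in pd.unique(g):
            m = g == label
            report.groups[str(label)] = _ols(x[m], y[m], str(label))
    return report


def run_validation(
    species: tuple[str, ...] = ("cereal", "legume"),
    growth_stages: tuple[float, ...] = (15.0, 25.0, 40.0),
    replicates: int = 3,
    density_per_m2: float = 16.0,
    leaves_per_plant: int = 4,
    arrangement: str = "natural",
    scan: ScanConfig | None = None,
    frame: CalibrationFrame | None = None,
    trait_config: TraitConfig | None = None,
    seed: int = 0,
) -> tuple[RegressionReport, pd.DataFrame]:
    """Scan a synthetic panel and regress estimated vs true leaf area.

    The panel crosses species archetypes with growth stages (nominal leaf
    sizes, cm^2 per leaf) and seeded replicates, mirroring a validation
    campaign in which sectors spanning a size range are scanned and then
    harvested.  Returns the regression report and the pair table
    (species, stage, replicate, true/estimated areas).
    """
    scan = scan or ScanConfig()
    frame = frame or CalibrationFrame(
        d_ground=2000.0, d_target=1710.0, target_height=290.0, pot_height=200.0
    )
    trait_config = trait_config or TraitConfig()
    rows = []
    ss = np.random.SeedSequence(seed)
    for sp in species:
        for stage in growth_stages:
            for rep in range(replicates):
                scene_seed = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
                scene = build_scene(
                    density_per_m2=density_per_m2,
                    species=sp,
                    leaf_area_cm2=stage,
                    leaves_per_plant=leaves_per_plant,
                    width_mm=scan.width_mm,
                    length_mm=scan.length_mm,
                    arrangement=arrangement,
                    base_height_mm=frame.pot_height + 60.0,
                    seed=scene_seed,
                    sector_id=f"{sp}-{stage:g}-{rep}",
                )
                cloud = render_scan(scene, scan, wind_ms=0.0, include_ground=False)
                traits = extract_traits(cloud, frame, trait_config)
                truth = scene_truth(scene, frame.pot_height, include_projected=False)
                rows.append(
                    {
                        "species": sp,
                        "stage_cm2": stage,
                        "replicate": rep,
                        "sector_id": scene.sector_id,
                        "observed_cm2": truth.leaf_area_3d_cm2,
                        "estimated_cm2": traits.leaf_area_3d_cm2,
                    }
                )
    pairs = pd.DataFrame(rows)
    report = fit_obs_vs_pred(
        pairs["observed_cm2"], pairs["estimated_cm2"], groups=pairs["species"]
    )
    return report, pairs
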