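"""Gravimetric transpiration from continuous load-cell weight traces.

Each sector sits on a 50 kg load cell read every second to minute; with
soil evaporation suppressed (pots sealed under polythene and bead mulch),
the pot weight decline is plant transpiration.  The chain is:

1. :func:`integrate_hourly` — average raw readings into clock-hour bins,
   which brings the scale noise down to the ~0.1 g regime;
2. :func:`detect_events` — segregate watering (step up) and drainage
   (fast step down) from the hourly trace;
3. :func:`compute_transpiration` — hourly transpiration = -(weight change)
   outside event hours, with a mass-balance audit;
4. :func:`transpiration_rate` — divide by interpolated leaf area to get a
   canopy-conductance proxy in mg cm^-2 min^-1.

Hour intervals are half-open [t, t+1h), clock-aligned UTC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd

__all__ = [
    "WaterEvent",
    "integrate_hourly",
    "detect_events",
    "compute_transpiration",
    "transpiration_rate",
    "mass_balance_residual",
    "treatment_response",
]

log = logging.getLogger(__name__)

FLAG_OK = "ok"
FLAG_MISSING = "missing"
FLAG_EVENT_IRRIGATION = "irrigation"
FLAG_EVENT_DRAINAGE = "drainage"
FLAG_WEIGHT_GAIN = "weight_gain"
FLAG_NOISE_GAIN = "noise_gain"

#: weight gains up to this magnitude are scale noise, not water input
#: (~5x the 0.1 g precision of hourly-integrated readings)
GAIN_TOLERANCE_G = 0.5

MG_PER_G = 1000.0
MIN_PER_H = 60.0


@dataclass(frozen=True)
class WaterEvent:
    """A watering or drainage episode on one sector's trace.

    ``magnitude_g`` is the net weight change over the interval: positive
    for irrigation, negative for drainage.  The interval is half-open
    [start, end) in hour bins.
    """

    kind: str  # "irrigation" | "drainage"
    start: pd.Timestamp
    end: pd.Timestamp
    magnitude_g: float

    def __post_init__(self):
        if self.kind == "irrigation" and self.magnitude_g <= 0:
            raise ValueError("irrigation magnitude must be > 0")
        if self.kind == "drainage" and self.magnitude_g >= 0:
            raise ValueError("drainage magnitude must be < 0")


def integrate_hourly(raw: pd.DataFrame) -> pd.DataFrame:
    """Average raw load-cell readings into clock-hour bins.

    ``raw`` needs columns ``timestamp`` and ``weight_g`` (a ``sector_id``
    column is carried through if present).  Returns one row per clock hour
    spanning the trace, with columns ``weight_g`` (mean of readings in
    [t, t+1h); NaN when the hour has no readings), ``n_readings`` and
    ``flag``.  Empty hours are flagged missing, never interpolated.
    """
    if raw.empty:
        return pd.DataFrame(
            columns=["hour_start", "weight_g", "n_readings", "flag"]
        ).set_index("hour_start")
    df = raw.sort_values("timestamp")
    hour = df["timestamp"].dt.floor("h")
    grouped = df.groupby(hour)["weight_g"].agg(["mean", "count"])
    full = pd.date_range(grouped.index.min(), grouped.index.max(), freq="1h")
    out = grouped.reindex(full)
    out.index.name = "hour_start"
    out.columns = ["weight_g", "n_readings"]
    out["n_readings"] = out["n_readings"].fillna(0).astype(int)
    out["flag"] = np.where(out["n_readings"] > 0, FLAG_OK, FLAG_MISSING)
    if "sector_id" in raw.columns and len(raw):
        out.insert(0, "sector_id", raw["sector_id"].iloc[0])
    return out


def detect_events(
    hourly: pd.DataFrame,
    step_threshold_g: float = 50.0,
    rate_threshold_g_per_h: float = 200.0,
) -> list[WaterEvent]:
    """Flag watering and drainage episodes on an hourly weight trace.

    An hour-to-hour weight *increase* above ``step_threshold_g`` marks
    irrigation; a *decrease* faster than ``rate_threshold_g_per_h`` marks
    drainage (plausible hourly transpiration of a pot-grown canopy is far
    below either default).  Consecutive offending hours of the same kind
    merge into one event spanning the whole episode.
    """
    w = hourly["weight_g"]
    if len(w) < 2:
        return []
    dw = w.diff().to_numpy()[1:]  # change over [t_i, t_{i+1})
    starts = hourly.index[:-1]
    kinds = np.where(
        dw > step_threshold_g,
        FLAG_EVENT_IRRIGATION,
        np.where(dw < -rate_threshold_g_per_h, FLAG_EVENT_DRAINAGE, ""),
    )
    events: list[WaterEvent] = []
    i = 0
    while i < len(kinds):
        if kinds[i]:
            j = i
            while j + 1 < len(kinds) and kinds[j + 1] == kinds[i]:
                j += 1
            events.append(
                WaterEvent(
                    kind=str(kinds[i]),
                    start=starts[i],
                    end=starts[j] + pd.Timedelta(hours=1),
                    magnitude_g=float(np.nansum(dw[i : j + 1])),
                )
            )
            i = j + 1
        else:
            i += 1
    return events


def _event_hour_flags(index: pd.DatetimeIndex, events: list[WaterEvent]) -> pd.Series:
    flags = pd.Series("", index=index, dtype=object)
    for ev in events:
        flags.loc[(index >= ev.start) & (index < ev.end)] = ev.kind
    return flags


def compute_transpiration(
    hourly: pd.DataFrame,
    events: list[WaterEvent] | None = None,
    gain_tolerance_g: float = GAIN_TOLERANCE_G,
) -> pd.DataFrame:
    """Hourly transpiration (g) from an hourly weight trace.

    Outside event intervals, transpiration over [t, t+1h) is the weight
    drop ``w(t) - w(t+1h)``.  Event hours are flagged and excluded; hours
    with a genuine weight *gain* outside any event (rain on an uncovered
    pot, disturbance) are censored to missing rather than clipped to
    zero, so the mass-balance audit stays honest.  Gains no larger than
    ``gain_tolerance_g`` are scale noise around a near-zero night-time
    flux: they keep their (slightly negative) value under a
    ``noise_gain`` flag, which leaves daily sums unbiased.  Hours
    adjacent to missing weights are missing.
    """
    events = events or []
    w = hourly["weight_g"]
    idx = hourly.index[:-1] if len(hourly) > 1 else hourly.index[:0]
    dw = w.diff().shift(-1).iloc[:-1] if len(hourly) > 1 else w.iloc[:0]
    transp = -dw
    flags = pd.Series(FLAG_OK, index=idx, dtype=object)
    flags[transp.isna()] = FLAG_MISSING
    ev_flags = _event_hour_flags(idx, events)
    in_event = ev_flags != ""
    flags[in_event] = ev_flags[in_event]
    transp = transp.where(~in_event)
    noise_gain = (transp < 0) & (transp >= -gain_tolerance_g) & ~in_event
    flags[noise_gain] = FLAG_NOISE_GAIN
    gain = (transp < -gain_tolerance_g) & ~in_event
    n_gain = int(gain.sum())
    if n_gain:
        log.warning(
            "%d hour(s) with weight gain outside events censored to missing", n_gain
        )
        flags[gain] = FLAG_WEIGHT_GAIN
        transp = transp.where(~gain)
    out = pd.DataFrame(
        {"transpiration_g": transp, "flag": flags}, index=idx
    )
    out.index.name = "hour_start"
    if "sector_id" in hourly.columns and len(hourly):
        out.insert(0, "sector_id", hourly["sector_id"].iloc[0])
    return out


def mass_balance_residual(
    hourly: pd.DataFrame, transp: pd.DataFrame, events: list[WaterEvent]
) -> float:
    """Audit: sum(transpiration) - sum(event magnitudes) + total weight change.

    Zero (to rounding) whenever no hour was censored; censored hours
    (missing readings, weight gains) show up as a nonzero residual of
    exactly the censored mass.
    """
    total_dw = float(hourly["weight_g"].iloc[-1] - hourly["weight_g"].iloc[0])
    s_t = float(transp["transpiration_g"].sum())
    s_e = float(sum(ev.magnitude_g for ev in events))
    return s_t - s_e + total_dw


def transpiration_rate(
    transp: pd.DataFrame, leaf_area_cm2: pd.Series
) -> pd.DataFrame:
    """Transpiration rate in mg cm^-2 min^-1 (canopy-conductance proxy).

    ``leaf_area_cm2`` is the interpolated hourly leaf area aligned on the
    same hour starts.  rate = (g h^-1 x 1000 mg/g) / (cm^2 x 60 min/h).
    Hours with zero, negative or missing leaf area get an
    ``undefined_rate`` flag.
    """
    la = leaf_area_cm2.reindex(transp.index)
    rate = transp["transpiration_g"] * MG_PER_G / (la * MIN_PER_H)
    out = transp.copy()
    bad = (~(la > 0)) & transp["transpiration_g"].notna()
    rate[bad] = np.nan
    out["leaf_area_cm2"] = la
    out["rate_mg_cm2_min"] = rate
    out.loc[bad, "flag"] = "undefined_rate"
    return out


def treatment_response(
    groups: dict[str, list[pd.Series]],
    treatment_time: pd.Timestamp | datetime,
) -> dict:
    """Pre/post treatment contrast of transpiration rates between groups.

    ``groups`` maps a group label (e.g. genotype x treatment) to the list
    of per-sector hourly rate series (replicates).  For each group the
    hourly mean +/- SE across replicates is computed, plus each sector's
    post/pre mean-rate ratio; the contrast is the difference of group mean
    ratios with combined SE.  Groups with a single replicate get NaN SEs
    and a flag (SE is undefined at n = 1).
    """
    treatment_time = pd.Timestamp(treatment_time)
    result: dict = {"groups": {}, "contrasts": {}}
    ratios: dict[str, np.ndarray] = {}
    for label, series_list in groups.items():
        if len(series_list) < 1:
            raise ValueError(f"group {label!r} has no replicates")
        mat = pd.concat(series_list, axis=1)
        n = mat.notna().sum(axis=1)
        mean = mat.mean(axis=1)
        se = mat.std(axis=1, ddof=1) / np.sqrt(n)
        r = []
        for s in series_list:
            pre = s[s.index < treatment_time].mean()
            post = s[s.index >= treatment_time].mean()
            r.append(post / pre if pre and np.isfinite(pre) and pre > 0 else np.nan)
        r = np.asarray(r, dtype=float)
        ratios[label] = r
        n_rep = int(np.isfinite(r).sum())
        result["groups"][label] = {
            "hourly_mean": mean,
            "hourly_se": se,
            "post_pre_ratio": float(np.nanmean(r)) if n_rep else np.nan,
            "ratio_se": (
                float(np.nanstd(r, ddof=1) / np.sqrt(n_rep)) if n_rep > 1 else np.nan
            ),
            "n_replicates": len(series_list),
            "flag": FLAG_OK if len(series_list) > 1 else "single_replicate",
        }
    labels = list(groups)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            ga, gb = result["groups"][a], result["groups"][b]
            contrast = ga["post_pre_ratio"] - gb["post_pre_ratio"]
            se = float(np.hypot(ga["ratio_se"], gb["ratio_se"]))
            result["contrasts"][f"{a} - {b}"] = {"ratio_diff": contrast, "se": se}
    return result
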