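"""Weather handling: VPD, thermal time, wind filtering and time joins.

Platform weather stations integrate temperature, relative humidity, wind,
light and rain every 30 minutes.  This module derives the two axes the
analyses run on — vapour pressure deficit (the evaporative demand driver)
and thermal time (degree-days, the developmental clock) — and performs
the quality filtering and time-stamp synchronisation that join scans,
weights and weather into one hourly analysis table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .errors import InputError, JoinError
from .lysimetry import compute_transpiration, detect_events, transpiration_rate

__all__ = [
    "ThermalTimeParams",
    "ThermalTimeAxis",
    "saturation_vapour_pressure",
    "vpd",
    "thermal_time",
    "wind_filter",
    "median_window",
    "interpolate_traits",
    "sync_join",
]

log = logging.getLogger(__name__)

#: default wind-speed threshold (m s^-1) above which scans are rejected
DEFAULT_WIND_THRESHOLD = 2.0

#: maximum timestamp distance for matching an observation to a weather record
MATCH_TOLERANCE = pd.Timedelta(minutes=30)


def saturation_vapour_pressure(temp_c):
    """Saturation vapour pressure over water (kPa), Tetens formulation.

    e_s(T) = 0.6108 * exp(17.27 T / (T + 237.3)), the standard agronomic
    (FAO-56) form.
    """
    t = np.asarray(temp_c, dtype=float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def vpd(temp_c, rh_pct):
    """Vapour pressure deficit (kPa) from temperature (degC) and RH (%)."""
    rh = np.asarray(rh_pct, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise InputError("relative humidity must be within [0, 100] %")
    out = saturation_vapour_pressure(temp_c) * (1.0 - rh / 100.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ThermalTimeParams:
    """Cardinal temperatures (degC) of the degree-day accumulation rule.

    Below ``t_base`` no thermal time accrues; between base and the optimal
    plateau it accrues at (T - t_base); across the plateau
    [t_opt_low, t_opt_high] at the plateau rate (t_opt_low - t_base);
    above the plateau it declines linearly to zero at ``t_ceiling``.
    """

    t_base: float = 10.0
    t_opt_low: float = 25.0
    t_opt_high: float = 35.0
    t_ceiling: float = 45.0

    def rate(self, temp_c):
        """Instantaneous accumulation rate (degC above base)."""
        t = np.asarray(temp_c, dtype=float)
        plateau = self.t_opt_low - self.t_base
        r = np.where(
            t <= self.t_base,
            0.0,
            np.where(
                t <= self.t_opt_low,
                t - self.t_base,
                np.where(
                    t <= self.t_opt_high,
                    plateau,
                    np.where(
                        t < self.t_ceiling,
                        plateau * (self.t_ceiling - t) / (self.t_ceiling - self.t_opt_high),
                        0.0,
                    ),
                ),
            ),
        )
        return r if r.ndim else float(r)


class ThermalTimeAxis:
    """Cumulative degree-days as a function of calendar time.

    Non-decreasing, zero at the sowing origin; query with :meth:`at`
    (linear interpolation between weather records).
    """

    def __init__(self, times: pd.DatetimeIndex, cumulative_dd: np.ndarray):
        self.times = times
        self.cumulative_dd = np.asarray(cumulative_dd, dtype=float)

    def at(self, when) -> float | np.ndarray:
        t = pd.DatetimeIndex(
            when if isinstance(when, (list, np.ndarray, pd.DatetimeIndex)) else [when]
        )
        x = (t - self.times[0]).total_seconds()
        xp = (self.times - self.times[0]).total_seconds()
        out = np.interp(x, xp, self.cumulative_dd)
        return float(out[0]) if np.ndim(when) == 0 and not isinstance(
            when, (list, np.ndarray, pd.DatetimeIndex)
        ) else out

    def as_series(self) -> pd.Series:
        return pd.Series(self.cumulative_dd, index=self.times, name="degree_days")


def thermal_time(
    env: pd.DataFrame,
    sowing: datetime | pd.Timestamp,
    params: ThermalTimeParams | None = None,
    max_gap: pd.Timedelta = pd.Timedelta(hours=2),
) -> ThermalTimeAxis:
    """Accumulate degree-days from 30-min weather records.

    Each record contributes rate(T) x (interval length in days), with the
    interval taken to the next record.  Gaps longer than ``max_gap`` are
    linearly bridged (the gap accrues at the mean of the flanking rates)
    and logged as a warning.  The axis starts at zero at ``sowing``.
    """
    params = params or ThermalTimeParams()
    sowing = pd.Timestamp(sowing)
    df = env.sort_values("timestamp")
    times = pd.DatetimeIndex(df["timestamp"])
    if len(times) == 0 or times[0] > sowing:
        raise InputError("weather records must cover the sowing date onward")
    rates = params.rate(df["temp_c"].to_numpy())  # degC
    dt_days = np.diff(times.asi8) / 1e9 / 86400.0
    gaps = np.diff(times.asi8) / 1e9 > max_gap.total_seconds()
    if gaps.any():
        log.warning("%d gap(s) > %s in weather records linearly bridged", gaps.sum(), max_gap)
    seg_rate = np.where(gaps, 0.5 * (rates[:-1] + rates[1:]), rates[:-1])
    increments = np.concatenate([[0.0], seg_rate * dt_days])
    cum = np.cumsum(increments)
    # re-zero at sowing
    axis = ThermalTimeAxis(times, cum)
    offset = axis.at(sowing)
    return ThermalTimeAxis(times, np.maximum(0.0, cum - offset))


def wind_filter(
    observations: pd.DataFrame,
    env: pd.DataFrame,
    threshold_ms: float = DEFAULT_WIND_THRESHOLD,
    timestamp_col: str = "timestamp",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reject observations recorded when wind exceeded the threshold.

    Each observation is matched to the *nearest* weather record within 30
    minutes and retained iff that record's wind <= ``threshold_ms``
    (inclusive; 2 m s^-1 default).  Observations with no weather record
    within tolerance are unmatchable: dropped with a warning.  Returns
    ``(retained, rejected)`` — the rejected frame carries a ``reason``
    column (``wind`` or ``unmatched``) so counts always conserve.
    """
    if observations.empty:
        rej = observations.copy()
        rej["reason"] = pd.Series(dtype=object)
        return observations.copy(), rej
    obs = observations.sort_values(timestamp_col).reset_index(drop=True)
    envs = env.sort_values("timestamp")
    matched = pd.merge_asof(
        obs[[timestamp_col]],
        envs[["timestamp", "wind_ms"]].rename(columns={"timestamp": "_env_ts"}),
        left_on=timestamp_col,
        right_on="_env_ts",
        direction="nearest",
        tolerance=MATCH_TOLERANCE,
    )
    unmatched = matched["_env_ts"].isna()
    if unmatched.any():
        log.warning(
            "%d observation(s) had no weather record within %s; dropped",
            int(unmatched.sum()),
            MATCH_TOLERANCE,
        )
    windy = matched["wind_ms"] > threshold_ms
    keep = ~unmatched & ~windy
    retained = obs[keep.to_numpy()].copy()
    rejected = obs[~keep.to_numpy()].copy()
    rejected["reason"] = np.where(unmatched[~keep].to_numpy(), "unmatched", "wind")
    return retained, rejected


def median_window(
    series: pd.DataFrame,
    at: datetime | pd.Timestamp,
    half_width: timedelta | pd.Timedelta,
    value_col: str = "value",
    timestamp_col: str = "timestamp",
) -> float:
    """Median of values within [at - half_width, at + half_width].

    Robust daily summary around a chosen time of day (leaves move with
    wind, so a single scan is noisy).  NaN when the window is empty.
    """
    half_width = pd.Timedelta(half_width)
    if half_width <= pd.Timedelta(0):
        raise InputError("half_width must be > 0")
    at = pd.Timestamp(at)
    ts = series[timestamp_col]
    mask = (ts >= at - half_width) & (ts <= at + half_width)
    vals = series.loc[mask, value_col].dropna()
    return float(vals.median()) if len(vals) else float("nan")


def interpolate_traits(
    observations: pd.DataFrame,
    targets: pd.DatetimeIndex,
    value_col: str = "value",
    timestamp_col: str = "timestamp",
) -> pd.Series:
    """Piecewise-linear interpolation of a trait series at target instants.

    No extrapolation: targets before the first or after the last surviving
    observation are missing.  Fewer than two observations make every
    target missing.
    """
    obs = observations.dropna(subset=[value_col]).sort_values(timestamp_col)
    out = pd.Series(np.nan, index=targets, name=value_col)
    if len(obs) < 2:
        return out
    t = pd.DatetimeIndex(obs[timestamp_col]).asi8.astype(float)
    v = obs[value_col].to_numpy(dtype=float)
    x = targets.asi8.astype(float)
    inside = (x >= t[0]) & (x <= t[-1])
    out.iloc[inside] = np.interp(x[inside], t, v)
    return out


def sync_join(
    traits: pd.DataFrame,
    weights: pd.DataFrame,
    env: pd.DataFrame,
    sowing: datetime | pd.Timestamp | None = None,
    tt_params: ThermalTimeParams | None = None,
    wind_threshold_ms: float = DEFAULT_WIND_THRESHOLD,
    step_threshold_g: float = 50.0,
    rate_threshold_g_per_h: float = 200.0,
) -> pd.DataFrame:
    """Synchronise traits, hourly weights and weather into one table.

    Per sector and clock hour: interpolated leaf area (after the wind
    filter), transpiration, transpiration rate, temperature, RH, VPD,
    wind and cumulative degree-days.  ``traits`` needs columns sector_id,
    timestamp, leaf_area_3d_cm2; ``weights`` is the *hourly* weight table
    per sector (sector_id, hour index or hour_start column, weight_g).
    Raises :class:`JoinError` when trait and weight sector ids do not
    match.
    """
    trait_sectors = set(traits["sector_id"].unique())
    wdf = weights.reset_index() if weights.index.name == "hour_start" else weights.copy()
    weight_sectors = set(wdf["sector_id"].unique())
    if trait_sectors != weight_sectors:
        raise JoinError(
            f"sector ids differ between traits {sorted(trait_sectors)} "
            f"and weights {sorted(weight_sectors)}"
        )

    env_sorted = env.sort_values("timestamp").copy()
    env_sorted["vpd_kpa"] = vpd(env_sorted["temp_c"], env_sorted["rh_pct"])
    axis = None
    if sowing is not None:
        axis = thermal_time(env_sorted, sowing, tt_params)

    frames = []
    for sector in sorted(trait_sectors):
        tr = traits[traits["sector_id"] == sector]
        tr_kept, _ = wind_filter(tr, env_sorted, threshold_ms=wind_threshold_ms)
        sw = wdf[wdf["sector_id"] == sector].set_index("hour_start").sort_index()
        events = detect_events(sw, step_threshold_g, rate_threshold_g_per_h)
        transp = compute_transpiration(sw, events)
        hours = transp.index
        la = interpolate_traits(
            tr_kept, hours, value_col="leaf_area_3d_cm2"
        )
        rates = transpiration_rate(transp, la)
        table = rates.copy()
        table["sector_id"] = sector
        # nearest 30-min weather record per hour start
        envm = pd.merge_asof(
            pd.DataFrame({"hour_start": hours}),
            env_sorted[["timestamp", "temp_c", "rh_pct", "wind_ms", "vpd_kpa"]],
            left_on="hour_start",
            right_on="timestamp",
            direction="nearest",
            tolerance=MATCH_TOLERANCE,
        ).drop(columns="timestamp")
        table = table.reset_index().merge(envm, on="hour_start", how="left")
        if axis is not None:
            table["degree_days"] = axis.at(pd.DatetimeIndex(table["hour_start"]))
        frames.append(table)
    out = pd.concat(frames, ignore_index=True)
    cols = ["sector_id", "hour_start", "leaf_area_cm2", "transpiration_g",
            "rate_mg_cm2_min", "temp_c", "rh_pct", "vpd_kpa", "wind_ms", "flag"]
    if axis is not None:
        cols.append("degree_days")
    return out[cols]
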