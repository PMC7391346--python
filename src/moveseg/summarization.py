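"""Per-6-hr observation vectors for the HMM.

Regularized positions become step lengths (great-circle km) and turning
angles (signed bearing changes); dive records, temperature-profile
summaries and haul-outs are binned to the same grid. The first 24 h after
release are excluded (post-release stress can bias behavior).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import geo

INTERVAL_COLUMNS = [
    "animal_id", "time", "step_km", "turn_rad", "n_dives",
    "max_depth_m", "dive_time_s", "haulout_s",
    "temp_median_C", "temp_mean_C", "temp_sd_C",
]


def steps_and_angles(lon: np.ndarray, lat: np.ndarray):
    """Step lengths and turning angles from regular-grid positions.

    ``step[i]`` is the great-circle distance (km) from position i to
    position i+1 (length ``n-1``); ``turn[i]`` is the signed change of
    bearing between step i-1 and step i wrapped to (-pi, pi], undefined
    (NaN) for the first step.
    """
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    steps = geo.haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    bearings = geo.initial_bearing_rad(lon[:-1], lat[:-1], lon[1:], lat[1:])
    turns = np.full(len(steps), np.nan)
    if len(steps) > 1:
        turns[1:] = geo.wrap_angle(np.diff(bearings))
    return steps, turns


def summarize_profile(temps: np.ndarray) -> tuple[float, float, float]:
    """(mean, median, SD) of a dive's 17 profile temperatures, unweighted."""
    t = np.asarray(temps, dtype=float)
    return float(t.mean()), float(np.median(t)), float(t.std(ddof=0))


def _overlap_seconds(start, end, a, b):
    return max(0.0, min(end, b) - max(start, a))


def bin_intervals(
    track: pd.DataFrame,
    dives: pd.DataFrame,
    profiles: pd.DataFrame,
    haulouts: pd.DataFrame,
    interval_h: float = 6.0,
) -> pd.DataFrame:
    """Interval records for one animal: movement plus binned dive covariates.

    ``track`` must hold one animal's regular-grid positions (columns
    animal_id, time, lon, lat). Each dive is assigned to the interval
    containing its START; haul-out spans are split proportionally across
    the intervals they overlap. The interval temperature median is the
    median of per-dive profile medians (two-stage). Intervals with no
    temperature-carrying dive leave the temperature fields missing — a
    missing covariate is distinct from a zero count.

    Returns one row per grid step, timestamped by the interval START.
    """
    aid = track["animal_id"].iat[0]
    t = track["time"].to_numpy(dtype=float)
    steps, turns = steps_and_angles(track["lon"].to_numpy(), track["lat"].to_numpy())
    n_iv = len(t) - 1
    edges = t  # interval i = [t[i], t[i+1])
    rec = pd.DataFrame(
        {
            "animal_id": aid,
            "time": t[:-1],
            "step_km": steps,
            "turn_rad": turns,
            "n_dives": 0.0,
            "max_depth_m": np.nan,
            "dive_time_s": 0.0,
            "haulout_s": 0.0,
            "temp_median_C": np.nan,
            "temp_mean_C": np.nan,
            "temp_sd_C": np.nan,
        }
    )
    d = dives[dives["animal_id"] == aid]
    if len(d):
        idx = np.searchsorted(edges, d["start"].to_numpy(), side="right") - 1
        inside = (idx >= 0) & (idx < n_iv)
        if (~inside).any():
            warnings.warn(f"{aid}: dropped {int((~inside).sum())} dive(s) outside the track span")
        d = d[inside]
        idx = idx[inside]
        grp = pd.DataFrame(
            {"iv": idx, "depth": d["max_depth_m"].to_numpy(), "dur": d["duration_s"].to_numpy()}
        ).groupby("iv")
        agg = grp.agg(n=("depth", "size"), mx=("depth", "max"), dt=("dur", "sum"))
        rec.loc[agg.index, "n_dives"] = agg["n"].to_numpy(dtype=float)
        rec.loc[agg.index, "max_depth_m"] = agg["mx"].to_numpy()
        rec.loc[agg.index, "dive_time_s"] = agg["dt"].to_numpy()
        # two-stage temperature summary: per-dive stats, then per-interval medians
        p = profiles[profiles["animal_id"] == aid]
        if len(p):
            dive_stats = (
                p.groupby("dive_start")["temp_C"]
                .agg(mean="mean", median="median", sd=lambda v: v.std(ddof=0))
                .reset_index()
            )
            div_iv = np.searchsorted(edges, dive_stats["dive_start"].to_numpy(), side="right") - 1
            ok = (div_iv >= 0) & (div_iv < n_iv)
            dive_stats = dive_stats[ok].assign(iv=div_iv[ok])
            tg = dive_stats.groupby("iv")
            iv_keys = list(tg.groups.keys())
            rec.loc[iv_keys, "temp_median_C"] = tg["median"].median().to_numpy()
            rec.loc[iv_keys, "temp_mean_C"] = tg["mean"].mean().to_numpy()
            rec.loc[iv_keys, "temp_sd_C"] = tg["sd"].median().to_numpy()
    h = haulouts[haulouts["animal_id"] == aid]
    for _, row in h.iterrows():
        lo = max(0, int(np.searchsorted(edges, row["start"], side="right")) - 1)
        hi = min(n_iv - 1, int(np.searchsorted(edges, row["end"], side="right")) - 1)
        for iv in range(lo, hi + 1):
            rec.loc[iv, "haulout_s"] += _overlap_seconds(row["start"], row["end"], edges[iv], edges[iv + 1])
    return rec[INTERVAL_COLUMNS]


def exclude_initial(records: pd.DataFrame, hours: float = 24.0) -> pd.DataFrame:
    """Drop each animal's records starting within ``hours`` of its release.

    Release = the animal's first interval start. Emits a warning for
    animals whose whole track is shorter than the exclusion window.
    """
    out = []
    for aid, grp in records.groupby("animal_id", sort=False):
        t0 = grp["time"].min()
        kept = grp[grp["time"] >= t0 + hours * 3600.0]
        if kept.empty:
            warnings.warn(f"{aid}: track shorter than the {hours:.0f}-h exclusion window")
        out.append(kept)
    return pd.concat(out, ignore_index=True) if out else records.iloc[0:0]
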