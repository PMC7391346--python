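"""Readers and writers for the four telemetry input streams and rasters.

All tabular files are comma-separated with a mandatory header and '.'
decimals. Timestamps are ISO-8601 UTC on disk and seconds since the Unix
epoch in memory (unambiguous interval arithmetic). Longitudes live in
[-180, 180); the supported study areas do not cross the antimeridian.

Streams
-------
argos fixes      : animal_id, time, lon, lat, semi_major_m, semi_minor_m, orientation_deg
dive records     : animal_id, start, end, max_depth_m, duration_s
temperature      : animal_id, dive_start, cut_index (1..17), depth_m, temp_C
haul-outs        : animal_id, start, end
bathymetry       : single-band ESRI ASCII grid (.asc), elevation m, negative = below sea level
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("moveseg")

N_PROFILE_POINTS = 17  # cut points per temperature profile (tag firmware constant)
MIN_DIVE_DEPTH_M = 4.0  # a dive starts below 4 m (tag dive definition)
MIN_HAULOUT_S = 300.0  # haul-out start rule: dry for 5 min
TEMP_RANGE_C = (-5.0, 35.0)  # sensor operating range

ARGOS_COLUMNS = ["animal_id", "time", "lon", "lat", "semi_major_m", "semi_minor_m", "orientation_deg"]
DIVE_COLUMNS = ["animal_id", "start", "end", "max_depth_m", "duration_s"]
PROFILE_COLUMNS = ["animal_id", "dive_start", "cut_index", "depth_m", "temp_C"]
HAULOUT_COLUMNS = ["animal_id", "start", "end"]

_TIME_COLS = {"time", "start", "end", "dive_start"}


def _parse_times(series: pd.Series) -> pd.Series:
    """ISO-8601 UTC strings -> float seconds since epoch."""
    ts = pd.to_datetime(series, utc=True, format="ISO8601")
    return ts.astype("int64") / 1e9


def _format_times(seconds) -> pd.Series:
    dt = pd.to_datetime(np.asarray(seconds, dtype=float) * 1e9, utc=True)
    return dt.strftime("%Y-%m-%dT%H:%M:%SZ")


def _read_table(path, mandatory: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    df = df[mandatory].copy()  # unknown columns ignored
    for c in mandatory:
        if c in _TIME_COLS:
            df[c] = _parse_times(df[c])
    return df


def _write_table(df: pd.DataFrame, path, columns: list[str]) -> None:
    out = df[columns].copy()
    for c in columns:
        if c in _TIME_COLS:
            out[c] = _format_times(out[c])
    out.to_csv(path, index=False)


def read_argos(path) -> pd.DataFrame:
    """Read Argos fixes; sort per animal by time, drop invalid and duplicate rows.

    Returns a DataFrame with :data:`ARGOS_COLUMNS` (times as epoch seconds).
    Rows violating the fix invariants (|lat| > 90, negative axes,
    semi-minor > semi-major, orientation outside [0, 180)) are skipped with
    a warning; exact-duplicate (animal, time) pairs keep the first record.
    """
    df = _read_table(path, ARGOS_COLUMNS)
    n0 = len(df)
    ok = (
        df["lat"].abs().le(90)
        & df["lon"].ge(-180) & df["lon"].lt(180)
        & df["semi_major_m"].ge(0)
        & df["semi_minor_m"].ge(0)
        & (df["semi_major_m"] >= df["semi_minor_m"])
        & df["orientation_deg"].ge(0) & df["orientation_deg"].lt(180)
        & df[ARGOS_COLUMNS].notna().all(axis=1)
    )
    if (~ok).any():
        warnings.warn(f"read_argos: skipped {int((~ok).sum())} invalid row(s)")
    df = df[ok]
    df = df.sort_values(["animal_id", "time"], kind="mergesort")
    before = len(df)
    df = df.drop_duplicates(subset=["animal_id", "time"], keep="first")
    dropped = n0 - len(df)
    if before != len(df):
        log.info("read_argos: collapsed %d duplicate-timestamp fix(es)", before - len(df))
    log.info("read_argos: %d fixes kept, %d rows dropped", len(df), dropped)
    return df.reset_index(drop=True)


def write_argos(df: pd.DataFrame, path) -> None:
    _write_table(df, path, ARGOS_COLUMNS)


def read_dives_profiles_haulouts(dive_path, profile_path, haulout_path):
    """Read the three auxiliary streams.

    Returns ``(dives, profiles, haulouts)`` DataFrames. Dives with
    ``end <= start``, depth < 4 m or nonpositive duration are rejected;
    profiles without exactly 17 cut points, with decreasing depths, or with
    temperatures outside the sensor range are rejected; haul-outs shorter
    than 5 min are rejected. Each rejection emits a warning. Profiles that
    reference an animal absent from the dive stream are kept (animals may
    lack fixes in a window).
    """
    dives = _read_table(dive_path, DIVE_COLUMNS)
    ok = (
        (dives["end"] > dives["start"])
        & (dives["max_depth_m"] >= MIN_DIVE_DEPTH_M)
        & (dives["duration_s"] > 0)
    )
    if (~ok).any():
        warnings.warn(f"read_dives: rejected {int((~ok).sum())} invalid dive(s)")
    dives = dives[ok].sort_values(["animal_id", "start"], kind="mergesort").reset_index(drop=True)

    prof = _read_table(profile_path, PROFILE_COLUMNS)
    keep_keys = []
    for key, grp in prof.groupby(["animal_id", "dive_start"], sort=False):
        g = grp.sort_values("cut_index")
        if (
            len(g) == N_PROFILE_POINTS
            and (g["cut_index"].to_numpy() == np.arange(1, N_PROFILE_POINTS + 1)).all()
            and (np.diff(g["depth_m"].to_numpy()) >= 0).all()
            and g["temp_C"].between(*TEMP_RANGE_C).all()
        ):
            keep_keys.append(key)
        else:
            warnings.warn(f"read_profiles: rejected malformed profile {key}")
    idx = pd.MultiIndex.from_tuples(keep_keys, names=["animal_id", "dive_start"]) if keep_keys else None
    if idx is not None:
        prof = prof.set_index(["animal_id", "dive_start"]).loc[idx].reset_index()
    else:
        prof = prof.iloc[0:0]
    prof = prof.sort_values(["animal_id", "dive_start", "cut_index"], kind="mergesort").reset_index(drop=True)
    unknown = set(prof["animal_id"]) - set(dives["animal_id"])
    if unknown:
        warnings.warn(f"read_profiles: profiles reference animals without dives: {sorted(unknown)}")

    hauls = _read_table(haulout_path, HAULOUT_COLUMNS)
    ok = (hauls["end"] - hauls["start"]) >= MIN_HAULOUT_S
    if (~ok).any():
        warnings.warn(f"read_haulouts: rejected {int((~ok).sum())} haul-out(s) shorter than 5 min")
    hauls = hauls[ok].sort_values(["animal_id", "start"], kind="mergesort").reset_index(drop=True)
    return dives, prof, hauls


def write_dives(df: pd.DataFrame, path) -> None:
    _write_table(df, path, DIVE_COLUMNS)


def write_profiles(df: pd.DataFrame, path) -> None:
    _write_table(df, path, PROFILE_COLUMNS)


def write_haulouts(df: pd.DataFrame, path) -> None:
    _write_table(df, path, HAULOUT_COLUMNS)


@dataclass
class BathymetryGrid:
    """Regular lon/lat elevation raster (m; negative below sea level).

    ``values`` is (nrows, ncols) with row 0 the NORTHERNMOST row, matching
    the ESRI ASCII layout. No-data cells are NaN, never silently zero.
    """

    values: np.ndarray
    lon_min: float  # west edge of the west column of cells
    lat_min: float  # south edge of the south row of cells
    cell_deg: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("bathymetry raster must be 2-D")

    @property
    def shape(self):
        return self.values.shape

    def lon_centers(self) -> np.ndarray:
        n = self.values.shape[1]
        return self.lon_min + (np.arange(n) + 0.5) * self.cell_deg

    def lat_centers(self) -> np.ndarray:
        """South-to-north cell-centre latitudes."""
        n = self.values.shape[0]
        return self.lat_min + (np.arange(n) + 0.5) * self.cell_deg

    def value_at(self, lon, lat):
        """Bilinear interpolation at lon/lat; NaN outside the extent or near no-data."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        nrows, ncols = self.values.shape
        # fractional index into cell-centre coordinates, south-up for rows
        fx = (lon - self.lon_min) / self.cell_deg - 0.5
        fy = (lat - self.lat_min) / self.cell_deg - 0.5
        south_up = self.values[::-1, :]
        out = np.full(lon.shape, np.nan)
        inside = (fx >= 0) & (fx <= ncols - 1) & (fy >= 0) & (fy <= nrows - 1)
        if inside.any():
            x0 = np.clip(np.floor(fx[inside]).astype(int), 0, ncols - 2)
            y0 = np.clip(np.floor(fy[inside]).astype(int), 0, nrows - 2)
            tx = fx[inside] - x0
            ty = fy[inside] - y0
            v00 = south_up[y0, x0]
            v01 = south_up[y0, x0 + 1]
            v10 = south_up[y0 + 1, x0]
            v11 = south_up[y0 + 1, x0 + 1]
            out[inside] = (
                v00 * (1 - tx) * (1 - ty)
                + v01 * tx * (1 - ty)
                + v10 * (1 - tx) * ty
                + v11 * tx * ty
            )  # NaN no-data propagates through the blend
        return out if out.size > 1 else float(out[0])


def read_bathymetry(path) -> BathymetryGrid:
    """Read a single-band ESRI ASCII grid (.asc).

    The six-line header must carry ncols/nrows, xllcorner/yllcorner (or
    the *center variants) and cellsize; a missing georeference is a hard
    error. NODATA cells become NaN.
    """
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter", "yllcenter",
                "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: ESRI ASCII grid missing '{key}' (no georeference)")
    cell = header["cellsize"]
    if "xllcorner" in header:
        lon_min = header["xllcorner"]
    elif "xllcenter" in header:
        lon_min = header["xllcenter"] - cell / 2.0
    else:
        raise ValueError(f"{path}: missing x georeference (xllcorner/xllcenter)")
    if "yllcorner" in header:
        lat_min = header["yllcorner"]
    elif "yllcenter" in header:
        lat_min = header["yllcenter"] - cell / 2.0
    else:
        raise ValueError(f"{path}: missing y georeference (yllcorner/yllcenter)")
    values = np.array([v for r in rows for v in r], dtype=float).reshape(
        int(header["nrows"]), int(header["ncols"])
    )
    nodata = header.get("nodata_value", -9999.0)
    values = np.where(values == nodata, np.nan, values)
    return BathymetryGrid(values, lon_min, lat_min, cell, nodata)


def write_bathymetry(grid: BathymetryGrid, path) -> None:
    """Write an ESRI ASCII grid; NaN cells become the nodata value."""
    nrows, ncols = grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.lon_min!r}\n")
        fh.write(f"yllcorner {grid.lat_min!r}\n")
        fh.write(f"cellsize {grid.cell_deg!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        vals = np.where(np.isnan(grid.values), grid.nodata, grid.values)
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
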