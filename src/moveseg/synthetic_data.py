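"""Synthetic telemetry generator with known ground truth.

Generates everything the pipeline consumes — true behavioral states, true
regular positions, Argos-corrupted fixes with error ellipses, dive
records, 17-cut-point temperature profiles, haul-outs, and an island
bathymetry raster — from a single seeded configuration, so that every
downstream stage can be verified by parameter recovery or exact truth
comparison.

The default configuration reproduces the published study conditions for
satellite-tracked juvenile loggerhead turtles in the southern Tyrrhenian
Sea: nine animals at 6-hr intervals; a 3-state chain (transit /
low-intensity diving / high-intensity diving) with self-transition
probabilities 0.86 / 0.80 / 0.86; Gamma step lengths with state means
8.152 / 6.2 / 5.3 km; von Mises turning angles with means 0.01 / 0.08 /
-0.11 rad and concentrations matched to circular SDs 1.4 / 1.85 / 1.91;
Poisson dive counts with rates 1.6 / 6.54 / 14.12 per 6 h; and an Argos
error model whose lognormal semi-major axis reproduces the reported mean
14,198 m, median 4,637 m and SD ~41,400 m simultaneously.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import geo
from .hmm import gamma_moments_to_shape_scale, kappa_from_circular_sd
from .ingest_io import (
    BathymetryGrid,
    MIN_DIVE_DEPTH_M,
    MIN_HAULOUT_S,
    N_PROFILE_POINTS,
    TEMP_RANGE_C,
)

#: transition probability matrix of the fitted 3-state model (row-stochastic)
TPM_DEFAULT = np.array(
    [
        [0.86, 0.13, 0.01],
        [0.13, 0.80, 0.07],
        [0.01, 0.13, 0.86],
    ]
)

#: state-dependent emission parameters of the fitted model
STEP_MEAN_KM = np.array([8.152, 6.2, 5.3])
STEP_SD_KM = np.array([3.27, 2.0, 1.5])
TURN_MEAN_RAD = np.array([0.01, 0.08, -0.11])
TURN_CIRC_SD = np.array([1.4, 1.85, 1.91])
DIVE_RATE = np.array([1.6, 6.54, 14.12])

#: Argos error-ellipse statistics (meters / degrees)
ELLIPSE_MAJOR_MEAN_M = 14198.0
ELLIPSE_MAJOR_MEDIAN_M = 4637.0
ELLIPSE_MINOR_MEAN_M = 802.0
ELLIPSE_MINOR_MEDIAN_M = 339.0
ELLIPSE_ORIENT_MEAN_DEG = 87.64
ELLIPSE_ORIENT_SD_DEG = 30.41


def _lognormal_params(mean: float, median: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal from its mean and median.

    median = exp(mu); mean = exp(mu + sigma^2/2), so
    sigma = sqrt(2 ln(mean/median)).
    """
    if mean <= median:
        raise ValueError("lognormal requires mean > median")
    return float(np.log(median)), float(np.sqrt(2.0 * np.log(mean / median)))


@dataclass
class SimConfig:
    """Study-condition configuration for the synthetic generator."""

    n_animals: int = 9
    n_intervals: int = 600
    interval_h: float = 6.0
    # emission parameters per state
    step_mean_km: np.ndarray = field(default_factory=lambda: STEP_MEAN_KM.copy())
    step_sd_km: np.ndarray = field(default_factory=lambda: STEP_SD_KM.copy())
    turn_mean_rad: np.ndarray = field(default_factory=lambda: TURN_MEAN_RAD.copy())
    turn_kappa: np.ndarray = field(
        default_factory=lambda: np.array([kappa_from_circular_sd(s) for s in TURN_CIRC_SD])
    )
    dive_rate: np.ndarray = field(default_factory=lambda: DIVE_RATE.copy())
    tpm: np.ndarray = field(default_factory=lambda: TPM_DEFAULT.copy())
    delta: np.ndarray = field(default_factory=lambda: np.array([1 / 3, 1 / 3, 1 / 3]))
    # Argos error model: lognormal axes matched to the reported mean/median
    ellipse_major_mean_m: float = ELLIPSE_MAJOR_MEAN_M
    ellipse_major_median_m: float = ELLIPSE_MAJOR_MEDIAN_M
    ellipse_minor_mean_m: float = ELLIPSE_MINOR_MEAN_M
    ellipse_minor_median_m: float = ELLIPSE_MINOR_MEDIAN_M
    ellipse_orient_mean_deg: float = ELLIPSE_ORIENT_MEAN_DEG
    ellipse_orient_sd_deg: float = ELLIPSE_ORIENT_SD_DEG
    error_scale: float = 1.0  # multiplies both axes; 0 disables location error
    fixes_per_interval: float = 3.0  # Poisson mean of irregular fixes per interval
    # dive / temperature / haul-out model
    dive_depth_median_m: float = 25.0
    dive_depth_sigma_log: float = 0.8
    dive_duration_mean_s: float = 900.0
    temp_base_C: float = 19.0  # surface mean (matches the mid-range of reported medians)
    temp_seasonal_amp_C: float = 3.0
    temp_lapse_C_per_m: float = 0.02  # vertical gradient
    temp_noise_C: float = 0.3
    haulout_prob: float = 0.05  # per transit interval
    haulout_mean_s: float = 1200.0
    # geography
    center_lon: float = geo.STUDY_CENTER_LON
    center_lat: float = geo.STUDY_CENTER_LAT
    t0_epoch_s: float = 1478217600.0  # 2016-11-04T00:00:00Z, first releases
    # island bathymetry fixture
    bathy_peak_m: float = 900.0
    bathy_slope_m_per_km: float = 30.0
    bathy_floor_m: float = -3600.0
    bathy_extent_km: float = 400.0
    bathy_cell_deg: float = 0.05
    seed: int = 42

    def __post_init__(self) -> None:
        self.tpm = np.asarray(self.tpm, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if not np.allclose(self.tpm.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if abs(self.delta.sum() - 1.0) > 1e-12:
            raise ValueError("initial distribution must sum to 1")
        for name in ("step_mean_km", "step_sd_km", "dive_rate"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be positive")

    @property
    def n_states(self) -> int:
        return self.tpm.shape[0]

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class SimulatedDataset:
    """Complete synthetic dataset with stored ground truth."""

    config: SimConfig
    truth: pd.DataFrame  # animal_id, interval start time, true state, true position, true observations
    argos: pd.DataFrame
    dives: pd.DataFrame
    profiles: pd.DataFrame
    haulouts: pd.DataFrame
    bathymetry: BathymetryGrid


def _animal_rng(config: SimConfig, animal_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, animal_index, stream]))


def simulate_hmm_track(config: SimConfig, animal_id: str, animal_index: int = 0):
    """Simulate one animal's state chain, observations and true positions.

    States follow the Markov chain (delta, tpm). Per 6-hr interval, step
    length ~ Gamma, turning angle ~ von Mises and dive count ~ Poisson,
    each with the state's parameters. Positions are built by dead
    reckoning in the planar km frame (heading accumulates the turning
    angles; the initial heading is uniform) and inverse-projected to
    lon/lat.

    Returns a DataFrame with columns time, state (1-based), x_km, y_km,
    lon, lat, step_km, turn_rad, n_dives; positions are the interval END
    points of each step, with the release point prepended.
    """
    if np.any(np.diag(config.tpm) >= 1.0 - 1e-15) and not np.allclose(config.tpm, np.eye(config.n_states)):
        pass  # absorbing rows are fine; fully deterministic identity also allowed
    rng = _animal_rng(config, animal_index, 0)
    T = config.n_intervals
    N = config.n_states
    states = np.empty(T, dtype=int)
    states[0] = rng.choice(N, p=config.delta)
    for t in range(1, T):
        states[t] = rng.choice(N, p=config.tpm[states[t - 1]])
    shape, scale = gamma_moments_to_shape_scale(config.step_mean_km, config.step_sd_km)
    steps = rng.gamma(shape[states], scale[states])
    turns = np.array(
        [rng.vonmises(config.turn_mean_rad[s], config.turn_kappa[s]) for s in states]
    )
    n_dives = rng.poisson(config.dive_rate[states])
    # dead reckoning: heading accrues turns; start heading uniform
    heading = rng.uniform(-np.pi, np.pi) + np.cumsum(turns)
    # start position jittered around the study centre so animals do not stack
    x0, y0 = rng.normal(0.0, 30.0, size=2)
    dx = steps * np.sin(heading)
    dy = steps * np.cos(heading)
    x = np.r_[x0, x0 + np.cumsum(dx)]
    y = np.r_[y0, y0 + np.cumsum(dy)]
    lon, lat = geo.unproject_aeqd(x, y, config.center_lon, config.center_lat)
    times = config.t0_epoch_s + np.arange(T + 1) * config.interval_h * 3600.0
    return pd.DataFrame(
        {
            "animal_id": animal_id,
            "time": times,
            "state": np.r_[states[0], states] + 1,  # state of the step ENDING at each point
            "x_km": x,
            "y_km": y,
            "lon": lon,
            "lat": lat,
            "step_km": np.r_[np.nan, steps],
            "turn_rad": np.r_[np.nan, turns],
            "n_dives": np.r_[-1, n_dives].astype(float),
        }
    ).assign(n_dives=lambda d: d["n_dives"].where(d["n_dives"] >= 0))


def sample_ellipses(config: SimConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Sample Argos error ellipses (meters, degrees).

    Semi-major and semi-minor axes are lognormal with (mu, sigma) chosen
    so the distribution reproduces the reported mean AND median of each
    axis; the minor axis is clipped at the major. Orientation is normal
    around the reported mean, wrapped to [0, 180).
    """
    muM, sgM = _lognormal_params(config.ellipse_major_mean_m, config.ellipse_major_median_m)
    mum, sgm = _lognormal_params(config.ellipse_minor_mean_m, config.ellipse_minor_median_m)
    major = rng.lognormal(muM, sgM, n)
    minor = np.minimum(rng.lognormal(mum, sgm, n), major)
    orient = rng.normal(config.ellipse_orient_mean_deg, config.ellipse_orient_sd_deg, n) % 180.0
    return pd.DataFrame(
        {
            "semi_major_m": major * config.error_scale,
            "semi_minor_m": minor * config.error_scale,
            "orientation_deg": orient,
        }
    )


def apply_argos_error(truth: pd.DataFrame, config: SimConfig, animal_index: int = 0) -> pd.DataFrame:
    """Corrupt a true track into irregular, error-prone Argos fixes.

    The number of fixes per interval is Poisson(``fixes_per_interval``) at
    uniform times within the interval; the true position at a fix time is
    linearly interpolated in the planar frame, then displaced by a
    bivariate normal draw whose covariance is the fix's sampled error
    ellipse (axes as 1-sigma extents, orientation from east). A fix at the
    release time is always included so the track start is observed.
    """
    from .regularization import ellipse_to_cov  # local import to avoid a cycle

    rng = _animal_rng(config, animal_index, 1)
    t = truth["time"].to_numpy()
    x = truth["x_km"].to_numpy()
    y = truth["y_km"].to_numpy()
    times = [np.array([t[0]])]
    for a, b in zip(t[:-1], t[1:]):
        k = rng.poisson(config.fixes_per_interval)
        if k:
            times.append(np.sort(rng.uniform(a, b, k)))
    ft = np.concatenate(times)
    ft = np.unique(ft)
    fx = np.interp(ft, t, x)
    fy = np.interp(ft, t, y)
    ell = sample_ellipses(config, ft.size, rng)
    dx = np.empty(ft.size)
    dy = np.empty(ft.size)
    for i in range(ft.size):
        cov_m2 = ellipse_to_cov(
            ell["semi_major_m"].iat[i], ell["semi_minor_m"].iat[i], ell["orientation_deg"].iat[i]
        )
        if np.allclose(cov_m2, 0.0):
            dx[i] = dy[i] = 0.0
        else:
            d = rng.multivariate_normal([0.0, 0.0], cov_m2 / 1e6)  # m^2 -> km^2
            dx[i], dy[i] = d
    lon, lat = geo.unproject_aeqd(fx + dx, fy + dy, config.center_lon, config.center_lat)
    return pd.DataFrame(
        {
            "animal_id": truth["animal_id"].iat[0],
            "time": ft,
            "lon": lon,
            "lat": lat,
            "semi_major_m": ell["semi_major_m"].to_numpy(),
            "semi_minor_m": ell["semi_minor_m"].to_numpy(),
            "orientation_deg": ell["orientation_deg"].to_numpy(),
        }
    )


def seasonal_temp_C(config: SimConfig, time_s, depth_m) -> np.ndarray:
    """Generator temperature field: base + seasonal sine - vertical lapse."""
    doy = (np.asarray(time_s, float) / 86400.0) % 365.25
    seasonal = config.temp_seasonal_amp_C * np.sin(2.0 * np.pi * (doy - 120.0) / 365.25)
    return config.temp_base_C + seasonal - config.temp_lapse_C_per_m * np.asarray(depth_m, float)


def simulate_dives_and_temps(truth: pd.DataFrame, config: SimConfig, animal_index: int = 0):
    """Dive records, 17-point temperature profiles and haul-outs for one track.

    Each interval receives exactly its true ``n_dives`` dives at uniform
    start times; max depth is lognormal (>= the 4-m dive threshold) and
    durations exponential. Every dive carries one profile whose 17 cut
    points run from the minimum depth to the dive's max depth, with
    temperatures from the seasonal/lapse field plus noise, clipped to the
    sensor range. Haul-outs (>= 5 min) occur only in transit intervals —
    a fixture assumption, not an inference.
    """
    rng = _animal_rng(config, animal_index, 2)
    animal = truth["animal_id"].iat[0]
    rows_d, rows_p, rows_h = [], [], []
    stepped = truth.iloc[1:]
    for _, r in stepped.iterrows():
        t1 = r["time"]
        t0 = t1 - config.interval_h * 3600.0
        k = int(r["n_dives"]) if np.isfinite(r["n_dives"]) else 0
        # whole-second start times, unique per animal (the tag clock ticks seconds)
        starts = np.sort(np.round(rng.uniform(t0, t1 - k, k)))
        for j in range(1, k):
            if starts[j] <= starts[j - 1]:
                starts[j] = starts[j - 1] + 1.0
        for ts in starts:
            depth = max(MIN_DIVE_DEPTH_M, rng.lognormal(np.log(config.dive_depth_median_m), config.dive_depth_sigma_log))
            dur = max(60.0, rng.exponential(config.dive_duration_mean_s))
            rows_d.append((animal, ts, ts + dur, depth, dur))
            depths = np.linspace(0.0, depth, N_PROFILE_POINTS)
            temps = seasonal_temp_C(config, ts, depths)
            if config.temp_noise_C > 0:
                temps = temps + rng.normal(0.0, config.temp_noise_C, N_PROFILE_POINTS)
            temps = np.clip(temps, *TEMP_RANGE_C)
            for ci in range(N_PROFILE_POINTS):
                rows_p.append((animal, ts, ci + 1, depths[ci], temps[ci]))
        if int(r["state"]) == 1 and rng.uniform() < config.haulout_prob:
            hs = rng.uniform(t0, t1 - MIN_HAULOUT_S)
            dur = MIN_HAULOUT_S + rng.exponential(config.haulout_mean_s)
            rows_h.append((animal, hs, min(hs + dur, t1)))
    dives = pd.DataFrame(rows_d, columns=["animal_id", "start", "end", "max_depth_m", "duration_s"])
    profiles = pd.DataFrame(rows_p, columns=["animal_id", "dive_start", "cut_index", "depth_m", "temp_C"])
    hauls = pd.DataFrame(rows_h, columns=["animal_id", "start", "end"])
    hauls = hauls[(hauls["end"] - hauls["start"]) >= MIN_HAULOUT_S].reset_index(drop=True)
    return dives, profiles, hauls


def make_bathymetry_island(config: SimConfig) -> BathymetryGrid:
    """Radially symmetric island raster around the study centre.

    Elevation = peak - slope * (km from centre), clipped below at the
    abyssal floor; the zero-crossing (coastline) radius is peak/slope km.
    """
    half_deg = config.bathy_extent_km / 111.0
    cell = config.bathy_cell_deg
    n = int(np.ceil(2 * half_deg / cell))
    lon_min = config.center_lon - half_deg
    lat_min = config.center_lat - half_deg
    lons = lon_min + (np.arange(n) + 0.5) * cell
    lats = lat_min + (np.arange(n) + 0.5) * cell  # south-to-north
    LON, LAT = np.meshgrid(lons, lats)
    x, y = geo.project_aeqd(LON, LAT, config.center_lon, config.center_lat)
    r = np.hypot(x, y)
    elev = np.maximum(config.bathy_peak_m - config.bathy_slope_m_per_km * r, config.bathy_floor_m)
    return BathymetryGrid(elev[::-1, :], lon_min, lat_min, cell)  # row 0 = north


def simulate_dataset(config: SimConfig | None = None) -> SimulatedDataset:
    """Generate the complete multi-animal dataset with its ground truth."""
    config = config or SimConfig()
    truths, argos, dives, profs, hauls = [], [], [], [], []
    for i in range(config.n_animals):
        aid = f"sim{i + 1:03d}"
        tr = simulate_hmm_track(config, aid, i)
        truths.append(tr)
        argos.append(apply_argos_error(tr, config, i))
        d, p, h = simulate_dives_and_temps(tr, config, i)
        dives.append(d)
        profs.append(p)
        hauls.append(h)
    def _cat(frames: list[pd.DataFrame]) -> pd.DataFrame:
        nonempty = [f for f in frames if len(f)] or frames[:1]
        return pd.concat(nonempty, ignore_index=True)

    return SimulatedDataset(
        config=config,
        truth=_cat(truths),
        argos=_cat(argos),
        dives=_cat(dives),
        profiles=_cat(profs),
        haulouts=_cat(hauls),
        bathymetry=make_bathymetry_island(config),
    )


def simulate_truth_records(config: SimConfig | None = None) -> pd.DataFrame:
    """Per-interval true observation vectors for all animals, tracks only.

    Generates just the state chains and emission draws (no Argos
    corruption, dives-as-records, profiles or raster) — the fast path for
    HMM recovery experiments on the true observations.
    """
    config = config or SimConfig()
    frames = []
    for i in range(config.n_animals):
        tr = simulate_hmm_track(config, f"sim{i + 1:03d}", i)
        rec = tr[tr["step_km"].notna()][["animal_id", "time", "state", "step_km", "turn_rad", "n_dives"]].copy()
        rec.iloc[0, rec.columns.get_loc("turn_rad")] = np.nan
        frames.append(rec)
    return pd.concat(frames, ignore_index=True)


def truth_records(dataset: SimulatedDataset) -> pd.DataFrame:
    """Per-interval true observation vectors (the generator's truth table).

    One row per 6-hr step per animal with the true state and the exact
    step/turn/dive-count emissions — the HMM-ready frame for
    recovery experiments that bypass the location-error stages.
    """
    df = dataset.truth
    out = df[df["step_km"].notna()][["animal_id", "time", "state", "step_km", "turn_rad", "n_dives"]].copy()
    # the first turn of each track is undefined (no previous bearing)
    first = out.groupby("animal_id")["time"].transform("min")
    out.loc[out["time"] == first, "turn_rad"] = np.nan
    return out.reset_index(drop=True)
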