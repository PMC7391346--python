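"""Continuous-time correlated random walk regularization of Argos tracks.

Position is modeled as the integral of a 2-D Ornstein-Uhlenbeck velocity
process (the CTCRW movement model): per coordinate,

    dv = -beta * v dt + sigma * dW,      x(t) = x(0) + int_0^t v(s) ds

with beta the velocity autocorrelation rate (1/h) and sigma the velocity
diffusion scale (km h^-3/2). The exact discrete-time transition over any
gap dt is linear-Gaussian, so irregular, error-prone fixes are handled by
a Kalman filter on the 4-state vector (x, vx, y, vy) with each fix's
bivariate-normal error ellipse as its measurement covariance. Maximum
likelihood estimates of (beta, sigma), Rauch-Tung-Striebel smoothing onto
the regular 6-hr grid, and joint draws of the position process (multiple
imputation) all run in the planar km frame of the study-centre azimuthal
equidistant projection.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import geo

#: diffuse prior variance on the initial position, km^2
P0_POSITION_KM2 = 1.0e4


def ellipse_to_cov(
    semi_major_m: float,
    semi_minor_m: float,
    orientation_deg: float,
    scale: float = 1.0,
    orientation_from_north: bool = False,
) -> np.ndarray:
    """Error-ellipse (axes, orientation) -> 2x2 covariance in m^2.

    Sigma = R(theta) diag((a*k)^2, (b*k)^2) R(theta)^T with the axes
    treated as 1-sigma extents scaled by ``scale`` (k = 1 by default; the
    scaling convention varies in the Argos literature) and theta measured
    anticlockwise from the x-axis (east). Tags that report orientation
    clockwise from north are handled with ``orientation_from_north``.
    """
    a = float(semi_major_m) * scale
    b = float(semi_minor_m) * scale
    if b > a:
        raise ValueError("semi-minor axis exceeds semi-major axis")
    theta = np.radians(90.0 - orientation_deg if orientation_from_north else orientation_deg)
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    return R @ np.diag([a**2, b**2]) @ R.T


@dataclass
class CTCRWParams:
    """Fitted movement parameters and the initial-state prior."""

    beta: float  # velocity autocorrelation rate, 1/h
    sigma: float  # velocity diffusion scale, km h^-1.5
    mean0: np.ndarray  # (4,) initial state mean [x, vx, y, vy]
    cov0: np.ndarray  # (4, 4) initial state covariance
    loglik: float = np.nan
    converged: bool = True

    def __post_init__(self):
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError("beta must be finite and positive")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError("sigma must be finite and positive")


@dataclass
class RegularTrack:
    """Smoothed positions at the exact 6-hr grid, with uncertainty."""

    animal_id: str
    times: np.ndarray  # epoch seconds, spacing exactly interval_h
    x_km: np.ndarray
    y_km: np.ndarray
    cov_km2: np.ndarray  # (T, 2, 2) smoothed position covariance
    lon: np.ndarray = field(default=None)
    lat: np.ndarray = field(default=None)
    gap_flag: np.ndarray = field(default=None)  # True where > 48 h to the nearest fix

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "time": self.times,
                "x_km": self.x_km,
                "y_km": self.y_km,
                "lon": self.lon,
                "lat": self.lat,
                "var_x_km2": self.cov_km2[:, 0, 0],
                "var_y_km2": self.cov_km2[:, 1, 1],
                "cov_xy_km2": self.cov_km2[:, 0, 1],
                "gap_flag": self.gap_flag,
            }
        )


@dataclass
class ImputedTrackSet:
    """nSims joint draws of the position process on the regular grid."""

    animal_id: str
    times: np.ndarray
    draws: np.ndarray  # (nSims, T, 2) planar km
    seed: int | None = None


# ---------------------------------------------------------------------------
# state-space matrices


def _transition(beta: float, sigma: float, dt: float):
    """Exact discrete OU-integrated transition (Phi, Q) for one coordinate pair.

    State (position, velocity); dt in hours.
    """
    bd = beta * dt
    if bd < 1e-6:
        # second-order Taylor, avoids catastrophic cancellation
        phi01 = dt * (1 - bd / 2 + bd**2 / 6)
        e = 1.0 - bd + bd**2 / 2
        qxx = sigma**2 * dt**3 / 3.0
        qxv = sigma**2 * dt**2 / 2.0
        qvv = sigma**2 * dt
    else:
        e = np.exp(-bd)
        one_me = -np.expm1(-bd)
        one_me2 = -np.expm1(-2.0 * bd)
        phi01 = one_me / beta
        qxx = (sigma**2 / beta**2) * (dt - 2.0 * one_me / beta + one_me2 / (2.0 * beta))
        qxv = (sigma**2 / (2.0 * beta**2)) * (1.0 - 2.0 * e + e**2)
        qvv = (sigma**2 / (2.0 * beta)) * one_me2
    Phi = np.array([[1.0, phi01], [0.0, e]])
    Q = np.array([[qxx, qxv], [qxv, qvv]])
    return Phi, Q


def _transition4(beta: float, sigma: float, dt: float):
    Phi2, Q2 = _transition(beta, sigma, dt)
    Phi = np.zeros((4, 4))
    Q = np.zeros((4, 4))
    Phi[:2, :2] = Phi2
    Phi[2:, 2:] = Phi2
    Q[:2, :2] = Q2
    Q[2:, 2:] = Q2
    return Phi, Q


_H = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 0.0, 1.0, 0.0]])


def default_prior(beta: float, sigma: float, x0: float, y0: float) -> tuple[np.ndarray, np.ndarray]:
    """Initial-state prior: diffuse position at the first fix, stationary velocity."""
    vvar = sigma**2 / (2.0 * beta)
    mean0 = np.array([x0, 0.0, y0, 0.0])
    cov0 = np.diag([P0_POSITION_KM2, vvar, P0_POSITION_KM2, vvar])
    return mean0, cov0


def kalman_filter(
    beta: float,
    sigma: float,
    times_h: np.ndarray,
    obs: np.ndarray,
    obs_cov: np.ndarray,
    mean0: np.ndarray,
    cov0: np.ndarray,
):
    """Kalman filter over an irregular timeline; NaN observation rows are skipped.

    Returns (loglik, filtered means, filtered covs, predicted means,
    predicted covs). All in the planar km / hour frame.
    """
    n = len(times_h)
    m_pred = np.empty((n, 4))
    P_pred = np.empty((n, 4, 4))
    m_filt = np.empty((n, 4))
    P_filt = np.empty((n, 4, 4))
    ll = 0.0
    m, P = mean0.copy(), cov0.copy()
    for t in range(n):
        if t > 0:
            dt = times_h[t] - times_h[t - 1]
            Phi, Q = _transition4(beta, sigma, dt)
            m = Phi @ m
            P = Phi @ P @ Phi.T + Q
        m_pred[t] = m
        P_pred[t] = P
        y = obs[t]
        if np.all(np.isfinite(y)):
            S = _H @ P @ _H.T + obs_cov[t]
            v = y - _H @ m
            L = np.linalg.cholesky(S)
            z = np.linalg.solve(L, v)
            ll -= 0.5 * (z @ z) + np.log(L[0, 0] * L[1, 1]) + np.log(2.0 * np.pi)
            K = np.linalg.solve(S, _H @ P).T
            m = m + K @ v
            P = P - K @ S @ K.T
            P = 0.5 * (P + P.T)
        m_filt[t] = m
        P_filt[t] = P
    return ll, m_filt, P_filt, m_pred, P_pred


def rts_smoother(beta, sigma, times_h, m_filt, P_filt, m_pred, P_pred):
    """Rauch-Tung-Striebel pass; returns smoothed means and covariances."""
    n = len(times_h)
    m_s = m_filt.copy()
    P_s = P_filt.copy()
    for t in range(n - 2, -1, -1):
        dt = times_h[t + 1] - times_h[t]
        Phi, _ = _transition4(beta, sigma, dt)
        G = np.linalg.solve(P_pred[t + 1], Phi @ P_filt[t]).T
        m_s[t] = m_filt[t] + G @ (m_s[t + 1] - m_pred[t + 1])
        P_s[t] = P_filt[t] + G @ (P_s[t + 1] - P_pred[t + 1]) @ G.T
        P_s[t] = 0.5 * (P_s[t] + P_s[t].T)
    return m_s, P_s


# ---------------------------------------------------------------------------
# data preparation


def _fixes_to_arrays(fixes: pd.DataFrame, center_lon: float, center_lat: float,
                     ellipse_scale: float = 1.0):
    """Planar observation arrays (times h, obs km, covs km^2) from a fix frame."""
    t_s = fixes["time"].to_numpy(dtype=float)
    x, y = geo.project_aeqd(fixes["lon"].to_numpy(), fixes["lat"].to_numpy(), center_lon, center_lat)
    obs = np.column_stack([x, y])
    covs = np.empty((len(fixes), 2, 2))
    for i, (a, b, th) in enumerate(
        zip(fixes["semi_major_m"], fixes["semi_minor_m"], fixes["orientation_deg"])
    ):
        covs[i] = ellipse_to_cov(a, b, th, scale=ellipse_scale) / 1.0e6  # m^2 -> km^2
    return t_s / 3600.0, obs, covs


def ctcrw_loglik(beta, sigma, times_h, obs, obs_cov, mean0=None, cov0=None) -> float:
    """Prospective (prediction-error) log-likelihood of the CTCRW."""
    if mean0 is None:
        mean0, cov0 = default_prior(beta, sigma, obs[0, 0], obs[0, 1])
    ll, *_ = kalman_filter(beta, sigma, times_h, obs, obs_cov, mean0, cov0)
    return float(ll)


def fit_ctcrw(
    fixes: pd.DataFrame,
    center_lon: float = geo.STUDY_CENTER_LON,
    center_lat: float = geo.STUDY_CENTER_LAT,
    ellipse_scale: float = 1.0,
    n_starts: int = 5,
) -> CTCRWParams:
    """Maximum-likelihood (beta, sigma) for one animal's fixes.

    Optimizes the Kalman prediction-error likelihood on (log beta,
    log sigma) with quasi-Newton iterations from ``n_starts`` spread
    starting points. Requires >= 10 fixes spanning at least 12 h.
    """
    if len(fixes) < 10:
        raise ValueError("need at least 10 fixes to fit the CTCRW")
    times_h, obs, covs = _fixes_to_arrays(fixes, center_lon, center_lat, ellipse_scale)
    if times_h[-1] - times_h[0] < 12.0:
        raise ValueError("fixes must span at least two 6-hr intervals")

    def nll(logp):
        beta, sigma = np.exp(logp)
        try:
            ll = ctcrw_loglik(beta, sigma, times_h, obs, covs)
        except np.linalg.LinAlgError:
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    starts = [
        (np.log(0.5), np.log(2.0)),
        (np.log(0.05), np.log(0.5)),
        (np.log(2.0), np.log(5.0)),
        (np.log(0.2), np.log(10.0)),
        (np.log(1.0), np.log(0.2)),
    ][: max(n_starts, 1)]
    best = None
    for s in starts:
        res = optimize.minimize(nll, np.array(s), method="L-BFGS-B",
                                options={"ftol": 1e-10, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError(f"CTCRW fit failed to converge; best incumbent {best.x}")
    beta, sigma = np.exp(best.x)
    mean0, cov0 = default_prior(beta, sigma, obs[0, 0], obs[0, 1])
    return CTCRWParams(beta=float(beta), sigma=float(sigma), mean0=mean0, cov0=cov0,
                       loglik=float(-best.fun), converged=bool(best.success))


def _merged_timeline(times_h: np.ndarray, interval_h: float):
    """Union of fix times and the regular grid anchored at the first fix.

    Returns (all times sorted unique, indices of grid points within it,
    grid times).
    """
    grid = np.arange(times_h[0], times_h[-1] + 1e-9, interval_h)
    allt = np.unique(np.concatenate([times_h, grid]))
    gidx = np.searchsorted(allt, grid)
    return allt, gidx, grid


def predict_regular(
    params: CTCRWParams,
    fixes: pd.DataFrame,
    interval_h: float = 6.0,
    center_lon: float = geo.STUDY_CENTER_LON,
    center_lat: float = geo.STUDY_CENTER_LAT,
    ellipse_scale: float = 1.0,
) -> RegularTrack:
    """Smoothed positions on the regular grid spanning first to last fix.

    The grid is anchored at the first fix time. Grid intervals farther
    than 48 h from the nearest fix are flagged rather than dropped.
    """
    times_h, obs, covs = _fixes_to_arrays(fixes, center_lon, center_lat, ellipse_scale)
    allt, gidx, grid = _merged_timeline(times_h, interval_h)
    if len(grid) < 3:
        raise ValueError("regular grid would have fewer than 3 points")
    obs_full = np.full((len(allt), 2), np.nan)
    cov_full = np.zeros((len(allt), 2, 2))
    oidx = np.searchsorted(allt, times_h)
    obs_full[oidx] = obs
    cov_full[oidx] = covs
    ll, m_f, P_f, m_p, P_p = kalman_filter(
        params.beta, params.sigma, allt, obs_full, cov_full, params.mean0, params.cov0
    )
    m_s, P_s = rts_smoother(params.beta, params.sigma, allt, m_f, P_f, m_p, P_p)
    xs = m_s[gidx][:, [0, 2]]
    Ps = P_s[gidx][:, [0, 2]][:, :, [0, 2]]
    nearest = np.min(np.abs(grid[:, None] - times_h[None, :]), axis=1)
    lon, lat = geo.unproject_aeqd(xs[:, 0], xs[:, 1], center_lon, center_lat)
    return RegularTrack(
        animal_id=str(fixes["animal_id"].iat[0]),
        times=grid * 3600.0,
        x_km=xs[:, 0],
        y_km=xs[:, 1],
        cov_km2=Ps,
        lon=lon,
        lat=lat,
        gap_flag=nearest > 48.0,
    )


def draw_imputations(
    params: CTCRWParams,
    fixes: pd.DataFrame,
    n_sims: int = 100,
    seed: int | None = None,
    interval_h: float = 6.0,
    center_lon: float = geo.STUDY_CENTER_LON,
    center_lat: float = geo.STUDY_CENTER_LAT,
    ellipse_scale: float = 1.0,
) -> ImputedTrackSet:
    """Joint draws of the position process at the grid times (simulation smoother).

    Uses the mean-correction simulation smoother: an unconditional state
    and observation sample is drawn from the model, both the real and the
    simulated observations are smoothed, and

        draw = smoothed(real) + (simulated states - smoothed(simulated))

    which has exactly the conditional (smoothing) distribution. Draws are
    reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    times_h, obs, covs = _fixes_to_arrays(fixes, center_lon, center_lat, ellipse_scale)
    allt, gidx, grid = _merged_timeline(times_h, interval_h)
    n = len(allt)
    obs_full = np.full((n, 2), np.nan)
    cov_full = np.zeros((n, 2, 2))
    oidx = np.searchsorted(allt, times_h)
    obs_full[oidx] = obs
    cov_full[oidx] = covs
    # smooth the real data once
    _, m_f, P_f, m_p, P_p = kalman_filter(
        params.beta, params.sigma, allt, obs_full, cov_full, params.mean0, params.cov0
    )
    m_s, _ = rts_smoother(params.beta, params.sigma, allt, m_f, P_f, m_p, P_p)
    # precompute transitions
    Phis, Qchols = [], []
    for t in range(1, n):
        Phi, Q = _transition4(params.beta, params.sigma, allt[t] - allt[t - 1])
        Phis.append(Phi)
        # Q can be near-singular for tiny gaps; jitter for the Cholesky
        Qchols.append(np.linalg.cholesky(Q + 1e-12 * np.eye(4)))
    L0 = np.linalg.cholesky(params.cov0 + 1e-12 * np.eye(4))
    obs_chol = np.empty((len(oidx), 2, 2))
    for i in range(len(oidx)):
        obs_chol[i] = np.linalg.cholesky(covs[i] + 1e-12 * np.eye(2))
    draws = np.empty((n_sims, len(grid), 2))
    for k in range(n_sims):
        a = np.empty((n, 4))
        a[0] = params.mean0 + L0 @ rng.standard_normal(4)
        for t in range(1, n):
            a[t] = Phis[t - 1] @ a[t - 1] + Qchols[t - 1] @ rng.standard_normal(4)
        yplus = np.full((n, 2), np.nan)
        for i, t in enumerate(oidx):
            yplus[t] = a[t, [0, 2]] + obs_chol[i] @ rng.standard_normal(2)
        _, mf2, Pf2, mp2, Pp2 = kalman_filter(
            params.beta, params.sigma, allt, yplus, cov_full, params.mean0, params.cov0
        )
        ms2, _ = rts_smoother(params.beta, params.sigma, allt, mf2, Pf2, mp2, Pp2)
        cond = m_s + (a - ms2)
        draws[k] = cond[gidx][:, [0, 2]]
    return ImputedTrackSet(
        animal_id=str(fixes["animal_id"].iat[0]), times=grid * 3600.0, draws=draws, seed=seed
    )
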