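"""Post hoc analysis of decoded behavioral states.

Two analyses follow the HMM: a multinomial logistic regression of the
decoded state on the interval's median water temperature (transit as the
baseline category), and activity budgets — within-bin state proportions —
against distance to the coast and seafloor depth.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import spatial, stats

from . import geo
from .ingest_io import BathymetryGrid


@dataclass
class MultinomialFit:
    """Softmax regression of state on temperature, baseline = state 1 (transit)."""

    coef: np.ndarray  # (N-1, 2): [intercept, slope] per non-baseline state
    se: np.ndarray  # same shape, Wald standard errors
    loglik: float
    n_obs: int
    categories: np.ndarray  # sorted unique state labels; categories[0] is baseline
    converged: bool = True
    ridge: float = 0.0

    def predict_probs(self, temp) -> np.ndarray:
        """(n, N) fitted category probabilities at the given temperatures."""
        t = np.atleast_1d(np.asarray(temp, dtype=float))
        eta = np.zeros((t.size, len(self.categories)))
        eta[:, 1:] = self.coef[:, 0][None, :] + t[:, None] * self.coef[:, 1][None, :]
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        return p / p.sum(axis=1, keepdims=True)

    @property
    def zvalues(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))


def fit_multinomial(states, temp_median, ridge: float = 0.0, max_iter: int = 200,
                    tol: float = 1e-8) -> MultinomialFit:
    """Multinomial logistic regression MLE by Newton-Raphson.

    ``states`` are hard category labels (e.g. Viterbi states 1..3),
    ``temp_median`` the interval median water temperatures; rows with
    missing temperature are the caller's responsibility to drop.
    Convergence requires the gradient infinity-norm below ``tol``. On
    complete separation (divergent coefficients) a ``RuntimeError``
    suggests the ridge fallback (``ridge=1e-6`` stabilizes the Hessian).
    """
    s = np.asarray(states)
    t = np.asarray(temp_median, dtype=float)
    ok = np.isfinite(t)
    s, t = s[ok], t[ok]
    cats = np.unique(s)
    N = len(cats)
    if N < 2:
        raise ValueError("need at least two observed categories")
    counts = np.array([(s == c).sum() for c in cats])
    if counts.min() < 10:
        raise ValueError(f"fewer than 10 observations in category {cats[counts.argmin()]}")
    Y = (s[:, None] == cats[None, :]).astype(float)  # (n, N) one-hot
    X = np.column_stack([np.ones_like(t), t])  # (n, 2)
    K = N - 1
    beta = np.zeros((K, 2))
    n = len(s)
    for _ in range(max_iter):
        eta = np.zeros((n, N))
        eta[:, 1:] = X @ beta.T
        eta -= eta.max(axis=1, keepdims=True)
        P = np.exp(eta)
        P /= P.sum(axis=1, keepdims=True)
        G = X.T @ (Y[:, 1:] - P[:, 1:])  # (2, K) gradient (column-major per category)
        grad = G.T.ravel() - ridge * beta.ravel()
        # Hessian blocks H[(k,a),(l,b)] = -sum_i x_ia x_ib P_ik (1{k=l} - P_il)
        H = np.empty((2 * K, 2 * K))
        for k in range(K):
            for l in range(K):
                w = P[:, k + 1] * ((1.0 if k == l else 0.0) - P[:, l + 1])
                H[2 * k : 2 * k + 2, 2 * l : 2 * l + 2] = -(X.T * w) @ X
        H -= ridge * np.eye(2 * K)
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError as e:
            raise RuntimeError(
                "singular Hessian (complete separation?); retry with ridge=1e-6"
            ) from e
        beta = beta + step.reshape(K, 2)
        if np.abs(grad).max() < tol:
            break
    else:
        if np.abs(beta).max() > 50.0:
            raise RuntimeError(
                "multinomial fit diverged (complete separation?); retry with ridge=1e-6"
            )
    eta = np.zeros((n, N))
    eta[:, 1:] = X @ beta.T
    eta -= eta.max(axis=1, keepdims=True)
    P = np.exp(eta)
    P /= P.sum(axis=1, keepdims=True)
    ll = float(np.sum(Y * np.log(np.maximum(P, 1e-300))))
    cov = np.linalg.inv(-H)
    se = np.sqrt(np.diag(cov)).reshape(K, 2)
    return MultinomialFit(coef=beta, se=se, loglik=ll, n_obs=n, categories=cats,
                          converged=np.abs(grad).max() < tol, ridge=ridge)


# ---------------------------------------------------------------------------
# bathymetry-derived covariates


def coastline_cells(grid: BathymetryGrid) -> tuple[np.ndarray, np.ndarray]:
    """Lon/lat centres of coastline cells (sea cells adjacent to a sign change).

    A cell is a coastline cell if its elevation and a 4-neighbour's have
    opposite signs (or either is exactly 0). Raises on all-sea or all-land
    rasters.
    """
    v = grid.values[::-1, :]  # south-up
    finite = np.isfinite(v)
    if not ((v[finite] > 0).any() and (v[finite] <= 0).any()):
        raise ValueError("raster is all sea or all land; no coastline")
    sign = np.where(v > 0, 1.0, -1.0)
    sign[~finite] = np.nan
    edge = np.zeros_like(sign, dtype=bool)
    edge[:-1, :] |= sign[:-1, :] * sign[1:, :] < 0
    edge[1:, :] |= sign[1:, :] * sign[:-1, :] < 0
    edge[:, :-1] |= sign[:, :-1] * sign[:, 1:] < 0
    edge[:, 1:] |= sign[:, 1:] * sign[:, :-1] < 0
    edge |= v == 0
    rows, cols = np.nonzero(edge & finite)
    lons = grid.lon_centers()[cols]
    lats = grid.lat_centers()[rows]
    return lons, lats


def distance_to_coast(lon, lat, grid: BathymetryGrid,
                      center_lon: float = geo.STUDY_CENTER_LON,
                      center_lat: float = geo.STUDY_CENTER_LAT):
    """Great-circle distance (km) from each point to the nearest coastline cell.

    Points over land (positive interpolated elevation) get NaN distance
    and a True entry in the returned land flag.

    Returns ``(dist_km, on_land)``.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    clon, clat = coastline_cells(grid)
    # nearest neighbour in the planar frame, verified in great-circle distance
    cx, cy = geo.project_aeqd(clon, clat, center_lon, center_lat)
    px, py = geo.project_aeqd(lon, lat, center_lon, center_lat)
    tree = spatial.cKDTree(np.column_stack([cx, cy]))
    _, idx = tree.query(np.column_stack([px, py]))
    d = geo.haversine_km(lon, lat, clon[idx], clat[idx])
    elev = np.atleast_1d(grid.value_at(lon, lat))
    on_land = elev > 0
    d = np.where(on_land, np.nan, d)
    return d, on_land


@dataclass
class ActivityBudget:
    """Counts and state proportions per covariate bin [edge, edge + width)."""

    bin_edges: np.ndarray  # left edges, length n_bins
    bin_width: float
    counts: np.ndarray  # (n_bins,) intervals per bin
    proportions: np.ndarray  # (n_bins, N) state proportions; NaN rows where count == 0
    states: np.ndarray  # the state labels of the proportion columns

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"bin_left": self.bin_edges, "count": self.counts})
        for j, st in enumerate(self.states):
            df[f"p_state{st}"] = self.proportions[:, j]
        return df


def activity_budget(states, values, bin_width: float, origin: float = 0.0) -> ActivityBudget:
    """State composition across half-open covariate bins [a, a + w).

    ``values`` is the per-interval covariate (km to coast, or seafloor
    depth in m); rows with missing values are dropped. Total counts are
    conserved across bins.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    s = np.asarray(states)
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    s, v = s[ok], v[ok]
    cats = np.unique(s)
    lo = origin + np.floor((v.min() - origin) / bin_width) * bin_width
    hi = origin + (np.floor((v.max() - origin) / bin_width) + 1) * bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    idx = np.floor((v - lo) / bin_width).astype(int)
    nb = len(edges) - 1
    idx = np.clip(idx, 0, nb - 1)
    counts = np.bincount(idx, minlength=nb).astype(float)
    props = np.full((nb, len(cats)), np.nan)
    for j, c in enumerate(cats):
        cc = np.bincount(idx[s == c], minlength=nb)
        with np.errstate(invalid="ignore", divide="ignore"):
            props[:, j] = np.where(counts > 0, cc / counts, np.nan)
    return ActivityBudget(bin_edges=edges[:-1], bin_width=bin_width, counts=counts,
                          proportions=props, states=cats)
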