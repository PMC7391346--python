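"""Three-state hidden Markov model over movement and dive data streams.

Observation vectors are 6-hr interval summaries: step length (Gamma),
turning angle (von Mises) and number of dives (Poisson), with optional
extra streams (normal or gamma) for candidate covariates such as maximum
dive depth or water temperature. The hidden chain is first order with a
row-stochastic transition matrix and a free initial distribution shared
across animals; each animal's track restarts the chain at the initial
distribution.

Fitting is by direct numerical maximization of the forward log-likelihood
over unconstrained working parameters (logs for positive parameters,
multinomial logits for transition rows and the initial distribution, and a
``(kappa*cos mu, kappa*sin mu)`` pair for each von Mises component), with
multi-start initialization. States are relabeled canonically by ascending
Poisson dive rate so state 1 is "transit" (fewest dives) and state 3
"high-intensity diving".
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize, special, stats

STATE_LABELS = ("transit", "low-intensity diving", "high-intensity diving")

# ---------------------------------------------------------------------------
# parameterization helpers


def gamma_moments_to_shape_scale(mean: float, sd: float) -> tuple[float, float]:
    """Convert a Gamma (mean, SD) pair to (shape, scale).

    shape = mean^2 / sd^2, scale = sd^2 / mean; the inverse of
    mean = shape*scale, sd^2 = shape*scale^2.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(mean <= 0) or np.any(sd <= 0):
        raise ValueError("gamma moments must be positive")
    return mean**2 / sd**2, sd**2 / mean


def gamma_shape_scale_to_moments(shape, scale):
    shape = np.asarray(shape, dtype=float)
    scale = np.asarray(scale, dtype=float)
    return shape * scale, np.sqrt(shape) * scale


def kappa_from_circular_sd(sd_rad: float) -> float:
    """von Mises concentration whose mean resultant length matches a circular SD.

    Uses the wrapped-normal correspondence R = exp(-sd^2/2) and inverts
    A1(kappa) = I1(kappa)/I0(kappa) = R numerically. Returns 0 for R <= 0.
    """
    r = float(np.exp(-0.5 * float(sd_rad) ** 2))
    if r <= 1e-12:
        return 0.0
    if r >= 1 - 1e-12:
        return 1e12

    def a1(k):
        return special.i1e(k) / special.i0e(k)

    return float(optimize.brentq(lambda k: a1(k) - r, 1e-10, 1e4, xtol=1e-12))


def circular_sd_from_kappa(kappa: float) -> float:
    r = special.i1e(kappa) / special.i0e(kappa)
    return float(np.sqrt(-2.0 * np.log(max(r, 1e-300))))


# ---------------------------------------------------------------------------
# model specification and parameter containers

#: stream family -> per-state parameter names
_FAMILY_PARAMS = {
    "gamma": ("mean", "sd"),
    "vonmises": ("mean", "kappa"),
    "poisson": ("rate",),
    "normal": ("mean", "sd"),
}


@dataclass(frozen=True)
class StreamSpec:
    """One observation stream: a record column and its state-dependent family."""

    name: str
    family: str
    circular: bool = False

    def __post_init__(self):
        if self.family not in _FAMILY_PARAMS:
            raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class HMMSpec:
    """Model structure: number of states and the observation streams."""

    n_states: int = 3
    streams: tuple[StreamSpec, ...] = (
        StreamSpec("step_km", "gamma"),
        StreamSpec("turn_rad", "vonmises", circular=True),
        StreamSpec("n_dives", "poisson"),
    )
    state_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if not self.streams:
            raise ValueError("at least one stream required")
        if self.state_labels is None and self.n_states == 3:
            object.__setattr__(self, "state_labels", STATE_LABELS)

    @property
    def n_free_params(self) -> int:
        n = self.n_states
        k = sum(len(_FAMILY_PARAMS[s.family]) for s in self.streams) * n
        k += n * (n - 1)  # transition matrix rows
        k += n - 1  # initial distribution
        return k


@dataclass
class HMMFit:
    """A fitted HMM: emission parameters, chain parameters and fit metadata."""

    spec: HMMSpec
    emissions: dict  # stream name -> {param name -> array over states}
    tpm: np.ndarray  # transition probability matrix, rows sum to 1
    delta: np.ndarray  # initial distribution
    loglik: float
    n_obs: int
    seed: int | None = None
    start_logliks: list = field(default_factory=list)
    converged: bool = True
    relabel_order: np.ndarray | None = None

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.spec.n_free_params

    def theta(self) -> np.ndarray:
        return _pack(self.spec, self.emissions, self.tpm, self.delta)


@dataclass
class StateSequence:
    """Decoded states: Viterbi path, local probabilities, merged diving probability."""

    viterbi: np.ndarray  # 1-based state indices
    local_probs: np.ndarray  # (T, N) forward-backward posteriors
    merged_diving_prob: np.ndarray  # P(state 2) + P(state 3)


# ---------------------------------------------------------------------------
# data preparation


def prepare_records(records: pd.DataFrame, spec: HMMSpec) -> tuple[np.ndarray, np.ndarray]:
    """Pooled observation matrix and track-start offsets from interval records.

    Records must be sorted by (animal, time). Returns ``(obs, starts)``
    where ``obs`` is (T, n_streams) with NaN for missing values and
    ``starts`` the index of each animal's first interval plus a final
    sentinel T. Zero step lengths are replaced by half the smallest
    positive observed step (the Gamma density has no mass at zero); the
    replacement count is reported via a warning.
    """
    cols = [s.name for s in spec.streams]
    obs = records[cols].to_numpy(dtype=float)
    try:
        i_step = cols.index("step_km")
    except ValueError:
        i_step = None
    if i_step is not None:
        col = obs[:, i_step]
        zero = col == 0.0
        if zero.any():
            pos = col[col > 0]
            if pos.size == 0:
                raise ValueError("all step lengths are zero")
            obs[zero, i_step] = 0.5 * pos.min()
            warnings.warn(f"replaced {int(zero.sum())} zero step length(s) by half the minimum positive step")
    ids = records["animal_id"].to_numpy()
    starts = np.flatnonzero(np.r_[True, ids[1:] != ids[:-1]])
    starts = np.r_[starts, len(ids)].astype(np.int64)
    return obs, starts


# ---------------------------------------------------------------------------
# emission densities


def _log_emissions(spec: HMMSpec, emissions: dict, obs: np.ndarray) -> np.ndarray:
    """(T, N) total log emission density; missing values contribute 0."""
    T = obs.shape[0]
    N = spec.n_states
    logB = np.zeros((T, N))
    for j, s in enumerate(spec.streams):
        x = obs[:, j]
        miss = ~np.isfinite(x)
        xs = np.where(miss, 1.0, x)
        p = emissions[s.name]
        if s.family == "gamma":
            shape, scale = gamma_moments_to_shape_scale(p["mean"], p["sd"])
            lb = stats.gamma.logpdf(xs[:, None], a=shape[None, :], scale=scale[None, :])
        elif s.family == "vonmises":
            lb = stats.vonmises.logpdf(xs[:, None], kappa=np.maximum(p["kappa"], 1e-12)[None, :], loc=p["mean"][None, :])
        elif s.family == "poisson":
            lb = stats.poisson.logpmf(np.round(xs[:, None]), mu=p["rate"][None, :])
        elif s.family == "normal":
            lb = stats.norm.logpdf(xs[:, None], loc=p["mean"][None, :], scale=p["sd"][None, :])
        else:  # pragma: no cover
            raise ValueError(s.family)
        lb = np.where(miss[:, None], 0.0, lb)
        if not np.all(np.isfinite(lb) | np.isneginf(lb)):
            bad = np.argwhere(np.isnan(lb))
            raise FloatingPointError(
                f"NaN emission density for stream {s.name!r} at interval {bad[0][0]}"
            )
        logB += lb
    return logB


# ---------------------------------------------------------------------------
# forward recursion, Viterbi, forward-backward (numba kernels)


@njit(cache=True)
def _forward_kernel(logB, tpm, delta, starts):
    total = 0.0
    n_tracks = starts.shape[0] - 1
    N = tpm.shape[0]
    for tr in range(n_tracks):
        a = starts[tr]
        b = starts[tr + 1]
        alpha = np.empty(N)
        m = logB[a].max()
        c = 0.0
        for i in range(N):
            alpha[i] = delta[i] * np.exp(logB[a, i] - m)
            c += alpha[i]
        total += np.log(c) + m
        for i in range(N):
            alpha[i] /= c
        for t in range(a + 1, b):
            m = logB[t].max()
            new = np.zeros(N)
            c = 0.0
            for j in range(N):
                s = 0.0
                for i in range(N):
                    s += alpha[i] * tpm[i, j]
                new[j] = s * np.exp(logB[t, j] - m)
                c += new[j]
            total += np.log(c) + m
            for j in range(N):
                alpha[j] = new[j] / c
    return total


@njit(cache=True)
def _viterbi_kernel(logB, log_tpm, log_delta, starts):
    T = logB.shape[0]
    N = log_tpm.shape[0]
    path = np.zeros(T, dtype=np.int64)
    n_tracks = starts.shape[0] - 1
    for tr in range(n_tracks):
        a = starts[tr]
        b = starts[tr + 1]
        L = b - a
        score = np.empty((L, N))
        back = np.zeros((L, N), dtype=np.int64)
        for i in range(N):
            score[0, i] = log_delta[i] + logB[a, i]
        for t in range(1, L):
            for j in range(N):
                best = -np.inf
                arg = 0
                for i in range(N):
                    v = score[t - 1, i] + log_tpm[i, j]
                    if v > best:  # strict: ties break toward the lower state index
                        best = v
                        arg = i
                score[t, j] = best + logB[a + t, j]
                back[t, j] = arg
        best = -np.inf
        arg = 0
        for i in range(N):
            if score[L - 1, i] > best:
                best = score[L - 1, i]
                arg = i
        path[a + L - 1] = arg
        for t in range(L - 1, 0, -1):
            arg = back[t, arg]
            path[a + t - 1] = arg
    return path


def forward_loglik(spec: HMMSpec, emissions: dict, tpm: np.ndarray, delta: np.ndarray,
                   records: pd.DataFrame | None = None, *,
                   obs: np.ndarray | None = None, starts: np.ndarray | None = None) -> float:
    """Scaled forward log-likelihood, summed over animals.

    Each animal's chain restarts at the initial distribution. Missing
    stream values contribute likelihood 1 for that stream.
    """
    if obs is None:
        obs, starts = prepare_records(records, spec)
    tpm = np.asarray(tpm, dtype=float)
    if not np.allclose(tpm.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition matrix rows must sum to 1")
    logB = _log_emissions(spec, emissions, obs)
    return float(_forward_kernel(logB, tpm, np.asarray(delta, float), np.asarray(starts, np.int64)))


def viterbi(fit: HMMFit, records: pd.DataFrame) -> np.ndarray:
    """Exact MAP state path (1-based), ties broken toward the lower state index."""
    obs, starts = prepare_records(records, fit.spec)
    logB = _log_emissions(fit.spec, fit.emissions, obs)
    with np.errstate(divide="ignore"):
        path = _viterbi_kernel(logB, np.log(fit.tpm), np.log(fit.delta), starts)
    return path + 1


def local_state_probs(fit: HMMFit, records: pd.DataFrame) -> StateSequence:
    """Forward-backward posterior state probabilities and the merged diving probability.

    The merged diving probability is P(state 2) + P(state 3) — the summed
    posterior mass of the two diving states (zero when N < 2 states beyond
    the first exist).
    """
    obs, starts = prepare_records(records, fit.spec)
    logB = _log_emissions(fit.spec, fit.emissions, obs)
    N = fit.spec.n_states
    T = obs.shape[0]
    post = np.empty((T, N))
    for a, b in zip(starts[:-1], starts[1:]):
        L = b - a
        alpha = np.empty((L, N))
        cs = np.empty(L)
        B = np.exp(logB[a:b] - logB[a:b].max(axis=1, keepdims=True))
        alpha[0] = fit.delta * B[0]
        cs[0] = alpha[0].sum()
        alpha[0] /= cs[0]
        for t in range(1, L):
            alpha[t] = (alpha[t - 1] @ fit.tpm) * B[t]
            cs[t] = alpha[t].sum()
            alpha[t] /= cs[t]
        beta = np.empty((L, N))
        beta[-1] = 1.0
        for t in range(L - 2, -1, -1):
            beta[t] = fit.tpm @ (B[t + 1] * beta[t + 1]) / cs[t + 1]
        p = alpha * beta
        post[a:b] = p / p.sum(axis=1, keepdims=True)
    merged = post[:, 1:].sum(axis=1) if N > 1 else np.zeros(T)
    vit = viterbi(fit, records)
    return StateSequence(viterbi=vit, local_probs=post, merged_diving_prob=merged)


# ---------------------------------------------------------------------------
# packing / unpacking of working parameters


def _pack(spec: HMMSpec, emissions: dict, tpm: np.ndarray, delta: np.ndarray) -> np.ndarray:
    parts = []
    for s in spec.streams:
        p = emissions[s.name]
        if s.family == "gamma" or s.family == "normal":
            parts += [np.log(p["mean"]), np.log(p["sd"])]
        elif s.family == "vonmises":
            parts += [p["kappa"] * np.cos(p["mean"]), p["kappa"] * np.sin(p["mean"])]
        elif s.family == "poisson":
            parts += [np.log(p["rate"])]
    N = spec.n_states
    if N > 1:
        tpm = np.asarray(tpm, float)
        for i in range(N):
            row = np.maximum(tpm[i], 1e-300)
            parts.append(np.log(np.delete(row, i) / row[i]))
        d = np.maximum(np.asarray(delta, float), 1e-300)
        parts.append(np.log(d[1:] / d[0]))
    return np.concatenate(parts)


def _unpack(spec: HMMSpec, theta: np.ndarray):
    N = spec.n_states
    pos = 0
    emissions: dict = {}
    for s in spec.streams:
        if s.family in ("gamma", "normal"):
            emissions[s.name] = {
                "mean": np.exp(theta[pos : pos + N]),
                "sd": np.exp(theta[pos + N : pos + 2 * N]),
            }
            pos += 2 * N
        elif s.family == "vonmises":
            x = theta[pos : pos + N]
            y = theta[pos + N : pos + 2 * N]
            emissions[s.name] = {"mean": np.arctan2(y, x), "kappa": np.hypot(x, y)}
            pos += 2 * N
        elif s.family == "poisson":
            emissions[s.name] = {"rate": np.exp(theta[pos : pos + N])}
            pos += N
    if N > 1:
        tpm = np.empty((N, N))
        for i in range(N):
            eta = theta[pos : pos + N - 1]
            pos += N - 1
            row = np.ones(N)
            row[np.arange(N) != i] = np.exp(np.clip(eta, -700, 700))
            tpm[i] = row / row.sum()
        eta = theta[pos : pos + N - 1]
        pos += N - 1
        d = np.ones(N)
        d[1:] = np.exp(np.clip(eta, -700, 700))
        delta = d / d.sum()
    else:
        tpm = np.ones((1, 1))
        delta = np.ones(1)
    return emissions, tpm, delta


# ---------------------------------------------------------------------------
# fitting


def _data_driven_init(spec: HMMSpec, obs: np.ndarray, rng: np.random.Generator, perturb: bool):
    """Initial parameters from an N-quantile split of each stream.

    The first start uses the split means/SDs directly; subsequent starts
    perturb positive parameters log-normally (scale 0.4) and angles
    uniformly.
    """
    N = spec.n_states
    emissions: dict = {}
    for j, s in enumerate(spec.streams):
        x = obs[:, j]
        x = x[np.isfinite(x)]
        if s.family in ("gamma", "normal", "poisson"):
            qs = np.quantile(x, np.linspace(0, 1, N + 1))
            means, sds = [], []
            for i in range(N):
                lo, hi = qs[i], qs[i + 1]
                sel = x[(x >= lo) & (x <= hi)]
                if sel.size < 2:
                    sel = x
                means.append(max(sel.mean(), 1e-6))
                sds.append(max(sel.std(), 1e-3 * max(sel.mean(), 1.0)))
            means = np.array(means)
            sds = np.array(sds)
            if perturb:
                means = means * np.exp(0.4 * rng.standard_normal(N))
                sds = sds * np.exp(0.4 * rng.standard_normal(N))
            if s.family == "poisson":
                emissions[s.name] = {"rate": means}
            else:
                emissions[s.name] = {"mean": means, "sd": sds}
        else:  # vonmises
            mu = np.zeros(N)
            kappa = np.full(N, 1.0)
            if perturb:
                mu = rng.uniform(-0.5, 0.5, N)
                kappa = kappa * np.exp(0.4 * rng.standard_normal(N))
            emissions[s.name] = {"mean": mu, "kappa": kappa}
    tpm = np.full((N, N), 0.1 / max(N - 1, 1)) + np.eye(N) * (0.9 - 0.1 / max(N - 1, 1))
    tpm /= tpm.sum(axis=1, keepdims=True)
    delta = np.full(N, 1.0 / N)
    if perturb and N > 1:
        tpm = tpm * np.exp(0.3 * rng.standard_normal((N, N)))
        tpm /= tpm.sum(axis=1, keepdims=True)
    return emissions, tpm, delta


def _canonical_order(spec: HMMSpec, emissions: dict) -> np.ndarray:
    """State permutation sorting by ascending Poisson dive rate.

    Falls back to ascending mean of the first stream when no Poisson
    stream is present.
    """
    for s in spec.streams:
        if s.family == "poisson":
            return np.argsort(emissions[s.name]["rate"], kind="stable")
    s0 = spec.streams[0]
    key = emissions[s0.name]["mean" if "mean" in emissions[s0.name] else "rate"]
    return np.argsort(key, kind="stable")


def _relabel(spec: HMMSpec, emissions: dict, tpm: np.ndarray, delta: np.ndarray, order: np.ndarray):
    em = {name: {k: np.asarray(v)[order].copy() for k, v in p.items()} for name, p in emissions.items()}
    return em, tpm[np.ix_(order, order)].copy(), delta[order].copy()


def fit_hmm(
    spec: HMMSpec,
    records: pd.DataFrame,
    n_starts: int = 25,
    seed: int | None = None,
    init: dict | None = None,
    maxiter_explore: int = 60,
    maxiter_polish: int = 1000,
) -> HMMFit:
    """Fit the HMM by multi-start direct likelihood maximization.

    Each start runs a short quasi-Newton exploration; the best incumbent is
    then polished to convergence. ``init`` may supply explicit
    ``{"emissions":..., "tpm":..., "delta":...}`` used as the first start.
    Returns the best fit with states relabeled by ascending dive rate and
    all starts' log-likelihoods recorded.
    """
    rng = np.random.default_rng(seed)
    obs, starts = prepare_records(records, spec)
    if np.any(np.diff(starts) < 1):
        raise ValueError("empty track")

    def nll(theta):
        emissions, tpm, delta = _unpack(spec, theta)
        try:
            logB = _log_emissions(spec, emissions, obs)
        except FloatingPointError:
            return 1e12
        ll = _forward_kernel(logB, tpm, delta, starts)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    results = []
    for k in range(max(n_starts, 1)):
        if k == 0 and init is not None:
            em0, tpm0, d0 = init["emissions"], np.asarray(init["tpm"], float), np.asarray(init["delta"], float)
        else:
            em0, tpm0, d0 = _data_driven_init(spec, obs, rng, perturb=k > 0)
        theta0 = _pack(spec, em0, tpm0, d0)
        try:
            res = optimize.minimize(nll, theta0, method="L-BFGS-B",
                                    options={"maxiter": maxiter_explore, "ftol": 1e-10})
            results.append((res.fun, res.x))
        except Exception:
            continue
    if not results:
        raise RuntimeError("all optimization starts failed")
    results.sort(key=lambda r: r[0])
    best_fun, best_x = results[0]
    res = optimize.minimize(nll, best_x, method="L-BFGS-B",
                            options={"maxiter": maxiter_polish, "ftol": 1e-12})
    if res.fun <= best_fun:
        best_fun, best_x = res.fun, res.x
    emissions, tpm, delta = _unpack(spec, best_x)
    order = _canonical_order(spec, emissions)
    emissions, tpm, delta = _relabel(spec, emissions, tpm, delta, order)
    return HMMFit(
        spec=spec,
        emissions=emissions,
        tpm=tpm,
        delta=delta,
        loglik=-best_fun,
        n_obs=obs.shape[0],
        seed=seed,
        start_logliks=[-f for f, _ in results],
        converged=bool(res.success or res.status == 1),
        relabel_order=order,
    )


# ---------------------------------------------------------------------------
# diagnostics


def pseudo_residuals(fit: HMMFit, records: pd.DataFrame) -> pd.DataFrame:
    """One-step-ahead forecast pseudo-residuals per stream.

    For each interval the forecast CDF under the fitted model (state
    probabilities propagated from the previous interval) is evaluated at
    the observation and probit-transformed; the discrete dive stream uses
    the mid-P convention F(x-1) + p(x)/2. Under a correctly specified
    model the residuals are standard normal and serially uncorrelated.
    Degenerate (0/1) forecast probabilities are clipped, never NaN.
    """
    spec = fit.spec
    obs, starts = prepare_records(records, spec)
    T = obs.shape[0]
    N = spec.n_states
    logB = _log_emissions(spec, fit.emissions, obs)
    # predictive state distribution before seeing interval t
    pred = np.empty((T, N))
    for a, b in zip(starts[:-1], starts[1:]):
        w = fit.delta.copy()
        for t in range(a, b):
            pred[t] = w
            B = np.exp(logB[t] - logB[t].max())
            alpha = w * B
            alpha /= alpha.sum()
            w = alpha @ fit.tpm
    out = {}
    for j, s in enumerate(spec.streams):
        x = obs[:, j]
        p = fit.emissions[s.name]
        if s.family == "gamma":
            shape, scale = gamma_moments_to_shape_scale(p["mean"], p["sd"])
            F = stats.gamma.cdf(x[:, None], a=shape[None, :], scale=scale[None, :])
        elif s.family == "vonmises":
            F = stats.vonmises.cdf(x[:, None], kappa=np.maximum(p["kappa"], 1e-12)[None, :], loc=p["mean"][None, :])
        elif s.family == "poisson":
            F = stats.poisson.cdf(np.round(x[:, None]) - 1, mu=p["rate"][None, :]) + 0.5 * stats.poisson.pmf(
                np.round(x[:, None]), mu=p["rate"][None, :]
            )
        elif s.family == "normal":
            F = stats.norm.cdf(x[:, None], loc=p["mean"][None, :], scale=p["sd"][None, :])
        u = np.einsum("tn,tn->t", pred, F)
        u = np.clip(u, 1e-12, 1 - 1e-12)
        r = stats.norm.ppf(u)
        r[~np.isfinite(x)] = np.nan
        out[s.name] = r
    return pd.DataFrame(out, index=records.index)


def residual_diagnostics(resid: pd.Series, max_lag: int = 10) -> dict:
    """Autocorrelation at lags 1..max_lag and a Jarque-Bera normality statistic."""
    r = np.asarray(resid, dtype=float)
    r = r[np.isfinite(r)]
    if r.size < max_lag + 2 or r.std() == 0:
        return {"acf": np.full(max_lag, np.nan), "jb_stat": np.nan, "jb_pvalue": np.nan,
                "degenerate": True}
    rc = r - r.mean()
    denom = np.dot(rc, rc)
    acf = np.array([np.dot(rc[: -k], rc[k:]) / denom for k in range(1, max_lag + 1)])
    jb, p = stats.jarque_bera(r)
    return {"acf": acf, "jb_stat": float(jb), "jb_pvalue": float(p), "degenerate": False}


# ---------------------------------------------------------------------------
# multiple-imputation pooling


def pool_mi_fits(fits: list[HMMFit]) -> dict:
    """Pool HMM fits across imputations by Rubin's rules.

    Estimates are averaged on the unconstrained working scale; the total
    variance is W + (1 + 1/M) B with W the mean within-imputation variance
    (zero here, as per-fit covariance is not propagated — the between-
    imputation term is what multiple imputation adds) and B the
    between-imputation variance. Returns pooled natural-scale parameters,
    pooled transition matrix/initial distribution, and working-scale
    means/variances.

    All fits must share the spec and the canonical dive-rate state
    ordering; misaligned fits raise ``ValueError``.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 imputation fits to pool")
    spec = fits[0].spec
    bad = []
    for i, f in enumerate(fits):
        if f.spec != spec:
            raise ValueError(f"fit {i} has a different spec")
        order = _canonical_order(spec, f.emissions)
        if not np.array_equal(order, np.arange(spec.n_states)):
            bad.append(i)
    if bad:
        raise ValueError(f"state labels misaligned (dive-rate ordering differs) in fits: {bad}")
    thetas = np.stack([f.theta() for f in fits])
    M = thetas.shape[0]
    qbar = thetas.mean(axis=0)
    between = thetas.var(axis=0, ddof=1)
    within = np.zeros_like(qbar)
    total_var = within + (1.0 + 1.0 / M) * between
    emissions, tpm, delta = _unpack(spec, qbar)
    return {
        "emissions": emissions,
        "tpm": tpm,
        "delta": delta,
        "theta_mean": qbar,
        "theta_total_var": total_var,
        "between_var": between,
        "within_var": within,
        "n_imputations": M,
        "mean_loglik": float(np.mean([f.loglik for f in fits])),
    }


def rubin_pool(estimates: np.ndarray, variances: np.ndarray) -> tuple[float, float]:
    """Classic Rubin's rules for scalar estimates with within variances.

    Returns (pooled estimate, total variance) where total = W + (1+1/M) B.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    M = q.size
    qbar = q.mean()
    w = u.mean()
    b = q.var(ddof=1) if M > 1 else 0.0
    return float(qbar), float(w + (1.0 + 1.0 / M) * b)
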