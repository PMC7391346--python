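import numpy as np
import pandas as pd
import pytest

from moveseg.synthetic_data import SimConfig, simulate_dataset, truth_records


@pytest.fixture(scope="session")
def small_dataset():
    """Three animals x 120 intervals with all four streams and bathymetry."""
    return simulate_dataset(SimConfig(n_animals=3, n_intervals=120, seed=5))


@pytest.fixture(scope="session")
def small_truth_records(small_dataset):
    return truth_records(small_dataset)


def exhaustive_hmm_likelihood(logB: np.ndarray, tpm: np.ndarray, delta: np.ndarray) -> float:
    """Brute-force likelihood: sum over every state path (oracle for the forward pass)."""
    import itertools

    T, N = logB.shape
    total = 0.0
    for path in itertools.product(range(N), repeat=T):
        p = delta[path[0]] * np.exp(logB[0, path[0]])
        for t in range(1, T):
            p *= tpm[path[t - 1], path[t]] * np.exp(logB[t, path[t]])
        total += p
    return float(np.log(total))


def exhaustive_viterbi(logB: np.ndarray, tpm: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Brute-force MAP path with ties broken toward the lexicographically smallest path."""
    import itertools

    T, N = logB.shape
    best, best_path = -np.inf, None
    with np.errstate(divide="ignore"):
        lg, ld = np.log(tpm), np.log(delta)
    for path in itertools.product(range(N), repeat=T):
        lp = ld[path[0]] + logB[0, path[0]]
        for t in range(1, T):
            lp += lg[path[t - 1], path[t]] + logB[t, path[t]]
        if lp > best:  # itertools yields lexicographic order; strict > keeps the smallest
            best, best_path = lp, path
    return np.array(best_path)


def exhaustive_posteriors(logB: np.ndarray, tpm: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Brute-force per-interval marginal state probabilities."""
    import itertools

    T, N = logB.shape
    post = np.zeros((T, N))
    for path in itertools.product(range(N), repeat=T):
        p = delta[path[0]] * np.exp(logB[0, path[0]])
        for t in range(1, T):
            p *= tpm[path[t - 1], path[t]] * np.exp(logB[t, path[t]])
        for t, s in enumerate(path):
            post[t, s] += p
    return post / post.sum(axis=1, keepdims=True)


def joint_gaussian_ctcrw_loglik(beta, sigma, times_h, obs, obs_cov):
    """CTCRW observation log-density via explicit joint-Gaussian construction.

    Builds the full joint covariance of all observed positions from the
    state-transition recursions (no Kalman filtering) — the brute-force
    oracle for the prediction-error likelihood.
    """
    from scipy.stats import multivariate_normal

    from moveseg.regularization import _H, _transition4, default_prior

    n = len(times_h)
    m0, P0 = default_prior(beta, sigma, obs[0, 0], obs[0, 1])
    means = [m0]
    cov = {(0, 0): P0}
    for i in range(1, n):
        Phi, Q = _transition4(beta, sigma, times_h[i] - times_h[i - 1])
        means.append(Phi @ means[-1])
        cov[(i, i)] = Phi @ cov[(i - 1, i - 1)] @ Phi.T + Q
        for j in range(i):
            cov[(j, i)] = cov[(j, i - 1)] @ Phi.T
    mu = np.concatenate([_H @ m for m in means])
    S = np.zeros((2 * n, 2 * n))
    for i in range(n):
        for j in range(n):
            P = cov[(i, j)] if i <= j else cov[(j, i)].T
            S[2 * i : 2 * i + 2, 2 * j : 2 * j + 2] = _H @ P @ _H.T
        S[2 * i : 2 * i + 2, 2 * i : 2 * i + 2] += obs_cov[i]
    return float(multivariate_normal.logpdf(obs.ravel(), mu, S))


def random_hmm_instance(rng, n_states=None, t_max=None):
    """A random small HMM instance (logB, tpm, delta) with N^T <= 1e5."""
    N = int(n_states or rng.integers(2, 5))
    T_cap = int(np.floor(np.log(1e5) / np.log(N)))
    T = int(t_max or rng.integers(3, T_cap + 1))
    tpm = rng.dirichlet(np.ones(N), size=N)
    delta = rng.dirichlet(np.ones(N))
    logB = rng.normal(-1.0, 1.5, size=(T, N))
    return logB, tpm, delta
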