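import numpy as np
import pandas as pd
import pytest

from conftest import joint_gaussian_ctcrw_loglik
from moveseg import geo
from moveseg.regularization import (
    CTCRWParams,
    _fixes_to_arrays,
    _transition4,
    ctcrw_loglik,
    default_prior,
    draw_imputations,
    ellipse_to_cov,
    fit_ctcrw,
    predict_regular,
)


# ---------------------------------------------------------------------------
# ellipse -> covariance


def test_isotropic_ellipse_any_orientation():
    for theta in (0.0, 37.0, 121.5):
        cov = ellipse_to_cov(100.0, 100.0, theta)
        assert np.allclose(cov, np.diag([1e4, 1e4]), atol=1e-6)


def test_axis_aligned_ellipse():
    cov = ellipse_to_cov(200.0, 100.0, 0.0)
    assert np.allclose(cov, np.diag([4e4, 1e4]), atol=1e-8)


def test_rotated_ellipse_eigenvalues_recover_axes():
    M, m, theta = 5000.0, 1200.0, 30.0
    cov = ellipse_to_cov(M, m, theta)
    w, v = np.linalg.eigh(cov)
    assert np.sqrt(w[-1]) == pytest.approx(M, rel=1e-12)
    assert np.sqrt(w[0]) == pytest.approx(m, rel=1e-12)
    # principal axis at theta from east
    ang = np.degrees(np.arctan2(v[1, -1], v[0, -1])) % 180.0
    assert ang == pytest.approx(theta, abs=1e-9)
    assert np.allclose(cov, cov.T)


def test_minor_exceeding_major_rejected():
    with pytest.raises(ValueError):
        ellipse_to_cov(100.0, 200.0, 0.0)


def test_orientation_from_north_convention():
    cov_east = ellipse_to_cov(200.0, 100.0, 0.0)
    cov_north = ellipse_to_cov(200.0, 100.0, 90.0, orientation_from_north=True)
    assert np.allclose(cov_east, cov_north, atol=1e-8)


# ---------------------------------------------------------------------------
# Kalman likelihood vs joint-Gaussian oracle


def _toy_fixes(n=4, err_km=0.5, seed=0):
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0, 24, n)) * 3600.0
    x = np.cumsum(rng.normal(0, 3, n))
    y = np.cumsum(rng.normal(0, 3, n))
    lon, lat = geo.unproject_aeqd(x, y)
    return pd.DataFrame(
        {
            "animal_id": "a",
            "time": t,
            "lon": lon,
            "lat": lat,
            "semi_major_m": err_km * 1000,
            "semi_minor_m": err_km * 1000 * 0.5,
            "orientation_deg": 42.0,
        }
    )


@pytest.mark.parametrize("n,seed", [(3, 0), (4, 1), (4, 2)])
def test_filter_likelihood_equals_joint_gaussian(n, seed):
    fixes = _toy_fixes(n=n, seed=seed)
    th, obs, cov = _fixes_to_arrays(fixes, geo.STUDY_CENTER_LON, geo.STUDY_CENTER_LAT)
    for beta, sigma in [(0.5, 2.0), (0.1, 0.7), (2.0, 5.0)]:
        got = ctcrw_loglik(beta, sigma, th, obs, cov)
        want = joint_gaussian_ctcrw_loglik(beta, sigma, th, obs, cov)
        assert got == pytest.approx(want, rel=1e-8)


def simulate_ctcrw_fixes(beta, sigma, n, err_km, seed, mean_gap_h=1.5):
    rng = np.random.default_rng(seed)
    times = np.cumsum(rng.exponential(mean_gap_h, n))
    state = np.zeros(4)
    xs = np.empty((n, 2))
    for i in range(n):
        if i > 0:
            Phi, Q = _transition4(beta, sigma, times[i] - times[i - 1])
            state = Phi @ state + np.linalg.cholesky(Q + 1e-15 * np.eye(4)) @ rng.standard_normal(4)
        xs[i] = state[[0, 2]]
    obs = xs + rng.normal(0, err_km, xs.shape)
    lon, lat = geo.unproject_aeqd(obs[:, 0], obs[:, 1])
    return (
        pd.DataFrame(
            {
                "animal_id": "a",
                "time": times * 3600.0,
                "lon": lon,
                "lat": lat,
                "semi_major_m": err_km * 1000,
                "semi_minor_m": err_km * 1000,
                "orientation_deg": 0.0,
            }
        ),
        xs,
        times,
    )


@pytest.fixture(scope="module")
def recovered():
    fixes, _, _ = simulate_ctcrw_fixes(0.5, 2.0, 2000, 1.0, seed=7)
    return fit_ctcrw(fixes)


def test_ctcrw_parameter_recovery(recovered):
    """beta = 0.5/h, sigma = 2.0 recovered within 15% at 2,000 fixes."""
    assert recovered.beta == pytest.approx(0.5, rel=0.15)
    assert recovered.sigma == pytest.approx(2.0, rel=0.15)


def test_loglik_degrades_with_added_noise(recovered):
    fixes, _, _ = simulate_ctcrw_fixes(0.5, 2.0, 300, 1.0, seed=8)
    th, obs, cov = _fixes_to_arrays(fixes, geo.STUDY_CENTER_LON, geo.STUDY_CENTER_LAT)
    base = ctcrw_loglik(recovered.beta, recovered.sigma, th, obs, cov)
    rng = np.random.default_rng(9)
    noisy = obs + rng.normal(0, 5.0, obs.shape)
    worse = ctcrw_loglik(recovered.beta, recovered.sigma, th, noisy, cov)
    assert np.isfinite(base) and np.isfinite(worse)
    assert worse < base


def test_translation_invariance_of_filter():
    fixes, _, _ = simulate_ctcrw_fixes(0.5, 2.0, 100, 1.0, seed=10)
    th, obs, cov = _fixes_to_arrays(fixes, geo.STUDY_CENTER_LON, geo.STUDY_CENTER_LAT)
    m0, P0 = default_prior(0.5, 2.0, obs[0, 0], obs[0, 1])
    base = ctcrw_loglik(0.5, 2.0, th, obs, cov)
    shift = np.array([123.4, -77.7])
    m0s, _ = default_prior(0.5, 2.0, obs[0, 0] + shift[0], obs[0, 1] + shift[1])
    shifted = ctcrw_loglik(0.5, 2.0, th, obs + shift, cov, m0s, P0)
    assert shifted == pytest.approx(base, abs=1e-9 * abs(base) + 1e-9)


def test_too_few_fixes_rejected():
    fixes = _toy_fixes(n=4)
    with pytest.raises(ValueError, match="at least 10"):
        fit_ctcrw(fixes)


# ---------------------------------------------------------------------------
# smoothing on the regular grid


def test_zero_error_dense_fixes_pass_through():
    fixes, xs, times = simulate_ctcrw_fixes(0.5, 2.0, 200, 1e-6, seed=11, mean_gap_h=2.0)
    m0, P0 = default_prior(0.5, 2.0, xs[0, 0], xs[0, 1])
    params = CTCRWParams(beta=0.5, sigma=2.0, mean0=m0, cov0=P0)
    tr = predict_regular(params, fixes, interval_h=6.0)
    # at grid times close to a fix the smoothed mean must be that fix (no error)
    for i in np.random.default_rng(0).integers(0, len(fixes), 20):
        t_h = fixes["time"].iloc[i] / 3600.0
        j = np.argmin(np.abs(tr.times / 3600.0 - t_h))
        if abs(tr.times[j] / 3600.0 - t_h) < 1e-9:
            assert tr.x_km[j] == pytest.approx(xs[i, 0], abs=1e-3)


def test_grid_spacing_and_anchor():
    fixes, _, _ = simulate_ctcrw_fixes(0.5, 2.0, 100, 1.0, seed=12)
    params = fit_ctcrw(fixes)
    tr = predict_regular(params, fixes, interval_h=6.0)
    dt = np.diff(tr.times)
    assert np.allclose(dt, 6 * 3600.0, atol=1e-6)
    assert tr.times[0] == pytest.approx(fixes["time"].iloc[0], abs=1e-6)


def test_smoother_variance_higher_at_observation_gaps():
    fixes, _, _ = simulate_ctcrw_fixes(0.4, 1.5, 60, 0.5, seed=13, mean_gap_h=5.0)
    params = fit_ctcrw(fixes)
    tr = predict_regular(params, fixes, interval_h=6.0)
    var = tr.cov_km2[:, 0, 0] + tr.cov_km2[:, 1, 1]
    ft = fixes["time"].to_numpy()
    near = np.min(np.abs(tr.times[:, None] - ft[None, :]), axis=1) / 3600.0
    # mean variance at far-from-fix grid points exceeds that near fixes
    assert var[near > 2.0].mean() > var[near < 0.5].mean()
    for P in tr.cov_km2:
        assert np.linalg.eigvalsh(P).min() > -1e-9  # PSD


def test_smoother_matches_conditional_gaussian_on_toy_problem():
    """RTS smoothed means equal the explicit joint-Gaussian conditional mean."""
    fixes = _toy_fixes(n=4, seed=3)
    th, obs, cov = _fixes_to_arrays(fixes, geo.STUDY_CENTER_LON, geo.STUDY_CENTER_LAT)
    beta, sigma = 0.6, 1.8
    m0, P0 = default_prior(beta, sigma, obs[0, 0], obs[0, 1])
    from moveseg.regularization import kalman_filter, rts_smoother

    ll, mf, Pf, mp, Pp = kalman_filter(beta, sigma, th, obs, cov, m0, P0)
    ms, _ = rts_smoother(beta, sigma, th, mf, Pf, mp, Pp)
    # explicit conditional: states s ~ N(mu_s, S_ss), y = H s + e
    n = len(th)
    means = [m0]
    C = {(0, 0): P0}
    for i in range(1, n):
        Phi, Q = _transition4(beta, sigma, th[i] - th[i - 1])
        means.append(Phi @ means[-1])
        C[(i, i)] = Phi @ C[(i - 1, i - 1)] @ Phi.T + Q
        for j in range(i):
            C[(j, i)] = C[(j, i - 1)] @ Phi.T
    H = np.array([[1.0, 0, 0, 0], [0, 0, 1.0, 0]])
    mu_s = np.concatenate(means)
    S_ss = np.zeros((4 * n, 4 * n))
    for i in range(n):
        for j in range(n):
            P = C[(i, j)] if i <= j else C[(j, i)].T
            S_ss[4 * i : 4 * i + 4, 4 * j : 4 * j + 4] = P
    Hbig = np.zeros((2 * n, 4 * n))
    R = np.zeros((2 * n, 2 * n))
    for i in range(n):
        Hbig[2 * i : 2 * i + 2, 4 * i : 4 * i + 4] = H
        R[2 * i : 2 * i + 2, 2 * i : 2 * i + 2] = cov[i]
    S_yy = Hbig @ S_ss @ Hbig.T + R
    S_sy = S_ss @ Hbig.T
    mu_y = Hbig @ mu_s
    cond = mu_s + S_sy @ np.linalg.solve(S_yy, obs.ravel() - mu_y)
    assert np.allclose(ms.ravel(), cond, rtol=1e-8, atol=1e-8)


# ---------------------------------------------------------------------------
# multiple imputation draws


@pytest.fixture(scope="module")
def imputation_setup():
    fixes, _, _ = simulate_ctcrw_fixes(0.5, 2.0, 150, 1.0, seed=14, mean_gap_h=2.0)
    params = fit_ctcrw(fixes)
    tr = predict_regular(params, fixes, interval_h=6.0)
    imps = draw_imputations(params, fixes, n_sims=500, seed=21, interval_h=6.0)
    return tr, imps


def test_imputation_ensemble_mean_matches_smoother(imputation_setup):
    tr, imps = imputation_setup
    mean = imps.draws.mean(axis=0)
    sd = imps.draws.std(axis=0) / np.sqrt(imps.draws.shape[0])
    for j, coord in enumerate([tr.x_km, tr.y_km]):
        diff = np.abs(mean[:, j] - coord)
        # within 2 Monte-Carlo SEs at 95%+ of grid points, no gross outliers
        frac = np.mean(diff <= 2.0 * np.maximum(sd[:, j], 1e-12))
        assert frac >= 0.9
        assert np.all(diff <= 6.0 * np.maximum(sd[:, j], 1e-12))


def test_imputation_ensemble_covariance_matches_smoother(imputation_setup):
    tr, imps = imputation_setup
    T = imps.draws.shape[1]
    errs = []
    for t in range(T):
        emp = np.cov(imps.draws[:, t, :].T)
        ref = tr.cov_km2[t]
        errs.append(np.linalg.norm(emp - ref) / max(np.linalg.norm(ref), 1e-12))
    assert np.median(errs) < 0.25  # Frobenius, 500 draws


def test_imputations_reproducible_from_seed(imputation_setup):
    tr, imps = imputation_setup
    fixes, _, _ = simulate_ctcrw_fixes(0.5, 2.0, 150, 1.0, seed=14, mean_gap_h=2.0)
    params = fit_ctcrw(fixes)
    again = draw_imputations(params, fixes, n_sims=5, seed=21, interval_h=6.0)
    np.testing.assert_allclose(again.draws, imps.draws[:5], rtol=1e-12)
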