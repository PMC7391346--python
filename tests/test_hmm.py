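import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import (
    exhaustive_hmm_likelihood,
    exhaustive_posteriors,
    exhaustive_viterbi,
    random_hmm_instance,
)
from moveseg import hmm
from moveseg.hmm import (
    HMMFit,
    HMMSpec,
    StreamSpec,
    fit_hmm,
    forward_loglik,
    gamma_moments_to_shape_scale,
    gamma_shape_scale_to_moments,
    kappa_from_circular_sd,
    local_state_probs,
    pool_mi_fits,
    pseudo_residuals,
    rubin_pool,
    viterbi,
)
from moveseg.hmm import _forward_kernel, _log_emissions


def _toy_records(rng, T=6, animal="a"):
    return pd.DataFrame(
        {
            "animal_id": animal,
            "time": np.arange(T) * 21600.0,
            "step_km": rng.gamma(4.0, 2.0, T),
            "turn_rad": np.r_[np.nan, rng.vonmises(0.0, 1.0, T - 1)],
            "n_dives": rng.poisson(3.0, T).astype(float),
        }
    )


def _toy_params(N):
    return {
        "step_km": {"mean": np.linspace(8.0, 4.0, N), "sd": np.linspace(3.0, 1.5, N)},
        "turn_rad": {"mean": np.zeros(N), "kappa": np.linspace(0.8, 0.3, N)},
        "n_dives": {"rate": np.linspace(1.5, 14.0, N)},
    }


# ---------------------------------------------------------------------------
# parameter bridges


def test_gamma_exponential_case():
    assert gamma_moments_to_shape_scale(1.0, 1.0) == (1.0, 1.0)


def test_gamma_study_value_round_trip():
    shape, scale = gamma_moments_to_shape_scale(8.152, 3.27)
    assert shape == pytest.approx(6.215, abs=0.002)
    assert scale == pytest.approx(1.3116, abs=0.002)
    m, s = gamma_shape_scale_to_moments(shape, scale)
    assert m == pytest.approx(8.152, rel=1e-12)
    assert s == pytest.approx(3.27, rel=1e-12)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(mean=st.floats(0.01, 100), sd=st.floats(0.01, 50))
def test_gamma_moment_identities(mean, sd):
    shape, scale = gamma_moments_to_shape_scale(mean, sd)
    assert shape * scale == pytest.approx(mean, rel=1e-12)
    assert shape * scale**2 == pytest.approx(sd**2, rel=1e-12)


def test_gamma_nonpositive_rejected():
    with pytest.raises(ValueError):
        gamma_moments_to_shape_scale(-1.0, 1.0)


def test_kappa_circular_sd_round_trip():
    for sd in (0.5, 1.4, 1.85, 1.91):
        k = kappa_from_circular_sd(sd)
        assert hmm.circular_sd_from_kappa(k) == pytest.approx(sd, rel=1e-6)
    # more directional persistence (smaller circular SD) -> larger concentration
    assert kappa_from_circular_sd(1.4) > kappa_from_circular_sd(1.85) > kappa_from_circular_sd(1.91)


# ---------------------------------------------------------------------------
# forward algorithm / decoding vs exhaustive oracles


@pytest.mark.parametrize("seed", range(8))
def test_forward_equals_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    logB, tpm, delta = random_hmm_instance(rng)
    starts = np.array([0, logB.shape[0]], dtype=np.int64)
    got = _forward_kernel(logB, tpm, delta, starts)
    want = exhaustive_hmm_likelihood(logB, tpm, delta)
    assert got == pytest.approx(want, rel=1e-10)


@pytest.mark.parametrize("seed", range(5))
def test_viterbi_equals_exhaustive_argmax(seed):
    rng = np.random.default_rng(100 + seed)
    logB, tpm, delta = random_hmm_instance(rng, n_states=2, t_max=6)
    from moveseg.hmm import _viterbi_kernel

    starts = np.array([0, logB.shape[0]], dtype=np.int64)
    with np.errstate(divide="ignore"):
        got = _viterbi_kernel(logB, np.log(tpm), np.log(delta), starts)
    want = exhaustive_viterbi(logB, tpm, delta)
    np.testing.assert_array_equal(got, want)


def test_forward_public_api_matches_enumeration_on_streams():
    """Toy 6-interval record, N = 2: forward equals the brute-force path sum."""
    rng = np.random.default_rng(0)
    rec = _toy_records(rng, T=6)
    spec = HMMSpec(n_states=2, state_labels=("a", "b"))
    params = _toy_params(2)
    tpm = np.array([[0.9, 0.1], [0.2, 0.8]])
    delta = np.array([0.6, 0.4])
    got = forward_loglik(spec, params, tpm, delta, rec)
    obs, _ = hmm.prepare_records(rec, spec)
    logB = _log_emissions(spec, params, obs)
    want = exhaustive_hmm_likelihood(logB, tpm, delta)
    assert got == pytest.approx(want, rel=1e-10)


def test_local_probs_match_enumeration_and_sum_to_one():
    rng = np.random.default_rng(1)
    rec = _toy_records(rng, T=6)
    spec = HMMSpec(n_states=2, state_labels=("a", "b"))
    params = _toy_params(2)
    fit = HMMFit(spec=spec, emissions=params, tpm=np.array([[0.9, 0.1], [0.2, 0.8]]),
                 delta=np.array([0.6, 0.4]), loglik=0.0, n_obs=6)
    seq = local_state_probs(fit, rec)
    assert np.allclose(seq.local_probs.sum(axis=1), 1.0, atol=1e-10)
    obs, _ = hmm.prepare_records(rec, spec)
    logB = _log_emissions(spec, params, obs)
    want = exhaustive_posteriors(logB, fit.tpm, fit.delta)
    assert np.allclose(seq.local_probs, want, atol=1e-10)
    assert np.allclose(seq.merged_diving_prob, seq.local_probs[:, 1:].sum(axis=1))


def test_single_state_degenerates_to_independent_densities():
    rng = np.random.default_rng(2)
    rec = _toy_records(rng, T=20)
    spec = HMMSpec(n_states=1, state_labels=("only",))
    params = {
        "step_km": {"mean": np.array([5.0]), "sd": np.array([2.0])},
        "turn_rad": {"mean": np.array([0.0]), "kappa": np.array([0.7])},
        "n_dives": {"rate": np.array([3.0])},
    }
    got = forward_loglik(spec, params, np.ones((1, 1)), np.ones(1), rec)
    x = rec["step_km"].to_numpy()
    t = rec["turn_rad"].to_numpy()
    d = rec["n_dives"].to_numpy()
    shape, scale = gamma_moments_to_shape_scale(5.0, 2.0)
    want = (
        stats.gamma.logpdf(x, a=shape, scale=scale).sum()
        + stats.vonmises.logpdf(t[1:], kappa=0.7).sum()
        + stats.poisson.logpmf(d.astype(int), 3.0).sum()
    )
    assert got == pytest.approx(want, rel=1e-10)
    seq = local_state_probs(
        HMMFit(spec=spec, emissions=params, tpm=np.ones((1, 1)), delta=np.ones(1),
               loglik=got, n_obs=20), rec)
    assert np.allclose(seq.local_probs, 1.0)


def test_state_permutation_leaves_likelihood_unchanged():
    rng = np.random.default_rng(3)
    rec = _toy_records(rng, T=30)
    spec = HMMSpec(n_states=3)
    params = _toy_params(3)
    tpm = np.array([[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]])
    delta = np.array([0.5, 0.3, 0.2])
    base = forward_loglik(spec, params, tpm, delta, rec)
    perm = np.array([2, 0, 1])
    params_p = {n: {k: v[perm] for k, v in p.items()} for n, p in params.items()}
    got = forward_loglik(spec, params_p, tpm[np.ix_(perm, perm)], delta[perm], rec)
    assert got == pytest.approx(base, rel=1e-12)


def test_identity_tpm_viterbi_constant_path():
    rng = np.random.default_rng(4)
    rec = _toy_records(rng, T=10)
    spec = HMMSpec(n_states=2, state_labels=("a", "b"))
    fit = HMMFit(spec=spec, emissions=_toy_params(2), tpm=np.eye(2),
                 delta=np.array([0.5, 0.5]), loglik=0.0, n_obs=10)
    path = viterbi(fit, rec)
    assert len(np.unique(path)) == 1


# ---------------------------------------------------------------------------
# fitting


@pytest.fixture(scope="module")
def fitted_small():
    """A light 3-state fit on 3 x 150 true-emission records."""
    from moveseg.synthetic_data import SimConfig, simulate_dataset, truth_records

    ds = simulate_dataset(SimConfig(n_animals=3, n_intervals=150, seed=31))
    rec = truth_records(ds)
    fit = fit_hmm(HMMSpec(), rec, n_starts=4, seed=8)
    return fit, rec


def test_fit_recovers_canonical_dive_ordering(fitted_small):
    fit, _ = fitted_small
    rates = fit.emissions["n_dives"]["rate"]
    assert (np.diff(rates) > 0).all()  # relabeled by ascending dive rate
    assert rates[0] == pytest.approx(1.6, rel=0.25)
    assert rates[2] == pytest.approx(14.12, rel=0.15)


def test_refit_from_optimum_is_fixed_point(fitted_small):
    fit, rec = fitted_small
    refit = fit_hmm(HMMSpec(), rec, n_starts=1, seed=9,
                    init={"emissions": fit.emissions, "tpm": fit.tpm, "delta": fit.delta})
    assert refit.loglik == pytest.approx(fit.loglik, rel=1e-7)


def test_aic_identity_and_row_sums(fitted_small):
    fit, _ = fitted_small
    assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.spec.n_free_params, abs=1e-9)
    assert np.allclose(fit.tpm.sum(axis=1), 1.0, atol=1e-10)
    assert fit.delta.sum() == pytest.approx(1.0, abs=1e-10)


def test_three_state_model_preferred_on_three_state_data():
    """AIC selects N = 3 over N = 2 on data with three distinct dive regimes."""
    from moveseg.synthetic_data import SimConfig, simulate_dataset, truth_records

    wins = 0
    n_rep = 5
    for rep in range(n_rep):
        ds = simulate_dataset(SimConfig(n_animals=2, n_intervals=150, seed=500 + rep))
        rec = truth_records(ds)
        f3 = fit_hmm(HMMSpec(), rec, n_starts=3, seed=rep)
        f2 = fit_hmm(HMMSpec(n_states=2, state_labels=("a", "b")), rec, n_starts=3, seed=rep)
        if f3.aic < f2.aic:
            wins += 1
    assert wins == n_rep


def test_zero_steps_replaced_with_warning():
    rng = np.random.default_rng(5)
    rec = _toy_records(rng, T=10)
    rec.loc[3, "step_km"] = 0.0
    spec = HMMSpec(n_states=2, state_labels=("a", "b"))
    with pytest.warns(UserWarning, match="zero step"):
        obs, _ = hmm.prepare_records(rec, spec)
    positive = rec["step_km"][rec["step_km"] > 0]
    assert obs[3, 0] == pytest.approx(0.5 * positive.min())


def test_optional_extra_stream_extends_model():
    """Adding a normal temperature stream adds 2N parameters and a finite loglik."""
    rng = np.random.default_rng(6)
    rec = _toy_records(rng, T=40)
    rec["temp_median_C"] = rng.normal(19.0, 2.0, 40)
    rec.loc[5:8, "temp_median_C"] = np.nan  # intervals without dives
    base_spec = HMMSpec(n_states=3)
    ext_spec = HMMSpec(
        n_states=3,
        streams=base_spec.streams + (StreamSpec("temp_median_C", "normal"),),
    )
    assert ext_spec.n_free_params == base_spec.n_free_params + 6
    params = _toy_params(3)
    params["temp_median_C"] = {"mean": np.array([18.0, 19.0, 20.0]), "sd": np.ones(3)}
    tpm = np.array([[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]])
    delta = np.array([1 / 3, 1 / 3, 1 / 3])
    ll_ext = forward_loglik(ext_spec, params, tpm, delta, rec)
    ll_base = forward_loglik(base_spec, {k: params[k] for k in ("step_km", "turn_rad", "n_dives")},
                             tpm, delta, rec)
    assert np.isfinite(ll_ext)
    assert ll_ext < ll_base  # the extra stream contributes negative log-density mass


# ---------------------------------------------------------------------------
# pseudo-residuals


def test_poisson_mid_p_residual_closed_form():
    lam, x = 3.7, 5
    fit = HMMFit(
        spec=HMMSpec(n_states=1, streams=(StreamSpec("n_dives", "poisson"),), state_labels=("s",)),
        emissions={"n_dives": {"rate": np.array([lam])}},
        tpm=np.ones((1, 1)), delta=np.ones(1), loglik=0.0, n_obs=1,
    )
    rec = pd.DataFrame({"animal_id": ["a"], "time": [0.0], "n_dives": [float(x)]})
    r = pseudo_residuals(fit, rec)["n_dives"].iloc[0]
    want = stats.norm.ppf(stats.poisson.cdf(x - 1, lam) + 0.5 * stats.poisson.pmf(x, lam))
    assert r == pytest.approx(want, abs=1e-12)


def test_residuals_calibrated_under_true_model(fitted_small):
    """Data simulated from (approximately) the fitted model give white residuals."""
    fit, rec = fitted_small
    res = pseudo_residuals(fit, rec)
    n = len(rec)
    for name in ("step_km", "n_dives"):
        diag = hmm.residual_diagnostics(res[name])
        assert not diag["degenerate"]
        assert np.abs(diag["acf"][0]) < 2.0 / np.sqrt(n) + 0.05


def test_constant_stream_degenerate_flagged():
    r = pd.Series(np.zeros(50))
    diag = hmm.residual_diagnostics(r)
    assert diag["degenerate"]
    assert np.isnan(diag["jb_stat"])


# ---------------------------------------------------------------------------
# multiple-imputation pooling


def test_rubin_hand_example_exact():
    # M = 2 fits: estimates 1.0 and 2.0 with within-variances 0.3 and 0.5
    q, tv = rubin_pool([1.0, 2.0], [0.3, 0.5])
    # qbar = 1.5; W = 0.4; B = 0.5; total = 0.4 + 1.5 * 0.5 = 1.15
    assert q == pytest.approx(1.5, abs=1e-12)
    assert tv == pytest.approx(1.15, abs=1e-12)


def test_pooling_identical_fits_has_zero_between_variance(fitted_small):
    fit, _ = fitted_small
    import copy

    pooled = pool_mi_fits([fit, copy.deepcopy(fit)])
    assert np.allclose(pooled["between_var"], 0.0, atol=1e-16)
    assert np.allclose(pooled["tpm"], fit.tpm, atol=1e-10)
    for name, p in pooled["emissions"].items():
        for k, v in p.items():
            assert np.allclose(v, fit.emissions[name][k], atol=1e-8)


def test_pooling_rejects_misaligned_labels(fitted_small):
    fit, _ = fitted_small
    import copy

    bad = copy.deepcopy(fit)
    # scramble the canonical dive ordering
    bad.emissions["n_dives"]["rate"] = bad.emissions["n_dives"]["rate"][::-1].copy()
    with pytest.raises(ValueError, match="misaligned"):
        pool_mi_fits([fit, bad])


def test_pooling_needs_at_least_two(fitted_small):
    fit, _ = fitted_small
    with pytest.raises(ValueError):
        pool_mi_fits([fit])
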