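"""EM estimation: E-step conditional means, M-step score roots, full fits,
and agreement with direct numerical likelihood maximization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maxerlb import (
    EMConfig,
    MaxErlBParams,
    direct_mle,
    em_fit,
    estep,
    estep_generic,
    mstep,
    observed_loglik,
    sample_maxerlb,
)
from maxerlb.em import _lam_score, _p_score, _solve_p


# ---------------------------------------------------------------- loglik

def test_loglik_single_point(params_ref):
    # density at x=0.2 is ~2.8094, so the log-likelihood is its log
    assert observed_loglik(np.array([0.2]), params_ref) == pytest.approx(
        math.log(2.80939838), abs=1e-6
    )


def test_loglik_matches_expanded_form(params_em):
    # k=2, n=3 expansion:
    # m[ln3 + ln p + 2 ln lam] - lam sum x - m ln(1-(1-p)^3)
    #   + sum[ln x + 2 ln(1 - p e^{-lam x}(1 + lam x))]
    rng = np.random.default_rng(3)
    x = rng.exponential(1.5, size=200)
    lam, p, m = params_em.lam, params_em.p, x.size
    s = np.exp(-lam * x) * (1 + lam * x)
    expanded = (
        m * (math.log(3) + math.log(p) + 2 * math.log(lam))
        - lam * x.sum()
        - m * math.log(1 - (1 - p) ** 3)
        + np.sum(np.log(x) + 2 * np.log(1 - p * s))
    )
    assert observed_loglik(x, params_em) == pytest.approx(expanded, abs=1e-10)


def test_loglik_additive_in_observations(params_ref):
    x = np.array([0.1, 0.3, 0.3])
    base = observed_loglik(x[:2], params_ref)
    assert observed_loglik(x, params_ref) == pytest.approx(
        base + observed_loglik(x[2:], params_ref), abs=1e-12
    )


def test_loglik_n1_reduces_to_erlang():
    params = MaxErlBParams(k=2, lam=3.0, n=1, p=0.4)
    x = np.array([0.2, 0.5, 1.1])
    erlang_ll = np.sum(2 * np.log(3.0) + np.log(x) - 3.0 * x)  # (k-1)! = 1
    assert observed_loglik(x, params) == pytest.approx(float(erlang_ll), abs=1e-12)


def test_loglik_rejects_nonpositive(params_ref):
    with pytest.raises(ValueError):
        observed_loglik(np.array([0.5, 0.0]), params_ref)


# ----------------------------------------------------------------- estep

def test_estep_reference_value():
    params = MaxErlBParams(k=2, lam=1.0, n=3, p=0.5)
    z = estep(np.array([1.0]), params)
    assert z[0] == pytest.approx(1.4180233, abs=1e-6)


def test_estep_limits(params_em):
    z_small = estep(np.array([1e-9]), params_em)
    assert z_small[0] == pytest.approx(1.0, abs=1e-9)
    z_large = estep(np.array([100.0]), params_em)
    assert z_large[0] == pytest.approx(1 + 2 * params_em.p, abs=1e-9)


def test_estep_bounds_and_monotonicity(params_em):
    x = np.linspace(0.01, 20, 400)
    z = estep(x, params_em)
    assert np.all(z >= 1.0) and np.all(z <= params_em.n)
    assert np.all(np.diff(z) > 0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    k=st.integers(1, 4),
    n=st.integers(2, 8),
    lam=st.floats(0.2, 15.0),
    p=st.floats(0.05, 0.95),
    x=st.floats(1e-3, 30.0),
)
def test_estep_specialized_equals_generic(k, n, lam, p, x):
    params = MaxErlBParams(k=k, lam=lam, n=n, p=p)
    xs = np.array([x])
    assert estep(xs, params)[0] == pytest.approx(
        estep_generic(xs, params)[0], abs=1e-12, rel=1e-12
    )


# ----------------------------------------------------------------- mstep

def test_lam_score_root_reduces_to_erlang_mle_when_z_is_one():
    # all z_j = 1: the rate score is k m / lam - sum x, root lam = k / xbar
    rng = np.random.default_rng(10)
    x = rng.gamma(2.0, 0.5, size=500)
    z = np.ones_like(x)
    lam_hat = 2.0 / x.mean()
    assert _lam_score(lam_hat, x, z, 2) == pytest.approx(0.0, abs=1e-8 * x.size)


def test_p_root_solves_truncated_binomial_moment_equation():
    # n=3, mean latent count 1.5: 3p/(1-(1-p)^3) = 1.5 at p = 0.381966
    p_hat = _solve_p(1.5, 3, xtol=1e-14)
    assert p_hat == pytest.approx(0.3819660, abs=1e-6)
    # grid-search oracle on the complete-data likelihood in p
    z_bar, m = 1.5, 1
    grid = np.linspace(1e-4, 1 - 1e-4, 200_001)
    ll = (
        z_bar * np.log(grid)
        + (3 - z_bar) * np.log(1 - grid)
        - np.log(1 - (1 - grid) ** 3)
    )
    assert grid[np.argmax(ll)] == pytest.approx(p_hat, abs=1e-4)
    # the raw printed score vanishes at the root
    assert _p_score(p_hat, z_sum=1.5, m=1, n=3) == pytest.approx(0.0, abs=1e-10)


def test_mstep_returns_score_roots(params_em):
    sample = sample_maxerlb(params_em, 5000, seed=44)
    z = estep(sample, params_em)
    lam_new, p_new = mstep(sample, z, params_em)
    assert _lam_score(lam_new, sample.values, z, 2) == pytest.approx(0.0, abs=1e-6)
    assert _p_score(p_new, z_sum=float(z.sum()), m=len(sample), n=3) == pytest.approx(
        0.0, abs=1e-6
    )


def test_mstep_degenerate_latent_mean(params_em):
    x = np.array([0.5, 1.0, 2.0])
    with pytest.raises(ValueError, match="degenerate"):
        mstep(x, np.ones(3), params_em)


def test_mstep_shape_mismatch(params_em):
    with pytest.raises(ValueError):
        mstep(np.array([1.0, 2.0]), np.array([1.5]), params_em)


# ---------------------------------------------------------------- em_fit

def test_em_fit_recovers_parameters(params_em):
    sample = sample_maxerlb(params_em, 100_000, seed=3)
    fit = em_fit(sample, EMConfig())
    assert fit.converged
    assert abs(fit.lam - 1.0) < 0.02
    assert abs(fit.p - 0.5) < 0.02
    assert 10 < fit.iterations < 1000


def test_em_fit_is_a_fixed_point(params_em):
    sample = sample_maxerlb(params_em, 20_000, seed=5)
    fit = em_fit(sample, EMConfig())
    refit = em_fit(sample, EMConfig(lam0=fit.lam, p0=fit.p))
    assert refit.iterations <= 3
    assert abs(refit.lam - fit.lam) < 1e-4
    assert abs(refit.p - fit.p) < 1e-4


def test_em_loglik_ascends(params_em):
    for seed in range(20):
        sample = sample_maxerlb(params_em, 2000, seed=600 + seed)
        fit = em_fit(sample, EMConfig(epsilon=1e-5))
        ll = np.array(fit.trace.loglik)
        assert np.all(np.diff(ll) >= -1e-8), f"descent at seed {seed}"


def test_em_agrees_with_direct_mle(params_em):
    sample = sample_maxerlb(params_em, 10_000, seed=77)
    fit = em_fit(sample, EMConfig(epsilon=1e-8))
    lam_d, p_d = direct_mle(sample)
    assert abs(fit.lam - lam_d) < 1e-3
    assert abs(fit.p - p_d) < 1e-3


def test_direct_mle_multistart_agrees(params_em):
    sample = sample_maxerlb(params_em, 10_000, seed=78)
    ref = direct_mle(sample)
    for f_lam, f_p in [(0.5, 0.6), (1.5, 0.4), (0.7, 1.4)]:
        alt = direct_mle(sample, init=(ref[0] * f_lam, min(0.9, 0.5 * f_p)))
        assert abs(alt[0] - ref[0]) < 1e-3
        assert abs(alt[1] - ref[1]) < 1e-3


def test_direct_mle_n1_flags_unidentified_p():
    x = np.array([0.3, 0.8, 1.4, 0.9])
    with pytest.warns(UserWarning, match="unidentified"):
        lam_hat, p_hat = direct_mle(x, k=2, n=1)
    assert lam_hat == pytest.approx(2.0 / x.mean(), abs=1e-12)
    assert math.isnan(p_hat)


def test_em_recovery_is_unbiased_across_seeds(params_em):
    lams, ps = [], []
    for seed in range(12):
        sample = sample_maxerlb(params_em, 20_000, seed=900 + seed)
        fit = em_fit(sample, EMConfig(epsilon=1e-5))
        lams.append(fit.lam)
        ps.append(fit.p)
    assert abs(np.mean(lams) - 1.0) < 0.01
    assert abs(np.mean(ps) - 0.5) < 0.01


def test_em_nonconvergence_is_reported_not_raised(params_em):
    sample = sample_maxerlb(params_em, 5000, seed=91)
    fit = em_fit(sample, EMConfig(max_iter=3))
    assert not fit.converged
    assert fit.iterations == 3


def test_em_config_validation():
    with pytest.raises(ValueError):
        EMConfig(lam0=-1.0)
    with pytest.raises(ValueError):
        EMConfig(p0=1.0)
    with pytest.raises(ValueError):
        EMConfig(epsilon=0.0)
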