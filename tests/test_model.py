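"""Kernel, NB2 likelihood and joint-density checks against independent math."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats

from isogp import (
    DesignMatrix,
    PriorConfig,
    build_kernel,
    joint_log_density,
    linear_predictor,
    nb_logpmf,
    prior_kernel_curves,
    tune_rhosq_upper,
)


# ---------------------------------------------------------------------------
# kernel
# ---------------------------------------------------------------------------
@pytest.mark.parametrize(
    "igg, eta_sq, rho_sq, expected_offdiag",
    [
        ([5, 5], 2.0, 3.0, 2.0),  # zero distance -> maximum covariance
        ([0, 1], 1.0, 2.0, np.exp(-1.0)),
        ([10, 110], 1.0, 0.01, np.exp(-50.0)),  # distant cells decorrelate
    ],
)
def test_kernel_closed_form_pairs(igg, eta_sq, rho_sq, expected_offdiag):
    k = build_kernel(np.array(igg), eta_sq, rho_sq, jitter=0.0)
    assert k.K[0, 1] == pytest.approx(expected_offdiag, rel=1e-12, abs=1e-300)
    assert k.K[0, 1] == k.K[1, 0]
    assert np.allclose(np.diag(k.K), eta_sq)


def test_kernel_matches_closed_form_on_grid():
    rng = np.random.default_rng(0)
    igg = rng.integers(0, 60, size=25)
    for eta_sq, rho_sq in [(0.5, 0.0), (2.0, 0.004), (3.7, 1.0)]:
        k = build_kernel(igg, eta_sq, rho_sq, jitter=0.0)
        d = igg[:, None].astype(float) - igg[None, :].astype(float)
        # duplicated counts make the raw kernel singular; the constructor
        # then bumps the diagonal, recorded in k.jitter
        expected = eta_sq * np.exp(-(rho_sq / 2.0) * d * d) + k.jitter * np.eye(igg.size)
        assert np.max(np.abs(k.K - expected)) < 1e-12


def test_kernel_flat_at_rho_zero():
    k = build_kernel(np.array([3, 9, 40]), 1.5, 0.0, jitter=1e-8)
    off = k.K[~np.eye(3, dtype=bool)]
    assert np.allclose(off, 1.5)
    assert np.allclose(np.diag(k.K), 1.5 + 1e-8)


@given(st.lists(st.integers(0, 200), min_size=3, max_size=12), st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_kernel_exchangeable_and_monotone(igg_list, perm_seed):
    igg = np.array(igg_list)
    kern = build_kernel(igg, 2.0, 0.01, jitter=0.0)
    k = kern.K
    # permuting cells permutes K identically
    perm = np.random.default_rng(perm_seed).permutation(igg.size)
    k_perm = build_kernel(igg[perm], 2.0, 0.01, jitter=kern.jitter).K
    assert np.allclose(k[np.ix_(perm, perm)], k_perm)
    # covariance is non-increasing in distance (jitter removed from diagonal)
    base = k - kern.jitter * np.eye(igg.size)
    d = np.abs(igg[:, None] - igg[None, :]).ravel()
    order = np.argsort(d, kind="stable")
    assert np.all(np.diff(base.ravel()[order]) <= 1e-12)


def test_kernel_rejects_bad_parameters():
    igg = np.array([1, 2, 3])
    with pytest.raises(ValueError, match="eta_sq"):
        build_kernel(igg, -1.0, 0.1)
    with pytest.raises(ValueError, match="finite"):
        build_kernel(igg, np.nan, 0.1)
    with pytest.raises(ValueError, match="rho_sq"):
        build_kernel(igg, 1.0, -0.5)
    with pytest.raises(ValueError):
        build_kernel(np.array([4]), 1.0, 0.1)


def test_kernel_jitter_doubling_and_failure_message():
    # duplicated isotype counts make the un-jittered kernel exactly singular
    igg = np.array([7, 7, 7, 7])
    k = build_kernel(igg, 1.0, 0.0, jitter=0.0)
    assert k.jitter > 0  # doubling kicked in starting from the default scale
    np.linalg.cholesky(k.K)
    with pytest.raises(np.linalg.LinAlgError, match="jitter"):
        build_kernel(igg, 1.0, 0.0, jitter=1e-300, max_jitter_doublings=0)


def test_tuned_rho_upper_bound_closed_form():
    igg = np.array([0, 10])
    # single pair at distance 10: hi solves exp(-hi/2 * 100) = 0.01
    hi = tune_rhosq_upper(igg, target_corr=0.01, distance_quantile=0.9)
    assert hi == pytest.approx(2 * np.log(100) / 100.0, rel=1e-12)


def test_prior_kernel_curves_shapes_and_limits():
    priors = PriorConfig(rhosq_lo=0.0, rhosq_hi=0.0)
    d = np.linspace(0, 50, 11)
    curves = prior_kernel_curves(priors, d, n_curves=8, seed=1)
    assert curves.shape == (8, 11)
    # rho_sq pinned at 0 -> every curve is flat at its eta_sq draw
    assert np.allclose(curves, curves[:, :1])
    assert np.all(curves > 0)


# ---------------------------------------------------------------------------
# linear predictor
# ---------------------------------------------------------------------------
def test_linear_predictor_intercept_and_levels():
    n = 4
    d0 = DesignMatrix.intercept_only(n)
    assert np.allclose(linear_predictor(d0, 3.0, None, np.zeros(n)), 3.0)

    d1 = DesignMatrix.from_codes(n, T=np.array([1, 1, 2, 2]))
    eta = linear_predictor(d1, 2.0, {"T": np.array([0.0, 0.5])}, np.zeros(n))
    assert np.allclose(eta, [2.0, 2.0, 2.5, 2.5])

    eta2 = linear_predictor(d0, 0.0, None, np.array([0.1, -0.1, 0.0, 0.2]))
    assert np.allclose(eta2, [0.1, -0.1, 0.0, 0.2])


def test_linear_predictor_design_mismatch():
    d1 = DesignMatrix.from_codes(4, T=np.array([1, 1, 2, 2]))
    with pytest.raises(ValueError, match="design mismatch"):
        linear_predictor(d1, 0.0, {"T": np.array([0.0])}, np.zeros(4))
    with pytest.raises(ValueError, match="missing coefficients"):
        linear_predictor(d1, 0.0, {}, np.zeros(4))


# ---------------------------------------------------------------------------
# NB2 log pmf
# ---------------------------------------------------------------------------
def _nb2_logpmf_reference(y, mu, phi):
    """Independent log-gamma-function implementation of the NB2 pmf."""
    return (
        special.gammaln(y + phi)
        - special.gammaln(phi)
        - special.gammaln(y + 1)
        + phi * (np.log(phi) - np.log(phi + mu))
        + y * (np.log(mu) - np.log(phi + mu))
    )


def test_nb_logpmf_normalizes():
    y = np.arange(10_001)
    total = np.exp(nb_logpmf(y, 20.0, 5.0)).sum()
    assert abs(total - 1.0) < 1e-10


def test_nb_logpmf_matches_loggamma_reference_on_grid():
    ys = np.array([0, 1, 2, 7, 50, 400])
    for mu in (0.3, 5.0, 200.0):
        for phi in (0.2, 1.0, 40.0):
            ours = nb_logpmf(ys, mu, phi)
            ref = _nb2_logpmf_reference(ys, mu, phi)
            assert np.max(np.abs(ours - ref)) < 1e-10


def test_nb_logpmf_zero_closed_form():
    for mu, phi in [(20.0, 5.0), (200.0, 1.0), (3.0, 0.4)]:
        assert nb_logpmf(0, mu, phi) == pytest.approx(
            phi * (np.log(phi) - np.log(phi + mu)), rel=1e-12
        )


def test_nb2_moments_by_monte_carlo():
    # Gamma-Poisson mixture draws as the independent sampling oracle
    rng = np.random.default_rng(2024)
    n = 1_000_000
    mu, phi = 200.0, 1.0
    draws = rng.poisson(mu * rng.gamma(phi, 1.0 / phi, size=n))
    mean, var = draws.mean(), draws.var()
    se_mean = draws.std() / np.sqrt(n)
    m2 = draws.astype(float) - mean
    se_var = np.sqrt((np.mean(m2**4) - var**2) / n)
    assert abs(mean - 200.0) < 3 * se_mean
    assert abs(var - (200.0 + 200.0**2 / 1.0)) < 3 * se_var


def test_nb_logpmf_domain_errors():
    with pytest.raises(ValueError):
        nb_logpmf(-1, 5.0, 1.0)
    with pytest.raises(ValueError):
        nb_logpmf(1.5, 5.0, 1.0)
    with pytest.raises(ValueError):
        nb_logpmf(1, -5.0, 1.0)


# ---------------------------------------------------------------------------
# joint log density
# ---------------------------------------------------------------------------
def _joint_reference(protein, igg, design, params, priors, jitter):
    """Brute-force sum of the separately coded prior, MVN and NB2 terms."""
    lp = stats.gamma.logpdf(params["mu0"], priors.mu0_shape, scale=1 / priors.mu0_rate)
    lp += stats.gamma.logpdf(params["phi"], priors.phi_shape, scale=1 / priors.phi_rate)
    a = -priors.etasq_loc / priors.etasq_scale
    lp += stats.truncnorm.logpdf(
        params["eta_sq"], a, np.inf, loc=priors.etasq_loc, scale=priors.etasq_scale
    )
    lp += stats.uniform.logpdf(
        params["rho_sq"], priors.rhosq_lo, priors.rhosq_hi - priors.rhosq_lo
    )
    for coef in (params.get("betas") or {}).values():
        lp += stats.norm.logpdf(np.asarray(coef)[1:], priors.beta_loc, priors.beta_scale).sum()
    d = np.subtract.outer(igg.astype(float), igg.astype(float))
    K = params["eta_sq"] * np.exp(-(params["rho_sq"] / 2) * d * d)
    K += jitter * np.eye(len(igg))
    lp += stats.multivariate_normal.logpdf(params["gamma"], cov=K)
    eta = params["mu0"] + np.asarray(params["gamma"], float)
    for k, name in enumerate(design.covariate_names):
        eta = eta + np.asarray(params["betas"][name])[design.codes()[:, k] - 1]
    lp += stats.nbinom.logpmf(
        protein, params["phi"], params["phi"] / (params["phi"] + np.exp(eta))
    ).sum()
    return float(lp)


def _toy_instance(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(3, 6)
    protein = rng.integers(0, 120, n)
    igg = rng.integers(0, 40, n)
    codes = rng.integers(1, 3, n)
    codes[:2] = [1, 2]  # both levels occupied
    design = DesignMatrix.from_codes(n, T=codes)
    priors = PriorConfig(rhosq_hi=0.05)
    params = {
        "mu0": float(rng.gamma(7, 0.5)),
        "phi": float(rng.gamma(2, 1)) + 0.2,
        "eta_sq": float(rng.uniform(0.5, 3)),
        "rho_sq": float(rng.uniform(0, 0.05)),
        "betas": {"T": np.array([0.0, rng.normal()])},
        "gamma": rng.normal(0, 0.3, n),
    }
    return protein, igg, design, params, priors


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_joint_log_density_equals_bruteforce_sum(seed):
    protein, igg, design, params, priors = _toy_instance(seed)
    jitter = 1e-6 * params["eta_sq"]
    ours = joint_log_density(protein, igg, design, params, priors, jitter=jitter)
    ref = _joint_reference(protein, igg, design, params, priors, jitter)
    assert ours == pytest.approx(ref, rel=1e-9, abs=1e-8)


def test_joint_log_density_outside_rho_support():
    protein, igg, design, params, priors = _toy_instance(0)
    params["rho_sq"] = priors.rhosq_hi + 1.0
    assert joint_log_density(protein, igg, design, params, priors) == -np.inf


def test_joint_log_density_gamma_zero_reduces_to_mvn_constant():
    protein, igg, design, params, priors = _toy_instance(1)
    params["gamma"] = np.zeros(len(igg))
    ours = joint_log_density(protein, igg, design, params, priors, jitter=1e-9)
    # at the origin the MVN term is exactly its log-normalizing constant:
    # subtracting it must leave prior + likelihood only
    d = np.subtract.outer(igg.astype(float), igg.astype(float))
    K = params["eta_sq"] * np.exp(-(params["rho_sq"] / 2) * d * d) + 1e-9 * np.eye(len(igg))
    const = -0.5 * np.linalg.slogdet(2 * np.pi * K)[1]
    no_gamma = _joint_reference(protein, igg, design, params, priors, 1e-9) - const
    assert ours - const == pytest.approx(no_gamma, rel=1e-9)


def test_prior_config_validation_and_defaults():
    p = PriorConfig()
    assert (p.mu0_shape, p.mu0_rate) == (7.0, 2.0)
    assert (p.phi_shape, p.phi_rate) == (0.5, 0.5)
    assert (p.etasq_loc, p.etasq_scale) == (2.0, 1.0)
    assert (p.rhosq_lo, p.rhosq_hi) == (0.0, 5000.0)
    with pytest.raises(ValueError):
        PriorConfig(mu0_rate=0.0)
    with pytest.raises(ValueError):
        PriorConfig(rhosq_lo=2.0, rhosq_hi=1.0)
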