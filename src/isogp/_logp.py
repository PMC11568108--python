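"""Unconstrained-space joint log density and analytic gradient.

The sampler works on the transformed vector

    q = [a, b, c, r, beta_free..., z...]

with mu0 = e^a, phi = e^b, eta_sq = e^c, rho_sq = lo + (hi - lo) * sigmoid(r)
and the non-centered GP offset gamma = L z where L is the Cholesky factor of
the kernel matrix.  All log-Jacobians and normalizing constants are included,
so the value here equals the constrained-space joint density plus the
transform Jacobians plus log|det L| (the z -> gamma change of variables) —
an identity the test suite checks against the reference implementation.

Kernel-hyperparameter gradients differentiate through the Cholesky factor.
Because K is proportional to eta_sq, the eta_sq direction reduces to the
closed form (L^T grad_gamma) . z / 2; the rho_sq direction propagates
dK/drho_sq with a forward-mode pass fused into the factorization loop.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

LOG_2PI = math.log(2.0 * math.pi)


@njit(cache=True, fastmath=True)
def _digamma(x: float) -> float:
    """Digamma for x > 0 via upward recurrence + asymptotic series."""
    r = 0.0
    while x < 6.0:
        r -= 1.0 / x
        x += 1.0
    inv = 1.0 / x
    inv2 = inv * inv
    return r + math.log(x) - 0.5 * inv - inv2 * (
        1.0 / 12.0 - inv2 * (1.0 / 120.0 - inv2 / 252.0)
    )


@njit(cache=True, fastmath=True)
def _cholesky_lower(K):
    """In-place-free lower Cholesky; returns (L, ok)."""
    n = K.shape[0]
    L = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            s = K[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return L, False
                L[i, i] = math.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return L, True


@njit(cache=True, fastmath=True)
def _cholesky_with_direction(K, dK):
    """Lower Cholesky of K and its forward-mode differential along dK.

    Runs the standard factorization recurrence with the differentiated
    recurrence fused into the same inner loop; returns (L, dL, ok).
    """
    n = K.shape[0]
    L = np.zeros((n, n))
    dL = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            s = K[i, j]
            ds = dK[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
                ds -= dL[i, k] * L[j, k] + L[i, k] * dL[j, k]
            if i == j:
                if s <= 0.0:
                    return L, dL, False
                L[i, i] = math.sqrt(s)
                dL[i, i] = 0.5 * ds / L[i, i]
            else:
                L[i, j] = s / L[j, j]
                dL[i, j] = (ds - L[i, j] * dL[j, j]) / L[j, j]
    return L, dL, True


@njit(cache=True, fastmath=True)
def logp_and_grad(q, y, D, codes, n_levels, beta_off, pr):
    """Joint log density and gradient on the unconstrained scale.

    Parameters
    ----------
    q : parameter vector [a, b, c, r, beta_free (F), z (n)]
    y : observed protein counts (float64, length n)
    D : squared isotype-count distance matrix (n x n)
    codes : integer covariate level codes, (n, n_cov), levels 1..L_k
    n_levels : number of levels per covariate, (n_cov,)
    beta_off : cumulative offsets into the free-beta block, (n_cov + 1,);
        covariate k's free coefficients (levels 2..L_k) sit at
        beta_off[k] .. beta_off[k+1]-1
    pr : prior/hyper vector [mu0_shape, mu0_rate, phi_shape, phi_rate,
        etasq_loc, etasq_scale, rhosq_lo, rhosq_hi, beta_loc, beta_scale,
        jitter_scale]
    """
    n = y.size
    n_cov = codes.shape[1]
    F = beta_off[n_cov]
    grad = np.zeros_like(q)

    a = q[0]
    b = q[1]
    c = q[2]
    r = q[3]
    if abs(a) > 600.0 or abs(b) > 600.0 or abs(c) > 600.0 or abs(r) > 600.0:
        return -np.inf, grad
    mu0 = math.exp(a)
    phi = math.exp(b)
    eta2 = math.exp(c)
    rho_lo = pr[6]
    rho_hi = pr[7]
    rho_free = rho_hi > rho_lo
    s = 1.0 / (1.0 + math.exp(-r))
    rho2 = rho_lo + (rho_hi - rho_lo) * s if rho_free else rho_lo
    jitter_scale = pr[10]

    # ---- kernel and offset --------------------------------------------------
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = eta2 * math.exp(-0.5 * rho2 * D[i, j])
        K[i, i] += jitter_scale * eta2
    if rho_free:
        # direction dK/drho_sq = -(D/2) o K; D_ii = 0 keeps the jitter out
        dK = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                dK[i, j] = -0.5 * D[i, j] * K[i, j]
        L, dL, ok = _cholesky_with_direction(K, dK)
    else:
        dL = np.zeros((1, 1))
        L, ok = _cholesky_lower(K)
    if not ok:
        return -np.inf, grad

    z = q[4 + F:]
    gamma = L @ z

    # ---- linear predictor and NB2 likelihood --------------------------------
    theta = np.empty(n)
    for i in range(n):
        t = mu0 + gamma[i]
        for k in range(n_cov):
            lv = codes[i, k]
            if lv >= 2:
                t += q[4 + beta_off[k] + lv - 2]
        theta[i] = t
        if t > 500.0:
            return -np.inf, grad

    logp = 0.0
    g = np.empty(n)  # d loglik / d theta_i
    dphi = 0.0  # d loglik / d phi
    lgam_phi = math.lgamma(phi)
    dig_phi = _digamma(phi)
    log_phi = b
    for i in range(n):
        mu = math.exp(theta[i])
        yi = y[i]
        denom = phi + mu
        log_denom = math.log(denom)
        logp += (
            math.lgamma(yi + phi)
            - lgam_phi
            - math.lgamma(yi + 1.0)
            + phi * (log_phi - log_denom)
            + yi * (theta[i] - log_denom)
        )
        g[i] = yi - (yi + phi) * mu / denom
        dphi += _digamma(yi + phi) - dig_phi + log_phi + 1.0 - log_denom - (yi + phi) / denom

    # ---- priors (with transform Jacobians and constants) ---------------------
    # mu0 = e^a ~ Gamma(shape, rate)
    sh, rt = pr[0], pr[1]
    logp += sh * math.log(rt) - math.lgamma(sh) + sh * a - rt * mu0
    grad[0] = sh - rt * mu0
    # phi = e^b ~ Gamma
    sh, rt = pr[2], pr[3]
    logp += sh * math.log(rt) - math.lgamma(sh) + sh * b - rt * phi
    grad[1] = sh - rt * phi + dphi * phi
    # eta2 = e^c ~ Normal(loc, scale) truncated to (0, inf)
    loc, scale = pr[4], pr[5]
    zeta = (eta2 - loc) / scale
    # survival of the untruncated normal at 0
    tail = 0.5 * (1.0 + math.erf((loc / scale) / math.sqrt(2.0)))
    logp += -0.5 * zeta * zeta - math.log(scale) - 0.5 * LOG_2PI - math.log(tail) + c
    grad[2] = -zeta / scale * eta2 + 1.0
    # rho2 via scaled sigmoid ~ Uniform(lo, hi): density and Jacobian combine
    if rho_free:
        logp += math.log(s * (1.0 - s))
        grad[3] = 1.0 - 2.0 * s
    else:
        logp += -0.5 * r * r - 0.5 * LOG_2PI
        grad[3] = -r
    # free betas ~ Normal(beta_loc, beta_scale)
    b_loc, b_scale = pr[8], pr[9]
    for f in range(F):
        bf = q[4 + f]
        zb = (bf - b_loc) / b_scale
        logp += -0.5 * zb * zb - math.log(b_scale) - 0.5 * LOG_2PI
        grad[4 + f] = -zb / b_scale
    # z ~ Normal(0, I)
    for i in range(n):
        logp += -0.5 * z[i] * z[i]
    logp += -0.5 * n * LOG_2PI

    # ---- likelihood gradients ------------------------------------------------
    grad[0] += np.sum(g) * mu0
    for i in range(n):
        for k in range(n_cov):
            lv = codes[i, k]
            if lv >= 2:
                grad[4 + beta_off[k] + lv - 2] += g[i]
    u = L.T @ g
    for i in range(n):
        grad[4 + F + i] = u[i] - z[i]

    # eta_sq direction: dK/dc = K, so A = I and the trace term is u.z / 2
    grad[2] += 0.5 * float(np.dot(u, z))

    # rho_sq direction (only when the prior leaves it free)
    if rho_free:
        dgamma = dL @ z
        grad[3] += float(np.dot(g, dgamma)) * (rho_hi - rho_lo) * s * (1.0 - s)

    return logp, grad


@njit(cache=True, fastmath=True)
def _tri_inverse_lower(L):
    """Inverse of a lower-triangular matrix."""
    n = L.shape[0]
    X = np.zeros((n, n))
    for j in range(n):
        X[j, j] = 1.0 / L[j, j]
        for i in range(j + 1, n):
            s = 0.0
            for k in range(j, i):
                s -= L[i, k] * X[k, j]
            X[i, j] = s / L[i, i]
    return X


@njit(cache=True, fastmath=True)
def logp_and_grad_centered(q, y, D, codes, n_levels, beta_off, pr):
    """Joint log density and gradient, centered GP parameterization.

    Identical posterior to :func:`logp_and_grad` but the state carries the
    total per-cell log level gt_i = mu0 + gamma_i directly:

        q = [a, b, c, r, beta_free..., gt...],   gt ~ MVN(mu0 * 1, K)

    Two pathologies of the whitened form disappear at once in the
    data-rich regime (counts informative enough to pin each cell's level):
    the kernel hyperparameters decouple from the latent field, and the
    soft translation trade-off between the intercept and the mean of the
    offsets becomes a single well-behaved coordinate — mu0 is informed
    only through the GP prior mean, not the likelihood.
    """
    n = y.size
    n_cov = codes.shape[1]
    F = beta_off[n_cov]
    grad = np.zeros_like(q)

    a = q[0]
    b = q[1]
    c = q[2]
    r = q[3]
    if abs(a) > 600.0 or abs(b) > 600.0 or abs(c) > 600.0 or abs(r) > 600.0:
        return -np.inf, grad
    mu0 = math.exp(a)
    phi = math.exp(b)
    eta2 = math.exp(c)
    rho_lo = pr[6]
    rho_hi = pr[7]
    rho_free = rho_hi > rho_lo
    s = 1.0 / (1.0 + math.exp(-r))
    rho2 = rho_lo + (rho_hi - rho_lo) * s if rho_free else rho_lo
    jitter_scale = pr[10]

    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = eta2 * math.exp(-0.5 * rho2 * D[i, j])
        K[i, i] += jitter_scale * eta2
    L, ok = _cholesky_lower(K)
    if not ok:
        return -np.inf, grad

    gt = q[4 + F:]

    theta = np.empty(n)
    for i in range(n):
        theta[i] = gt[i]
        if gt[i] > 500.0:
            return -np.inf, grad

    logp = 0.0
    g = np.empty(n)  # d loglik / d theta_i
    dphi = 0.0
    lgam_phi = math.lgamma(phi)
    dig_phi = _digamma(phi)
    log_phi = b
    for i in range(n):
        mu = math.exp(theta[i])
        yi = y[i]
        denom = phi + mu
        log_denom = math.log(denom)
        logp += (
            math.lgamma(yi + phi)
            - lgam_phi
            - math.lgamma(yi + 1.0)
            + phi * (log_phi - log_denom)
            + yi * (theta[i] - log_denom)
        )
        g[i] = yi - (yi + phi) * mu / denom
        dphi += _digamma(yi + phi) - dig_phi + log_phi + 1.0 - log_denom - (yi + phi) / denom

    # priors on (a, b, c, r) and betas: same families as the whitened form
    sh, rt = pr[0], pr[1]
    logp += sh * math.log(rt) - math.lgamma(sh) + sh * a - rt * mu0
    grad[0] = sh - rt * mu0
    sh, rt = pr[2], pr[3]
    logp += sh * math.log(rt) - math.lgamma(sh) + sh * b - rt * phi
    grad[1] = sh - rt * phi + dphi * phi
    loc, scale = pr[4], pr[5]
    zeta = (eta2 - loc) / scale
    tail = 0.5 * (1.0 + math.erf((loc / scale) / math.sqrt(2.0)))
    logp += -0.5 * zeta * zeta - math.log(scale) - 0.5 * LOG_2PI - math.log(tail) + c
    grad[2] = -zeta / scale * eta2 + 1.0
    if rho_free:
        logp += math.log(s * (1.0 - s))
        grad[3] = 1.0 - 2.0 * s
    else:
        logp += -0.5 * r * r - 0.5 * LOG_2PI
        grad[3] = -r
    b_loc, b_scale = pr[8], pr[9]
    for f in range(F):
        bf = q[4 + f]
        zb = (bf - b_loc) / b_scale
        logp += -0.5 * zb * zb - math.log(b_scale) - 0.5 * LOG_2PI
        grad[4 + f] = -zb / b_scale

    # gt ~ MVN(mu0 * 1, K): density and gradients via v = K^-1 (gt - mu0)
    Linv = _tri_inverse_lower(L)
    gamma = np.empty(n)
    for i in range(n):
        m_i = mu0
        for k in range(n_cov):
            lv = codes[i, k]
            if lv >= 2:
                m_i += q[4 + beta_off[k] + lv - 2]
        gamma[i] = gt[i] - m_i
    # w = L^-1 gamma; quad = w.w; v = L^-T w
    w = np.zeros(n)
    for i in range(n):
        sacc = 0.0
        for k in range(i + 1):
            sacc += Linv[i, k] * gamma[k]
        w[i] = sacc
    quad = 0.0
    logdet = 0.0
    for i in range(n):
        quad += w[i] * w[i]
        logdet += math.log(L[i, i])
    logp += -0.5 * quad - logdet - 0.5 * n * LOG_2PI
    v = np.zeros(n)
    for i in range(n):
        sacc = 0.0
        for k in range(i, n):
            sacc += Linv[k, i] * w[k]
        v[i] = sacc

    # likelihood + MVN-mean gradients
    vsum = 0.0
    for i in range(n):
        vsum += v[i]
    grad[0] += mu0 * vsum
    for i in range(n):
        for k in range(n_cov):
            lv = codes[i, k]
            if lv >= 2:
                grad[4 + beta_off[k] + lv - 2] += v[i]
        grad[4 + F + i] = g[i] - v[i]

    # d/dc of the MVN term with dK/dc = K: quad/2 - n/2
    grad[2] += 0.5 * quad - 0.5 * n

    if rho_free:
        # dK/drho2 = -(D/2) o K (D_ii = 0); need
        #   0.5 * v' dK v - 0.5 * tr(K^-1 dK),  K^-1 = Linv' Linv
        Kinv = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1):
                sacc = 0.0
                kmin = i if i > j else j
                for k in range(kmin, n):
                    sacc += Linv[k, i] * Linv[k, j]
                Kinv[i, j] = sacc
                Kinv[j, i] = sacc
        quad_dir = 0.0
        tr_dir = 0.0
        for i in range(n):
            for j in range(n):
                dkij = -0.5 * D[i, j] * K[i, j]
                quad_dir += v[i] * dkij * v[j]
                tr_dir += Kinv[i, j] * dkij
        grad[3] += (0.5 * quad_dir - 0.5 * tr_dir) * (rho_hi - rho_lo) * s * (1.0 - s)

    return logp, grad
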