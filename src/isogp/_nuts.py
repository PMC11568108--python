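"""A compact No-U-Turn sampler with Stan-style windowed warmup.

Implements the efficient slice-variable NUTS tree (doubling trajectory with
the no-U-turn termination criterion), dual-averaging step-size adaptation
toward a target acceptance statistic, and mass-matrix estimation in
expanding memory windows.  The metric may be diagonal, dense, or — the
default — diagonal during warmup with a dense-clipped estimate installed in
the final window, which picks up residual linear correlations (a regression
coefficient trading off against a block of latents, say) once the chain
mixes well enough to measure them.  The target is supplied as a callable
returning ``(logp, grad)``; everything here is generic over models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

__all__ = ["sample_nuts", "ChainResult"]

MAX_DELTA_H = 1000.0  # divergence threshold on the Hamiltonian error


@dataclass
class ChainResult:
    draws: np.ndarray  # (n_sampling, dim), unconstrained
    divergences: int  # during sampling
    warmup_divergences: int
    step_size: float
    inv_metric: np.ndarray
    accept_stat: float  # mean over sampling iterations
    n_leapfrog: int


class _Metric:
    """Euclidean metric M; momenta ~ N(0, M), inv_metric estimates the
    posterior covariance.  Diagonal or dense."""

    def __init__(self, dim: int):
        self.dense = False
        self.inv_m = np.ones(dim)
        self._sqrt_m = np.ones(dim)

    def update(self, inv_m: np.ndarray) -> None:
        """Install a new inverse metric; 1-D arrays mean diagonal, 2-D dense."""
        self.dense = inv_m.ndim == 2
        self.inv_m = inv_m
        if self.dense:
            self._chol_inv = np.linalg.cholesky(inv_m)
        else:
            self._sqrt_m = 1.0 / np.sqrt(inv_m)

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        xi = rng.standard_normal(self.inv_m.shape[0])
        if self.dense:
            # p ~ N(0, inv_m^-1): with inv_m = C C^T, p = C^-T xi
            return sla.solve_triangular(self._chol_inv, xi, lower=True, trans="T",
                                        check_finite=False)
        return self._sqrt_m * xi

    def velocity(self, p: np.ndarray) -> np.ndarray:
        """inv_m @ p: dq/dt, also used by the U-turn criterion."""
        if self.dense:
            return self.inv_m @ p
        return self.inv_m * p

    def kinetic(self, p: np.ndarray) -> float:
        with np.errstate(over="ignore", invalid="ignore"):
            return 0.5 * float(np.dot(p, self.velocity(p)))


class _Tree:
    """State carried through the doubling recursion."""

    __slots__ = (
        "q_minus", "p_minus", "grad_minus", "q_plus", "p_plus", "grad_plus",
        "q_prop", "logp_prop", "grad_prop", "n", "s", "alpha", "n_alpha",
        "divergent", "n_leapfrog",
    )


def _leapfrog(logp_grad, q, p, grad, eps, metric):
    p_half = p + 0.5 * eps * grad
    q_new = q + eps * metric.velocity(p_half)
    logp_new, grad_new = logp_grad(q_new)
    p_new = p_half + 0.5 * eps * grad_new
    return q_new, p_new, logp_new, grad_new


def _no_uturn(q_plus, q_minus, p_plus, p_minus, metric):
    dq = q_plus - q_minus
    return (np.dot(dq, metric.velocity(p_minus)) >= 0.0) and (
        np.dot(dq, metric.velocity(p_plus)) >= 0.0
    )


def _build_tree(logp_grad, q, p, grad, log_u, v, j, eps, h0, metric, rng):
    if j == 0:
        q1, p1, logp1, grad1 = _leapfrog(logp_grad, q, p, grad, v * eps, metric)
        h1 = -logp1 + metric.kinetic(p1) if np.isfinite(logp1) else np.inf
        t = _Tree()
        t.q_minus = t.q_plus = q1
        t.p_minus = t.p_plus = p1
        t.grad_minus = t.grad_plus = grad1
        t.q_prop, t.logp_prop, t.grad_prop = q1, logp1, grad1
        t.n = 1 if log_u <= -h1 else 0
        t.divergent = (log_u - MAX_DELTA_H) > -h1
        t.s = 0 if t.divergent else 1
        t.alpha = np.exp(min(0.0, h0 - h1)) if np.isfinite(h1) else 0.0
        t.n_alpha = 1
        t.n_leapfrog = 1
        return t
    t = _build_tree(logp_grad, q, p, grad, log_u, v, j - 1, eps, h0, metric, rng)
    if t.s == 1:
        if v == -1:
            t2 = _build_tree(logp_grad, t.q_minus, t.p_minus, t.grad_minus,
                             log_u, v, j - 1, eps, h0, metric, rng)
            t.q_minus, t.p_minus, t.grad_minus = t2.q_minus, t2.p_minus, t2.grad_minus
        else:
            t2 = _build_tree(logp_grad, t.q_plus, t.p_plus, t.grad_plus,
                             log_u, v, j - 1, eps, h0, metric, rng)
            t.q_plus, t.p_plus, t.grad_plus = t2.q_plus, t2.p_plus, t2.grad_plus
        if t2.n > 0 and rng.uniform() < t2.n / max(t.n + t2.n, 1):
            t.q_prop, t.logp_prop, t.grad_prop = t2.q_prop, t2.logp_prop, t2.grad_prop
        t.alpha += t2.alpha
        t.n_alpha += t2.n_alpha
        t.n += t2.n
        t.divergent = t.divergent or t2.divergent
        t.s = t2.s if _no_uturn(t.q_plus, t.q_minus, t.p_plus, t.p_minus, metric) else 0
        t.n_leapfrog += t2.n_leapfrog
    return t


def _nuts_step(logp_grad, q, logp, grad, eps, metric, rng, max_treedepth):
    p0 = metric.sample_momentum(rng)
    h0 = -logp + metric.kinetic(p0)
    log_u = -h0 + np.log(rng.uniform())
    q_minus = q_plus = q
    p_minus = p_plus = p0
    grad_minus = grad_plus = grad
    q_new, logp_new, grad_new = q, logp, grad
    n, s, j = 1, 1, 0
    alpha_sum, n_alpha_sum, n_leapfrog, divergent = 0.0, 0, 0, False
    while s == 1 and j < max_treedepth:
        v = 1 if rng.uniform() < 0.5 else -1
        if v == -1:
            t = _build_tree(logp_grad, q_minus, p_minus, grad_minus,
                            log_u, v, j, eps, h0, metric, rng)
            q_minus, p_minus, grad_minus = t.q_minus, t.p_minus, t.grad_minus
        else:
            t = _build_tree(logp_grad, q_plus, p_plus, grad_plus,
                            log_u, v, j, eps, h0, metric, rng)
            q_plus, p_plus, grad_plus = t.q_plus, t.p_plus, t.grad_plus
        if t.s == 1 and t.n > 0 and rng.uniform() < min(1.0, t.n / n):
            q_new, logp_new, grad_new = t.q_prop, t.logp_prop, t.grad_prop
        alpha_sum += t.alpha
        n_alpha_sum += t.n_alpha
        n_leapfrog += t.n_leapfrog
        divergent = divergent or t.divergent
        n += t.n
        s = t.s if _no_uturn(q_plus, q_minus, p_plus, p_minus, metric) else 0
        j += 1
    accept_stat = alpha_sum / max(n_alpha_sum, 1)
    return q_new, logp_new, grad_new, accept_stat, divergent, n_leapfrog


def _find_reasonable_epsilon(logp_grad, q, logp, grad, metric, rng):
    eps = 1.0
    p = metric.sample_momentum(rng)
    h0 = -logp + metric.kinetic(p)
    _, p1, logp1, _ = _leapfrog(logp_grad, q, p, grad, eps, metric)
    h1 = -logp1 + metric.kinetic(p1) if np.isfinite(logp1) else np.inf
    direction = 1.0 if (h0 - h1) > np.log(0.5) else -1.0
    for _ in range(50):
        eps = eps * (2.0**direction)
        _, p1, logp1, _ = _leapfrog(logp_grad, q, p, grad, eps, metric)
        h1 = -logp1 + metric.kinetic(p1) if np.isfinite(logp1) else np.inf
        if direction * (h0 - h1) < direction * np.log(0.5):
            break
    return max(eps, 1e-10)


def _adaptation_windows(n_warmup):
    """(init_buffer, metric window boundaries, term_buffer) a la Stan."""
    if n_warmup < 20:
        return n_warmup, [], 0
    init_buffer, term_buffer, base = 75, 50, 25
    if init_buffer + term_buffer + base > n_warmup:
        init_buffer = int(0.15 * n_warmup)
        term_buffer = int(0.10 * n_warmup)
        base = n_warmup - init_buffer - term_buffer
    boundaries = []
    start = init_buffer
    size = base
    while True:
        end = start + size
        if end + 2 * size + term_buffer > n_warmup:
            end = n_warmup - term_buffer
            boundaries.append(end)
            break
        boundaries.append(end)
        start = end
        size *= 2
    return init_buffer, boundaries, term_buffer


class _DualAveraging:
    """Nesterov dual averaging of log step size (delta = target acceptance)."""

    def __init__(self, eps0, delta=0.8, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * eps0)
        self.delta, self.gamma, self.t0, self.kappa = delta, gamma, t0, kappa
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.m = 0

    def update(self, accept_stat):
        self.m += 1
        frac = 1.0 / (self.m + self.t0)
        self.h_bar = (1.0 - frac) * self.h_bar + frac * (self.delta - accept_stat)
        log_eps = self.mu - np.sqrt(self.m) / self.gamma * self.h_bar
        w = self.m ** (-self.kappa)
        self.log_eps_bar = w * log_eps + (1.0 - w) * self.log_eps_bar
        return np.exp(log_eps)

    @property
    def adapted(self):
        return np.exp(self.log_eps_bar)


def _regularized_cov(draws: np.ndarray, dense: bool):  # noqa: C901
    """Shrunk covariance (or variance) estimate of a warmup window.

    The dense estimate keeps marginal variances but clips the spectrum of
    the sample correlation matrix to the Marchenko-Pastur noise band: only
    eigen-directions whose eigenvalues rise above (or fall below) what pure
    sampling noise would produce are retained; the rest are reset to 1
    (i.e. treated as uncorrelated).  This captures genuine soft modes —
    such as an intercept trading off against the mean of a latent field —
    without letting a noisy high-dimensional covariance distort the
    well-behaved directions.
    """
    m, d = draws.shape
    shrink = m / (m + 5.0)
    prior_w = 1e-3 * (5.0 / (m + 5.0))
    var = np.maximum(shrink * np.var(draws, axis=0, ddof=1) + prior_w, 1e-10)
    if not dense or m < 10:
        return var
    sd = np.sqrt(var)
    x = (draws - draws.mean(axis=0)) / sd
    corr = (x.T @ x) / max(m - 1, 1)
    np.fill_diagonal(corr, 1.0)
    lam, vec = np.linalg.eigh(corr)
    ratio = d / m
    upper = (1.0 + np.sqrt(ratio)) ** 2
    lower = max((1.0 - np.sqrt(ratio)) ** 2, 1e-4)
    lam_clipped = np.where((lam > upper) | (lam < lower), lam, 1.0)
    lam_clipped = np.maximum(lam_clipped, 1e-6)
    corr_reg = (vec * lam_clipped) @ vec.T
    return (sd[:, None] * corr_reg) * sd[None, :]


def sample_nuts(
    logp_grad,
    init: np.ndarray,
    n_warmup: int,
    n_sampling: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    metric: str = "final",
    fixed_inv_metric: np.ndarray | None = None,
) -> ChainResult:
    """Run one chain; returns post-warmup draws and sampler statistics.

    ``metric`` selects the mass-matrix adaptation: ``"diag"`` (per-coordinate
    variances in every window), ``"dense"`` (regularized dense covariance in
    every window), or ``"final"`` — diagonal through warmup for robustness,
    switching to the dense-clipped estimate only in the last window, once the
    chain mixes well enough to measure cross-correlations.  Fully windowed
    ``"dense"`` adaptation can self-reinforce a mis-estimated correlation
    (a direction the metric underestimates mixes slowly and never corrects),
    so prefer ``"final"`` unless a good reason exists.  A fixed inverse
    metric disables adaptation entirely.
    """
    if metric not in ("diag", "dense", "final"):
        raise ValueError(f"unknown metric mode {metric!r}")
    q = np.asarray(init, dtype=float).copy()
    dim = q.size
    logp, grad = logp_grad(q)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")
    metric_mode = metric
    metric = _Metric(dim)
    if fixed_inv_metric is not None:
        metric.update(fixed_inv_metric)

    eps = _find_reasonable_epsilon(logp_grad, q, logp, grad, metric, rng)
    da = _DualAveraging(eps, delta=target_accept)
    init_buffer, boundaries, _ = _adaptation_windows(n_warmup)
    boundary_set = set(boundaries)

    warmup_div = 0
    total_leapfrog = 0
    window_draws: list[np.ndarray] = []
    for it in range(n_warmup):
        q, logp, grad, astat, div, nlf = _nuts_step(
            logp_grad, q, logp, grad, eps, metric, rng, max_treedepth
        )
        warmup_div += div
        total_leapfrog += nlf
        eps = da.update(astat)
        if fixed_inv_metric is None and it >= init_buffer and boundaries:
            window_draws.append(q)
            if (it + 1) in boundary_set:
                is_last = (it + 1) == boundaries[-1]
                dense = metric_mode == "dense" or (metric_mode == "final" and is_last)
                metric.update(_regularized_cov(np.asarray(window_draws), dense))
                window_draws.clear()
                # keep the current step size; restart its averaging around it
                da = _DualAveraging(eps, delta=target_accept)
    eps = da.adapted if n_warmup > 0 else eps

    draws = np.empty((n_sampling, dim))
    divergences = 0
    accept_sum = 0.0
    for it in range(n_sampling):
        q, logp, grad, astat, div, nlf = _nuts_step(
            logp_grad, q, logp, grad, eps, metric, rng, max_treedepth
        )
        divergences += div
        accept_sum += astat
        total_leapfrog += nlf
        draws[it] = q
    return ChainResult(
        draws=draws,
        divergences=divergences,
        warmup_divergences=warmup_div,
        step_size=float(eps),
        inv_metric=metric.inv_m,
        accept_stat=accept_sum / max(n_sampling, 1),
        n_leapfrog=total_leapfrog,
    )
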