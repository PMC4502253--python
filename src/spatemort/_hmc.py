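"""A small Hamiltonian Monte Carlo engine.

Static-trajectory HMC with a jittered number of leapfrog steps, dual-averaging
step-size adaptation towards a target acceptance rate, and a diagonal mass
matrix estimated from warmup draws.  The target density supplies its own
analytic gradient, so no autodiff dependency is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

#: energy error beyond which a trajectory is declared divergent
DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class HMCStats:
    accept_rate: float
    step_size: float
    n_divergent: int


def _leapfrog(
    logp_grad: LogpGrad,
    x: np.ndarray,
    p: np.ndarray,
    grad: np.ndarray,
    eps: float,
    n_steps: int,
    apply_inv_mass,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        x = x + eps * apply_inv_mass(p)
        lp, grad = logp_grad(x)
        if not np.isfinite(lp):
            return x, p, -np.inf, grad
        if step < n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return x, p, lp, grad


def _adaptation_windows(n_warmup: int) -> list[int]:
    """End indices of doubling mass-adaptation windows (Stan-style schedule).

    An initial fast phase (step size only), then windows of 25, 50, 100, ...
    iterations for variance estimation, and a terminal fast phase.
    """
    init_buffer = max(int(0.15 * n_warmup), 10)
    term_buffer = max(int(0.10 * n_warmup), 10)
    ends = []
    pos, size = init_buffer, 25
    while pos + size < n_warmup - term_buffer:
        if pos + 3 * size >= n_warmup - term_buffer:
            size = n_warmup - term_buffer - pos  # absorb the remainder
        ends.append(pos + size)
        pos += size
        size *= 2
    return ends


def hmc_sample(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.85,
    max_leapfrog: int = 32,
    init_step: float = 0.05,
    init_inv_mass: np.ndarray | None = None,
    mass_matrix: np.ndarray | None = None,
) -> tuple[np.ndarray, HMCStats]:
    """Sample ``n_draws`` post-warmup states of ``exp(logp)``.

    Either a diagonal inverse mass seed (``init_inv_mass``, refined from
    warmup draws over doubling windows) or a fixed dense ``mass_matrix``
    (e.g. the Fisher information at the start, which whitens the
    likelihood-induced correlations; no mass adaptation then) may be given.
    Returns a (n_draws, dim) array and sampler statistics.  Fully
    deterministic given ``rng``'s state.
    """
    x = np.array(x0, dtype=float)
    dim = x.size
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise FloatingPointError("non-finite log density at the initial point")

    dense = mass_matrix is not None
    if dense:
        mass_chol = np.linalg.cholesky(mass_matrix)
        inv_mass_mat = np.linalg.inv(mass_matrix)
        inv_mass_mat = 0.5 * (inv_mass_mat + inv_mass_mat.T)
        inv_mass = None
        sqrt_mass = None
    else:
        inv_mass = np.ones(dim) if init_inv_mass is None else np.asarray(init_inv_mass, float)
        sqrt_mass = 1.0 / np.sqrt(inv_mass)

    # dual averaging (step size) state
    log_eps = np.log(init_step)
    mu = np.log(10.0 * init_step)
    log_eps_bar, h_bar = 0.0, 0.0
    da_gamma, da_t0, da_kappa = 0.05, 10.0, 0.75
    da_count = 0

    window_ends = _adaptation_windows(n_warmup)
    window_start = window_ends[0] - 25 if window_ends else n_warmup
    mass_buf: list[np.ndarray] = []

    draws = np.empty((n_draws, dim))
    n_accept = 0.0
    n_divergent = 0

    if dense:
        def apply_inv_mass(p):
            return inv_mass_mat @ p

        def draw_momentum():
            return mass_chol @ rng.standard_normal(dim)

        def kinetic(p):
            return 0.5 * float(p @ (inv_mass_mat @ p))
    else:
        def apply_inv_mass(p):
            return inv_mass * p

        def draw_momentum():
            return rng.standard_normal(dim) * sqrt_mass

        def kinetic(p):
            return 0.5 * float(np.sum(inv_mass * p**2))

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        eps = np.exp(log_eps) if warming else np.exp(log_eps_bar)
        n_steps = int(rng.integers(1, max_leapfrog + 1))
        p0 = draw_momentum()
        h0 = -lp + kinetic(p0)
        x_new, p_new, lp_new, grad_new = _leapfrog(
            logp_grad, x, p0, grad, eps, n_steps, apply_inv_mass
        )
        if np.isfinite(lp_new):
            h1 = -lp_new + kinetic(p_new)
            delta_h = h0 - h1
        else:
            delta_h = -np.inf
        if not np.isfinite(delta_h) or -delta_h > DIVERGENCE_THRESHOLD:
            accept_prob = 0.0
            n_divergent += int(not warming)
        else:
            accept_prob = min(1.0, float(np.exp(min(delta_h, 0.0))))
        if rng.uniform() < accept_prob:
            x, lp, grad = x_new, lp_new, grad_new

        if warming:
            da_count += 1
            frac = 1.0 / (da_count + da_t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - accept_prob)
            log_eps = mu - np.sqrt(da_count) / da_gamma * h_bar
            weight = da_count ** (-da_kappa)
            log_eps_bar = weight * log_eps + (1.0 - weight) * log_eps_bar
            if not dense and it >= window_start:
                mass_buf.append(x.copy())
            if not dense and window_ends and it == window_ends[0] - 1:
                window_ends.pop(0)
                if len(mass_buf) >= 10:
                    arr = np.asarray(mass_buf)
                    var = arr.var(axis=0, ddof=1)
                    n = arr.shape[0]
                    # Stan-style shrinkage of the variance estimate
                    new_inv = (n / (n + 5.0)) * var + (5.0 / (n + 5.0)) * 1e-3
                    inv_mass = np.maximum(new_inv, 1e-12)
                    sqrt_mass = 1.0 / np.sqrt(inv_mass)
                    # restart step-size adaptation around the current step
                    mu = np.log(10.0) + log_eps
                    h_bar, da_count = 0.0, 0
                mass_buf = []
        else:
            n_accept += accept_prob
            draws[it - n_warmup] = x

    stats = HMCStats(
        accept_rate=float(n_accept / max(n_draws, 1)),
        step_size=float(np.exp(log_eps_bar)),
        n_divergent=n_divergent,
    )
    return draws, stats
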