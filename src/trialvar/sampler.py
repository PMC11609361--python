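"""Adaptive Hamiltonian Monte Carlo on a differentiable log posterior.

Static-trajectory HMC with the two adaptations that matter in practice:

* dual-averaging step-size tuning toward a target acceptance statistic
  (Nesterov primal averaging, the standard schedule), and
* a diagonal mass matrix (inverse metric = marginal posterior variances)
  estimated over an expanding-window warmup schedule, Stan-style: an initial
  fast interval for step size only, doubling slow windows for the metric, and
  a terminal fast interval.

The number of leapfrog steps is chosen as (trajectory length / step size),
jittered uniformly over [0.5 L, L] to avoid resonances. Proposals whose energy
error exceeds 1000 are counted as divergences and rejected.

The contract is posterior correctness, not a named algorithm; the suite checks
this sampler against conjugate posteriors and closed-form estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["HMCStats", "hmc_sample"]

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class HMCStats:
    """Per-chain sampler diagnostics."""

    accept_rate: float
    step_size: float
    n_divergent: int
    energy: np.ndarray  # per kept draw


def _find_initial_step(
    logp_grad: LogpGrad, q: np.ndarray, inv_mass: np.ndarray, rng: np.random.Generator
) -> float:
    """Double/halve the step size until the one-step acceptance crosses 1/2."""
    eps = 0.1
    lp, grad = logp_grad(q)
    p = rng.standard_normal(q.size) / np.sqrt(inv_mass)

    def energy_error(eps: float) -> float:
        p1 = p + 0.5 * eps * grad
        q1 = q + eps * inv_mass * p1
        lp1, grad1 = logp_grad(q1)
        p1 = p1 + 0.5 * eps * grad1
        if not np.isfinite(lp1):
            return -np.inf
        h0 = -lp + 0.5 * np.sum(inv_mass * p * p)
        h1 = -lp1 + 0.5 * np.sum(inv_mass * p1 * p1)
        return h0 - h1  # log acceptance probability

    direction = 1 if energy_error(eps) > np.log(0.5) else -1
    for _ in range(50):
        trial = eps * (2.0 if direction == 1 else 0.5)
        if direction == 1 and energy_error(trial) <= np.log(0.5):
            break
        if direction == -1 and energy_error(trial) > np.log(0.5):
            eps = trial
            break
        eps = trial
    return float(np.clip(eps, 1e-8, 10.0))


def _warmup_schedule(n_warmup: int) -> tuple[int, int, list[tuple[int, int]]]:
    """Stan-like (init_fast, term_fast, slow windows) split of the warmup."""
    if n_warmup < 20:
        return n_warmup, 0, []
    init = max(10, int(0.15 * n_warmup))
    term = max(10, int(0.10 * n_warmup))
    slow_total = n_warmup - init - term
    windows = []
    start, width = init, max(10, int(0.25 * slow_total))
    while start < init + slow_total:
        end = min(start + width, init + slow_total)
        # absorb a too-small final window into the previous one
        if init + slow_total - end < 10:
            end = init + slow_total
        windows.append((start, end))
        start, width = end, width * 2
    return init, term, windows


def hmc_sample(
    logp_grad: LogpGrad,
    init: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    trajectory_length: float = 1.2,
    max_leapfrog: int = 256,
) -> tuple[np.ndarray, HMCStats]:
    """Run one adaptive HMC chain; returns (draws, stats).

    ``draws`` has shape (n_draws, dim) and contains only post-warmup states.
    """
    q = np.array(init, dtype=float)
    dim = q.size
    inv_mass = np.ones(dim)
    lp, grad = logp_grad(q)
    if not np.isfinite(lp):
        raise ValueError("non-finite log posterior at the initial point")

    eps = _find_initial_step(logp_grad, q, inv_mass, rng)
    # dual averaging state
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar, da_m = 0.0, 0.0, 0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    init_fast, term_fast, slow_windows = _warmup_schedule(n_warmup)
    window_ends = {end: start for start, end in slow_windows}
    welford_n, welford_mean, welford_m2 = 0, np.zeros(dim), np.zeros(dim)

    draws = np.empty((n_draws, dim))
    energies = np.empty(n_draws)
    n_divergent = 0
    n_accept, n_total = 0.0, 0

    total = n_warmup + n_draws
    for it in range(total):
        warming = it < n_warmup
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = -lp + 0.5 * np.sum(inv_mass * p0 * p0)

        n_steps = int(np.ceil(trajectory_length / eps))
        n_steps = max(1, min(max_leapfrog, n_steps))
        if n_steps > 1:
            n_steps = int(rng.integers((n_steps + 1) // 2, n_steps + 1))

        q_new, p_new, lp_new, grad_new = q, p0, lp, grad
        diverged = False
        p_new = p_new + 0.5 * eps * grad_new
        for step in range(n_steps):
            q_new = q_new + eps * inv_mass * p_new
            lp_new, grad_new = logp_grad(q_new)
            if not np.all(np.isfinite(grad_new)) or not np.isfinite(lp_new):
                diverged = True
                break
            if step < n_steps - 1:
                p_new = p_new + eps * grad_new
        if not diverged:
            p_new = p_new + 0.5 * eps * grad_new
            h1 = -lp_new + 0.5 * np.sum(inv_mass * p_new * p_new)
            delta_h = h0 - h1
            if not np.isfinite(delta_h) or delta_h < -1000.0:
                diverged = True
        if diverged:
            accept_prob = 0.0
            n_divergent += int(not warming)
        else:
            accept_prob = float(min(1.0, np.exp(min(0.0, delta_h))))
            if rng.random() < accept_prob:
                q, lp, grad = q_new, lp_new, grad_new

        if warming:
            # dual averaging (counter restarts with each metric update)
            da_m += 1
            h_bar = (1 - 1 / (da_m + t0)) * h_bar + (
                target_accept - accept_prob
            ) / (da_m + t0)
            log_eps = mu - np.sqrt(da_m) / gamma * h_bar
            w = da_m ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            # metric accumulation inside slow windows
            in_slow = any(s <= it < e for s, e in slow_windows)
            if in_slow:
                welford_n += 1
                delta = q - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (q - welford_mean)
            if (it + 1) in window_ends and welford_n > 2:
                var = welford_m2 / (welford_n - 1)
                # regularize toward unit scale as Stan does
                shrink = welford_n / (welford_n + 5.0)
                inv_mass = shrink * var + (1 - shrink) * 1e-3 * np.ones(dim)
                inv_mass = np.clip(inv_mass, 1e-10, 1e10)
                welford_n, welford_mean, welford_m2 = 0, np.zeros(dim), np.zeros(dim)
                eps = _find_initial_step(logp_grad, q, inv_mass, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_m = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            n_accept += accept_prob
            n_total += 1
            k = it - n_warmup
            draws[k] = q
            energies[k] = h0

    stats = HMCStats(
        accept_rate=n_accept / max(n_total, 1),
        step_size=eps,
        n_divergent=n_divergent,
        energy=energies,
    )
    return draws, stats
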