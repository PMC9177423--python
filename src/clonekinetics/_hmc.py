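"""Hamiltonian Monte Carlo with dual-averaging step-size and diagonal mass adaptation.

A deliberately small sampler: fixed-length leapfrog trajectories (with step
jitter to avoid periodicity), warm-up split into step-size adaptation,
mass-matrix estimation, and step-size re-adaptation. Gradients are supplied
analytically by the caller, so no autodiff framework is required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HMCResult", "hmc_sample", "hmc_chains"]

_DIVERGENCE_ENERGY = 1000.0


@dataclass
class HMCResult:
    samples: np.ndarray  # (n_chains, n_draws, dim)
    accept_rate: float
    n_divergent: int
    step_size: float


def _leapfrog(logp_grad, x, p, eps, n_steps, inv_mass):
    # rejected trajectories may briefly visit non-finite states; silence the
    # resulting harmless floating-point warnings
    with np.errstate(all="ignore"):
        lp, grad = logp_grad(x)
        for _ in range(n_steps):
            p = p + 0.5 * eps * grad
            x = x + eps * inv_mass * p
            if not np.all(np.isfinite(x)):
                return x, p, -np.inf, grad
            lp, grad = logp_grad(x)
            if not np.isfinite(lp):
                return x, p, lp, grad
            p = p + 0.5 * eps * grad
    return x, p, lp, grad


def hmc_sample(
    logp_grad,
    x0: np.ndarray,
    *,
    n_draws: int,
    n_warmup: int,
    leapfrog_steps: int,
    seed: int,
    target_accept: float = 0.8,
    init_step: float = 0.1,
):
    """One HMC chain. Returns (samples, accept_rate, n_divergent, step_size)."""
    rng = np.random.default_rng(seed)
    dim = x0.size
    x = np.asarray(x0, dtype=float).copy()
    lp, grad = logp_grad(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")

    mass = np.ones(dim)  # diagonal; momentum ~ N(0, mass)
    inv_mass = 1.0 / mass

    # dual averaging state (Nesterov-style, as in NUTS warm-up)
    mu = np.log(10 * init_step)
    log_eps = np.log(init_step)
    log_eps_bar = 0.0
    h_bar = 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    mass_window_start = n_warmup // 4
    mass_window_end = (3 * n_warmup) // 4
    window_draws = []

    samples = np.empty((n_draws, dim))
    n_accept = 0
    n_divergent = 0
    total = n_warmup + n_draws

    for it in range(total):
        adapting = it < n_warmup
        eps = np.exp(log_eps if adapting else log_eps_bar)
        steps = int(rng.integers(max(1, int(0.8 * leapfrog_steps)),
                                 int(1.2 * leapfrog_steps) + 1))
        p0 = rng.normal(size=dim) * np.sqrt(mass)
        h0 = -lp + 0.5 * np.sum(p0 * p0 * inv_mass)
        x_new, p_new, lp_new, grad_new = _leapfrog(logp_grad, x, p0, eps, steps, inv_mass)
        if np.isfinite(lp_new):
            h1 = -lp_new + 0.5 * np.sum(p_new * p_new * inv_mass)
            delta_h = h0 - h1
        else:
            delta_h = -np.inf
        divergent = not np.isfinite(delta_h) or delta_h < -_DIVERGENCE_ENERGY
        accept_prob = 0.0 if divergent else min(1.0, np.exp(min(delta_h, 0.0)))
        if not divergent and rng.random() < accept_prob:
            x, lp, grad = x_new, lp_new, grad_new
            if not adapting:
                n_accept += 1
        if divergent and not adapting:
            n_divergent += 1

        if adapting:
            m = it + 1
            h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - accept_prob) / (m + t0)
            log_eps = mu - np.sqrt(m) / gamma * h_bar
            eta = m ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            if mass_window_start <= it < mass_window_end:
                window_draws.append(x.copy())
            if it == mass_window_end - 1 and len(window_draws) >= 10:
                var = np.var(np.asarray(window_draws), axis=0)
                mass = 1.0 / np.maximum(var, 1e-10)
                inv_mass = 1.0 / mass
                # restart step-size adaptation under the new metric
                mu = np.log(10 * np.exp(log_eps))
                h_bar = 0.0
        else:
            samples[it - n_warmup] = x

    accept_rate = n_accept / max(n_draws, 1)
    return samples, accept_rate, n_divergent, float(np.exp(log_eps_bar))


def hmc_chains(
    logp_grad,
    x0: np.ndarray,
    *,
    n_chains: int,
    n_draws: int,
    n_warmup: int,
    leapfrog_steps: int,
    seed: int,
    target_accept: float = 0.8,
    init_jitter: float = 0.5,
) -> HMCResult:
    """Run several independent chains from jittered starting points."""
    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    all_samples = []
    acc, div, eps = [], 0, []
    for c in range(n_chains):
        rng = np.random.default_rng(seeds[c])
        start = x0 + init_jitter * rng.normal(size=x0.size) * 0.1
        s, a, d, e = hmc_sample(
            logp_grad,
            start,
            n_draws=n_draws,
            n_warmup=n_warmup,
            leapfrog_steps=leapfrog_steps,
            seed=int(rng.integers(2**31 - 1)),
            target_accept=target_accept,
        )
        all_samples.append(s)
        acc.append(a)
        div += d
        eps.append(e)
    return HMCResult(
        samples=np.asarray(all_samples),
        accept_rate=float(np.mean(acc)),
        n_divergent=div,
        step_size=float(np.mean(eps)),
    )
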