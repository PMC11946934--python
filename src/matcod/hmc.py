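"""A compact adaptive Hamiltonian Monte Carlo sampler.

Static-trajectory HMC with leapfrog integration, a diagonal mass matrix
estimated during warmup, dual-averaging step-size adaptation targeting a
given acceptance rate, and jittered trajectory lengths to decorrelate
successive draws. The target supplies a fused log-density-and-gradient
callable; all parameters are unconstrained reals (constrained model
parameters are transformed before they reach the sampler).

Divergent transitions (energy error above a large threshold) are
rejected and counted; a high divergence count in the returned stats is
the signal to raise ``target_accept`` or reparametrise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

_DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class ChainStats:
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
    inv_mass: np.ndarray,
):
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        x = x + eps * inv_mass * p
        logp, grad = logp_grad(x)
        if not np.isfinite(logp):
            return x, p, -np.inf, grad
        if step != n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return x, p, logp, grad


def _initial_step_size(
    logp_grad: LogpGrad, x: np.ndarray, rng: np.random.Generator, inv_mass: np.ndarray
) -> float:
    """Heuristic: double/halve until one leapfrog step has accept prob near 0.5."""
    eps = 0.1
    logp0, grad0 = logp_grad(x)
    p0 = rng.standard_normal(x.size) / np.sqrt(inv_mass)
    h0 = logp0 - 0.5 * float(p0 * inv_mass @ p0)

    def joint(eps_try: float) -> float:
        _, p1, logp1, _ = _leapfrog(logp_grad, x, p0, grad0, eps_try, 1, inv_mass)
        if not np.isfinite(logp1):
            return -np.inf
        return logp1 - 0.5 * float(p1 * inv_mass @ p1)

    direction = 1 if joint(eps) - h0 > math.log(0.5) else -1
    for _ in range(50):
        eps_next = eps * (2.0 if direction == 1 else 0.5)
        diff = joint(eps_next) - h0
        if (direction == 1 and diff < math.log(0.5)) or (
            direction == -1 and diff > math.log(0.5)
        ):
            break
        eps = eps_next
    return eps


def sample_chain(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.85,
    leapfrog_steps: int = 24,
) -> tuple[np.ndarray, ChainStats]:
    """Run one HMC chain; returns post-warmup draws of shape (n_draws, dim)."""
    x = np.asarray(x0, dtype=float).copy()
    dim = x.size
    inv_mass = np.ones(dim)

    # dual-averaging state (re-initialised after the mass-matrix update)
    def reset_da(eps0: float):
        return {"mu": math.log(10.0 * eps0), "log_eps_bar": 0.0, "h_bar": 0.0, "t": 0}

    eps = _initial_step_size(logp_grad, x, rng, inv_mass)
    da = reset_da(eps)
    gamma, t0, kappa = 0.05, 10.0, 0.75

    logp, grad = logp_grad(x)
    draws = np.empty((n_draws, dim))
    n_divergent = 0
    n_accept = 0.0
    warmup_buf: list[np.ndarray] = []
    mass_update_iter = int(0.6 * n_warmup) if n_warmup >= 100 else None

    total = n_warmup + n_draws
    for it in range(total):
        warming = it < n_warmup
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = logp - 0.5 * float(p0 * inv_mass @ p0)
        n_steps = int(rng.integers(max(1, leapfrog_steps // 2), leapfrog_steps + 1))
        x1, p1, logp1, grad1 = _leapfrog(logp_grad, x, p0, grad, eps, n_steps, inv_mass)
        if np.isfinite(logp1):
            h1 = logp1 - 0.5 * float(p1 * inv_mass @ p1)
            delta = h1 - h0
        else:
            delta = -np.inf
        if delta < -_DIVERGENCE_THRESHOLD or not np.isfinite(delta):
            alpha = 0.0
            if not warming:
                n_divergent += 1
        else:
            alpha = min(1.0, math.exp(min(delta, 0.0)))
        if rng.random() < alpha:
            x, logp, grad = x1, logp1, grad1
        if warming:
            da["t"] += 1
            t = da["t"]
            frac = 1.0 / (t + t0)
            da["h_bar"] = (1 - frac) * da["h_bar"] + frac * (target_accept - alpha)
            log_eps = da["mu"] - math.sqrt(t) / gamma * da["h_bar"]
            eta = t ** (-kappa)
            da["log_eps_bar"] = eta * log_eps + (1 - eta) * da["log_eps_bar"]
            eps = math.exp(log_eps)
            warmup_buf.append(x.copy())
            if mass_update_iter is not None and it == mass_update_iter:
                window = np.asarray(warmup_buf[len(warmup_buf) // 2 :])
                var = window.var(axis=0)
                n_w = window.shape[0]
                # shrink toward unit mass to guard short windows
                var = (n_w / (n_w + 5.0)) * var + (5.0 / (n_w + 5.0)) * 1.0
                inv_mass = np.maximum(var, 1e-8)
                eps = _initial_step_size(logp_grad, x, rng, inv_mass)
                da = reset_da(eps)
            if it == n_warmup - 1:
                eps = math.exp(da["log_eps_bar"])
        else:
            draws[it - n_warmup] = x
            n_accept += alpha
    stats = ChainStats(
        accept_rate=n_accept / max(n_draws, 1), step_size=eps, n_divergent=n_divergent
    )
    return draws, stats


def sample(
    logp_grad: LogpGrad,
    x0s: Sequence[np.ndarray],
    n_warmup: int,
    n_draws: int,
    seed: int,
    target_accept: float = 0.85,
    leapfrog_steps: int = 24,
) -> tuple[np.ndarray, list[ChainStats]]:
    """Run several chains sequentially; returns (chains, n_draws, dim)."""
    seeds = np.random.SeedSequence(seed).spawn(len(x0s))
    all_draws = []
    all_stats = []
    for x0, s in zip(x0s, seeds):
        d, st = sample_chain(
            logp_grad,
            x0,
            n_warmup,
            n_draws,
            np.random.default_rng(s),
            target_accept=target_accept,
            leapfrog_steps=leapfrog_steps,
        )
        all_draws.append(d)
        all_stats.append(st)
    return np.stack(all_draws), all_stats
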