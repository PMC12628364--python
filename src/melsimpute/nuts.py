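"""No-U-turn sampler with dual-averaging step size and diagonal mass adaptation.

A self-contained gradient-based MCMC engine for the hierarchical
posteriors in this package.  The implementation follows the standard
recursive tree-doubling construction with a slice variable, a Stan-style
windowed warmup schedule for the diagonal metric, and dual averaging of
the step size toward a target acceptance statistic.

The target is supplied as ``logp_grad(z) -> (logp, grad)`` on an
unconstrained parameter vector; constraint transforms (log-SDs, tanh
correlations, non-centered latents) live in :mod:`melsimpute.posteriors`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["nuts_sample", "NUTSStats"]

_MAX_DELTA_H = 1000.0  # divergence threshold on the energy error


@dataclass
class NUTSStats:
    step_size: float
    inv_mass: np.ndarray
    mean_accept: float
    n_divergent: int
    logp: np.ndarray  # per retained draw


def _find_reasonable_epsilon(logp_grad, z, inv_mass, rng):
    eps = 1.0
    logp, grad = logp_grad(z)
    r = rng.standard_normal(z.size) / np.sqrt(inv_mass)
    h0 = logp - 0.5 * np.sum(inv_mass * r * r)
    z1, r1, logp1, _ = _leapfrog(logp_grad, z, r, grad, eps, inv_mass)
    h1 = logp1 - 0.5 * np.sum(inv_mass * r1 * r1)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(60):
        eps *= 2.0**direction
        z1, r1, logp1, _ = _leapfrog(logp_grad, z, r, grad, eps, inv_mass)
        h1 = logp1 - 0.5 * np.sum(inv_mass * r1 * r1)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) < direction * np.log(0.5):
            break
    return max(eps, 1e-8)


def _leapfrog(logp_grad, z, r, grad, eps, inv_mass):
    r = r + 0.5 * eps * grad
    z = z + eps * inv_mass * r
    logp, grad = logp_grad(z)
    if not np.isfinite(logp):
        logp = -np.inf
        grad = np.zeros_like(z)
    r = r + 0.5 * eps * grad
    return z, r, logp, grad


class _Tree:
    __slots__ = (
        "z_minus", "r_minus", "grad_minus",
        "z_plus", "r_plus", "grad_plus",
        "z_prop", "logp_prop", "n", "stop",
        "sum_accept", "n_accept", "divergent",
    )


def _build_tree(logp_grad, z, r, grad, logu, direction, depth, eps, inv_mass, h0, rng):
    t = _Tree()
    if depth == 0:
        z1, r1, logp1, grad1 = _leapfrog(logp_grad, z, r, grad, direction * eps, inv_mass)
        h1 = logp1 - 0.5 * np.sum(inv_mass * r1 * r1)
        t.z_minus = t.z_plus = t.z_prop = z1
        t.r_minus = t.r_plus = r1
        t.grad_minus = t.grad_plus = grad1
        t.logp_prop = logp1
        t.n = int(logu <= h1)
        t.divergent = (h1 - logu) < -_MAX_DELTA_H or not np.isfinite(h1)
        t.stop = t.divergent
        t.sum_accept = float(min(1.0, np.exp(h1 - h0))) if np.isfinite(h1) else 0.0
        t.n_accept = 1
        return t
    # recursively build left and right subtrees
    t = _build_tree(logp_grad, z, r, grad, logu, direction, depth - 1, eps, inv_mass, h0, rng)
    if t.stop:
        return t
    if direction == -1:
        t2 = _build_tree(
            logp_grad, t.z_minus, t.r_minus, t.grad_minus, logu,
            direction, depth - 1, eps, inv_mass, h0, rng,
        )
        t.z_minus, t.r_minus, t.grad_minus = t2.z_minus, t2.r_minus, t2.grad_minus
    else:
        t2 = _build_tree(
            logp_grad, t.z_plus, t.r_plus, t.grad_plus, logu,
            direction, depth - 1, eps, inv_mass, h0, rng,
        )
        t.z_plus, t.r_plus, t.grad_plus = t2.z_plus, t2.r_plus, t2.grad_plus
    total = t.n + t2.n
    if t2.n > 0 and rng.random() < t2.n / max(total, 1):
        t.z_prop, t.logp_prop = t2.z_prop, t2.logp_prop
    t.n = total
    t.sum_accept += t2.sum_accept
    t.n_accept += t2.n_accept
    t.divergent = t.divergent or t2.divergent
    dz = t.z_plus - t.z_minus
    uturn = (dz @ (inv_mass * t.r_minus) < 0) or (dz @ (inv_mass * t.r_plus) < 0)
    t.stop = t.divergent or t2.stop or uturn
    return t


def _warmup_windows(n_warmup):
    """Stan-like schedule: fast start, doubling slow windows, fast end."""
    init = max(int(0.15 * n_warmup), 10)
    term = max(int(0.10 * n_warmup), 10)
    if n_warmup < 40:
        return init, [], term
    slow_total = n_warmup - init - term
    windows = []
    w = max(25, slow_total // 8)
    pos = 0
    while pos < slow_total:
        if pos + 3 * w >= slow_total:
            w = slow_total - pos
        windows.append(w)
        pos += w
        w *= 2
    return init, windows, term


def nuts_sample(
    logp_grad,
    z0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    seed,
    target_accept: float = 0.8,
    max_depth: int = 10,
):
    """Run one NUTS chain; returns (draws, NUTSStats).

    ``draws`` has shape (n_draws, dim), warmup iterations discarded.
    """
    rng = np.random.default_rng(seed)
    z = np.asarray(z0, dtype=float).copy()
    dim = z.size
    inv_mass = np.ones(dim)
    logp, grad = logp_grad(z)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log-density")

    eps = _find_reasonable_epsilon(logp_grad, z, inv_mass, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    init, slow_windows, term = _warmup_windows(n_warmup)
    window_ends = []
    pos = init
    for w in slow_windows:
        pos += w
        window_ends.append(pos)
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    accepts = []
    n_div = 0

    total = n_warmup + n_draws
    for it in range(total):
        adapting = it < n_warmup
        r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = logp - 0.5 * np.sum(inv_mass * r0 * r0)
        logu = h0 - rng.exponential()
        z_minus = z_plus = z
        r_minus = r_plus = r0
        grad_minus = grad_plus = grad
        z_new, logp_new = z, logp
        n_kept = 1
        stop = False
        accept_sum, accept_n = 0.0, 0
        depth = 0
        while not stop and depth < max_depth:
            direction = -1 if rng.random() < 0.5 else 1
            if direction == -1:
                t = _build_tree(
                    logp_grad, z_minus, r_minus, grad_minus, logu,
                    direction, depth, eps, inv_mass, h0, rng,
                )
                z_minus, r_minus, grad_minus = t.z_minus, t.r_minus, t.grad_minus
            else:
                t = _build_tree(
                    logp_grad, z_plus, r_plus, grad_plus, logu,
                    direction, depth, eps, inv_mass, h0, rng,
                )
                z_plus, r_plus, grad_plus = t.z_plus, t.r_plus, t.grad_plus
            if not t.stop and t.n > 0 and rng.random() < min(1.0, t.n / n_kept):
                z_new, logp_new = t.z_prop, t.logp_prop
            n_kept += t.n
            accept_sum += t.sum_accept
            accept_n += t.n_accept
            if t.divergent:
                n_div += 1
            dz = z_plus - z_minus
            uturn = (dz @ (inv_mass * r_minus) < 0) or (dz @ (inv_mass * r_plus) < 0)
            stop = t.stop or uturn
            depth += 1

        z = z_new
        logp, grad = logp_grad(z)
        alpha = accept_sum / max(accept_n, 1)
        accepts.append(alpha)

        if adapting:
            # dual averaging of the step size
            m = it + 1
            h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - alpha) / (m + t0)
            log_eps = mu - np.sqrt(m) / gamma * h_bar
            eta = m**-kappa
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            # accumulate draws for the metric inside slow windows
            if init <= it < (n_warmup - term):
                welford_n += 1
                d = z - welford_mean
                welford_mean += d / welford_n
                welford_m2 += d * (z - welford_mean)
                if window_ends and it + 1 == init + window_ends[0]:
                    if welford_n > 2:
                        var = welford_m2 / (welford_n - 1)
                        # regularized diagonal metric (Stan's shrinkage)
                        var = (welford_n / (welford_n + 5.0)) * var + 1e-3 * (
                            5.0 / (welford_n + 5.0)
                        )
                        inv_mass = var
                    welford_n = 0
                    welford_mean = np.zeros(dim)
                    welford_m2 = np.zeros(dim)
                    window_ends.pop(0)
                    eps = _find_reasonable_epsilon(logp_grad, z, inv_mass, rng)
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar = 0.0, 0.0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = z
            logps[it - n_warmup] = logp

    stats = NUTSStats(
        step_size=eps,
        inv_mass=inv_mass,
        mean_accept=float(np.mean(accepts[n_warmup:])) if n_draws else float("nan"),
        n_divergent=n_div,
        logp=logps,
    )
    return draws, stats
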