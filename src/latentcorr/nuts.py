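"""A self-contained No-U-Turn sampler with dual-averaging step-size adaptation.

Multinomial trajectory sampling (progressive, biased toward the new subtree),
diagonal mass-matrix estimation during a warm-up window, and a divergence
guard on the Hamiltonian error.  The target density is supplied as a
callable ``logp_grad(q) -> (logp, grad)``; everything else is plain numpy so
the sampler is reusable for any smooth unconstrained density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np

__all__ = ["NutsStats", "nuts_sample"]

_DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class NutsStats:
    """Per-chain sampler diagnostics."""

    accept_rate: float
    n_divergent: int
    step_size: float
    mean_tree_depth: float


def _leapfrog(logp_grad, q, p, grad, eps, minv):
    p_half = p + 0.5 * eps * grad
    q_new = q + eps * minv * p_half
    logp_new, grad_new = logp_grad(q_new)
    p_new = p_half + 0.5 * eps * grad_new
    return q_new, p_new, logp_new, grad_new


def _kinetic(p, minv):
    return 0.5 * float(np.dot(p, minv * p))


def _is_turning(q_minus, q_plus, p_minus, p_plus, minv):
    dq = q_plus - q_minus
    return (
        float(np.dot(dq, minv * p_minus)) < 0.0
        or float(np.dot(dq, minv * p_plus)) < 0.0
    )


class _Tree:
    __slots__ = (
        "q_minus", "p_minus", "grad_minus",
        "q_plus", "p_plus", "grad_plus",
        "q_prop", "logp_prop", "grad_prop",
        "log_weight", "turning", "diverging",
        "sum_accept", "n_steps",
    )

    def __init__(self, q, p, grad, q_prop, logp_prop, grad_prop,
                 log_weight, turning, diverging, sum_accept, n_steps):
        self.q_minus = q
        self.p_minus = p
        self.grad_minus = grad
        self.q_plus = q
        self.p_plus = p
        self.grad_plus = grad
        self.q_prop = q_prop
        self.logp_prop = logp_prop
        self.grad_prop = grad_prop
        self.log_weight = log_weight
        self.turning = turning
        self.diverging = diverging
        self.sum_accept = sum_accept
        self.n_steps = n_steps


def _build_tree(logp_grad, q, p, grad, direction, depth, eps, energy0, minv, rng):
    if depth == 0:
        q1, p1, logp1, grad1 = _leapfrog(
            logp_grad, q, p, grad, direction * eps, minv
        )
        energy1 = -logp1 + _kinetic(p1, minv) if np.isfinite(logp1) else np.inf
        delta = energy0 - energy1  # > 0 means the move gained probability
        diverging = (not np.isfinite(energy1)) or (-delta > _DIVERGENCE_THRESHOLD)
        accept = min(1.0, np.exp(min(delta, 0.0))) if np.isfinite(delta) else 0.0
        log_weight = delta if np.isfinite(delta) else -np.inf
        return _Tree(q1, p1, grad1, q1, logp1, grad1,
                     log_weight, False, diverging, accept, 1)

    first = _build_tree(
        logp_grad, q, p, grad, direction, depth - 1, eps, energy0, minv, rng
    )
    if first.turning or first.diverging:
        return first
    if direction > 0:
        edge = (first.q_plus, first.p_plus, first.grad_plus)
    else:
        edge = (first.q_minus, first.p_minus, first.grad_minus)
    second = _build_tree(
        logp_grad, *edge, direction, depth - 1, eps, energy0, minv, rng
    )

    total = np.logaddexp(first.log_weight, second.log_weight)
    if np.isfinite(second.log_weight) and rng.random() < np.exp(
        second.log_weight - total
    ):
        first.q_prop = second.q_prop
        first.logp_prop = second.logp_prop
        first.grad_prop = second.grad_prop
    if direction > 0:
        first.q_plus = second.q_plus
        first.p_plus = second.p_plus
        first.grad_plus = second.grad_plus
    else:
        first.q_minus = second.q_minus
        first.p_minus = second.p_minus
        first.grad_minus = second.grad_minus
    first.log_weight = total
    first.sum_accept += second.sum_accept
    first.n_steps += second.n_steps
    first.diverging = second.diverging
    first.turning = second.turning or _is_turning(
        first.q_minus, first.q_plus, first.p_minus, first.p_plus, minv
    )
    return first


def _nuts_step(logp_grad, q, logp, grad, eps, max_depth, minv, p_std, rng):
    p0 = rng.standard_normal(q.shape[0]) * p_std
    energy0 = -logp + _kinetic(p0, minv)

    q_minus = q
    p_minus = p0
    grad_minus = grad
    q_plus = q
    p_plus = p0
    grad_plus = grad
    q_prop, logp_prop, grad_prop = q, logp, grad
    log_weight = 0.0
    sum_accept = 0.0
    n_steps = 0
    divergent = False
    depth = 0

    while depth < max_depth:
        direction = 1 if rng.random() < 0.5 else -1
        if direction > 0:
            tree = _build_tree(
                logp_grad, q_plus, p_plus, grad_plus,
                direction, depth, eps, energy0, minv, rng,
            )
            q_plus, p_plus, grad_plus = tree.q_plus, tree.p_plus, tree.grad_plus
        else:
            tree = _build_tree(
                logp_grad, q_minus, p_minus, grad_minus,
                direction, depth, eps, energy0, minv, rng,
            )
            q_minus, p_minus, grad_minus = (
                tree.q_minus, tree.p_minus, tree.grad_minus
            )
        sum_accept += tree.sum_accept
        n_steps += tree.n_steps
        if tree.diverging:
            divergent = True
            break
        if not tree.turning:
            # biased progressive sampling: favour the fresh subtree
            if rng.random() < np.exp(
                min(0.0, tree.log_weight - log_weight)
            ):
                q_prop = tree.q_prop
                logp_prop = tree.logp_prop
                grad_prop = tree.grad_prop
        log_weight = np.logaddexp(log_weight, tree.log_weight)
        if tree.turning or _is_turning(q_minus, q_plus, p_minus, p_plus, minv):
            break
        depth += 1

    alpha = sum_accept / max(n_steps, 1)
    return q_prop, logp_prop, grad_prop, alpha, divergent, depth


def _find_reasonable_epsilon(logp_grad, q, logp, grad, minv, p_std, rng):
    eps = 1.0
    p0 = rng.standard_normal(q.shape[0]) * p_std
    energy0 = -logp + _kinetic(p0, minv)
    _, p1, logp1, _ = _leapfrog(logp_grad, q, p0, grad, eps, minv)
    energy1 = -logp1 + _kinetic(p1, minv) if np.isfinite(logp1) else np.inf
    delta = energy0 - energy1
    direction = 1.0 if delta > np.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0**direction
        _, p1, logp1, _ = _leapfrog(logp_grad, q, p0, grad, eps, minv)
        energy1 = -logp1 + _kinetic(p1, minv) if np.isfinite(logp1) else np.inf
        delta = energy0 - energy1
        if direction * delta < direction * np.log(0.5):
            break
    return eps


def nuts_sample(
    logp_grad: Callable[[np.ndarray], Tuple[float, np.ndarray]],
    q0: np.ndarray,
    n_samples: int,
    n_burnin: int,
    rng: np.random.Generator,
    target_accept: float = 0.65,
    max_depth: int = 10,
    adapt_mass: bool = True,
    minv0: np.ndarray | None = None,
) -> Tuple[np.ndarray, NutsStats]:
    """Draw ``n_samples`` iterations, discarding the first ``n_burnin``.

    Step size is tuned by dual averaging toward ``target_accept`` during
    burn-in and frozen afterwards; a diagonal mass matrix is estimated from
    a mid-burn-in window when ``adapt_mass`` is set.  ``minv0`` seeds the
    inverse mass (per-coordinate posterior variance guess) so early burn-in
    does not pay for badly scaled coordinates.  Returns the retained draws
    with shape ``(n_samples - n_burnin, dim)`` plus diagnostics.
    """
    q = np.array(q0, dtype=np.float64)
    dim = q.shape[0]
    logp, grad = logp_grad(q)
    if not np.isfinite(logp):
        raise ValueError("log posterior is not finite at the initial point")

    minv = np.ones(dim) if minv0 is None else np.asarray(minv0, dtype=np.float64)
    p_std = 1.0 / np.sqrt(minv)

    eps = _find_reasonable_epsilon(logp_grad, q, logp, grad, minv, p_std, rng)
    # dual averaging state (Hoffman & Gelman 2014 defaults)
    mu_da = np.log(10.0 * eps)
    log_eps_bar = 0.0
    h_bar = 0.0
    gamma_da, t0_da, kappa_da = 0.05, 10.0, 0.75

    # mass adaptation window inside burn-in
    win_lo = int(0.25 * n_burnin)
    win_hi = int(0.75 * n_burnin)
    collect = adapt_mass and n_burnin >= 100
    window: list[np.ndarray] = []

    kept = np.empty((n_samples - n_burnin, dim))
    accepts: list[float] = []
    depths: list[int] = []
    n_divergent = 0
    adapt_count = 0

    for it in range(n_samples):
        q, logp, grad, alpha, divergent, depth = _nuts_step(
            logp_grad, q, logp, grad, eps, max_depth, minv, p_std, rng
        )
        if divergent and it >= n_burnin:
            n_divergent += 1

        if it < n_burnin:
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0_da)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - alpha)
            log_eps = mu_da - np.sqrt(adapt_count) / gamma_da * h_bar
            weight = adapt_count**-kappa_da
            log_eps_bar = weight * log_eps + (1.0 - weight) * log_eps_bar
            eps = float(np.exp(log_eps))

            if collect and win_lo <= it < win_hi:
                window.append(q.copy())
            if collect and it == win_hi - 1 and len(window) >= 20:
                draws = np.asarray(window)
                var = draws.var(axis=0, ddof=1)
                nw = draws.shape[0]
                minv = (nw / (nw + 5.0)) * var + (5.0 / (nw + 5.0)) * minv
                minv = np.maximum(minv, 1e-8)
                p_std = 1.0 / np.sqrt(minv)
                # restart step-size adaptation for the new metric
                eps = _find_reasonable_epsilon(
                    logp_grad, q, logp, grad, minv, p_std, rng
                )
                mu_da = np.log(10.0 * eps)
                h_bar = 0.0
                log_eps_bar = 0.0
                adapt_count = 0
            if it == n_burnin - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            kept[it - n_burnin] = q
            accepts.append(alpha)
            depths.append(depth)

    stats = NutsStats(
        accept_rate=float(np.mean(accepts)) if accepts else np.nan,
        n_divergent=n_divergent,
        step_size=eps,
        mean_tree_depth=float(np.mean(depths)) if depths else np.nan,
    )
    return kept, stats
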