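"""No-U-Turn sampler (multinomial variant) with dual-averaging step-size
adaptation and windowed diagonal mass-matrix adaptation.

Self-contained and model-agnostic: the target is any callable
``logp_grad(q) -> (float, ndarray)`` returning ``-inf`` for invalid states
(treated as divergences).  The interface deliberately mirrors the familiar
dynamic-HMC stack: warm-up iterations interleave step-size adaptation with
expanding variance-estimation windows, and sampling iterations run at the
adapted settings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

_MAX_DELTA_H = 1000.0  # divergence threshold on the energy error


@dataclass
class _Leaf:
    q: np.ndarray
    p: np.ndarray
    lp: float
    grad: np.ndarray


@dataclass
class _Tree:
    minus: _Leaf
    plus: _Leaf
    prop: _Leaf
    log_w: float
    sum_accept: float
    n_leaf: int
    divergent: bool
    turning: bool


class NutsKernel:
    """One-transition NUTS kernel over a fixed target."""

    def __init__(self, logp_grad: Callable, inv_mass: np.ndarray,
                 max_treedepth: int = 10):
        self.logp_grad = logp_grad
        self.inv_mass = inv_mass
        self.sqrt_mass = 1.0 / np.sqrt(inv_mass)
        self.max_treedepth = max_treedepth
        self.n_evals = 0

    def _kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(p @ (self.inv_mass * p))

    def _leapfrog(self, leaf: _Leaf, eps: float) -> _Leaf:
        p = leaf.p + 0.5 * eps * leaf.grad
        q = leaf.q + eps * (self.inv_mass * p)
        lp, grad = self.logp_grad(q)
        self.n_evals += 1
        p = p + 0.5 * eps * grad
        return _Leaf(q, p, lp, grad)

    def _build(self, leaf: _Leaf, v: int, depth: int, eps: float,
               H0: float, rng: np.random.Generator) -> _Tree:
        if depth == 0:
            new = self._leapfrog(leaf, v * eps)
            if np.isfinite(new.lp):
                H1 = -new.lp + self._kinetic(new.p)
            else:
                H1 = np.inf
            dH = H1 - H0
            divergent = not np.isfinite(dH) or dH > _MAX_DELTA_H
            log_w = -np.inf if divergent else -dH
            accept = 0.0 if divergent else float(np.exp(min(0.0, -dH)))
            return _Tree(new, new, new, log_w, accept, 1, divergent, False)

        first = self._build(leaf, v, depth - 1, eps, H0, rng)
        if first.divergent or first.turning:
            return first
        inner = first.plus if v > 0 else first.minus
        second = self._build(inner, v, depth - 1, eps, H0, rng)

        log_w = np.logaddexp(first.log_w, second.log_w)
        # multinomial sampling among subtrees, proportional to their weight
        if np.isfinite(second.log_w) and np.log(rng.uniform()) < second.log_w - log_w:
            prop = second.prop
        else:
            prop = first.prop
        minus = first.minus if v > 0 else second.minus
        plus = second.plus if v > 0 else first.plus
        tree = _Tree(minus, plus, prop, log_w,
                     first.sum_accept + second.sum_accept,
                     first.n_leaf + second.n_leaf,
                     second.divergent, second.turning)
        if not tree.divergent and not tree.turning:
            tree.turning = self._uturn(minus, plus)
        return tree

    def _uturn(self, minus: _Leaf, plus: _Leaf) -> bool:
        dq = plus.q - minus.q
        return (float(dq @ (self.inv_mass * minus.p)) < 0.0
                or float(dq @ (self.inv_mass * plus.p)) < 0.0)

    def transition(self, q0: np.ndarray, lp0: float, grad0: np.ndarray,
                   eps: float, rng: np.random.Generator) -> dict:
        p0 = rng.standard_normal(q0.size) * self.sqrt_mass
        H0 = -lp0 + self._kinetic(p0)
        start = _Leaf(q0, p0, lp0, grad0)
        current = _Tree(start, start, start, 0.0, 0.0, 0, False, False)
        depth = 0
        divergent = False
        sum_accept, n_leaf = 0.0, 0
        while depth < self.max_treedepth:
            v = 1 if rng.uniform() < 0.5 else -1
            edge = current.plus if v > 0 else current.minus
            sub = self._build(edge, v, depth, eps, H0, rng)
            sum_accept += sub.sum_accept
            n_leaf += sub.n_leaf
            if sub.divergent:
                divergent = True
                break
            if sub.turning:
                break
            # biased progressive sampling: favour the new subtree
            if np.log(rng.uniform()) < sub.log_w - current.log_w:
                current.prop = sub.prop
            current.log_w = np.logaddexp(current.log_w, sub.log_w)
            if v > 0:
                current.plus = sub.plus
            else:
                current.minus = sub.minus
            depth += 1
            if self._uturn(current.minus, current.plus):
                break
        leaf = current.prop
        return dict(q=leaf.q, lp=leaf.lp, grad=leaf.grad,
                    accept_stat=sum_accept / max(n_leaf, 1),
                    depth=depth, divergent=divergent,
                    energy=H0)


class DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman-Gelman schedule)."""

    def __init__(self, eps0: float, target: float = 0.8,
                 gamma: float = 0.05, t0: float = 10.0, kappa: float = 0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept_stat: float) -> float:
        self.count += 1
        m = self.count
        frac = 1.0 / (m + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_stat)
        self.log_eps = self.mu - np.sqrt(m) / self.gamma * self.h_bar
        w = m ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))

    def restart(self, eps: float) -> None:
        self.mu = np.log(10.0 * eps)
        self.log_eps = np.log(eps)
        self.h_bar = 0.0
        self.count = 0


def find_initial_step_size(logp_grad: Callable, q0: np.ndarray, lp0: float,
                           grad0: np.ndarray, inv_mass: np.ndarray,
                           rng: np.random.Generator, eps: float = 1.0) -> float:
    """Crude bracketing of a step size with acceptance probability near 0.8."""
    kernel = NutsKernel(logp_grad, inv_mass, max_treedepth=1)
    p0 = rng.standard_normal(q0.size) * kernel.sqrt_mass
    H0 = -lp0 + kernel._kinetic(p0)

    def accept(e: float) -> float:
        leaf = kernel._leapfrog(_Leaf(q0, p0, lp0, grad0), e)
        if not np.isfinite(leaf.lp):
            return 0.0
        return float(np.exp(min(0.0, H0 - (-leaf.lp + kernel._kinetic(leaf.p)))))

    a = accept(eps)
    direction = 1 if a > 0.8 else -1
    for _ in range(50):
        eps_new = eps * (2.0 if direction > 0 else 0.5)
        a_new = accept(eps_new)
        if (direction > 0 and a_new < 0.8) or (direction < 0 and a_new > 0.8):
            return eps_new if direction < 0 else eps
        eps, a = eps_new, a_new
        if eps < 1e-10 or eps > 1e7:
            break
    return eps


class WelfordVariance:
    def __init__(self, dim: int):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def update(self, x: np.ndarray) -> None:
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (x - self.mean)

    def variance(self) -> np.ndarray:
        if self.n < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.n - 1)
        # shrink toward unit scale as Stan does for stability
        return (self.n / (self.n + 5.0)) * var + 1e-3 * (5.0 / (self.n + 5.0))

    def reset(self) -> None:
        self.n = 0
        self.mean[:] = 0.0
        self.m2[:] = 0.0


def adaptation_windows(n_warmup: int) -> tuple[int, int, list[int]]:
    """Stan-style warm-up phases: (initial buffer, terminal buffer, window ends)."""
    init = max(int(round(0.15 * n_warmup)), 10)
    term = max(int(round(0.10 * n_warmup)), 10)
    if init + term + 20 > n_warmup:
        init = max(n_warmup // 5, 1)
        term = max(n_warmup // 10, 1)
    ends = []
    start = init
    size = max((n_warmup - init - term) // 4, 10)
    while start + size < n_warmup - term:
        ends.append(start + size)
        start += size
        size *= 2
    ends.append(n_warmup - term)
    return init, term, ends
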