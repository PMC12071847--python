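"""No-U-Turn Hamiltonian Monte Carlo sampler.

A self-contained multinomial-slice NUTS implementation operating on any
differentiable log density supplied as ``logp_grad(x) -> (float, ndarray)``:
leapfrog integration with a diagonal mass matrix, recursive tree doubling
with the u-turn termination criterion, dual-averaging step-size adaptation,
and Stan-style windowed estimation of the diagonal metric during warmup.
Divergences are flagged when the Hamiltonian error along a trajectory
exceeds 1000 nats.

The hierarchical RBC-lifespan posterior is smooth and (in its non-centered
parameterization) well conditioned, so a diagonal metric suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NutsConfig", "ChainResult", "sample_nuts"]

_DELTA_MAX = 1000.0  # Hamiltonian error (nats) that flags a divergence


@dataclass(frozen=True)
class NutsConfig:
    n_warmup: int = 1000
    n_draws: int = 1000
    target_accept: float = 0.9
    max_treedepth: int = 10
    init_buffer: int = 75
    term_buffer: int = 50
    base_window: int = 25


@dataclass
class ChainResult:
    draws: np.ndarray          # (n_draws, dim), post-warmup only
    logp: np.ndarray           # (n_draws,)
    accept_stat: np.ndarray    # mean Metropolis acceptance per draw
    treedepth: np.ndarray
    diverging: np.ndarray      # bool per post-warmup draw
    energy: np.ndarray
    step_size: float
    inv_mass: np.ndarray
    n_warmup_divergences: int = 0


class _Point:
    __slots__ = ("x", "p", "grad", "logp")

    def __init__(self, x, p, grad, logp):
        self.x, self.p, self.grad, self.logp = x, p, grad, logp


def _leapfrog(logp_grad, pt: _Point, eps: float, inv_mass: np.ndarray) -> _Point:
    p = pt.p + 0.5 * eps * pt.grad
    x = pt.x + eps * inv_mass * p
    logp, grad = logp_grad(x)
    p = p + 0.5 * eps * grad
    return _Point(x, p, grad, logp)


def _hamiltonian(pt: _Point, inv_mass: np.ndarray) -> float:
    if not np.isfinite(pt.logp):
        return np.inf
    with np.errstate(over="ignore", invalid="ignore"):
        kinetic = 0.5 * float(np.dot(pt.p * pt.p, inv_mass))
    return -pt.logp + kinetic if np.isfinite(kinetic) else np.inf


def _find_reasonable_epsilon(logp_grad, pt: _Point, inv_mass, rng) -> float:
    """Heuristic initial step size: double/halve until the one-step
    acceptance probability crosses 0.5."""
    eps = 1.0
    p0 = rng.standard_normal(pt.x.size) / np.sqrt(inv_mass)
    start = _Point(pt.x, p0, pt.grad, pt.logp)
    h0 = _hamiltonian(start, inv_mass)
    nxt = _leapfrog(logp_grad, start, eps, inv_mass)
    dh = h0 - _hamiltonian(nxt, inv_mass)
    direction = 1.0 if dh > np.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0**direction
        nxt = _leapfrog(logp_grad, start, eps, inv_mass)
        dh = h0 - _hamiltonian(nxt, inv_mass)
        if direction * dh <= direction * np.log(0.5):
            break
    return eps


class _Tree:
    """Result of building one NUTS subtree (slice-sampling variant)."""

    __slots__ = ("minus", "plus", "proposal", "n_valid", "keep_going",
                 "sum_alpha", "n_alpha", "divergent")

    def __init__(self, minus, plus, proposal, n_valid, keep_going,
                 sum_alpha, n_alpha, divergent):
        self.minus, self.plus, self.proposal = minus, plus, proposal
        self.n_valid, self.keep_going = n_valid, keep_going
        self.sum_alpha, self.n_alpha, self.divergent = sum_alpha, n_alpha, divergent


def _no_uturn(minus: _Point, plus: _Point, inv_mass) -> bool:
    dx = plus.x - minus.x
    return (np.dot(dx, inv_mass * minus.p) >= 0) and (np.dot(dx, inv_mass * plus.p) >= 0)


def _build_tree(logp_grad, pt, log_u, direction, depth, eps, h0, inv_mass, rng):
    if depth == 0:
        nxt = _leapfrog(logp_grad, pt, direction * eps, inv_mass)
        h = _hamiltonian(nxt, inv_mass)
        n_valid = int(log_u <= -h)
        divergent = not (log_u < _DELTA_MAX - h)
        alpha = np.exp(min(0.0, h0 - h)) if np.isfinite(h) else 0.0
        return _Tree(nxt, nxt, nxt, n_valid, not divergent, alpha, 1, divergent)

    inner = _build_tree(logp_grad, pt, log_u, direction, depth - 1, eps, h0, inv_mass, rng)
    if not inner.keep_going:
        return inner
    start = inner.minus if direction < 0 else inner.plus
    outer = _build_tree(logp_grad, start, log_u, direction, depth - 1, eps, h0, inv_mass, rng)
    minus = outer.minus if direction < 0 else inner.minus
    plus = inner.plus if direction < 0 else outer.plus
    n_valid = inner.n_valid + outer.n_valid
    proposal = inner.proposal
    if outer.n_valid and rng.uniform() < outer.n_valid / max(n_valid, 1):
        proposal = outer.proposal
    keep_going = outer.keep_going and _no_uturn(minus, plus, inv_mass)
    return _Tree(minus, plus, proposal, n_valid, keep_going,
                 inner.sum_alpha + outer.sum_alpha, inner.n_alpha + outer.n_alpha,
                 inner.divergent or outer.divergent)


def _nuts_step(logp_grad, x, logp, grad, eps, inv_mass, max_depth, rng):
    p0 = rng.standard_normal(x.size) / np.sqrt(inv_mass)
    current = _Point(x, p0, grad, logp)
    h0 = _hamiltonian(current, inv_mass)
    log_u = np.log(rng.uniform()) - h0
    minus = plus = current
    proposal = current
    n_valid, depth, divergent = 1, 0, False
    sum_alpha, n_alpha = 0.0, 0
    while depth < max_depth:
        direction = 1.0 if rng.uniform() < 0.5 else -1.0
        start = minus if direction < 0 else plus
        tree = _build_tree(logp_grad, start, log_u, direction, depth, eps, h0, inv_mass, rng)
        if direction < 0:
            minus = tree.minus
        else:
            plus = tree.plus
        sum_alpha += tree.sum_alpha
        n_alpha += tree.n_alpha
        divergent = divergent or tree.divergent
        if not tree.keep_going:
            break
        if tree.n_valid and rng.uniform() < tree.n_valid / max(n_valid, 1):
            proposal = tree.proposal
        n_valid += tree.n_valid
        depth += 1
        if not _no_uturn(minus, plus, inv_mass):
            break
    accept = sum_alpha / max(n_alpha, 1)
    return proposal, accept, depth, divergent, h0


class _DualAveraging:
    """Nesterov dual averaging of log step size (gamma=0.05, t0=10, kappa=0.75)."""

    def __init__(self, eps0: float, target: float):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept: float) -> float:
        self.count += 1
        frac = 1.0 / (self.count + 10.0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept)
        self.log_eps = self.mu - np.sqrt(self.count) / 0.05 * self.h_bar
        w = self.count**-0.75
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


class _Welford:
    def __init__(self, dim):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def push(self, x):
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.m2 += d * (x - self.mean)

    def variance(self):
        var = self.m2 / max(self.n - 1, 1)
        # Stan-style regularization toward unit scale
        return (self.n / (self.n + 5.0)) * var + 1e-3 * (5.0 / (self.n + 5.0))


def _window_ends(cfg: NutsConfig) -> set[int]:
    """Iteration indices (1-based) at which a slow adaptation window closes."""
    n = cfg.n_warmup
    if n < cfg.init_buffer + cfg.term_buffer + cfg.base_window:
        return {n} if n >= 20 else set()
    ends = set()
    start = cfg.init_buffer
    size = cfg.base_window
    while True:
        end = start + size
        if end + 2 * size > n - cfg.term_buffer:
            ends.add(n - cfg.term_buffer)
            break
        ends.add(end)
        start, size = end, 2 * size
    return ends


def sample_nuts(logp_grad, x0: np.ndarray, config: NutsConfig,
                rng: np.random.Generator, progress=None) -> ChainResult:
    """Run one NUTS chain from ``x0``; returns post-warmup draws."""
    dim = x0.size
    inv_mass = np.ones(dim)
    logp, grad = logp_grad(x0)
    if not np.isfinite(logp):
        raise RuntimeError("chain initialization failed: non-finite log density at x0")
    x = x0.astype(float).copy()

    eps = _find_reasonable_epsilon(logp_grad, _Point(x, np.zeros(dim), grad, logp), inv_mass, rng)
    da = _DualAveraging(eps, config.target_accept)
    welford = _Welford(dim)
    ends = _window_ends(config)
    collecting_from = config.init_buffer if config.n_warmup >= (
        config.init_buffer + config.term_buffer + config.base_window) else 0

    n_total = config.n_warmup + config.n_draws
    draws = np.empty((config.n_draws, dim))
    logps = np.empty(config.n_draws)
    accepts = np.empty(config.n_draws)
    depths = np.empty(config.n_draws, dtype=int)
    divs = np.zeros(config.n_draws, dtype=bool)
    energies = np.empty(config.n_draws)
    warm_divs = 0

    for it in range(1, n_total + 1):
        warmup = it <= config.n_warmup
        pt, accept, depth, divergent, energy = _nuts_step(
            logp_grad, x, logp, grad, eps, inv_mass, config.max_treedepth, rng)
        x, logp, grad = pt.x, pt.logp, pt.grad
        if warmup:
            warm_divs += int(divergent)
            eps = da.update(accept)
            if it > collecting_from:
                welford.push(x)
            if it in ends and welford.n >= 10:
                inv_mass = welford.variance()
                welford = _Welford(dim)
                eps = _find_reasonable_epsilon(
                    logp_grad, _Point(x, np.zeros(dim), grad, logp), inv_mass, rng)
                da = _DualAveraging(eps, config.target_accept)
            if it == config.n_warmup:
                eps = da.adapted
        else:
            i = it - config.n_warmup - 1
            draws[i] = x
            logps[i] = logp
            accepts[i] = accept
            depths[i] = depth
            divs[i] = divergent
            energies[i] = energy
        if progress is not None and it % 200 == 0:
            progress(it, n_total)

    return ChainResult(draws, logps, accepts, depths, divs, energies,
                       eps, inv_mass, warm_divs)
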