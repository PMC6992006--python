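"""Norm updating and coevolution of the resource-management trait.

After every interaction phase all agents *synchronously* revise their norms.
With probability ``mu`` an agent explores: it adopts a fresh norm drawn
uniformly on ``[0, 0.5]²``. Otherwise it picks one neighbour uniformly at
random and imitates that neighbour's norm with the Fermi (pairwise-comparison)
probability ``T(ΔP) = 1 / (1 + exp(−ΔP / K))``, where ``ΔP`` is the payoff
advantage of the role model and ``K`` the selection noise. Imitation is
imprecise: each copied component is perturbed by i.i.d. uniform noise on
``[−eps, eps]`` and clipped back into ``[0, 0.5]``. Role-model norms are read
from the pre-update generation (synchronous semantics) and agents never
sample themselves.

When coevolution is enabled, the per-agent intensity ``Δ_i`` evolves by the
same pairwise-comparison principle on a separate time scale: after each norm
update, ``round(s·N)`` sequential micro-steps each pick a random agent and a
random neighbour and copy the neighbour's Δ (plus a uniform perturbation on
``[−0.025, 0.025]``, clipped to ``[0, 1]``) with the Fermi probability
computed from the payoffs of the last interaction phase. Payoffs are not
recomputed between micro-steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .game_core import NORM_HIGH, NORM_LOW, PopulationState

__all__ = ["UpdateConfig", "fermi_probability", "norm_update_phase",
           "coevolution_phase"]

log = logging.getLogger("egalnorm")

DELTA_PERTURB_HALFRANGE = 0.025


@dataclass
class UpdateConfig:
    """Parameters of the updating phases."""

    mu: float = 0.0
    K: float = 0.1
    eps: float = 5e-3
    coevo_enabled: bool = False
    s: float = 0.0
    delta_perturb_halfrange: float = DELTA_PERTURB_HALFRANGE

    def __post_init__(self):
        if self.K <= 0:
            raise ValueError("noise K must be positive")
        if self.eps < 0:
            raise ValueError("eps must be >= 0")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must be in [0, 1]")
        if self.s < 0:
            raise ValueError("s must be >= 0")


def fermi_probability(payoff_target, payoff_self, K: float):
    """Probability of adopting the target's trait under the Fermi rule.

    ``T(x) = 1 / (1 + exp(−x / K))`` with ``x = payoff_target − payoff_self``.
    Accepts scalars or arrays; strictly increasing in the payoff difference,
    with ``T(0) = 1/2`` and ``T(x) + T(−x) = 1``.
    """
    if K <= 0:
        raise ValueError("noise K must be positive")
    return expit((np.asarray(payoff_target) - np.asarray(payoff_self)) / K)


def _random_neighbors(state: PopulationState, rng) -> np.ndarray:
    """One uniform-random neighbour per agent; -1 for isolated agents."""
    net = state.network
    n = state.n
    if net.complete:
        j = rng.integers(0, n - 1, size=n)
        j += j >= np.arange(n)  # skip self, stay uniform over the others
        return j
    picks = np.full(n, -1, dtype=np.int64)
    u = rng.random(n)
    for i in range(n):
        nbrs = net.neighbors[i]
        if len(nbrs):
            picks[i] = nbrs[int(u[i] * len(nbrs))]
    return picks


def norm_update_phase(state: PopulationState, payoffs: np.ndarray,
                      config: UpdateConfig, rng: np.random.Generator):
    """Synchronously updated norms for all agents.

    Returns ``(new_p, new_q)``; the input state is not modified. Draw order is
    fixed, so a seeded generator makes the phase bit-reproducible.
    """
    n = state.n
    explore = rng.random(n) < config.mu
    fresh_p = rng.uniform(NORM_LOW, NORM_HIGH, size=n)
    fresh_q = rng.uniform(NORM_LOW, NORM_HIGH, size=n)
    models = _random_neighbors(state, rng)
    have_model = models >= 0
    safe = np.where(have_model, models, 0)
    t = fermi_probability(payoffs[safe], payoffs, config.K)
    imitate = (~explore) & have_model & (rng.random(n) < t)
    err_p = rng.uniform(-config.eps, config.eps, size=n)
    err_q = rng.uniform(-config.eps, config.eps, size=n)

    new_p = state.p.copy()
    new_q = state.q.copy()
    new_p[imitate] = state.p[safe[imitate]] + err_p[imitate]
    new_q[imitate] = state.q[safe[imitate]] + err_q[imitate]
    new_p[explore] = fresh_p[explore]
    new_q[explore] = fresh_q[explore]
    np.clip(new_p, NORM_LOW, NORM_HIGH, out=new_p)
    np.clip(new_q, NORM_LOW, NORM_HIGH, out=new_q)
    return new_p, new_q


def coevolution_phase(state: PopulationState, payoffs: np.ndarray,
                      config: UpdateConfig, rng: np.random.Generator):
    """Evolve the per-agent resource-management intensities Δ_i.

    Performs ``round(s·N)`` sequential micro-steps (sampling with
    replacement; an agent may be picked several times) and returns the new
    Δ array. Copies are perturbed and clipped to ``[0, 1]``; payoffs stay
    those of the last interaction phase throughout.
    """
    n = state.n
    exact = config.s * n
    steps = int(round(exact))
    if steps != exact:
        log.debug("s*N = %s is not an integer; using %d micro-steps",
                  exact, steps)
    deltas = state.deltas.copy()
    if steps == 0:
        return deltas
    net = state.network
    focal = rng.integers(0, n, size=steps)
    pick = rng.random(steps)        # neighbour selector
    accept = rng.random(steps)
    xi = rng.uniform(-config.delta_perturb_halfrange,
                     config.delta_perturb_halfrange, size=steps)
    k = config.K
    for m in range(steps):
        i = focal[m]
        if net.complete:
            j = int(pick[m] * (n - 1))
            if j >= i:
                j += 1
        else:
            nbrs = net.neighbors[i]
            if not len(nbrs):
                continue
            j = nbrs[int(pick[m] * len(nbrs))]
        t = 1.0 / (1.0 + np.exp(-(payoffs[j] - payoffs[i]) / k))
        if accept[m] < t:
            deltas[i] = min(1.0, max(0.0, deltas[j] + xi[m]))
    return deltas
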