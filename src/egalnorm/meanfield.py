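"""Mini Ultimatum Game: two-norm reduction and replicator dynamics.

The full model has a continuum of norms; its dynamics are illuminated by a
reduction to two discrete self-compatible norms, an egalitarian norm
``IN₂ = [p₂, q₂]`` and a less generous ``IN₁ = [p₁, q₁]`` (``IN₂`` more
generous: ``p₂ > p₁`` and ``p₂ ≥ q₁``). Three orderings are possible:

1. ``q₁ ≤ q₂ ≤ p₁ < p₂``  — every deal succeeds; payoffs independent of Δ.
2. ``q₂ < q₁ ≤ p₁ < p₂``  — likewise.
3. ``q₁ ≤ p₁ < q₂ ≤ p₂``  — IN₂ rejects IN₁'s low offer; the mixed pair has a
   persistent one-sided conflict, which is exactly where resource management
   acts.

In case 3 the stationary 2×2 payoff matrix (row player IN₂, entries
``a b / c d`` against columns IN₂, IN₁) is::

    a = 1                 b = (1 − p₂)(1 + Δ)
    c = p₂(1 + Δ)         d = 1

At Δ = 0 this is the classical bistable mini-game with unstable interior
frequency x* = p₂ and basin of attraction 1 − p₂ > 1/2 for the egalitarian
norm (risk dominance). Raising Δ shifts b − d upward; once
``(1 − p₂)(1 + Δ) ≥ 1``, i.e. ``Δ ≥ p₂ / (1 − p₂)``, bistability gives way to
complete dominance of IN₂. At p₂ = 1/2 dominance is unattainable for any Δ
(a draw at best), which is why the population never settles at the fully
egalitarian corner.

Replicator dynamics for the frequency x of IN₂:
``ẋ = x(1 − x)[(a − c)x + (b − d)(1 − x)]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .game_core import Norm, resolve_deal

__all__ = ["MiniGame", "ReplicatorResult", "build_minigame",
           "replicator_analyze", "integrate_replicator",
           "dominance_threshold", "phase_grid"]

ABSORB_TOL = 1e-9


@dataclass(frozen=True)
class MiniGame:
    """2×2 game between an egalitarian norm (strategy 2) and a less
    egalitarian one (strategy 1); ``matrix = (a, b, c, d)`` are the payoffs of
    (IN₂ vs IN₂, IN₂ vs IN₁, IN₁ vs IN₂, IN₁ vs IN₁)."""

    norm1: Norm
    norm2: Norm
    delta: float
    matrix: tuple[float, float, float, float]
    case_id: int


@dataclass(frozen=True)
class ReplicatorResult:
    """Fixed-point structure of a 2×2 replicator flow.

    ``x_star`` is the interior fixed-point frequency of the egalitarian norm
    (None if none in (0, 1)); ``basin_IN2`` the length of the x-interval from
    which the flow converges to all-IN₂ (None in the neutral regime).
    """

    x_star: Optional[float]
    regime: str  # bistable | IN2-dominant | IN1-dominant | coexistence | neutral
    basin_IN2: Optional[float]


def _classify_case(n1: Norm, n2: Norm) -> int:
    if n1.p < n2.q:
        return 3
    return 1 if n1.q <= n2.q else 2


def build_minigame(norm1: Norm, norm2: Norm, delta: float) -> MiniGame:
    """Payoff matrix of the two-norm mini-game at stationarity.

    Entries are per-round pair payoffs after the deal ledger has settled (one
    round of burn-in): in cases 1–2 every deal succeeds, resources stay at 1
    and Δ cancels; in case 3 the mixed pair's conflict is persistent, so the
    egalitarian proposer's deal carries resource 1 + Δ and the rejected one
    1 − Δ, giving ``b = (1 − p₂)(1 + Δ)`` and ``c = p₂(1 + Δ)``.
    """
    if not (0.0 <= delta <= 1.0):
        raise ValueError(f"delta={delta} outside [0, 1]")
    for name, n in (("norm1", norm1), ("norm2", norm2)):
        if not n.self_compatible:
            raise ValueError(f"{name} is self-incompatible (p < q)")
    if not (norm2.p > norm1.p and norm2.p >= norm1.q):
        raise ValueError("norm2 must be more generous than norm1 "
                         "(p2 > p1 and p2 >= q1)")
    p1, p2 = norm1.p, norm2.p
    case = _classify_case(norm1, norm2)
    a = 1.0
    d = 1.0
    if case == 3:
        b = (1.0 - p2) * (1.0 + delta)
        c = p2 * (1.0 + delta)
    else:
        # all four deals succeed, so the ledger stays all-true and R = 1
        b = (1.0 - p2) * resolve_deal(norm2, norm1) + p1 * resolve_deal(norm1, norm2)
        c = (1.0 - p1) * resolve_deal(norm1, norm2) + p2 * resolve_deal(norm2, norm1)
    return MiniGame(norm1=norm1, norm2=norm2, delta=delta,
                    matrix=(a, b, c, d), case_id=case)


def replicator_analyze(game: MiniGame) -> ReplicatorResult:
    """Classify the replicator flow of a 2×2 game.

    Regimes follow the sign pattern of the invasion payoffs: with ``a > c``
    and ``b < d`` both norms are best replies to themselves (bistability,
    unstable interior point ``x* = (d − b)/(a − b − c + d)``, basin of the
    egalitarian norm ``1 − x*``); with ``b ≥ d`` and ``a ≥ c`` (not both ties)
    the egalitarian norm dominates and its basin is the whole interval.
    """
    a, b, c, d = game.matrix
    s1 = a - c  # selection against IN1 invading a resident IN2 population
    s0 = b - d  # selection for IN2 invading a resident IN1 population
    if s1 == 0.0 and s0 == 0.0:
        return ReplicatorResult(x_star=None, regime="neutral", basin_IN2=None)
    if s1 >= 0.0 and s0 >= 0.0:
        return ReplicatorResult(x_star=None, regime="IN2-dominant",
                                basin_IN2=1.0)
    if s1 <= 0.0 and s0 <= 0.0:
        return ReplicatorResult(x_star=None, regime="IN1-dominant",
                                basin_IN2=0.0)
    x_star = -s0 / (s1 - s0)  # = (d - b) / (a - b - c + d)
    if s1 > 0.0 > s0:
        return ReplicatorResult(x_star=x_star, regime="bistable",
                                basin_IN2=1.0 - x_star)
    return ReplicatorResult(x_star=x_star, regime="coexistence",
                            basin_IN2=None)


def integrate_replicator(matrix, x0: float, t_max: float = 600.0,
                         dt: float = 0.01) -> float:
    """Forward-integrate ``ẋ = x(1−x)[(a−c)x + (b−d)(1−x)]`` with fixed-step
    RK4 from ``x0``; absorbs (and returns exactly 0 or 1) once x comes within
    1e-9 of a boundary. Used as the numerical cross-check of the closed-form
    fixed-point analysis."""
    a, b, c, d = matrix

    def f(x):
        return x * (1.0 - x) * ((a - c) * x + (b - d) * (1.0 - x))

    x = float(x0)
    steps = int(t_max / dt)
    for _ in range(steps):
        if x <= ABSORB_TOL:
            return 0.0
        if x >= 1.0 - ABSORB_TOL:
            return 1.0
        k1 = f(x)
        k2 = f(x + 0.5 * dt * k1)
        k3 = f(x + 0.5 * dt * k2)
        k4 = f(x + dt * k3)
        x += dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        x = min(1.0, max(0.0, x))
    return x


def dominance_threshold(p2: float) -> Optional[float]:
    """Smallest Δ at which the egalitarian norm dominates the mini-game.

    Solves ``(1 − p₂)(1 + Δ) = 1``: Δ* = p₂ / (1 − p₂), which lies in (0, 1)
    for 0 < p₂ < 1/2. Returns None for p₂ ≥ 1/2 (no dominance for any Δ — at
    an even split the egalitarian norm draws at best) and also when the
    solution would exceed the admissible range Δ ≤ 1.
    """
    if not (0.0 < p2 <= 0.5):
        raise ValueError("offer level p2 must be in (0, 0.5]")
    if p2 >= 0.5:
        return None
    d_star = p2 / (1.0 - p2)
    return d_star if d_star <= 1.0 else None


def phase_grid(p2_values, delta_values, p1: float = 0.0,
               q1: float = 0.0) -> pd.DataFrame:
    """Regime map of the case-3 mini-game over a (p₂, Δ) grid.

    The less egalitarian norm defaults to the fully selfish [0, 0]; the
    egalitarian norm is the empathetic [p₂, p₂]. Columns:
    ``p2, delta, regime, x_star, basin_IN2``.
    """
    rows = []
    for p2 in np.asarray(p2_values, dtype=float):
        for delta in np.asarray(delta_values, dtype=float):
            game = build_minigame(Norm(p1, q1), Norm(p2, p2), float(delta))
            res = replicator_analyze(game)
            rows.append((p2, delta, res.regime,
                         np.nan if res.x_star is None else res.x_star,
                         np.nan if res.basin_IN2 is None else res.basin_IN2))
    return pd.DataFrame(rows, columns=["p2", "delta", "regime", "x_star",
                                       "basin_IN2"])
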