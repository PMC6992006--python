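"""Population-level observables: fairness, empathy, conformity.

Four variables summarize the collective state:

* fairness — mean offer level ``p̄ = Σ p_i / N`` and mean acceptance level
  ``q̄ = Σ q_i / N``;
* empathy — ``ē = Σ e_i / N`` with ``e_i = 1 − |p_i − q_i| / 0.5``: how close
  an agent's offer is to what it would itself accept;
* collective conformity — ``c̄ = Σ c_i / N`` with
  ``c_i = 1 − ‖(p_i, q_i) − (p̄, q̄)‖ / (√2/2)``: how close individual norms
  sit to the population-mean norm. The normalizer √2/2 is the diameter of the
  norm square [0, 0.5]², so c_i ∈ [0, 1].

Conformity is computed against the *same-step* population means. A
coevolution run additionally tracks the mean intensity ``Δ̄``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .game_core import Norm, PopulationState

__all__ = ["PopulationSummary", "empathy_of", "conformity_of", "summarize",
           "equilibrium_average", "norm_histogram", "summaries_to_frame"]

EMPATHY_NORMALIZER = 0.5
CONFORMITY_NORMALIZER = math.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class PopulationSummary:
    """One row of the collective time series."""

    t: int
    p_bar: float
    q_bar: float
    e_bar: float
    c_bar: float
    delta_bar: float


def empathy_of(norm: Norm) -> float:
    """Empathy level ``e = 1 − |p − q| / 0.5`` of a single norm, in [0, 1]."""
    return 1.0 - abs(norm.p - norm.q) / EMPATHY_NORMALIZER


def conformity_of(norm: Norm, p_bar: float, q_bar: float) -> float:
    """Conformity ``c = 1 − ‖(p, q) − (p̄, q̄)‖ / (√2/2)``, in [0, 1]."""
    dist = math.hypot(norm.p - p_bar, norm.q - q_bar)
    return 1.0 - dist / CONFORMITY_NORMALIZER


def summarize(state: PopulationState, t: int = 0) -> PopulationSummary:
    """Collective summary of a population state at time ``t``."""
    if state.n == 0:
        raise ValueError("cannot summarize an empty population")
    p, q = state.p, state.q
    p_bar = float(p.mean())
    q_bar = float(q.mean())
    e_bar = float(np.mean(1.0 - np.abs(p - q) / EMPATHY_NORMALIZER))
    dist = np.hypot(p - p_bar, q - q_bar)
    c_bar = float(np.mean(1.0 - dist / CONFORMITY_NORMALIZER))
    return PopulationSummary(t=t, p_bar=p_bar, q_bar=q_bar, e_bar=e_bar,
                             c_bar=c_bar, delta_bar=float(state.deltas.mean()))


def summaries_to_frame(series: Iterable[PopulationSummary]) -> pd.DataFrame:
    cols = [f.name for f in fields(PopulationSummary)]
    return pd.DataFrame([[getattr(s, c) for c in cols] for s in series],
                        columns=cols)


def equilibrium_average(series: Sequence[PopulationSummary] | pd.DataFrame,
                        transient: int, window: int) -> PopulationSummary:
    """Arithmetic per-field mean over ``series[transient : transient+window]``.

    Equilibrium values are time averages taken after discarding a transient;
    the series index is position, not the recorded ``t`` column.
    """
    if transient < 0 or window < 1:
        raise ValueError("need transient >= 0 and window >= 1")
    if isinstance(series, pd.DataFrame):
        frame = series
    else:
        frame = summaries_to_frame(series)
    if len(frame) < transient + window:
        raise ValueError(
            f"series of length {len(frame)} too short for "
            f"transient={transient} + window={window}")
    win = frame.iloc[transient:transient + window]
    mean = win.mean()
    return PopulationSummary(t=int(win["t"].iloc[-1]),
                             p_bar=float(mean["p_bar"]),
                             q_bar=float(mean["q_bar"]),
                             e_bar=float(mean["e_bar"]),
                             c_bar=float(mean["c_bar"]),
                             delta_bar=float(mean["delta_bar"]))


def norm_histogram(state: PopulationState, bins: int = 50):
    """2-D histogram of the norm distribution over [0, 0.5]².

    Returns ``(counts, p_edges, q_edges)`` as from ``numpy.histogram2d``;
    mirrors the norm-density snapshots used to visualize the population.
    """
    return np.histogram2d(state.p, state.q, bins=bins,
                          range=[[0.0, 0.5], [0.0, 0.5]])
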