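"""Run orchestration: initialization, the main loop, recording and writers.

One time step = interaction phase → synchronous norm update → (if coevolution
is enabled) ``s·N`` trait micro-steps. The collective summary recorded for
step ``t`` describes the norms *entering* that step, so the first recorded row
is the initial distribution.

A run is fully determined by its configuration and seed: identical
``RunConfig`` ⇒ byte-identical output files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .game_core import (DealLedger, ModelParams, Network, PopulationState,
                        complete_network, interaction_phase, read_edge_list)
from .norm_dynamics import (UpdateConfig, coevolution_phase,
                            norm_update_phase)
from .observables import (PopulationSummary, equilibrium_average, summarize,
                          summaries_to_frame)

__all__ = ["RunConfig", "RunResult", "initialize", "run"]

log = logging.getLogger("egalnorm")

TIMESERIES_COLUMNS = ["t", "p_bar", "q_bar", "e_bar", "c_bar", "delta_bar"]


@dataclass
class RunConfig:
    """Everything a run needs besides code.

    ``transient`` and ``window`` delimit the equilibrium averaging span (in
    recorded rows' time steps); both default to half the horizon. Norm
    initialization modes: ``uniform`` (p, q i.i.d. uniform on [0, 0.5]),
    ``selfish`` (all [0, 0]), ``homogeneous`` ([init_p0, init_q0] with a
    fraction ``violator_fraction`` of uniform-random violators).
    """

    params: ModelParams = field(default_factory=ModelParams)
    n: int = 500
    edge_list: Optional[str] = None   # path; None + n => complete graph
    record_every: int = 1
    transient: Optional[int] = None   # steps discarded before averaging
    window: Optional[int] = None      # steps averaged
    snapshot_times: Sequence[int] = ()
    output_dir: Optional[str] = None
    init_p0: float = 0.4
    init_q0: float = 0.4
    violator_fraction: float = 0.0

    def __post_init__(self):
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        horizon = self.params.horizon
        if self.transient is None:
            self.transient = horizon // 2
        if self.window is None:
            self.window = horizon - self.transient
        if self.transient + self.window > horizon:
            raise ValueError("transient + window exceed the horizon")
        if not (0.0 <= self.violator_fraction <= 1.0):
            raise ValueError("violator_fraction must be in [0, 1]")

    def network(self) -> Network:
        if self.edge_list is None:
            return complete_network(self.n)
        return read_edge_list(self.edge_list, n=self.n or None)

    def update_config(self) -> UpdateConfig:
        p = self.params
        return UpdateConfig(mu=p.mu, K=p.K, eps=p.eps,
                            coevo_enabled=p.s > 0, s=p.s)


@dataclass
class RunResult:
    timeseries: pd.DataFrame
    equilibrium: PopulationSummary
    final_state: PopulationState
    snapshots: dict


def initialize(config: RunConfig,
               rng: np.random.Generator) -> tuple[PopulationState, DealLedger]:
    """Build the initial population and the all-true deal ledger.

    The all-true ledger is the unique boolean state for which every resource
    allocated in the first round equals 1 (unit initial resources). In fixed
    mode every agent carries Δ_i = Δ; with coevolution enabled the population
    starts without any resource-management capability (Δ_i = 0).
    """
    net = config.network()
    n = net.n
    params = config.params
    mode = params.init_mode
    if mode == "uniform":
        p = rng.uniform(0.0, 0.5, size=n)
        q = rng.uniform(0.0, 0.5, size=n)
    elif mode == "selfish":
        p = np.zeros(n)
        q = np.zeros(n)
    elif mode == "homogeneous":
        p = np.full(n, config.init_p0)
        q = np.full(n, config.init_q0)
        n_viol = int(round(config.violator_fraction * n))
        if n_viol:
            idx = rng.choice(n, size=n_viol, replace=False)
            p[idx] = rng.uniform(0.0, 0.5, size=n_viol)
            q[idx] = rng.uniform(0.0, 0.5, size=n_viol)
    else:  # pragma: no cover - ModelParams already rejects this
        raise ValueError(f"unknown init_mode {mode!r}")
    deltas = np.zeros(n) if params.s > 0 else np.full(n, params.delta)
    state = PopulationState(p=p, q=q, deltas=deltas,
                            payoffs=np.zeros(n), network=net)
    return state, DealLedger.all_true(net)


def run(config: RunConfig) -> RunResult:
    """Execute a full run and (optionally) write its outputs.

    Returns the recorded time series, the equilibrium-window average, the
    final state and any requested snapshots. When ``config.output_dir`` is
    set, writes ``timeseries.csv``, ``snapshot_t<step>.csv`` files and a
    ``manifest.txt`` with the config hash, seed and package version.
    """
    params = config.params
    rng = np.random.default_rng(params.seed)
    state, ledger = initialize(config, rng)
    ucfg = config.update_config()
    if (state.network.degrees == 0).any():
        log.warning("network has isolated nodes; their payoff is fixed at 0")

    records: list[PopulationSummary] = []
    snapshots: dict[int, pd.DataFrame] = {}
    snap_times = set(int(t) for t in config.snapshot_times)

    for t in range(1, params.horizon + 1):
        if t == 1 or t % config.record_every == 0:
            records.append(summarize(state, t))
        if t in snap_times:
            snapshots[t] = pd.DataFrame({
                "agent_id": np.arange(state.n), "p": state.p, "q": state.q,
                "delta": state.deltas})
        payoffs, ledger = interaction_phase(state, ledger, params)
        state.payoffs = payoffs
        new_p, new_q = norm_update_phase(state, payoffs, ucfg, rng)
        state.p, state.q = new_p, new_q
        if ucfg.coevo_enabled:
            state.deltas = coevolution_phase(state, payoffs, ucfg, rng)
        _check_invariants(state, t)

    frame = summaries_to_frame(records)
    eq = _window_average(frame, config)
    result = RunResult(timeseries=frame, equilibrium=eq,
                       final_state=state, snapshots=snapshots)
    if config.output_dir is not None:
        _write_outputs(config, result)
    return result


def _check_invariants(state: PopulationState, t: int) -> None:
    # cheap O(N) guards; a violation indicates a programming error
    if not (np.all((state.p >= 0.0) & (state.p <= 0.5))
            and np.all((state.q >= 0.0) & (state.q <= 0.5))):
        raise RuntimeError(f"norm outside [0, 0.5] at step {t}")
    if not np.all((state.deltas >= 0.0) & (state.deltas <= 1.0)):
        raise RuntimeError(f"delta outside [0, 1] at step {t}")
    if not (np.all(np.isfinite(state.payoffs)) and np.all(state.payoffs >= 0)):
        raise RuntimeError(f"non-finite or negative payoff at step {t}")


def _window_average(frame: pd.DataFrame, config: RunConfig) -> PopulationSummary:
    # select recorded rows falling inside [transient+1, transient+window]
    lo, hi = config.transient, config.transient + config.window
    win = frame[(frame["t"] > lo) & (frame["t"] <= hi)]
    if win.empty:
        raise ValueError("no recorded rows inside the equilibrium window")
    return equilibrium_average(win.reset_index(drop=True), 0, len(win))


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_outputs(config: RunConfig, result: RunResult) -> None:
    out = Path(config.output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        result.timeseries.to_csv(out / "timeseries.csv", index=False,
                                 float_format="%.10g")
        for t, snap in result.snapshots.items():
            snap.to_csv(out / f"snapshot_t{t}.csv", index=False,
                        float_format="%.10g")
        eq = result.equilibrium
        manifest = (
            f"egalnorm {__version__}\n"
            f"config_hash {_config_hash(config)}\n"
            f"seed {config.params.seed}\n"
            f"equilibrium p_bar={eq.p_bar:.6f} q_bar={eq.q_bar:.6f} "
            f"e_bar={eq.e_bar:.6f} c_bar={eq.c_bar:.6f} "
            f"delta_bar={eq.delta_bar:.6f}\n")
        (out / "manifest.txt").write_text(manifest)
    except OSError as exc:
        raise OSError(f"failed writing outputs under {out}: {exc}") from exc
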