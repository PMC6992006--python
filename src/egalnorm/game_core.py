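"""Core game mechanics: norms, deal resolution, resource allocation, payoffs.

The model is a continuous Ultimatum Game on a network. Each agent carries an
individual norm ``IN = [p, q]``: when proposing it offers the fraction ``p`` of
the resource at stake, and when responding it accepts any offer of at least
``q``. Both components live in ``[0, 0.5]`` (a rational proposer never offers
more than half). Within one interaction phase every connected pair plays two
deals — one per proposer role.

Resource management couples consecutive rounds: each pair remembers whether
each of its two deals succeeded last round (the *deal ledger*) and shifts this
round's resources toward the deal that previously worked, with intensity
``Δ ∈ [0, 1]``:

=====================  =====================
previous outcome        current resources
(i→j, j→i)              (R_i, R_j)
=====================  =====================
success, success        (1, 1)
success, failure        (1 + Δ, 1 − Δ)
failure, success        (1 − Δ, 1 + Δ)
failure, failure        (1, 1)
=====================  =====================

The pair total ``R_i + R_j = 2`` is conserved, so resource management
redistributes — it never creates — resources.

Acceptance is a Heaviside rule with ties accepted: an offer ``p`` against a
threshold ``q`` succeeds iff ``p ≥ q`` (``H(0) = 1``). This matters on the
boundary: an agent playing against a copy of itself always reaches agreement
when it is self-compatible (``p ≥ q``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

__all__ = [
    "Norm",
    "Network",
    "DealLedger",
    "ModelParams",
    "PopulationState",
    "resolve_deal",
    "allocate_resources",
    "pair_payoff",
    "interaction_phase",
    "complete_network",
    "network_from_edges",
    "read_edge_list",
]

NORM_LOW = 0.0
NORM_HIGH = 0.5


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Norm:
    """An individual norm ``IN = [p, q]``.

    Parameters
    ----------
    p : float
        Offer level — fraction of the resource given away when proposing.
    q : float
        Acceptance threshold — minimum fraction accepted when responding.

    Both components must lie in ``[0, 0.5]``.
    """

    p: float
    q: float

    def __post_init__(self):
        if not (NORM_LOW <= self.p <= NORM_HIGH):
            raise ValueError(f"offer level p={self.p} outside [0, 0.5]")
        if not (NORM_LOW <= self.q <= NORM_HIGH):
            raise ValueError(f"acceptance threshold q={self.q} outside [0, 0.5]")

    @property
    def self_compatible(self) -> bool:
        """True if the agent would accept its own offer (p >= q)."""
        return self.p >= self.q


@dataclass
class Network:
    """Interaction structure.

    Either a complete graph on ``n`` nodes (``edges is None``) or an arbitrary
    undirected simple graph given by an ``(E, 2)`` integer edge array. Complete
    graphs get a dense vectorized fast path in :func:`interaction_phase`; the
    behavioural contract of the two paths is identical.
    """

    n: int
    edges: np.ndarray | None = None  # (E, 2) int array, or None for complete
    neighbors: list = field(default_factory=list, repr=False)
    degrees: np.ndarray = field(default=None, repr=False)

    @property
    def complete(self) -> bool:
        return self.edges is None

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("network needs at least one node")
        if self.edges is None:
            self.degrees = np.full(self.n, self.n - 1, dtype=np.int64)
            return
        e = np.asarray(self.edges, dtype=np.int64)
        if e.ndim != 2 or e.shape[1] != 2:
            raise ValueError("edges must be an (E, 2) array")
        if e.size and (e.min() < 0 or e.max() >= self.n):
            raise ValueError("edge endpoint outside [0, n)")
        if np.any(e[:, 0] == e[:, 1]):
            raise ValueError("self-loops are not allowed")
        self.edges = e
        self.degrees = np.bincount(e.ravel(), minlength=self.n)
        nbrs = [[] for _ in range(self.n)]
        for u, v in e:
            nbrs[u].append(v)
            nbrs[v].append(u)
        self.neighbors = [np.array(sorted(a), dtype=np.int64) for a in nbrs]


def complete_network(n: int) -> Network:
    """Fully connected network on ``n`` nodes."""
    return Network(n=n)


def network_from_edges(n: int, edges) -> Network:
    return Network(n=n, edges=np.asarray(edges, dtype=np.int64))


def read_edge_list(path, n: int | None = None) -> Network:
    """Read a plain-text edge list: one undirected edge per line, two
    whitespace-separated 0-based node ids. ``n`` defaults to max id + 1."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            u, v = line.split()[:2]
            edges.append((int(u), int(v)))
    e = np.asarray(edges, dtype=np.int64)
    if n is None:
        n = int(e.max()) + 1 if e.size else 0
    return Network(n=n, edges=e)


@dataclass
class DealLedger:
    """Per ordered pair memory of the previous round's deal outcomes.

    For every ordered neighbour pair ``(i proposer → j responder)`` the ledger
    stores one boolean: did that deal reach agreement last round? At the start
    of evolution every entry is true, which makes every allocated resource
    equal to 1 (unit initial resources).

    Storage is a dense boolean matrix for complete graphs and two edge-aligned
    arrays (one per direction) for sparse graphs; the contract is identical.
    The ledger is attached to the *pair*, not the norm: it persists when an
    agent changes norm.
    """

    network: Network
    matrix: np.ndarray | None = None  # (N, N) bool, complete graphs
    s_uv: np.ndarray | None = None    # (E,) bool, edge u -> v
    s_vu: np.ndarray | None = None    # (E,) bool, edge v -> u

    @classmethod
    def all_true(cls, network: Network) -> "DealLedger":
        if network.complete:
            return cls(network=network,
                       matrix=np.ones((network.n, network.n), dtype=bool))
        e = len(network.edges)
        return cls(network=network,
                   s_uv=np.ones(e, dtype=bool),
                   s_vu=np.ones(e, dtype=bool))

    def success(self, i: int, j: int) -> bool:
        """Outcome of the previous deal with ``i`` proposing to ``j``."""
        if self.network.complete:
            return bool(self.matrix[i, j])
        e = self.network.edges
        hit = np.flatnonzero((e[:, 0] == i) & (e[:, 1] == j))
        if hit.size:
            return bool(self.s_uv[hit[0]])
        hit = np.flatnonzero((e[:, 0] == j) & (e[:, 1] == i))
        if hit.size:
            return bool(self.s_vu[hit[0]])
        raise KeyError(f"({i}, {j}) is not an edge")


@dataclass
class ModelParams:
    """Model parameters.

    Parameters
    ----------
    delta : float
        Resource-management intensity Δ in [0, 1]. Δ = 0 disables resource
        management (all resources stay at 1).
    mu : float
        Exploration rate: probability an agent adopts a fresh uniform-random
        norm instead of imitating.
    K : float
        Selection noise of the Fermi imitation rule; must be > 0.
    eps : float
        Learning-error half-range: imitated norm components are perturbed by
        i.i.d. uniform noise on [-eps, eps].
    s : float
        Time-scale ratio of norm evolution to resource-management evolution.
        s > 0 enables coevolution of per-agent Δ_i (s·N pairwise-comparison
        micro-steps per time step); s = 0 keeps Δ fixed.
    horizon : int
        Number of time steps to simulate.
    seed : int
        RNG seed; a run is bit-reproducible given seed and config.
    init_mode : str
        One of {"uniform", "selfish", "homogeneous"}.
    """

    delta: float = 1.0
    mu: float = 0.0
    K: float = 0.1
    eps: float = 5e-3
    s: float = 0.0
    horizon: int = 5000
    seed: int = 0
    init_mode: str = "uniform"

    def __post_init__(self):
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError(f"delta={self.delta} outside [0, 1]")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError(f"mu={self.mu} outside [0, 1]")
        if self.K <= 0:
            raise ValueError("noise K must be positive")
        if self.eps < 0:
            raise ValueError("learning-error range eps must be >= 0")
        if self.s < 0:
            raise ValueError("time-scale ratio s must be >= 0")
        if self.init_mode not in ("uniform", "selfish", "homogeneous"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")


@dataclass
class PopulationState:
    """All per-agent state: norms, Δ_i, last payoffs, and the network."""

    p: np.ndarray        # (N,) offer levels
    q: np.ndarray        # (N,) acceptance thresholds
    deltas: np.ndarray   # (N,) per-agent resource-management intensity
    payoffs: np.ndarray  # (N,) average payoff from the last interaction phase
    network: Network

    @property
    def n(self) -> int:
        return len(self.p)

    def norm(self, i: int) -> Norm:
        return Norm(float(self.p[i]), float(self.q[i]))

    def copy(self) -> "PopulationState":
        return replace(self, p=self.p.copy(), q=self.q.copy(),
                       deltas=self.deltas.copy(), payoffs=self.payoffs.copy())


# ---------------------------------------------------------------------------
# Scalar operations
# ---------------------------------------------------------------------------


def resolve_deal(proposer: Norm, responder: Norm) -> bool:
    """Does the deal succeed? True iff ``proposer.p >= responder.q``.

    Ties are accepted: the acceptance rule is the Heaviside step with
    ``H(0) = 1``, so an offer exactly at the threshold goes through.
    """
    return proposer.p >= responder.q


def allocate_resources(prev_success_ij: bool, prev_success_ji: bool,
                       delta: float) -> tuple[float, float]:
    """Resources for the pair's two current deals, given last round's outcomes.

    Implements the four-case adaptive scheme, equivalent to the closed form
    ``R_i = 1 + Δ·(S_ij − S_ji)`` with ``S ∈ {0, 1}``; ``R_i + R_j = 2``
    always.
    """
    if not (0.0 <= delta <= 1.0):
        raise ValueError(f"delta={delta} outside [0, 1]")
    r_i = 1.0 + delta * (int(prev_success_ij) - int(prev_success_ji))
    return r_i, 2.0 - r_i


def pair_payoff(norm_i: Norm, norm_j: Norm, r_i: float, r_j: float) -> float:
    """Payoff agent *i* collects from its two deals with *j*.

    ``P(IN_i, IN_j) = (1 − p_i)·H(p_i − q_j)·R_i + p_j·H(p_j − q_i)·R_j``:
    the retained share of i's own successful proposal plus the received share
    of j's successful proposal.
    """
    if r_i < 0 or r_j < 0:
        raise ValueError("resources must be non-negative")
    own = (1.0 - norm_i.p) * r_i if resolve_deal(norm_i, norm_j) else 0.0
    recv = norm_j.p * r_j if resolve_deal(norm_j, norm_i) else 0.0
    return own + recv


# ---------------------------------------------------------------------------
# Interaction phase
# ---------------------------------------------------------------------------


def _pair_delta_dense(state: PopulationState) -> Union[float, np.ndarray]:
    d = state.deltas
    if np.ptp(d) == 0.0:
        return float(d[0])
    # coevolution: the pair uses the more conservative of the two intensities
    return np.minimum(d[:, None], d[None, :])


def _workspace(network: Network) -> dict:
    ws = getattr(network, "_ws", None)
    if ws is None or ws["a"].shape[0] != network.n:
        n = network.n
        ws = {"a": np.empty((n, n)), "b": np.empty((n, n)),
              "c": np.empty((n, n))}
        network._ws = ws
    return ws


def _interaction_complete(state, ledger):
    # dense O(N^2) fast path; same contract as the per-edge loop
    p, q = state.p, state.q
    n = state.n
    if n == 1:
        return np.zeros(1), DealLedger(network=state.network,
                                       matrix=ledger.matrix.copy())
    ws = _workspace(state.network)
    a, b = ws["a"], ws["b"]
    success = p[:, None] >= q[None, :]        # deal i -> j succeeds now
    a[:] = ledger.matrix                      # bool -> float copy
    b[:] = a.T
    np.subtract(a, b, out=a)                  # S_prev - S_prev^T
    deltas = state.deltas
    if np.ptp(deltas) == 0.0:
        a *= float(deltas[0])
    else:
        # coevolution: pair uses the more conservative intensity
        np.minimum(deltas[:, None], deltas[None, :], out=ws["c"])
        a *= ws["c"]
    a += 1.0                                  # resource of deal i -> j
    np.multiply(a, success, out=a)            # realized split size
    b[:] = a.T
    b *= p[None, :]                           # share received as responder
    a *= (1.0 - p)[:, None]                   # share kept as proposer
    a += b
    np.fill_diagonal(a, 0.0)
    payoffs = a.sum(axis=1)
    payoffs /= n - 1
    return payoffs, DealLedger(network=state.network, matrix=success)


def _interaction_sparse(state, ledger):
    p, q, d = state.p, state.q, state.deltas
    net = state.network
    u, v = net.edges[:, 0], net.edges[:, 1]
    if np.ptp(d) == 0.0:
        delta_e = float(d[0]) if len(d) else 0.0
    else:
        delta_e = np.minimum(d[u], d[v])
    s_uv = p[u] >= q[v]
    s_vu = p[v] >= q[u]
    r_uv = 1.0 + delta_e * (ledger.s_uv.astype(np.float64)
                            - ledger.s_vu.astype(np.float64))
    r_vu = 2.0 - r_uv
    g_uv = s_uv * r_uv
    g_vu = s_vu * r_vu
    pay_u = (1.0 - p[u]) * g_uv + p[v] * g_vu
    pay_v = (1.0 - p[v]) * g_vu + p[u] * g_uv
    total = (np.bincount(u, weights=pay_u, minlength=net.n)
             + np.bincount(v, weights=pay_v, minlength=net.n))
    deg = net.degrees
    payoffs = np.divide(total, deg, out=np.zeros(net.n), where=deg > 0)
    new = DealLedger(network=net, s_uv=s_uv, s_vu=s_vu)
    return payoffs, new


def interaction_phase(state: PopulationState, ledger: DealLedger,
                      params: ModelParams | None = None):
    """Play one full round of Ultimatum Games along every edge.

    Every agent plays each neighbour twice (once per proposer role). Resources
    come from :func:`allocate_resources` applied to the ledger; with per-agent
    Δ_i the pair uses ``Δ = min(Δ_i, Δ_j)``. Returns the per-agent average
    payoff (mean over neighbours of :func:`pair_payoff`; isolated agents get
    payoff 0) and the ledger of this round's outcomes.
    """
    if state.network.complete:
        return _interaction_complete(state, ledger)
    return _interaction_sparse(state, ledger)
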