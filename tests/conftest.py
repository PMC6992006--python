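import numpy as np
import pytest

from egalnorm import DealLedger, PopulationState, complete_network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_state(p, q, deltas=None, network=None):
    """Population state from explicit arrays; complete graph by default."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    n = len(p)
    if deltas is None:
        deltas = np.zeros(n)
    if network is None:
        network = complete_network(n)
    return PopulationState(p=p, q=q, deltas=np.asarray(deltas, dtype=float),
                           payoffs=np.zeros(n), network=network)


@pytest.fixture
def two_agent_conflict():
    """Generous [0.4, 0.3] vs less generous [0.2, 0.1] with Δ = 1.

    The pair has a one-sided persistent conflict: the generous offer is
    accepted, the stingy one rejected.
    """
    state = make_state([0.4, 0.2], [0.3, 0.1], deltas=[1.0, 1.0])
    return state, DealLedger.all_true(state.network)
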