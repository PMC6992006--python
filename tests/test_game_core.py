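"""Deal resolution, resource allocation and payoff mechanics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egalnorm import (DealLedger, ModelParams, Norm, allocate_resources,
                      complete_network, interaction_phase, network_from_edges,
                      pair_payoff, read_edge_list, resolve_deal)
from egalnorm.observables import summarize

from conftest import make_state

norms = st.builds(Norm,
                  p=st.floats(0, 0.5, allow_nan=False),
                  q=st.floats(0, 0.5, allow_nan=False))


class TestNorm:
    @pytest.mark.parametrize("p,q", [(-0.1, 0.2), (0.6, 0.2), (0.2, 0.51)])
    def test_out_of_range_rejected(self, p, q):
        with pytest.raises(ValueError):
            Norm(p, q)

    def test_self_compatibility(self):
        assert Norm(0.3, 0.3).self_compatible
        assert not Norm(0.1, 0.3).self_compatible


class TestResolveDeal:
    @pytest.mark.parametrize("p,q,expect", [
        (0.3, 0.3, True),   # tie accepted: H(0) = 1
        (0.2, 0.3, False),
        (0.4, 0.1, True),
    ])
    def test_acceptance_rule(self, p, q, expect):
        assert resolve_deal(Norm(p, 0.0), Norm(0.5, q)) is expect


class TestAllocateResources:
    # the four-case table: (prev i->j, prev j->i) -> (R_i, R_j) as Δ-functions
    TABLE = {
        (True, True): lambda d: (1.0, 1.0),
        (True, False): lambda d: (1.0 + d, 1.0 - d),
        (False, True): lambda d: (1.0 - d, 1.0 + d),
        (False, False): lambda d: (1.0, 1.0),
    }

    @pytest.mark.parametrize("sij,sji", list(itertools.product([True, False],
                                                               repeat=2)))
    @pytest.mark.parametrize("delta", np.linspace(0, 1, 11).tolist())
    def test_matches_four_case_table(self, sij, sji, delta):
        r_i, r_j = allocate_resources(sij, sji, delta)
        expect = self.TABLE[(sij, sji)](delta)
        assert (r_i, r_j) == pytest.approx(expect)
        assert r_i + r_j == pytest.approx(2.0)  # conservation, exactly
        assert r_i >= 0 and r_j >= 0

    @pytest.mark.parametrize("delta", [-0.1, 1.1])
    def test_delta_out_of_range(self, delta):
        with pytest.raises(ValueError):
            allocate_resources(True, False, delta)

    @pytest.mark.parametrize("examples", [
        ((True, True, 1.0), (1.0, 1.0)),
        ((True, False, 1.0), (2.0, 0.0)),
        ((False, False, 0.5), (1.0, 1.0)),
        ((False, True, 0.5), (0.5, 1.5)),
    ])
    def test_reference_points(self, examples):
        args, expect = examples
        assert allocate_resources(*args) == pytest.approx(expect)


class TestPairPayoff:
    def test_generous_vs_stingy_unit_resources(self):
        gen, sting = Norm(0.4, 0.3), Norm(0.2, 0.1)
        assert pair_payoff(gen, sting, 1, 1) == pytest.approx(0.6)
        assert pair_payoff(sting, gen, 1, 1) == pytest.approx(0.4)

    def test_even_split_diagonal(self):
        half = Norm(0.5, 0.5)
        assert pair_payoff(half, half, 1, 1) == pytest.approx(1.0)

    def test_after_resource_shift(self):
        # stationary conflict at Δ=1: generous proposer's deal carries R=2
        gen, sting = Norm(0.4, 0.3), Norm(0.2, 0.1)
        assert pair_payoff(gen, sting, 2, 0) == pytest.approx(1.2)
        assert pair_payoff(sting, gen, 0, 2) == pytest.approx(0.8)

    def test_negative_resource_rejected(self):
        with pytest.raises(ValueError):
            pair_payoff(Norm(0.4, 0.3), Norm(0.2, 0.1), -1, 3)

    @settings(deadline=None, max_examples=200)
    @given(a=norms, b=norms, r=st.floats(0, 2, allow_nan=False))
    def test_bounded_by_total_resource(self, a, b, r):
        assert 0.0 <= pair_payoff(a, b, r, 2 - r) <= 2.0


class TestInteractionPhase:
    def test_homogeneous_even_split_pair(self):
        state = make_state([0.5, 0.5], [0.5, 0.5], deltas=[0.7, 0.7])
        pay, led = interaction_phase(state, DealLedger.all_true(state.network))
        assert pay == pytest.approx([1.0, 1.0])
        assert led.success(0, 1) and led.success(1, 0)

    def test_two_agent_conflict_recursion(self, two_agent_conflict):
        state, ledger = two_agent_conflict
        pay1, ledger = interaction_phase(state, ledger)
        assert pay1 == pytest.approx([0.6, 0.4])
        pay2, ledger = interaction_phase(state, ledger)
        assert pay2 == pytest.approx([1.2, 0.8])
        pay3, ledger = interaction_phase(state, ledger)  # stationary
        assert pay3 == pytest.approx([1.2, 0.8])

    def test_triangle_of_identical_compatible_norms(self):
        state = make_state([0.25] * 3, [0.25] * 3, deltas=[0.3] * 3)
        pay, _ = interaction_phase(state, DealLedger.all_true(state.network))
        assert pay == pytest.approx([1.0, 1.0, 1.0])

    def test_homogeneous_payoff_stays_one(self, rng):
        # any homogeneous self-compatible population: payoff exactly 1 forever
        state = make_state([0.31] * 6, [0.22] * 6, deltas=[0.9] * 6)
        ledger = DealLedger.all_true(state.network)
        for _ in range(5):
            pay, ledger = interaction_phase(state, ledger)
            assert pay == pytest.approx(np.ones(6))

    @pytest.mark.parametrize("all_success", [True, False])
    def test_delta_invariance_off_conflict_path(self, all_success):
        # if last round's deals all succeeded (or all failed), Δ is irrelevant
        if all_success:
            p, q = [0.3, 0.2], [0.1, 0.2]   # every offer accepted
        else:
            p, q = [0.1, 0.2], [0.4, 0.45]  # every offer rejected
        results = []
        for delta in (0.0, 0.5, 1.0):
            state = make_state(p, q, deltas=[delta, delta])
            ledger = DealLedger.all_true(state.network)
            rounds = []
            for _ in range(3):  # covers prev all-success and prev all-failed
                pay, ledger = interaction_phase(state, ledger)
                rounds.append(pay)
            results.append(np.concatenate(rounds))
        assert results[0] == pytest.approx(results[1])
        assert results[0] == pytest.approx(results[2])

    def test_sparse_path_matches_dense_on_complete_graph(self, rng):
        n = 12
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
        p, q = rng.uniform(0, 0.5, n), rng.uniform(0, 0.5, n)
        deltas = rng.uniform(0, 1, n)
        dense = make_state(p, q, deltas)
        sparse = make_state(p, q, deltas, network=network_from_edges(n, edges))
        pd_, ld = interaction_phase(dense, DealLedger.all_true(dense.network))
        ps_, ls = interaction_phase(sparse,
                                    DealLedger.all_true(sparse.network))
        np.testing.assert_allclose(pd_, ps_)
        pd2, _ = interaction_phase(dense, ld)
        ps2, _ = interaction_phase(sparse, ls)
        np.testing.assert_allclose(pd2, ps2)

    def test_isolated_node_gets_zero_payoff(self):
        net = network_from_edges(3, [(0, 1)])  # node 2 isolated
        state = make_state([0.3, 0.3, 0.3], [0.2, 0.2, 0.2], network=net)
        pay, _ = interaction_phase(state, DealLedger.all_true(net))
        assert pay[2] == 0.0
        assert pay[0] > 0 and pay[1] > 0

    def test_payoffs_finite_nonnegative_random_states(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 30))
            state = make_state(rng.uniform(0, 0.5, n), rng.uniform(0, 0.5, n),
                               rng.uniform(0, 1, n))
            ledger = DealLedger.all_true(state.network)
            for _ in range(3):
                pay, ledger = interaction_phase(state, ledger)
            assert np.all(np.isfinite(pay)) and np.all(pay >= 0)
            assert np.all(pay <= 2.0)


class TestConservation:
    def test_total_payoff_equals_total_resource(self, rng):
        # mutually acceptable self-compatible norms: every deal succeeds,
        # so the population-wide payoff equals the resource put at stake
        n = 20
        q = rng.uniform(0, 0.2, n)
        p = rng.uniform(0.25, 0.5, n)  # all offers above every threshold
        for delta in (0.0, 1.0):
            state = make_state(p, q, deltas=[delta] * n)
            ledger = DealLedger.all_true(state.network)
            for _ in range(3):
                pay, ledger = interaction_phase(state, ledger)
                assert pay.sum() == pytest.approx(n)


class TestNetworkIO:
    def test_read_edge_list(self, tmp_path):
        path = tmp_path / "net.txt"
        path.write_text("# a comment\n0 1\n1 2\n\n2 3\n")
        net = read_edge_list(path)
        assert net.n == 4
        assert net.degrees.tolist() == [1, 2, 2, 1]

    def test_invalid_edges_rejected(self):
        with pytest.raises(ValueError):
            network_from_edges(3, [(0, 3)])
        with pytest.raises(ValueError):
            network_from_edges(3, [(1, 1)])

    def test_ledger_success_lookup_sparse(self):
        net = network_from_edges(3, [(0, 1), (1, 2)])
        led = DealLedger.all_true(net)
        assert led.success(0, 1) and led.success(1, 0)
        with pytest.raises(KeyError):
            led.success(0, 2)


class TestModelParams:
    @pytest.mark.parametrize("kwargs", [
        dict(delta=1.2), dict(mu=-0.1), dict(K=0.0), dict(eps=-1e-3),
        dict(s=-1.0), dict(init_mode="bogus"),
    ])
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)
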