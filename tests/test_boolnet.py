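"""Ternary Boolean network enumeration, checked against brute force.

The brute-force oracle enumerates complete networks (every sign assignment
to every permitted edge) and simulates each one with the synchronous update,
deliberately ignoring the per-target factorization the implementation uses.
"""

import itertools

import numpy as np
import pytest

import psdanet as pn
from psdanet.boolnet import InfeasibleTrajectoryError, _minimal_vectors
from psdanet.data import ValidationError

from oracles import (brute_force_count as _brute_force_count,
                     brute_force_count_vectorized as _brute_force_count_vectorized,
                     make_trajectory as _traj,
                     random_trajectory as _random_trajectory)


class TestStep:
    def test_one_node_positive_self_edge_bistable(self):
        net = pn.TernaryNetwork(["input", "C1"],
                                np.array([[0, 0], [0, 1]]))
        assert pn.step(net, [1, 1]).tolist() == [1, 1]
        assert pn.step(net, [1, 0]).tolist() == [1, 0]  # h = 0 -> hold

    def test_one_node_negative_self_edge_decays(self):
        net = pn.TernaryNetwork(["input", "C1"],
                                np.array([[0, 0], [0, -1]]))
        assert pn.step(net, [1, 1]).tolist() == [1, 0]
        assert pn.step(net, [1, 0]).tolist() == [1, 0]

    def test_agrees_with_truth_table_oracle_on_random_networks(self):
        """step() vs a per-node reimplementation on all 2^3 free states."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = rng.integers(-1, 2, size=(4, 4))
            a[:, 0] = 0
            net = pn.TernaryNetwork(["input", "A", "B", "C"], a)
            for bits in itertools.product((0, 1), repeat=3):
                state = np.array((1,) + bits)
                got = pn.step(net, state)
                exp = state.copy()
                for i in range(4):
                    h = sum(state[j] * a[j, i] for j in range(4))
                    exp[i] = 1 if h > 0 else (0 if h < 0 else state[i])
                exp[0] = 1
                np.testing.assert_array_equal(got, exp)

    def test_input_without_incoming_edges_enforced(self):
        with pytest.raises(ValidationError):
            pn.TernaryNetwork(["input", "C1"], np.array([[0, 1], [1, 0]]))


class TestConsistentVectors:
    def test_single_state_trajectory_vacuous(self):
        traj = _traj([[1, 0, 1]])
        _, kept = pn.consistent_input_vectors(1, traj, allow_self=True)
        assert len(kept) == 27  # 3^3: no constraint at all

    def test_copy_of_input_with_idle_sources(self):
        # C1 switches on after the input; C2 stays 0
        traj = _traj([[1, 0, 0], [1, 1, 0]])
        sources, kept = pn.consistent_input_vectors(1, traj, allow_self=True)
        kept_set = {tuple(v) for v in kept}
        # brute force over all 27 vectors with the same rule
        expected = set()
        for v in itertools.product((-1, 0, 1), repeat=3):
            good = True
            for prev, nxt in traj.transitions():
                h = int(prev[sources] @ np.array(v))
                pred = 1 if h > 0 else (0 if h < 0 else prev[1])
                if pred != nxt[1]:
                    good = False
                    break
            if good:
                expected.add(v)
        assert kept_set == expected
        # every kept vector must produce ON from the all-off start: +1 from input
        assert all((np.array(v) @ np.array([1, 0, 0])) > 0 for v in kept_set)

    def test_contradictory_target_reports_infeasible(self):
        # C1 must both rise and fall while all sources are constant
        traj = _traj([[1, 0, 0], [1, 1, 0], [1, 0, 0]])
        with pytest.raises(InfeasibleTrajectoryError, match="C1"):
            pn.consistent_input_vectors(1, traj, allow_self=False)


class TestCounting:
    def test_single_state_count_is_three_to_the_six(self):
        traj = _traj([[1, 0, 1]])
        assert pn.count_consistent_networks(traj, allow_self=True) == 3 ** 6

    @pytest.mark.parametrize("allow_self", [True, False])
    def test_product_count_matches_brute_force_n2(self, allow_self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            traj = _random_trajectory(rng, n_free=2, n_steps=rng.integers(2, 5))
            assert (pn.count_consistent_networks(traj, allow_self)
                    == _brute_force_count(traj, allow_self))

    def test_product_count_matches_vectorized_brute_force_n3(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            traj = _random_trajectory(rng, n_free=3, n_steps=rng.integers(2, 4))
            assert (pn.count_consistent_networks(traj, allow_self=True)
                    == _brute_force_count_vectorized(traj, allow_self=True))

    def test_infeasible_trajectory_counts_zero(self):
        traj = _traj([[1, 0, 0], [1, 1, 0], [1, 0, 0]])
        assert pn.count_consistent_networks(traj, allow_self=False) == 0


class TestMinimalNetworks:
    def test_support_inclusion_example(self):
        kept = np.array([[1, 0], [1, 1]])
        mins = _minimal_vectors(kept)
        assert [v.tolist() for v in mins] == [[1, 0]]

    def test_minimal_equals_deletion_critical_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            traj = _random_trajectory(rng, n_free=2, n_steps=3)
            try:
                mins = pn.minimal_networks(traj, allow_self=True)
            except InfeasibleTrajectoryError:
                continue
            # oracle: scan all complete networks for consistent ones whose
            # every single-edge deletion is inconsistent
            n = traj.n_nodes
            slots = [(j, i) for i in range(1, n) for j in range(n)]
            expected = []
            for signs in itertools.product((-1, 0, 1), repeat=len(slots)):
                a = np.zeros((n, n), dtype=int)
                for (j, i), s in zip(slots, signs):
                    a[j, i] = s
                net = pn.TernaryNetwork(list(traj.node_names), a)
                if not pn.is_consistent(net, traj):
                    continue
                critical = True
                for j, i in zip(*np.nonzero(a)):
                    b = a.copy()
                    b[j, i] = 0
                    if pn.is_consistent(pn.TernaryNetwork(list(traj.node_names), b),
                                        traj):
                        critical = False
                        break
                if critical:
                    expected.append(a)
            got = sorted(net.adjacency.tobytes() for net in mins)
            exp = sorted(a.astype(mins[0].adjacency.dtype).tobytes()
                         for a in expected) if mins else []
            assert got == exp

    def test_every_minimal_network_is_consistent_and_critical(self, ):
        traj = _traj([[1, 0, 0, 0], [1, 1, 0, 0], [1, 1, 1, 0], [1, 1, 1, 1]])
        for net in pn.minimal_networks(traj):
            assert pn.is_consistent(net, traj)
            for j, i in zip(*np.nonzero(net.adjacency)):
                a = net.adjacency.copy()
                a[j, i] = 0
                assert not pn.is_consistent(
                    pn.TernaryNetwork(list(net.node_names), a), traj)


class TestEdgeClassification:
    def test_rigid_interchangeable_by_definition(self):
        # target C1 must copy the input; C2 is always 0 so its edge is free
        traj = _traj([[1, 0, 0], [1, 1, 0]])
        labels = pn.classify_edges(traj, allow_self=False)
        assert labels[("input", "C1")] == "rigid"
        assert labels[("C1", "C2")] == "interchangeable"

    def test_labels_match_brute_force_scan(self):
        rng = np.random.default_rng(11)
        traj = _random_trajectory(rng, 2, 3)
        try:
            labels = pn.classify_edges(traj, allow_self=True)
        except InfeasibleTrajectoryError:
            pytest.skip("sampled trajectory infeasible")
        n = traj.n_nodes
        slots = [(j, i) for i in range(1, n) for j in range(n)]
        seen = {slot: set() for slot in slots}
        for signs in itertools.product((-1, 0, 1), repeat=len(slots)):
            a = np.zeros((n, n), dtype=int)
            for slot, s in zip(slots, signs):
                a[slot] = s
            if pn.is_consistent(pn.TernaryNetwork(list(traj.node_names), a), traj):
                for slot, s in zip(slots, signs):
                    seen[slot].add(s)
        for (j, i), signs in seen.items():
            key = (traj.node_names[j], traj.node_names[i])
            if signs == {0}:
                assert labels[key] == "forbidden"
            elif len(signs) == 1:
                assert labels[key] == "rigid"
            else:
                assert labels[key] == "interchangeable"

    def test_equivariant_under_node_relabeling(self):
        states = [[1, 0, 1], [1, 1, 1], [1, 1, 0]]
        traj = _traj(states, ["input", "X", "Y"])
        swapped = _traj([[s[0], s[2], s[1]] for s in states], ["input", "Y", "X"])
        la = pn.classify_edges(traj)
        lb = pn.classify_edges(swapped)
        assert la == lb


class TestPriorConstraints:
    def _nets(self):
        traj = _traj([[1, 0, 0], [1, 1, 0], [1, 1, 1]])
        return pn.minimal_networks(traj)

    def test_empty_constraints_identity(self):
        nets = self._nets()
        assert pn.apply_prior_constraints(nets) == nets

    def test_required_edge_filters_exactly(self):
        nets = self._nets()
        required = [("input", "C1", 1)]
        kept = pn.apply_prior_constraints(nets, required=required)
        idx = {n: i for i, n in enumerate(nets[0].node_names)}
        assert all(n.adjacency[idx["input"], idx["C1"]] == 1 for n in kept)
        assert len(kept) == sum(n.adjacency[idx["input"], idx["C1"]] == 1
                                for n in nets)

    def test_contradictory_constraints_rejected(self):
        with pytest.raises(ValidationError):
            pn.apply_prior_constraints(self._nets(),
                                       required=[("input", "C1", 1)],
                                       forbidden=[("input", "C1")])

    def test_forbidding_needed_edges_leaves_nothing(self):
        nets = self._nets()
        kept = pn.apply_prior_constraints(
            nets, forbidden=[(s, "C1") for s in nets[0].node_names])
        assert kept == []


class TestAttractorLandscape:
    def test_one_node_positive_self_edge_two_fixed_points(self):
        net = pn.TernaryNetwork(["input", "C1"], np.array([[0, 0], [0, 1]]))
        ls = pn.attractor_landscape(net)
        assert ls.n_states == 2
        assert sorted(ls.basin_sizes) == [1, 1]
        assert len(ls.attractors) == 2

    def test_one_node_negative_self_edge_single_attractor(self):
        net = pn.TernaryNetwork(["input", "C1"], np.array([[0, 0], [0, -1]]))
        ls = pn.attractor_landscape(net)
        assert ls.basin_sizes == [2]
        assert ls.attractors == [((1, 0),)]

    def test_six_free_nodes_enumerate_sixty_four_states(self):
        rng = np.random.default_rng(5)
        a = rng.integers(-1, 2, size=(7, 7))
        a[:, 0] = 0
        net = pn.TernaryNetwork(["input"] + [f"C{i}" for i in range(1, 7)], a)
        ls = pn.attractor_landscape(net)
        assert ls.n_states == 64
        assert sum(ls.basin_sizes) == 64

    def test_cycle_states_map_into_their_cycle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a = rng.integers(-1, 2, size=(4, 4))
            a[:, 0] = 0
            net = pn.TernaryNetwork(["input", "A", "B", "C"], a)
            ls = pn.attractor_landscape(net)
            assert sum(ls.basin_sizes) == ls.n_states == 8
            for cyc in ls.attractors:
                for s in cyc:
                    assert tuple(pn.step(net, np.array(s))) in cyc

    def test_landscape_json_shape(self):
        net = pn.TernaryNetwork(["input", "C1"], np.array([[0, 0], [0, -1]]))
        import json
        payload = json.loads(pn.attractor_landscape(net).to_json())
        assert payload["n_states"] == 2
        assert payload["attractors"] == [["10"]]


class TestEdgeListIO:
    def test_roundtrip(self, tmp_path):
        names = ["input", "C1", "C2"]
        a = np.array([[0, 1, -1], [0, 0, 1], [0, -1, 0]])
        net = pn.TernaryNetwork(names, a)
        path = tmp_path / "net.tsv"
        net.write_edge_list(path, header_comment="test")
        back = pn.TernaryNetwork.read_edge_list(path, names)
        np.testing.assert_array_equal(back.adjacency, a)
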