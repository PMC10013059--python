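"""Single-invader initialization, payoffs, fitness profiles, and the
death-birth process."""

import numpy as np
import pytest

import networkx as nx

from syncgame import (
    GameParameters,
    PopulationState,
    Strategy,
    all_to_all,
    assign_costs,
    death_birth_step,
    expected_payoff,
    fitness,
    fitness_profile,
    grid_layout,
    initialize_invasion,
    nearest_neighbor_8,
    run_simulation,
)
from syncgame.dynamics import candidate_payoffs, export_trajectory

from conftest import star_topology, topology_from_networkx


def state_from_strategies(strategies, d=10):
    codes = np.array([s.code(d) for s in strategies], dtype=np.int64)
    return PopulationState(codes=codes, d=d)


class TestInitializeInvasion:
    def test_single_invader_at_opposite_phase(self):
        topo = all_to_all(100)
        state = initialize_invasion(topo, 10, rng=3)
        flags = [s.flag for s in state.strategies]
        assert flags.count("C") == 1
        assert flags.count("N") == 99
        invader = state.strategies[flags.index("C")]
        assert invader.phase_index == 6  # 1 + 10//2, cyclic distance 5 from 1
        residents = {s.phase_index for s in state.strategies if s.flag == "N"}
        assert residents == {1}
        assert state.p == pytest.approx(1 / 100)

    def test_odd_phase_count(self):
        topo = all_to_all(10)
        state = initialize_invasion(topo, 7, rng=0)
        invader = [s for s in state.strategies if s.flag == "C"][0]
        assert invader.phase_index == 4  # 1 + 7//2: maximal cyclic distance 3

    def test_placement_uses_rng(self):
        topo = all_to_all(200)
        a = initialize_invasion(topo, 10, rng=1)
        b = initialize_invasion(topo, 10, rng=2)
        assert int(np.argmin(a.codes)) != int(np.argmin(b.codes))

    def test_invalid_phase_count_rejected(self):
        with pytest.raises(ValueError):
            initialize_invasion(all_to_all(2), 1, rng=0)


class TestExpectedPayoff:
    def test_silent_among_silent_is_zero(self, default_params):
        topo = star_topology(3)
        state = state_from_strategies([Strategy("N", 1)] * 4)
        assert expected_payoff(state, default_params, topo, 0) == 0

    def test_hand_summed_communicator(self):
        # hub (C,p1) with neighbors (C,p1),(C,p1),(C,p6),(N,p1):
        # 10 + 10 + 0 + 5 = 25
        params = GameParameters(b0=20, beta0=15, cost=10.0, d=10)
        topo = star_topology(4)
        state = state_from_strategies(
            [Strategy("C", 1), Strategy("C", 1), Strategy("C", 1),
             Strategy("C", 6), Strategy("N", 1)]
        )
        assert expected_payoff(state, params, topo, 0) == pytest.approx(25)

    def test_hand_summed_free_rider(self):
        # hub (N,p1) with neighbors (C,p1),(C,p6): beta(0) + beta(5)
        params = GameParameters(b0=20, beta0=15, cost=10.0, d=10)
        topo = star_topology(2)
        state = state_from_strategies(
            [Strategy("N", 1), Strategy("C", 1), Strategy("C", 6)]
        )
        assert expected_payoff(state, params, topo, 0) == pytest.approx(22.5)

    def test_mean_aggregation_divides_by_degree(self):
        params = GameParameters(b0=20, beta0=15, cost=10.0, d=10,
                                payoff_aggregation="mean")
        topo = star_topology(4)
        state = state_from_strategies(
            [Strategy("C", 1), Strategy("C", 1), Strategy("C", 1),
             Strategy("C", 6), Strategy("N", 1)]
        )
        assert expected_payoff(state, params, topo, 0) == pytest.approx(25 / 4)

    def test_isolated_node_zero(self, default_params):
        g = nx.Graph([(1, 2)])
        g.add_node(0)
        topo = topology_from_networkx(g)
        state = state_from_strategies([Strategy("C", 1)] * 3)
        assert expected_payoff(state, default_params, topo, 0) == 0


class TestFitness:
    def test_reference_points(self):
        assert fitness(0.0, 1.0) == 1.0
        assert fitness(123.0, 0.0) == 1.0
        assert fitness(25.0, 1.0) == pytest.approx(np.exp(25))
        assert fitness(10.0, 1.0) > fitness(9.0, 1.0)


class TestFitnessProfile:
    def test_normalized(self, default_params, nn4_costed):
        state = initialize_invasion(nn4_costed, 10, rng=0)
        nb, probs = fitness_profile(state, default_params, nn4_costed, 12)
        assert probs.sum() == pytest.approx(1.0)
        assert np.all(probs >= 0)
        assert nb.size == probs.size

    def test_uniform_for_homogeneous_neighborhood(self, default_params):
        topo = star_topology(5)
        state = state_from_strategies([Strategy("N", 1)] * 6)
        _, probs = fitness_profile(state, default_params, topo, 0)
        np.testing.assert_allclose(probs, 1 / 5)

    def test_identical_neighborhoods_same_profile(self, default_params):
        # complete bipartite: nodes 0 and 1 share the same neighbor set
        g = nx.complete_bipartite_graph(2, 3)
        topo = topology_from_networkx(g)
        state = state_from_strategies(
            [Strategy("N", 1), Strategy("N", 1), Strategy("C", 6),
             Strategy("N", 1), Strategy("C", 1)]
        )
        nb0, p0 = fitness_profile(state, default_params, topo, 0)
        nb1, p1 = fitness_profile(state, default_params, topo, 1)
        np.testing.assert_array_equal(nb0, nb1)
        np.testing.assert_allclose(p0, p1)

    def test_shift_invariance(self, default_params):
        # adding a constant to every candidate payoff leaves the normalized
        # exponential weights unchanged
        topo = star_topology(4)
        state = state_from_strategies(
            [Strategy("N", 1), Strategy("C", 1), Strategy("C", 6),
             Strategy("N", 1), Strategy("N", 1)]
        )
        pis = candidate_payoffs(state, default_params, topo, 0)
        w = np.exp(default_params.delta * (pis - pis.max()))
        shifted = np.exp(default_params.delta * ((pis + 137.0) - (pis + 137.0).max()))
        np.testing.assert_allclose(w / w.sum(), shifted / shifted.sum())

    def test_extreme_payoffs_stay_finite(self):
        # all-to-all with summed payoffs: delta*pi far beyond exp range
        params = GameParameters(b0=40, beta0=40, cost=0.0, d=10, delta=50.0)
        topo = all_to_all(200)
        state = state_from_strategies(
            [Strategy("C", 1)] * 199 + [Strategy("N", 1)], d=10
        )
        _, probs = fitness_profile(state, params, topo, 0)
        assert np.all(np.isfinite(probs))
        assert probs.sum() == pytest.approx(1.0)

    def test_isolated_node_rejected(self, default_params):
        g = nx.Graph([(1, 2)])
        g.add_node(0)
        topo = topology_from_networkx(g)
        state = state_from_strategies([Strategy("N", 1)] * 3)
        with pytest.raises(ValueError, match="no neighbors"):
            fitness_profile(state, default_params, topo, 0)


class TestDeathBirthStep:
    def test_homogeneous_population_is_fixed(self, default_params, nn4_costed):
        codes = np.full(nn4_costed.n, Strategy("N", 1).code(10))
        state = PopulationState(codes=codes, d=10)
        rng = np.random.default_rng(0)
        for _ in range(30):
            death_birth_step(state, default_params, nn4_costed, rng)
        assert state.p == 0.0
        assert state.absorbed and state.absorption_time == 0
        assert len(state.trajectory) == 31

    def test_unanimous_neighbors_impose_their_flag(self, default_params):
        class ForcedDeath:
            """Deterministic stream: always kills node 0."""

            def integers(self, n):
                return 0

            def random(self):
                return 0.5

        topo = star_topology(4)
        state = state_from_strategies(
            [Strategy("N", 1)] + [Strategy("C", 1)] * 4
        )
        death_birth_step(state, default_params, topo, ForcedDeath())
        assert state.strategy_at(0).flag == "C"
        # and the phase stays the node's own
        assert state.strategy_at(0).phase_index == 1

    def test_at_most_one_change_per_step(self, default_params, nn4_costed):
        rng = np.random.default_rng(11)
        state = initialize_invasion(nn4_costed, 10, rng)
        prev = state.n_communicative
        for _ in range(300):
            death_birth_step(state, default_params, nn4_costed, rng)
            now = state.n_communicative
            assert abs(now - prev) <= 1
            prev = now

    def test_neutral_parameters_copy_uniformly(self):
        # with all payoffs zero the profile is uniform over neighbors
        params = GameParameters(b0=0, beta0=0, cost=0.0, d=10)
        topo = star_topology(4)
        state = state_from_strategies(
            [Strategy("N", 1), Strategy("C", 6), Strategy("N", 1),
             Strategy("N", 1), Strategy("N", 1)]
        )
        _, probs = fitness_profile(state, params, topo, 0)
        np.testing.assert_allclose(probs, 0.25)


class TestRunSimulation:
    def test_homogeneous_start_absorbs_immediately(self, default_params, nn4_costed):
        codes = np.full(nn4_costed.n, Strategy("C", 1).code(10))
        state = PopulationState(codes=codes, d=10)
        final = run_simulation(default_params, nn4_costed, 100, 0, state=state)
        assert final.absorbed and final.absorption_time == 0
        assert final.p == 1.0

    def test_deterministic_given_seed(self, default_params, nn4_costed):
        a = run_simulation(default_params, nn4_costed, 2000, 42)
        b = run_simulation(default_params, nn4_costed, 2000, 42)
        assert a.trajectory == b.trajectory
        np.testing.assert_array_equal(a.codes, b.codes)

    def test_step_and_engine_agree(self, default_params, nn4_costed):
        # the convenience single-step API and the vectorized engine consume
        # the random stream identically and visit the same states
        seed = 7
        fast = run_simulation(default_params, nn4_costed, 500, seed)
        rng = np.random.default_rng(seed)
        slow = initialize_invasion(nn4_costed, 10, rng)
        for _ in range(500):
            if slow.absorbed:
                break
            death_birth_step(slow, default_params, nn4_costed, rng)
        np.testing.assert_array_equal(fast.codes, slow.codes)
        np.testing.assert_allclose(fast.trajectory, slow.trajectory[: len(fast.trajectory)])

    def test_absorption_truncates_trajectory(self, nn4_costed):
        # PD-region parameters kill the invader quickly
        params = GameParameters(b0=8, beta0=5, cost=10.0, d=10)
        final = run_simulation(params, nn4_costed, 50_000, 1)
        assert final.absorbed
        assert final.p == 0.0
        assert final.absorption_time == len(final.trajectory) - 1
        assert final.trajectory[-1] == 0.0

    def test_isolated_nodes_are_inert(self, default_params):
        g = nx.Graph([(1, 2), (2, 3), (1, 3)])
        g.add_node(0)  # isolated
        topo = topology_from_networkx(g)
        codes = np.array(
            [Strategy("C", 6).code(10)] + [Strategy("N", 1).code(10)] * 3
        )
        state = PopulationState(codes=codes, d=10)
        final = run_simulation(
            default_params, topo, 500, 3, state=state, record_trajectory=False
        )
        assert final.strategy_at(0) == Strategy("C", 6)

    def test_time_average_recorded_without_trajectory(self, default_params, nn4_costed):
        final = run_simulation(
            default_params, nn4_costed, 1000, 5, record_trajectory=False
        )
        assert 0.0 <= final.time_average_p <= 1.0
        assert len(final.trajectory) == 1

    def test_invalid_budget(self, default_params, nn4_costed):
        with pytest.raises(ValueError):
            run_simulation(default_params, nn4_costed, 0, 0)


class TestTrajectoryExport:
    def test_decimated_csv(self, tmp_path, default_params, nn4_costed):
        final = run_simulation(default_params, nn4_costed, 100, 0)
        out = tmp_path / "traj.csv"
        export_trajectory(final, out, decimate=10)
        lines = out.read_text().strip().splitlines()
        assert lines[0] == "iteration,p"
        # every 10th iteration plus the final entry
        assert len(lines) - 1 <= len(final.trajectory) // 10 + 2
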