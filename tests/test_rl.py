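"""SARSA(lambda), model-based planning, hybrid mixing and softmax choice."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gridnav as gn
from gridnav.maze import DIR_INDEX, DIRECTIONS
from gridnav.rl import ConvergenceError, zeros_q

from conftest import random_leg


def one_step_sarsa(maze, legs, alpha):
    """Independent one-step SARSA oracle (no traces), per reward context."""
    q = {c: np.zeros((maze.n_rooms, 4)) for c in range(len(maze.reward_rooms))}
    for context, steps in legs:
        for i, (state, action, reward) in enumerate(steps):
            si, ai = maze.room_index(state.room), DIR_INDEX[action]
            if i == len(steps) - 1:
                target = 0.0
            else:
                nxt_state, nxt_action, _ = steps[i + 1]
                target = q[context][
                    maze.room_index(nxt_state.room), DIR_INDEX[nxt_action]
                ]
            q[context][si, ai] += alpha * (reward + target - q[context][si, ai])
    return q


class TestSarsaLambda:
    def test_single_step_onto_reward(self, maze):
        """One rewarded step from zero values moves Q to alpha * R."""
        params = gn.ModelParams(alpha=0.5, beta=1, lam=0.9, omega=0)
        q, z = zeros_q(maze), zeros_q(maze)
        state = gn.AgentState((0, 1), None)
        gn.sarsa_lambda_step(q, z, state, "E", None, None, 1.0, params, maze)
        assert q[maze.room_index((0, 1)), DIR_INDEX["E"]] == 0.5
        assert np.count_nonzero(q) == 1

    def test_two_step_leg_full_credit(self, maze):
        """alpha=1, lam=1: the terminal error propagates fully to both pairs."""
        params = gn.ModelParams(alpha=1.0, beta=1, lam=1.0, omega=0)
        qs = np.stack([zeros_q(maze) for _ in range(3)])
        s0 = gn.AgentState((0, 0), None)
        s1 = gn.transition(maze, s0, "E")
        leg = [(s0, "E", 0.0), (s1, "E", 1.0)]
        assert maze.neighbor(s1.room, "E") == maze.reward_rooms[0]
        gn.run_model_free_trial(qs, [(0, leg)], params, maze)
        assert qs[0][maze.room_index((0, 0)), DIR_INDEX["E"]] == 1.0
        assert qs[0][maze.room_index((0, 1)), DIR_INDEX["E"]] == 1.0

    def test_lambda_zero_matches_one_step_oracle(self, maze):
        """lam=0 reduces SARSA(lambda) to one-step SARSA, bit for bit."""
        rng = np.random.default_rng(5)
        params = gn.ModelParams(alpha=0.37, beta=1, lam=0.0, omega=0)
        legs = [(int(rng.integers(3)), None) for _ in range(20)]
        legs = [(c, random_leg(maze, rng, c)) for c, _ in legs]
        qs = np.stack([zeros_q(maze) for _ in range(3)])
        for c, steps in legs:
            gn.run_model_free_trial(qs, [(c, steps)], params, maze)
        oracle = one_step_sarsa(maze, legs, params.alpha)
        for c in range(3):
            assert np.array_equal(qs[c], oracle[c])

    def test_values_stay_in_unit_interval(self, maze):
        """With r in {0, 1} and alpha, lam in [0,1], Q never leaves [0, 1]."""
        rng = np.random.default_rng(9)
        params = gn.ModelParams(alpha=0.9, beta=1, lam=0.8, omega=0)
        qs = np.stack([zeros_q(maze) for _ in range(3)])
        for _ in range(30):
            c = int(rng.integers(3))
            gn.run_model_free_trial(qs, [(c, random_leg(maze, rng, c))], params, maze)
        assert qs.min() >= 0.0 and qs.max() <= 1.0

    def test_unvisited_pairs_stay_zero(self, maze):
        rng = np.random.default_rng(3)
        params = gn.ModelParams(alpha=0.5, beta=1, lam=0.5, omega=0)
        qs = np.stack([zeros_q(maze) for _ in range(3)])
        steps = random_leg(maze, rng, 1)
        gn.run_model_free_trial(qs, [(1, steps)], params, maze)
        visited = {
            (maze.room_index(s.room), DIR_INDEX[a]) for s, a, _ in steps
        }
        untouched = np.ones((maze.n_rooms, 4), dtype=bool)
        for si, ai in visited:
            untouched[si, ai] = False
        assert np.all(qs[1][untouched] == 0.0)
        assert np.all(qs[0] == 0.0) and np.all(qs[2] == 0.0)

    def test_legs_update_only_their_context(self, maze):
        rng = np.random.default_rng(4)
        params = gn.ModelParams(alpha=0.5, beta=1, lam=0.5, omega=0)
        qs = np.stack([zeros_q(maze) for _ in range(3)])
        gn.run_model_free_trial(qs, [(2, random_leg(maze, rng, 2))], params, maze)
        assert np.all(qs[0] == 0) and np.all(qs[1] == 0) and qs[2].max() > 0

    def test_repeated_route_drives_values_toward_reward(self, maze):
        """Replaying one successful route grows its Q values monotonically."""
        rng = np.random.default_rng(12)
        params = gn.ModelParams(alpha=0.3, beta=1, lam=0.7, omega=0)
        steps = random_leg(maze, rng, 0)
        qs = np.stack([zeros_q(maze) for _ in range(3)])
        last_pair = (maze.room_index(steps[-1][0].room), DIR_INDEX[steps[-1][1]])
        prev = 0.0
        for _ in range(25):
            gn.run_model_free_trial(qs, [(0, steps)], params, maze)
            cur = qs[0][last_pair]
            assert cur >= prev
            prev = cur
        assert prev > 0.99  # approaches R = 1

    def test_leg_must_end_on_reward(self, maze):
        params = gn.ModelParams()
        qs = np.stack([zeros_q(maze) for _ in range(3)])
        bad_leg = [(gn.AgentState((0, 0), None), "E", 0.0)]
        with pytest.raises(ValueError):
            gn.run_model_free_trial(qs, [(0, bad_leg)], params, maze)


class TestValueIteration:
    def test_door_into_reward_equals_reward(self, maze):
        q, _ = gn.value_iteration(maze, maze.reward_rooms[0])
        goal = maze.reward_rooms[0]
        for room in sorted(maze.rooms):
            for d in DIRECTIONS:
                if maze.has_door(room, d) and maze.neighbor(room, d) == goal:
                    assert q[maze.room_index(room), DIR_INDEX[d]] == 1.0

    def test_closed_form_fixed_point(self, maze):
        """Q(s,a) = (1-gamma)^(d-1) R with d the no-backtrack route length."""
        gamma = 0.1
        for goal in maze.reward_rooms:
            q, _ = gn.value_iteration(maze, goal, gamma=gamma)
            for room in sorted(maze.rooms):
                for d in DIRECTIONS:
                    if not maze.has_door(room, d):
                        continue
                    succ = maze.neighbor(room, d)
                    dist = gn.shortest_steps(maze, gn.AgentState(succ, d), goal)
                    expected = (1 - gamma) ** dist
                    assert q[maze.room_index(room), DIR_INDEX[d]] == pytest.approx(
                        expected, abs=1e-10
                    )

    def test_converges_within_25_sweeps(self, maze):
        _, iters = gn.value_iteration_all(maze, tol=1e-12)
        assert all(it <= 25 for it in iters)

    def test_two_steps_away_is_point_nine(self, maze):
        goal = maze.reward_rooms[0]  # (0, 2)
        q, _ = gn.value_iteration(maze, goal)
        # (0,0) -E-> (0,1): successor one step from the reward, so d = 2
        assert q[maze.room_index((0, 0)), DIR_INDEX["E"]] == pytest.approx(0.9)

    def test_invalid_inputs(self, maze):
        with pytest.raises(ValueError):
            gn.value_iteration(maze, maze.reward_rooms[0], gamma=1.5)
        with pytest.raises(ValueError):
            gn.value_iteration(maze, maze.reward_rooms[0], tol=0)

    def test_non_convergence_diagnostic(self, maze):
        with pytest.raises(ConvergenceError) as err:
            gn.value_iteration(maze, maze.reward_rooms[0], max_iter=1)
        assert err.value.last_delta > 0


class TestHybrid:
    def test_endpoints_and_midpoint(self, maze, q_mb):
        q_mf = np.full((maze.n_rooms, 4), 0.2)
        assert np.array_equal(gn.hybrid_values(q_mf, q_mb[0], 0.0), q_mf)
        assert np.array_equal(gn.hybrid_values(q_mf, q_mb[0], 1.0), q_mb[0])
        mixed = gn.hybrid_values(
            np.full((1, 1), 0.2), np.full((1, 1), 0.9), 0.5
        )
        assert mixed[0, 0] == pytest.approx(0.55)

    def test_mismatched_support_raises(self):
        with pytest.raises(ValueError):
            gn.hybrid_values(np.zeros((2, 4)), np.zeros((3, 4)), 0.5)

    def test_omega_out_of_range_raises(self):
        with pytest.raises(ValueError):
            gn.hybrid_values(np.zeros((2, 4)), np.zeros((2, 4)), 1.5)


class TestSoftmax:
    def test_zero_beta_is_uniform(self, maze, q_mb):
        state = gn.AgentState((2, 2), "N")
        legal = gn.legal_actions(maze, state)
        p = gn.softmax_policy(q_mb[0], state, legal, 0.0, maze)
        assert np.allclose(p, 1.0 / len(legal))

    def test_two_action_logistic(self, maze):
        q = zeros_q(maze)
        state = gn.AgentState((0, 0), None)
        q[maze.room_index((0, 0)), DIR_INDEX["E"]] = 1.0
        p = gn.softmax_policy(q, state, ["E", "S"], 1.0, maze)
        e = np.e
        assert p[0] == pytest.approx(e / (e + 1), abs=1e-12)
        assert p[1] == pytest.approx(1 / (e + 1), abs=1e-12)

    def test_greedy_limit(self, maze):
        q = zeros_q(maze)
        q[maze.room_index((2, 2)), DIR_INDEX["N"]] = 0.3
        state = gn.AgentState((2, 2), "N")
        p = gn.softmax_policy(q, state, gn.legal_actions(maze, state), 500.0, maze)
        assert p[gn.legal_actions(maze, state).index("N")] > 0.999999

    def test_empty_legal_raises(self, maze, q_mb):
        with pytest.raises(ValueError):
            gn.softmax_policy(q_mb[0], gn.AgentState((2, 2), None), [], 1.0, maze)

    @settings(deadline=None, max_examples=40)
    @given(
        vals=st.lists(
            st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=2, max_size=4
        ),
        beta=st.floats(min_value=0, max_value=50),
    )
    def test_sums_to_one_and_permutation_equivariant(self, vals, beta):
        maze = gn.default_maze()
        q = zeros_q(maze)
        state = gn.AgentState((2, 2), None)
        legal = gn.legal_actions(maze, state)[: len(vals)]
        vals = vals[: len(legal)]
        for a, v in zip(legal, vals):
            q[maze.room_index(state.room), DIR_INDEX[a]] = v
        p = gn.softmax_policy(q, state, legal, beta, maze)
        assert abs(p.sum() - 1.0) < 1e-12
        order = list(reversed(range(len(legal))))
        p_rev = gn.softmax_policy(q, state, [legal[i] for i in order], beta, maze)
        assert np.allclose(p_rev, p[order], atol=1e-15)
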