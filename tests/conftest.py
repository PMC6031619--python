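import numpy as np
import pytest

import gridnav as gn


@pytest.fixture(scope="session")
def maze():
    return gn.default_maze()


@pytest.fixture(scope="session")
def q_mb(maze):
    tables, _ = gn.value_iteration_all(maze)
    return tables


@pytest.fixture(scope="session")
def small_cohort(maze):
    """A 6-subject cohort simulated at study trial counts; log + truth."""
    return gn.simulate_cohort(maze, n_subjects=6, seed=11)


@pytest.fixture(scope="session")
def one_subject_log(maze, q_mb):
    """One full-session log from a mid-range hybrid subject."""
    spec = gn.SubjectSpec(
        "S01", gn.ModelParams(alpha=0.5, beta=5.0, lam=0.6, omega=0.3), seed=42
    )
    schedule = gn.make_session_schedule(maze, 7)
    return spec, gn.simulate_subject(maze, spec, schedule, q_mb=q_mb)


def random_leg(maze, rng, context=0):
    """A random legal trajectory ending at the context's reward room.

    Returns a list of (state, action, reward) steps for trial-replay tests.
    """
    goal = maze.reward_rooms[context]
    start_candidates = [r for r in sorted(maze.rooms) if r != goal]
    start = start_candidates[rng.integers(len(start_candidates))]
    state = gn.AgentState(start, None)
    steps = []
    while True:
        legal = gn.legal_actions(maze, state)
        action = legal[rng.integers(len(legal))]
        nxt = maze.neighbor(state.room, action)
        reward = 1.0 if nxt == goal else 0.0
        steps.append((state, action, reward))
        if reward:
            return steps
        state = gn.AgentState(nxt, action)
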