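"""Valuation models: SARSA(lambda) model-free learning, dynamic-programming
model-based planning, their hybrid mixture, and the softmax choice rule.

State-action values are stored as ``(n_rooms, 4)`` float arrays indexed by
room index and absolute move direction (N, E, S, W).  Each reward context
(one of the three targets) has its own independent table; there is no
interference or generalisation between contexts.

Model-free values are learned on-policy along the traversed trajectory with
replacing eligibility traces.  The temporal-difference error for step ``i``
is ``delta = r + Q(s', a') - Q(s, a)`` with no discount, where ``(s', a')``
is the next state-action actually taken (0 at the terminal, rewarded step).

Model-based values are the fixed point of the planning recursion

    Q_MB(s, a) = R(s')                          if s' is the reward room
    Q_MB(s, a) = (1 - gamma) max_{a'} Q_MB(s', a')   otherwise

where the maximum runs over the successor's legal actions excluding
backtracking, and gamma (default 0.1) is a per-step planning cost.  The
fixed point is ``(1 - gamma)^(d-1) R`` for a pair whose shortest
no-backtracking route to the reward takes ``d`` moves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .maze import AgentState, DIR_INDEX, DIRECTIONS, Maze, opposite

_OPP_IDX = np.array([DIR_INDEX[opposite(d)] for d in DIRECTIONS])


class ConvergenceError(RuntimeError):
    """Value iteration failed to converge; carries the last max change."""

    def __init__(self, message: str, last_delta: float):
        super().__init__(message)
        self.last_delta = last_delta


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of the learning models.

    alpha  -- learning rate in [0, 1]
    beta   -- softmax inverse temperature, >= 0
    lam    -- eligibility-trace decay in [0, 1]
    omega  -- hybrid weight in [0, 1]; 0 = pure model-free, 1 = pure model-based
    gamma  -- planning cost of the model-based recursion; fixed, not fitted
    """

    alpha: float = 0.5
    beta: float = 3.0
    lam: float = 0.5
    omega: float = 0.5
    gamma: float = field(default=0.1)

    def __post_init__(self) -> None:
        for name in ("alpha", "lam", "omega"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.beta < 0:
            raise ValueError(f"beta={self.beta} must be >= 0")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError(f"gamma={self.gamma} outside (0, 1)")


def zeros_q(maze: Maze) -> np.ndarray:
    """A fresh all-zero state-action value table."""
    return np.zeros((maze.n_rooms, 4))


def _successor_masks(maze: Maze) -> np.ndarray:
    """``(n_rooms, 4, 4)`` bool: action a' legal at the successor of (s, a)."""
    nbr = maze.neighbor_array
    has_door = nbr >= 0
    masks = np.zeros((maze.n_rooms, 4, 4), dtype=bool)
    for a in range(4):
        succ = nbr[:, a]
        valid = succ >= 0
        masks[valid, a, :] = has_door[succ[valid]]
        masks[:, a, _OPP_IDX[a]] = False
    return masks


def value_iteration(
    maze: Maze,
    reward_room,
    gamma: float = 0.1,
    reward_magnitude: float = 1.0,
    tol: float = 1e-12,
    max_iter: int = 500,
) -> tuple[np.ndarray, int]:
    """Solve the model-based planning recursion by synchronous sweeps.

    Returns the converged ``(n_rooms, 4)`` table and the number of sweeps
    needed for the maximum absolute change to fall below ``tol``.  Entries
    without a door stay 0 and are ignored by the convergence test.
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    if tol <= 0:
        raise ValueError("tol must be positive")
    nbr = maze.neighbor_array
    has_door = nbr >= 0
    goal = maze.room_index(tuple(reward_room))
    masks = _successor_masks(maze)
    succ = np.where(has_door, nbr, 0)
    enters_goal = has_door & (nbr == goal)

    q = np.zeros((maze.n_rooms, 4))
    for it in range(1, max_iter + 1):
        # max over the successor's legal continuations; 0 if it has none
        succ_q = np.where(masks, q[succ][:, :, :], -np.inf)
        best = succ_q.max(axis=2)
        best = np.where(np.isfinite(best), best, 0.0)
        q_new = np.where(enters_goal, reward_magnitude, (1.0 - gamma) * best)
        q_new = np.where(has_door, q_new, 0.0)
        delta = np.abs(q_new - q)[has_door].max()
        q = q_new
        if delta < tol:
            return q, it
    raise ConvergenceError(
        f"value iteration did not converge in {max_iter} sweeps", float(delta)
    )


def value_iteration_all(
    maze: Maze,
    gamma: float = 0.1,
    reward_magnitude: float = 1.0,
    tol: float = 1e-12,
    max_iter: int = 500,
) -> tuple[np.ndarray, list[int]]:
    """Converged model-based tables for every reward context.

    Returns ``(n_contexts, n_rooms, 4)`` and the per-context sweep counts.
    """
    tables, iters = [], []
    for room in maze.reward_rooms:
        q, it = value_iteration(maze, room, gamma, reward_magnitude, tol, max_iter)
        tables.append(q)
        iters.append(it)
    return np.stack(tables), iters


def sarsa_lambda_step(
    q: np.ndarray,
    z: np.ndarray,
    state: AgentState,
    action: str,
    next_state: AgentState | None,
    next_action: str | None,
    reward: float,
    params: ModelParams,
    maze: Maze,
) -> tuple[np.ndarray, np.ndarray]:
    """One on-policy update with replacing eligibility traces, in place.

    ``next_action is None`` marks the terminal (rewarded) step, where the
    successor value term is 0.  The visited pair's trace is set to 1, every
    traced pair is moved by ``alpha * delta * z``, then all traces decay
    by ``lam``.
    """
    si = maze.room_index(state.room)
    ai = DIR_INDEX[action]
    if next_action is None:
        target = 0.0
    else:
        target = q[maze.room_index(next_state.room), DIR_INDEX[next_action]]
    delta = reward + target - q[si, ai]
    z[si, ai] = 1.0
    q += params.alpha * delta * z
    z *= params.lam
    return q, z


def run_model_free_trial(
    q_per_context: np.ndarray,
    legs: list[tuple[int, list[tuple[AgentState, str, float]]]],
    params: ModelParams,
    maze: Maze,
) -> np.ndarray:
    """Replay a completed trial through SARSA(lambda), leg by leg.

    ``legs`` holds ``(context, steps)`` pairs where each step is
    ``(state, action, reward)`` and the final step of each leg carries the
    reward.  Each leg updates only its own context's table, with traces
    reset at the leg start and never carried across legs.
    """
    for context, steps in legs:
        if not steps or steps[-1][2] <= 0:
            raise ValueError("each leg must end on its rewarded step")
        q = q_per_context[context]
        z = np.zeros_like(q)
        for i, (state, action, reward) in enumerate(steps):
            terminal = i == len(steps) - 1
            nxt_state, nxt_action = (None, None) if terminal else steps[i + 1][:2]
            sarsa_lambda_step(
                q, z, state, action, nxt_state, nxt_action, reward, params, maze
            )
    return q_per_context


def hybrid_values(q_mf: np.ndarray, q_mb: np.ndarray, omega: float) -> np.ndarray:
    """Convex combination ``(1 - omega) Q_MF + omega Q_MB``."""
    if not 0.0 <= omega <= 1.0:
        raise ValueError("omega must lie in [0, 1]")
    if q_mf.shape != q_mb.shape:
        raise ValueError(f"mismatched supports {q_mf.shape} vs {q_mb.shape}")
    return (1.0 - omega) * q_mf + omega * q_mb


def softmax_policy(
    q: np.ndarray,
    state: AgentState,
    legal: list[str],
    beta: float,
    maze: Maze,
) -> np.ndarray:
    """Choice probabilities over the legal actions, in the given order.

    ``p(a) ∝ exp(beta * Q(room, a))``, stabilised by max subtraction.
    ``beta = 0`` yields the uniform policy.
    """
    if not legal:
        raise ValueError("legal action set is empty")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    si = maze.room_index(state.room)
    vals = np.array([beta * q[si, DIR_INDEX[a]] for a in legal])
    vals -= vals.max()
    ex = np.exp(vals)
    return ex / ex.sum()
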