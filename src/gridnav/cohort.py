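"""Synthetic subjects performing the three-phase wayfinding task.

Subjects are simulated from the hybrid learning model: at every decision the
agent draws an action from the softmax over ``(1 - omega) Q_MF + omega Q_MB``
with its own parameters, while the model-free tables learn online along the
traversed path.  Pure route-followers and pure map-planners are the
``omega = 0`` and ``omega = 1`` endpoints of the same generator.

Model-free learning persists across phases by default (one continuous
session), while model fitting treats phases separately; both behaviours are
switchable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maze import (
    AgentState,
    DIR_INDEX,
    Maze,
    TrialSpec,
    legal_actions,
    make_session_schedule,
)
from .rl import ModelParams, hybrid_values, softmax_policy, value_iteration_all, zeros_q

LOG_COLUMNS = [
    "subject_id",
    "phase",
    "trial",
    "leg_context",
    "step",
    "room_row",
    "room_col",
    "entry_dir",
    "available",
    "chosen",
    "reward",
    "p_chosen",
    "truncated",
]

#: Default per-parameter uniform sampling bounds for synthetic cohorts.
DEFAULT_SAMPLER: dict[str, tuple[float, float]] = {
    "alpha": (0.1, 0.9),
    "beta": (1.0, 10.0),
    "lam": (0.0, 1.0),
    "omega": (0.0, 1.0),
}

_PARAM_RANGES = {"alpha": (0, 1), "beta": (0, np.inf), "lam": (0, 1), "omega": (0, 1)}


@dataclass(frozen=True)
class SubjectSpec:
    """A synthetic subject: identifier, generative parameters, private seed."""

    subject_id: str
    params: ModelParams
    seed: int


class TruncatedLegWarning(UserWarning):
    """A simulated leg hit the step cap before reaching its reward."""


def simulate_subject(
    maze: Maze,
    spec: SubjectSpec,
    schedule: list[TrialSpec],
    q_mb: np.ndarray | None = None,
    carry_over: bool = True,
    step_cap: int = 200,
) -> pd.DataFrame:
    """Simulate one subject over a full trial schedule.

    Returns one row per decision.  SARSA(lambda) updates are applied in the
    on-policy order (a step's update lands once the next action is known;
    the terminal update lands on reward receipt), so the recorded
    ``p_chosen`` matches a likelihood replay of the same log at the
    generative parameters.

    A leg that exceeds ``step_cap`` decisions aborts its trial; its rows are
    flagged ``truncated`` and downstream stages exclude them.
    """
    params = spec.params
    if q_mb is None:
        q_mb, _ = value_iteration_all(maze, gamma=params.gamma)
    rng = np.random.default_rng(spec.seed)
    q_mf = np.stack([zeros_q(maze) for _ in maze.reward_rooms])
    z = zeros_q(maze)
    # pending SARSA update: (context, room_idx, act_idx, reward)
    pending: tuple[int, int, int, float] | None = None
    rows: list[tuple] = []
    current_phase = schedule[0].phase

    def flush_terminal() -> None:
        nonlocal pending
        if pending is not None:
            c, si, ai, r = pending
            if r > 0:
                delta = r - q_mf[c, si, ai]
                z[si, ai] = 1.0
                q_mf[c] += params.alpha * delta * z
                z[:] *= params.lam
            pending = None
        z[:] = 0.0

    for trial in schedule:
        if trial.phase != current_phase:
            current_phase = trial.phase
            if not carry_over:
                flush_terminal()
                q_mf[:] = 0.0
        state = AgentState(trial.start, None)
        step_in_trial = 0
        trial_rows: list[list] = []
        aborted = False
        for target in trial.target_sequence:
            context = maze.reward_rooms.index(target)
            flush_terminal()
            got_reward = False
            for _ in range(step_cap):
                legal = legal_actions(maze, state)
                q_h = hybrid_values(q_mf[context], q_mb[context], params.omega)
                probs = softmax_policy(q_h, state, legal, params.beta, maze)
                choice = int(rng.choice(len(legal), p=probs))
                action = legal[choice]
                next_room = maze.neighbor(state.room, action)
                reward = 1.0 if next_room == target else 0.0
                si = maze.room_index(state.room)
                ai = DIR_INDEX[action]
                if pending is not None:
                    # previous step's update, now that its successor is known
                    c, psi, pai, pr = pending
                    delta = pr + q_mf[c, si, ai] - q_mf[c, psi, pai]
                    z[psi, pai] = 1.0
                    q_mf[c] += params.alpha * delta * z
                    z[:] *= params.lam
                trial_rows.append(
                    [
                        spec.subject_id,
                        trial.phase,
                        trial.trial_index,
                        context,
                        step_in_trial,
                        state.room[0],
                        state.room[1],
                        state.entry_dir or "",
                        "".join(legal),
                        action,
                        int(reward),
                        float(probs[choice]),
                        False,
                    ]
                )
                pending = (context, si, ai, reward)
                state = AgentState(next_room, action)
                step_in_trial += 1
                if reward > 0:
                    got_reward = True
                    break
            if not got_reward:
                aborted = True
                pending = None
                warnings.warn(
                    f"{spec.subject_id} {trial.phase} trial {trial.trial_index}: "
                    f"leg for context {context} hit the {step_cap}-step cap; "
                    "trial flagged truncated",
                    TruncatedLegWarning,
                    stacklevel=2,
                )
                break
        if aborted:
            for row in trial_rows:
                row[-1] = True
        rows.extend(map(tuple, trial_rows))
    flush_terminal()
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def sample_params(
    rng: np.random.Generator,
    sampler: dict[str, tuple[float, float]] | None = None,
) -> ModelParams:
    """Draw one parameter set from independent uniform ranges."""
    bounds = dict(DEFAULT_SAMPLER)
    bounds.update(sampler or {})
    draws = {}
    for name, (lo, hi) in bounds.items():
        rlo, rhi = _PARAM_RANGES[name]
        if not (rlo <= lo <= hi <= rhi):
            raise ValueError(f"sampler bounds for {name} invalid: ({lo}, {hi})")
        draws[name] = float(rng.uniform(lo, hi))
    return ModelParams(**draws)


def simulate_cohort(
    maze: Maze,
    n_subjects: int = 27,
    param_sampler: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_encoding: int = 8,
    n_retrieval: int = 15,
    n_search: int = 15,
    carry_over: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort with parameters drawn from a uniform sampler.

    Returns the concatenated choice log and the ground-truth parameter
    table (one row per subject), the latter for recovery analyses.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    q_mb, _ = value_iteration_all(maze)
    logs, truth = [], []
    for i in range(n_subjects):
        params = sample_params(rng, param_sampler)
        sub_seed = int(rng.integers(2**31))
        sched_seed = int(rng.integers(2**31))
        spec = SubjectSpec(f"S{i + 1:02d}", params, sub_seed)
        schedule = make_session_schedule(
            maze, sched_seed, n_encoding, n_retrieval, n_search
        )
        logs.append(
            simulate_subject(maze, spec, schedule, q_mb=q_mb, carry_over=carry_over)
        )
        truth.append(
            {
                "subject_id": spec.subject_id,
                "alpha": params.alpha,
                "beta": params.beta,
                "lam": params.lam,
                "omega": params.omega,
            }
        )
    return pd.concat(logs, ignore_index=True), pd.DataFrame(truth)


def write_log(log: pd.DataFrame, path) -> None:
    """Write a choice log as tab-separated text."""
    log.to_csv(path, sep="\t", index=False)


def read_log(path) -> pd.DataFrame:
    """Read a choice log written by :func:`write_log`."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"entry_dir": str})
    if "truncated" in df:
        df["truncated"] = df["truncated"].astype(str).str.lower().eq("true")
    return df
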