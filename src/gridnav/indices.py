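"""Navigation-strategy indices from choice logs.

Three per-phase indices summarise how a subject navigated:

* ``I_PATH``  — fraction of trials solved on a shortest path,
* ``I_STEPS`` — ``(n_max_steps - n_obs_steps) / (n_max_steps - n_shortest_steps)``
  with ``n_max_steps`` the worst per-phase step total across the cohort;
  1 = always optimal, 0 = the cohort's worst,
* ``I_ROUTE`` — ``n_route / (n_route + n_shortest)``, the share of learned-route
  repetitions among route and shortest trials.

Shortest paths honour the no-backtracking rule (breadth-first search over
(room, entry-direction) states).  A trial counts as a route repetition when
at least 60% of its directed room-to-room transitions occur in the
subject's reference route for that reward context — the final encoding-phase
leg — and it is not itself a shortest-path trial.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .maze import AgentState, Maze, PHASES

#: Minimum transition overlap with the reference route for a route trial.
ROUTE_OVERLAP_THRESHOLD = 0.6


class IndexComputationWarning(UserWarning):
    pass


def shortest_steps(maze: Maze, state: AgentState, goal) -> int:
    """Minimal number of moves from a state to a goal room, no backtracking."""
    goal = tuple(goal)
    if goal not in maze.rooms:
        raise ValueError(f"unknown goal room {goal}")
    if state.room == goal:
        return 0
    lengths = nx.single_source_shortest_path_length(
        maze.state_graph, (state.room, state.entry_dir)
    )
    best = min(
        (d for (room, _entry), d in lengths.items() if room == goal), default=None
    )
    if best is None:
        raise ValueError(f"goal {goal} unreachable from {state}")
    return best


def route_overlap(path: list, reference: list) -> float:
    """Fraction of the path's directed transitions found in the reference."""
    if len(path) < 2 or len(reference) < 2:
        raise ValueError("paths must contain at least one transition")
    ref_transitions = {
        (tuple(a), tuple(b)) for a, b in zip(reference[:-1], reference[1:])
    }
    transitions = [(tuple(a), tuple(b)) for a, b in zip(path[:-1], path[1:])]
    hits = sum(t in ref_transitions for t in transitions)
    return hits / len(transitions)


def compute_i_path(obs_steps, shortest: np.ndarray | list) -> float:
    """Fraction of trials whose observed step count equals the optimum."""
    obs = np.asarray(obs_steps)
    short = np.asarray(shortest)
    if obs.size == 0:
        raise ValueError("empty trial set")
    return float(np.mean(obs == short))

def compute_i_steps(obs_total: float, shortest_total: float, max_total: float) -> float:
    """Normalised excess steps over a phase; 1 = optimal, 0 = cohort worst."""
    if max_total <= shortest_total:
        warnings.warn(
            "cohort maximum does not exceed the optimum; I_STEPS degenerate, "
            "defined as 1",
            IndexComputationWarning,
            stacklevel=2,
        )
        return 1.0
    return float((max_total - obs_total) / (max_total - shortest_total))


def compute_i_route(n_route: int, n_shortest: int) -> float:
    """Share of route repetitions among route plus shortest trials."""
    denom = n_route + n_shortest
    if denom == 0:
        warnings.warn(
            "no route or shortest trials; I_ROUTE undefined for this phase",
            IndexComputationWarning,
            stacklevel=2,
        )
        return float("nan")
    return float(n_route / denom)


def _leg_paths(log: pd.DataFrame, maze: Maze) -> pd.DataFrame:
    """Per-leg observed path, step count and optimum, one row per leg."""
    if log["truncated"].any():
        n_bad = int(log.loc[log["truncated"], ["subject_id", "trial"]].drop_duplicates().shape[0])
        warnings.warn(
            f"excluding {n_bad} truncated trial(s) from index computation",
            IndexComputationWarning,
            stacklevel=2,
        )
        log = log.loc[~log["truncated"]]
    records = []
    for (subject, phase, trial, context), leg in log.groupby(
        ["subject_id", "phase", "trial", "leg_context"], sort=False
    ):
        leg = leg.sort_values("step")
        rooms = list(zip(leg["room_row"], leg["room_col"]))
        goal = maze.reward_rooms[context]
        path = rooms + [goal]
        entry = leg["entry_dir"].iloc[0] or None
        records.append(
            {
                "subject_id": subject,
                "phase": phase,
                "trial": trial,
                "leg_context": context,
                "obs_steps": len(leg),
                "shortest_steps": shortest_steps(
                    maze, AgentState(rooms[0], entry), goal
                ),
                "path": path,
            }
        )
    return pd.DataFrame(records)


def build_route_library(legs: pd.DataFrame) -> dict[tuple[str, int], list]:
    """Reference route per (subject, context): the final encoding-phase leg."""
    library: dict[tuple[str, int], list] = {}
    enc = legs[legs["phase"] == "encoding"]
    for (subject, context), group in enc.groupby(["subject_id", "leg_context"]):
        last = group.loc[group["trial"].idxmax()]
        library[(subject, context)] = last["path"]
    return library


def trial_table(log: pd.DataFrame, maze: Maze) -> pd.DataFrame:
    """Per-trial observed/optimal steps and route/shortest classification.

    Encoding trials aggregate their three legs: step counts are summed and
    the route overlap pools all legs' transitions against their respective
    per-context reference routes.  A trial that is both shortest and
    route-overlapping counts as shortest.
    """
    legs = _leg_paths(log, maze)
    library = build_route_library(legs)
    rows = []
    for (subject, phase, trial), group in legs.groupby(
        ["subject_id", "phase", "trial"], sort=False
    ):
        obs = int(group["obs_steps"].sum())
        short = int(group["shortest_steps"].sum())
        hits = total = 0
        for _, leg in group.iterrows():
            ref = library.get((subject, leg["leg_context"]))
            if ref is None:
                continue
            n_trans = len(leg["path"]) - 1
            hits += route_overlap(leg["path"], ref) * n_trans
            total += n_trans
        overlap = hits / total if total else 0.0
        is_shortest = obs == short
        rows.append(
            {
                "subject_id": subject,
                "phase": phase,
                "trial": trial,
                "obs_steps": obs,
                "shortest_steps": short,
                "overlap": overlap,
                "is_shortest": is_shortest,
                "is_route": (overlap >= ROUTE_OVERLAP_THRESHOLD) and not is_shortest,
            }
        )
    return pd.DataFrame(rows)


def compute_indices(log: pd.DataFrame, maze: Maze) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-phase and phase-averaged indices for every subject in a log.

    Returns ``(per_phase, averaged)``.  ``per_phase`` has one row per
    subject x phase with the three indices and their constituent counts;
    ``averaged`` holds the across-phase arithmetic means (skipping phases
    where an index is undefined).
    """
    trials = trial_table(log, maze)
    per_phase_rows = []
    for phase in PHASES:
        ph = trials[trials["phase"] == phase]
        if ph.empty:
            continue
        totals = ph.groupby("subject_id")[["obs_steps", "shortest_steps"]].sum()
        n_max = int(totals["obs_steps"].max())
        for subject, sub in ph.groupby("subject_id"):
            n_shortest_trial = int(sub["is_shortest"].sum())
            n_route_trial = int(sub["is_route"].sum())
            obs_total = int(sub["obs_steps"].sum())
            short_total = int(sub["shortest_steps"].sum())
            per_phase_rows.append(
                {
                    "subject_id": subject,
                    "phase": phase,
                    "i_path": compute_i_path(
                        sub["obs_steps"].to_numpy(), sub["shortest_steps"].to_numpy()
                    ),
                    "i_steps": compute_i_steps(obs_total, short_total, n_max),
                    "i_route": compute_i_route(n_route_trial, n_shortest_trial),
                    "n_shortest_trial": n_shortest_trial,
                    "n_route_trial": n_route_trial,
                    "n_total_trial": len(sub),
                    "n_obs_steps": obs_total,
                    "n_shortest_steps": short_total,
                    "n_max_steps": n_max,
                }
            )
    per_phase = pd.DataFrame(per_phase_rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        averaged = (
            per_phase.groupby("subject_id")[["i_path", "i_steps", "i_route"]]
            .agg(lambda s: np.nanmean(s.to_numpy(dtype=float)))
            .reset_index()
        )
    return per_phase, averaged


def write_indices(per_phase: pd.DataFrame, averaged: pd.DataFrame, path) -> None:
    """Write per-phase rows plus an 'averaged' pseudo-phase row per subject."""
    avg = averaged.copy()
    avg.insert(1, "phase", "averaged")
    pd.concat([per_phase, avg], ignore_index=True).to_csv(path, sep="\t", index=False)
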