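"""Grid-world maze, movement rules, and task-phase schedules.

The environment is a rectangular grid of rooms (default 5x5) connected by
doors between orthogonal neighbours.  An agent occupies one room at a time
and remembers the direction through which it entered; backtracking — leaving
through the door just entered — is forbidden, so an interior room offers at
most three choices, an edge room two, and a corner room one once entered.

A session consists of three phases:

* ``encoding``   — repeated trials from a fixed start collecting three
  rewards in a fixed order (route learning by repetition),
* ``retrieval``  — single-reward trials from the same start,
* ``search``     — single-reward trials from varying start rooms.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import yaml

Room = tuple[int, int]

#: Absolute compass directions; also the canonical action alphabet.
DIRECTIONS: tuple[str, ...] = ("N", "E", "S", "W")

DIR_INDEX: dict[str, int] = {d: i for i, d in enumerate(DIRECTIONS)}

_DELTA: dict[str, tuple[int, int]] = {
    "N": (-1, 0),
    "E": (0, 1),
    "S": (1, 0),
    "W": (0, -1),
}

_OPPOSITE: dict[str, str] = {"N": "S", "S": "N", "E": "W", "W": "E"}

PHASES: tuple[str, ...] = ("encoding", "retrieval", "search")


class MazeError(ValueError):
    """Invalid maze input (unknown room, unknown phase, bad configuration)."""


class IllegalMoveError(RuntimeError):
    """An action violated the movement contract (wall or backtracking)."""


def opposite(direction: str) -> str:
    """Opposite compass direction (``N`` <-> ``S``, ``E`` <-> ``W``)."""
    return _OPPOSITE[direction]


@dataclass(frozen=True)
class AgentState:
    """Agent position plus the direction of the move that entered the room.

    ``entry_dir`` is ``None`` only at the first step of a trial, where no
    backtracking exclusion applies.
    """

    room: Room
    entry_dir: str | None = None


@dataclass(frozen=True)
class TrialSpec:
    """One trial: phase, start room, and the ordered reward targets.

    Encoding trials carry the full three-reward sequence; retrieval and
    search trials carry a single target.
    """

    phase: str
    trial_index: int
    start: Room
    target_sequence: tuple[Room, ...]


@dataclass
class Maze:
    """Room grid with door adjacency, reward rooms and start rooms.

    ``doors`` is a set of frozensets of room pairs; adjacency is symmetric
    by construction.  Rooms are 0-based ``(row, col)`` with row 0 at the
    north edge.
    """

    n_rows: int = 5
    n_cols: int = 5
    doors: set[frozenset[Room]] = field(default_factory=set)
    reward_rooms: tuple[Room, ...] = ()
    start_room: Room = (4, 0)
    start_rooms_search: tuple[Room, ...] = ()

    def __post_init__(self) -> None:
        if not self.doors:
            self.doors = full_grid_doors(self.n_rows, self.n_cols)
        self.reward_rooms = tuple(map(tuple, self.reward_rooms))
        self.start_room = tuple(self.start_room)
        self.start_rooms_search = tuple(map(tuple, self.start_rooms_search))
        self._validate()

    def _validate(self) -> None:
        for pair in self.doors:
            a, b = tuple(pair)
            if a not in self.rooms or b not in self.rooms:
                raise MazeError(f"door {a}-{b} references a room off the grid")
            if abs(a[0] - b[0]) + abs(a[1] - b[1]) != 1:
                raise MazeError(f"door {a}-{b} does not join orthogonal neighbours")
        if len(set(self.reward_rooms)) != len(self.reward_rooms):
            raise MazeError("reward rooms must be distinct")
        if self.start_room in self.reward_rooms:
            raise MazeError("start room must differ from every reward room")

    @property
    def rooms(self) -> set[Room]:
        return {(r, c) for r in range(self.n_rows) for c in range(self.n_cols)}

    @property
    def n_rooms(self) -> int:
        return self.n_rows * self.n_cols

    def room_index(self, room: Room) -> int:
        return room[0] * self.n_cols + room[1]

    def index_room(self, idx: int) -> Room:
        return divmod(idx, self.n_cols)

    def has_door(self, room: Room, direction: str) -> bool:
        dr, dc = _DELTA[direction]
        nbr = (room[0] + dr, room[1] + dc)
        return frozenset((room, nbr)) in self.doors

    def neighbor(self, room: Room, direction: str) -> Room:
        dr, dc = _DELTA[direction]
        return (room[0] + dr, room[1] + dc)

    def door_directions(self, room: Room) -> list[str]:
        return [d for d in DIRECTIONS if self.has_door(room, d)]

    @functools.cached_property
    def neighbor_array(self) -> np.ndarray:
        """``(n_rooms, 4)`` successor room index per direction; -1 where no door."""
        arr = np.full((self.n_rooms, 4), -1, dtype=np.int64)
        for room in self.rooms:
            for d in self.door_directions(room):
                arr[self.room_index(room), DIR_INDEX[d]] = self.room_index(
                    self.neighbor(room, d)
                )
        return arr

    @functools.cached_property
    def state_graph(self) -> nx.DiGraph:
        """Directed graph over (room, entry_dir) states under no-backtracking."""
        g = nx.DiGraph()
        for room in self.rooms:
            for entry in (None, *DIRECTIONS):
                state = AgentState(room, entry)
                for action in legal_actions(self, state):
                    g.add_edge((room, entry), (self.neighbor(room, action), action))
        return g


def full_grid_doors(n_rows: int, n_cols: int) -> set[frozenset[Room]]:
    """All doors of a fully connected rectangular grid."""
    doors: set[frozenset[Room]] = set()
    for r in range(n_rows):
        for c in range(n_cols):
            if r + 1 < n_rows:
                doors.add(frozenset({(r, c), (r + 1, c)}))
            if c + 1 < n_cols:
                doors.add(frozenset({(r, c), (r, c + 1)}))
    return doors


def default_maze() -> Maze:
    """The default 5x5 task layout: full grid, three well-separated rewards.

    The start sits in the south-west corner; the three ordered reward rooms
    are spread across the grid so that consecutive targets are several steps
    apart.  Search-phase starts may be any non-reward room.
    """
    rewards = ((0, 2), (2, 4), (4, 2))
    search_starts = tuple(
        (r, c) for r in range(5) for c in range(5) if (r, c) not in rewards
    )
    return Maze(
        n_rows=5,
        n_cols=5,
        reward_rooms=rewards,
        start_room=(4, 0),
        start_rooms_search=search_starts,
    )


def legal_actions(maze: Maze, state: AgentState) -> list[str]:
    """Directions with a door, excluding the backtrack direction.

    At a trial's first step (``entry_dir is None``) no exclusion applies,
    so up to four doors may be available.
    """
    if state.room not in maze.rooms:
        raise MazeError(f"unknown room {state.room}")
    banned = opposite(state.entry_dir) if state.entry_dir is not None else None
    return [d for d in maze.door_directions(state.room) if d != banned]


def transition(maze: Maze, state: AgentState, action: str) -> AgentState:
    """Apply a legal move; the new entry direction is the move direction."""
    if action not in legal_actions(maze, state):
        raise IllegalMoveError(
            f"action {action} illegal in room {state.room} (entry {state.entry_dir})"
        )
    return AgentState(maze.neighbor(state.room, action), action)


def make_phase_schedule(
    maze: Maze,
    phase: str,
    n_trials: int,
    rng_seed: int | np.random.Generator,
) -> list[TrialSpec]:
    """Build the trial list for one phase.

    Encoding trials all run from the fixed start with the full ordered
    reward sequence.  Retrieval trials run from the fixed start with one
    uniformly drawn target each.  Search trials draw both a start (from the
    maze's search-start pool, never equal to the target, never repeating the
    previous trial's start) and a single target.
    """
    if phase not in PHASES:
        raise MazeError(f"unknown phase {phase!r}; expected one of {PHASES}")
    if n_trials < 1:
        raise MazeError("n_trials must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    specs: list[TrialSpec] = []
    prev_start: Room | None = None
    for t in range(n_trials):
        if phase == "encoding":
            specs.append(TrialSpec(phase, t, maze.start_room, maze.reward_rooms))
            continue
        target = maze.reward_rooms[rng.integers(len(maze.reward_rooms))]
        if phase == "retrieval":
            start = maze.start_room
        else:
            pool = [
                s
                for s in maze.start_rooms_search
                if s != target and s != prev_start
            ]
            start = pool[rng.integers(len(pool))]
            prev_start = start
        specs.append(TrialSpec(phase, t, start, (target,)))
    return specs


def make_session_schedule(
    maze: Maze,
    seed: int | np.random.Generator,
    n_encoding: int = 8,
    n_retrieval: int = 15,
    n_search: int = 15,
) -> list[TrialSpec]:
    """Full three-phase schedule: encoding, retrieval, then search."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return (
        make_phase_schedule(maze, "encoding", n_encoding, rng)
        + make_phase_schedule(maze, "retrieval", n_retrieval, rng)
        + make_phase_schedule(maze, "search", n_search, rng)
    )


def save_maze(maze: Maze, path) -> None:
    """Write the maze/task configuration as YAML."""
    data = {
        "n_rows": maze.n_rows,
        "n_cols": maze.n_cols,
        "reward_rooms": [list(r) for r in maze.reward_rooms],
        "start_room": list(maze.start_room),
        "start_rooms_search": [list(r) for r in maze.start_rooms_search],
        "doors": sorted(sorted(map(list, pair)) for pair in maze.doors),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_maze(path) -> Maze:
    """Read a maze/task configuration written by :func:`save_maze`."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    doors = {
        frozenset((tuple(a), tuple(b))) for a, b in data.get("doors", [])
    } or full_grid_doors(data["n_rows"], data["n_cols"])
    return Maze(
        n_rows=data["n_rows"],
        n_cols=data["n_cols"],
        doors=doors,
        reward_rooms=tuple(tuple(r) for r in data["reward_rooms"]),
        start_room=tuple(data["start_room"]),
        start_rooms_search=tuple(tuple(r) for r in data["start_rooms_search"]),
    )
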