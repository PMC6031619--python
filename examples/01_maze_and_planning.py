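"""Build the default grid world and inspect the model-based planning values.

The maze is a 5x5 grid of rooms; backtracking through the door just entered
is forbidden, so an entered interior room offers 3 choices, an edge room 2
and a corner room 1.  Value iteration solves the planning recursion for one
reward context: a state-action pair d moves from the reward is worth
(1 - gamma)^(d-1), so values form a gradient that a greedy agent can descend
to the reward along a shortest path.
"""

import numpy as np

from gridnav import AgentState, default_maze, legal_actions, value_iteration
from gridnav.maze import DIR_INDEX

maze = default_maze()
print(f"rooms: {maze.n_rooms}, start: {maze.start_room}, rewards: {maze.reward_rooms}")

for room, entry in [((2, 2), "N"), ((0, 2), "E"), ((0, 0), "W"), ((2, 2), None)]:
    acts = legal_actions(maze, AgentState(room, entry))
    print(f"room {room} entered {entry or 'at trial start'}: actions {acts}")

q, sweeps = value_iteration(maze, maze.reward_rooms[0], gamma=0.1, tol=1e-12)
print(f"\nvalue iteration for reward at {maze.reward_rooms[0]} converged in {sweeps} sweeps")
best = np.max(q, axis=1).reshape(5, 5)
print("max action value per room (1 next to the reward, decaying by 0.9 per step):")
print(np.array2string(best, precision=3))
d = q[maze.room_index((0, 0)), DIR_INDEX["E"]]
print(f"Q((0,0), E) = {d:.3f} — two moves from the reward, (1-0.1)^1 = 0.9")
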