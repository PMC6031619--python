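"""Simulate a synthetic cohort performing the three-phase wayfinding task.

Each subject is a hybrid reinforcement-learning agent with its own
(alpha, beta, lambda, omega) drawn uniformly; omega sets the mix between
learned route values (model-free) and planned map values (model-based).
The session is 8 encoding trials (three ordered rewards from a fixed
start), 15 retrieval trials (one reward, same start) and 15 search trials
(one reward, varying starts).
"""

from gridnav import default_maze, simulate_cohort

maze = default_maze()
logs, truth = simulate_cohort(maze, n_subjects=6, seed=7)

print("ground-truth parameters:")
print(truth.round(3).to_string(index=False))

print("\nfirst decisions of subject S01:")
cols = ["phase", "trial", "leg_context", "step", "room_row", "room_col",
        "entry_dir", "available", "chosen", "reward"]
print(logs[logs.subject_id == "S01"][cols].head(8).to_string(index=False))

rewards = logs.groupby(["subject_id", "phase"])["reward"].sum().unstack()
print("\nrewards collected per phase (24 = 8 trials x 3 rewards):")
print(rewards.to_string())
steps = logs.groupby(["subject_id", "phase"]).size().unstack()
print("\ndecisions per phase (fewer = more direct navigation):")
print(steps.to_string())
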