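"""Compiled replay of a choice log through the hybrid learning model.

The kernel walks a flattened choice log in chronological order, scoring each
choice with the softmax over hybrid values exactly as they stood when the
choice was made, and applying the SARSA(lambda) updates in the same order a
behaving agent would: the update for step ``i`` needs the next on-policy
action, so it lands after the following choice has been scored; the terminal
update of a leg lands before the next leg's first choice.  This makes the
per-step probabilities bit-identical to those used during simulation.

The model-free tables are mutated in place so callers can chain phases when
learning carries over.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _apply_update(q_mf, z, context, s, a, delta, alpha, lam):
    z[s, a] = 1.0
    n_rooms, n_dirs = z.shape
    for r in range(n_rooms):
        for d in range(n_dirs):
            q_mf[context, r, d] += alpha * delta * z[r, d]
            z[r, d] *= lam


@njit(cache=False)
def replay_logprobs(
    room, act, avail, reward, context, new_leg, q_mb, alpha, beta, lam, omega, q_mf
):
    """Per-step log probability of each recorded choice under the hybrid model.

    room, act      -- int64[n] room index and direction index of each decision
    avail          -- bool[n, 4] legality mask of each decision
    reward         -- float64[n] reward received on the step (1.0 at leg end)
    context        -- int64[n] active reward context
    new_leg        -- bool[n] True at the first step of every leg
    q_mb           -- float64[n_ctx, n_rooms, 4] converged planning values
    q_mf           -- float64[n_ctx, n_rooms, 4] learned values, updated in place
    """
    n = room.shape[0]
    n_rooms = q_mf.shape[1]
    logp = np.empty(n)
    z = np.zeros((n_rooms, 4))
    prev = -1
    for i in range(n):
        if new_leg[i] and prev >= 0:
            # previous leg's terminal update (successor value 0), then traces reset
            cp = context[prev]
            delta = reward[prev] - q_mf[cp, room[prev], act[prev]]
            _apply_update(q_mf, z, cp, room[prev], act[prev], delta, alpha, lam)
            z[:, :] = 0.0
        c = context[i]
        m = -1.0e308
        for d in range(4):
            if avail[i, d]:
                v = beta * (
                    (1.0 - omega) * q_mf[c, room[i], d] + omega * q_mb[c, room[i], d]
                )
                if v > m:
                    m = v
        s = 0.0
        for d in range(4):
            if avail[i, d]:
                v = beta * (
                    (1.0 - omega) * q_mf[c, room[i], d] + omega * q_mb[c, room[i], d]
                )
                s += np.exp(v - m)
        v_chosen = beta * (
            (1.0 - omega) * q_mf[c, room[i], act[i]]
            + omega * q_mb[c, room[i], act[i]]
        )
        logp[i] = v_chosen - m - np.log(s)
        if prev >= 0 and not new_leg[i]:
            # pending non-terminal update for the previous step
            delta = (
                reward[prev]
                + q_mf[c, room[i], act[i]]
                - q_mf[c, room[prev], act[prev]]
            )
            _apply_update(q_mf, z, c, room[prev], act[prev], delta, alpha, lam)
        prev = i
    if prev >= 0:
        cp = context[prev]
        delta = reward[prev] - q_mf[cp, room[prev], act[prev]]
        _apply_update(q_mf, z, cp, room[prev], act[prev], delta, alpha, lam)
    return logp
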