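"""Independent brute-force oracle for discrete attractor structure.

Builds the full functional graph over all 2^N states (each node's single
out-edge is one synchronous update) and reads off cycle membership,
period and transient by explicit O(M^2) path-following — no state
hashing, no shared code with the trajectory-based detector it checks.
"""

import itertools

import numpy as np


def _next_state(W, x, off, zero_off):
    h = W @ x
    out = np.where(h > 0, 1.0, off)
    out[h == 0] = zero_off
    return out


def transition_table(W, map="pm1", zero_convention="minus"):
    """(states, next_index) over the full 2^N state space."""
    n = W.shape[0]
    off = -1.0 if map == "pm1" else 0.0
    on = 1.0
    zero_off = off if zero_convention == "minus" else on
    states = [np.array(bits, dtype=float)
              for bits in itertools.product((off, 1.0), repeat=n)]
    index = {s.tobytes(): i for i, s in enumerate(states)}
    nxt = np.array([index[_next_state(W, s, off, zero_off).tobytes()]
                    for s in states])
    return states, nxt


def census(W, map="pm1", zero_convention="minus"):
    """Per-state (outcome, period, transient) for every initial state.

    A node is cyclic iff following the functional graph from it returns
    to it; the transient of any start node is the number of hops to the
    first cyclic node on its path.
    """
    states, nxt = transition_table(W, map, zero_convention)
    m = len(states)
    cycle_len = np.zeros(m, dtype=int)
    for v in range(m):
        u = nxt[v]
        steps = 1
        while u != v and steps <= m:
            u = nxt[u]
            steps += 1
        if u == v:
            cycle_len[v] = steps
    results = []
    for s in range(m):
        t, u = 0, s
        while cycle_len[u] == 0:
            u = nxt[u]
            t += 1
        period = int(cycle_len[u])
        outcome = "fixed_point" if period == 1 else "cycle"
        results.append((outcome, period, t))
    return states, results
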