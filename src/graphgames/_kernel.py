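"""Compiled Monte-Carlo kernel for the death-Birth process.

Strategies are encoded as 1 (the invading type) and 0 (the resident).
``pay1[c]`` / ``pay0[c]`` give the payoff of a type-1 / type-0 player with
``c`` type-1 neighbors, so the same kernel serves either invasion direction.

Two exact accelerations:

* a per-run SplitMix64 stream seeded by counter from the master seed, so
  realizations are independent of execution order;
* deaths at vertices whose whole neighborhood agrees with them cannot change
  the state, so the kernel tracks the set of "active" vertices (those with
  at least one disagreeing neighbor) and only simulates deaths that land on
  it — conditioned on landing in the active set, the dying vertex is uniform
  over it, hence fixation probabilities are untouched.
"""

import numba as nb
import numpy as np

_U = np.uint64
_GOLDEN = _U(0x9E3779B97F4A7BC5)
_MIX1 = _U(0xBF58476D1CE4E5B9)
_MIX2 = _U(0x94D049BB133111EB)
_INV53 = 2.0 ** -53


@nb.njit(nb.types.UniTuple(nb.uint64, 2)(nb.uint64), inline="always")
def _sm64(state):
    """One SplitMix64 step: returns (new_state, output_word)."""
    state = state + _GOLDEN
    z = state
    z = (z ^ (z >> _U(30))) * _MIX1
    z = (z ^ (z >> _U(27))) * _MIX2
    z = z ^ (z >> _U(31))
    return state, z


@nb.njit(cache=False)
def run_one(adj, pay1, pay0, w, seed):
    """One realization from a single type-1 mutant; returns 1 if it fixes."""
    N, k = adj.shape
    state = np.zeros(N, np.int8)
    n1 = np.zeros(N, np.int64)  # type-1 neighbors per vertex

    rs = seed
    rs, z = _sm64(rs)
    v0 = int(np.floor(float(z >> _U(11)) * _INV53 * N))
    state[v0] = 1
    for i in range(k):
        n1[adj[v0, i]] += 1
    count1 = 1

    # active set: vertices with at least one disagreeing neighbor
    act = np.empty(N, np.int64)
    pos = np.full(N, -1, np.int64)
    nact = 0
    for v in range(N):
        if (state[v] == 1 and n1[v] < k) or (state[v] == 0 and n1[v] > 0):
            act[nact] = v
            pos[v] = nact
            nact += 1

    cum = np.empty(k, np.float64)
    while 0 < count1 < N:
        rs, z = _sm64(rs)
        v = act[int(np.floor(float(z >> _U(11)) * _INV53 * nact))]
        total = 0.0
        for i in range(k):
            u = adj[v, i]
            p = pay1[n1[u]] if state[u] == 1 else pay0[n1[u]]
            total += 1.0 - w + w * p
            cum[i] = total
        rs, z = _sm64(rs)
        r = float(z >> _U(11)) * _INV53 * total
        i = 0
        while i < k - 1 and cum[i] <= r:
            i += 1
        u = adj[v, i]
        if state[u] != state[v]:
            new = state[u]
            state[v] = new
            delta = 1 if new == 1 else -1
            count1 += delta
            for i2 in range(k):
                n1[adj[v, i2]] += delta
            # refresh active membership of v and its neighbors
            for t in range(k + 1):
                x = v if t == k else adj[v, t]
                is_act = (state[x] == 1 and n1[x] < k) or (
                    state[x] == 0 and n1[x] > 0
                )
                if is_act and pos[x] < 0:
                    act[nact] = x
                    pos[x] = nact
                    nact += 1
                elif (not is_act) and pos[x] >= 0:
                    p_ = pos[x]
                    last = act[nact - 1]
                    act[p_] = last
                    pos[last] = p_
                    pos[x] = -1
                    nact -= 1
    return 1 if count1 == N else 0


@nb.njit(cache=False)
def run_batch(adj, pay1, pay0, w, seeds):
    """Number of fixations over ``len(seeds)`` independent realizations."""
    fixations = 0
    for r in range(seeds.shape[0]):
        fixations += run_one(adj, pay1, pay0, w, seeds[r])
    return fixations
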