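"""Pure-Python twin of the compiled Monte-Carlo kernel.

Bit-for-bit identical to :mod:`graphgames._kernel` (same SplitMix64 stream,
same branch structure), so the two backends produce identical fixation
counts for identical seeds.  Used as a fallback and to cross-check the
compiled kernel on tiny run counts.
"""

import numpy as np

_MASK = (1 << 64) - 1
_INV53 = 2.0 ** -53


def _sm64(state: int):
    state = (state + 0x9E3779B97F4A7BC5) & _MASK
    z = state
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK
    z = z ^ (z >> 31)
    return state, z


def run_one_py(adj, pay1, pay0, w, seed):
    N, k = adj.shape
    state = np.zeros(N, np.int8)
    n1 = np.zeros(N, np.int64)

    rs = int(seed)
    rs, z = _sm64(rs)
    v0 = int((z >> 11) * _INV53 * N)
    state[v0] = 1
    for u in adj[v0]:
        n1[u] += 1
    count1 = 1

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
        v = act[int((z >> 11) * _INV53 * nact)]
        total = 0.0
        for i in range(k):
            u = adj[v, i]
            p = pay1[n1[u]] if state[u] == 1 else pay0[n1[u]]
            total += 1.0 - w + w * p
            cum[i] = total
        rs, z = _sm64(rs)
        r = (z >> 11) * _INV53 * total
        i = 0
        while i < k - 1 and cum[i] <= r:
            i += 1
        u = adj[v, i]
        if state[u] != state[v]:
            new = state[u]
            state[v] = new
            delta = 1 if new == 1 else -1
            count1 += delta
            for u2 in adj[v]:
                n1[u2] += delta
            for t in range(k + 1):
                x = v if t == k else int(adj[v, t])
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


def run_batch_py(adj, pay1, pay0, w, seeds):
    return sum(run_one_py(adj, pay1, pay0, w, s) for s in seeds)
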