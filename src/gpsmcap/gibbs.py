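"""Numba-compiled single-site Gibbs (heat-bath) sweeps for Potts sampling.

Couplings are passed as a dense symmetric ``(L, L, q, q)`` tensor so the
conditional at one site is a contiguous gather.  An optional three-site
interaction tensor supports the triplet mis-specification experiments.
Randomness uses numba's module-level legacy RNG, seeded inside the kernel,
so a run is fully determined by its seed argument.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _site_conditional_draw(state, i, h, Jfull, tpos, K, has_triplet, L, q):
    # energies of the q states of site i given the rest of the sequence
    e = np.empty(q)
    for a in range(q):
        x = h[i, a]
        for j in range(L):
            if j != i:
                x += Jfull[i, j, a, state[j]]
        e[a] = x
    if has_triplet:
        t0, t1, t2 = tpos[0], tpos[1], tpos[2]
        if i == t0:
            for a in range(q):
                e[a] += K[a, state[t1], state[t2]]
        elif i == t1:
            for a in range(q):
                e[a] += K[state[t0], a, state[t2]]
        elif i == t2:
            for a in range(q):
                e[a] += K[state[t0], state[t1], a]
    m = e[0]
    for a in range(1, q):
        if e[a] < m:
            m = e[a]
    tot = 0.0
    for a in range(q):
        e[a] = np.exp(-(e[a] - m))
        tot += e[a]
    u = np.random.random() * tot
    acc = 0.0
    for a in range(q):
        acc += e[a]
        if u <= acc:
            return a
    return q - 1


@njit(cache=True)
def gibbs_run(states, h, Jfull, tpos, K, has_triplet, n_sweeps_burn, thin, n_records, seed):
    """Run Gibbs sweeps on ``states`` (n_chains x L, modified in place).

    After ``n_sweeps_burn`` burn-in sweeps, records the chain states every
    ``thin`` sweeps, ``n_records`` times.  Returns an array of shape
    (n_records, n_chains, L).
    """
    np.random.seed(seed)
    n_chains, L = states.shape
    q = h.shape[1]
    out = np.empty((n_records, n_chains, L), dtype=np.uint8)

    for _ in range(n_sweeps_burn):
        order = np.random.permutation(L)
        for c in range(n_chains):
            for k in range(L):
                i = order[k]
                states[c, i] = _site_conditional_draw(
                    states[c], i, h, Jfull, tpos, K, has_triplet, L, q
                )
    for r in range(n_records):
        for _ in range(thin):
            order = np.random.permutation(L)
            for c in range(n_chains):
                for k in range(L):
                    i = order[k]
                    states[c, i] = _site_conditional_draw(
                        states[c], i, h, Jfull, tpos, K, has_triplet, L, q
                    )
        out[r] = states
    return out
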