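"""Numba inner loops for the exact stochastic engine.

The direct-method step draws two uniforms per event: an exponential
waiting time from the total propensity and a channel proportional to its
propensity.  Bimolecular propensities divide by the population size S (not
S-1), and same-species channels use the ordered-pair count X(X-1) without
a 1/2 symmetry factor, so the S -> infinity limit reproduces the
mean-field rate laws r_i x_U x_i and z x_i^2 exactly as written.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["ssa_run", "waiting_times"]


@njit(cache=True)
def ssa_run(kind, s_a, s_b, rate, net, counts_init, S, t_end, seed, grid,
            record_events):  # pragma: no cover - exercised via stochastic
    np.random.seed(seed)
    nsp = counts_init.shape[0]
    nr = kind.shape[0]
    counts = counts_init.copy()
    ng = grid.shape[0]
    grid_states = np.zeros((ng, nsp), dtype=np.int64)
    gi = 0

    cap = 1024 if record_events else 1
    ev_t = np.empty(cap, dtype=np.float64)
    ev_s = np.empty((cap, nsp), dtype=np.int64)
    n_ev = 0

    t = 0.0
    props = np.empty(nr, dtype=np.float64)
    n_events_total = 0
    while True:
        a0 = 0.0
        for m in range(nr):
            s = counts[s_a[m]]
            if kind[m] == 0:
                p = rate[m] * s
            elif kind[m] == 1:
                p = rate[m] * s * counts[s_b[m]] / S
            else:
                p = rate[m] * s * (s - 1) / S
            props[m] = p
            a0 += p
        if a0 <= 0.0:
            t_next = np.inf  # absorbing state: hold forever
        else:
            t_next = t - np.log(1.0 - np.random.random()) / a0
        while gi < ng and grid[gi] < t_next:
            for j in range(nsp):
                grid_states[gi, j] = counts[j]
            gi += 1
        if t_next > t_end:
            break
        thr = np.random.random() * a0
        m_sel = nr - 1
        c = 0.0
        for m in range(nr):
            c += props[m]
            if thr < c:
                m_sel = m
                break
        t = t_next
        for j in range(nsp):
            counts[j] += net[m_sel, j]
        n_events_total += 1
        if record_events:
            if n_ev == cap:
                cap2 = cap * 2
                new_t = np.empty(cap2, dtype=np.float64)
                new_s = np.empty((cap2, nsp), dtype=np.int64)
                new_t[:cap] = ev_t
                new_s[:cap] = ev_s
                ev_t = new_t
                ev_s = new_s
                cap = cap2
            ev_t[n_ev] = t
            for j in range(nsp):
                ev_s[n_ev, j] = counts[j]
            n_ev += 1
    while gi < ng:
        for j in range(nsp):
            grid_states[gi, j] = counts[j]
        gi += 1
    return grid_states, ev_t[:n_ev].copy(), ev_s[:n_ev].copy(), n_events_total


@njit(cache=True)
def waiting_times(a0, n, seed):  # pragma: no cover - exercised via stochastic
    np.random.seed(seed)
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        out[i] = -np.log(1.0 - np.random.random()) / a0
    return out
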