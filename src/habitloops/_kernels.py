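"""Compiled inner loop of the Euler integration.

The kernel mirrors :meth:`habitloops.network.Network.step` exactly (the test
suite checks the two integrators against each other on noise-free dynamics).
Noise is drawn from numba's internal RNG, seeded once per simulated subject
via :func:`seed_noise` for bit-reproducible runs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# phase return codes
DONE = 0
CROSSED = 1
UNSTABLE = 2


@njit(cache=True)
def seed_noise(seed):
    np.random.seed(seed)


@njit(cache=True)
def run_phase(G, v, r, tau, baseline, gain, ext, dt, n_steps, noise_amp_vec,
              thr_lo, thr_hi, threshold, avg_out, collect_avg,
              inst_bound, t0_ms):
    """Integrate ``n_steps`` Euler steps in place.

    Returns ``(status, steps_done, unit)`` where ``status`` is DONE, CROSSED
    (a unit in ``[thr_lo, thr_hi)`` reached ``threshold``; ``unit`` is the
    winning index relative to ``thr_lo``, ties broken by higher rate then
    lower index) or UNSTABLE (``unit`` is the absolute index of the runaway
    unit).  When ``collect_avg`` is true, ``avg_out`` accumulates the mean
    rate vector over the executed steps.
    """
    n = v.shape[0]
    detect = threshold > 0.0 and thr_hi > thr_lo
    for step in range(n_steps):
        u = np.dot(G, r)
        for i in range(n):
            du = (dt / tau[i]) * (u[i] + baseline[i] + ext[i] - v[i])
            if noise_amp_vec[i] > 0.0:
                du += np.random.uniform(-noise_amp_vec[i], noise_amp_vec[i])
            v[i] += du
            ri = v[i]
            if ri < 0.0:
                ri = 0.0
            r[i] = ri * gain[i]
        for i in range(n):
            if not np.isfinite(v[i]) or not np.isfinite(r[i]) or r[i] > inst_bound:
                return UNSTABLE, step + 1, i
        if collect_avg:
            for i in range(n):
                avg_out[i] += r[i]
        if detect:
            best = -1
            best_r = 0.0
            for i in range(thr_lo, thr_hi):
                # winner: highest rate above threshold; lower index on ties
                if r[i] >= threshold and (best < 0 or r[i] > best_r):
                    best_r = r[i]
                    best = i - thr_lo
            if best >= 0:
                if collect_avg:
                    for i in range(n):
                        avg_out[i] /= (step + 1)
                return CROSSED, step + 1, best
    if collect_avg and n_steps > 0:
        for i in range(n):
            avg_out[i] /= n_steps
    return DONE, n_steps, -1
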