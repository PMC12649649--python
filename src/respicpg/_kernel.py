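"""Inner simulation loop (numba-compiled).

The network state is advanced on a fixed grid with the exact propagator of
the four-variable linear subsystem (V, I_adap, I_dep, I_syn); spikes are
drawn from the escape-rate probability per step, resets applied, and each
spike's weight pushed into a ring buffer that realizes the synaptic delay.

Randomness is counter-based: every (seed, step, neuron) triple is hashed
through a splitmix64-style finalizer to a uniform in [0, 1).  Because no
stream state is carried between steps, a run split into segments that carry
the neuron state and ring buffer is bit-identical to an uninterrupted run —
the property the closed-loop controller relies on.  Steps are therefore
always indexed absolutely.

Conventions: a spike drawn during step ``s`` is stamped ``(s + 1) * dt`` (end
of the update interval); an edge with delay ``d`` steps delivers its weight
at the start of step ``s + 1 + d``, i.e. exactly ``d * dt`` after the stamp.
An external (generator) spike at time ``t`` is processed at step
``round(t / dt)`` and delivered with ring offset ``d``, so its influence also
starts exactly ``d * dt`` after the stamp.
"""

from __future__ import annotations

import numpy as np
from numba import njit, uint64

_U1 = uint64(0x9E3779B97F4A7C15)
_U2 = uint64(0xBF58476D1CE4E5B9)
_U3 = uint64(0x94D049BB133111EB)
_INV = 1.0 / 9007199254740992.0  # 2**-53


@njit(inline="always", cache=True)
def _uniform(seed, step, i):
    z = uint64(seed) + uint64(step) * _U1 + uint64(i + 1) * _U2
    z = (z ^ (z >> uint64(30))) * _U2
    z = (z ^ (z >> uint64(27))) * _U3
    z = z ^ (z >> uint64(31))
    return float((z >> uint64(11))) * _INV


@njit(cache=True)
def run_steps(
    step_start, n_steps, dt,
    pop,                    # (n,) population index per neuron
    A, b,                   # (npop, 4, 4), (npop, 4): free propagator
    Ac, bc,                 # (npop, 2, 2), (npop, 2): clamped-V propagator
    es_syn,                 # (npop,) per-step I_syn decay factor
    lam0, tauV, Vth, Vr, A2, A1,   # (npop,)
    dep_inc,                # (npop,) float64: 1.0 accumulate A1, 0.0 set
    tref_steps,             # (npop,) int64
    V, Iadap, Idep, Isyn,   # (n,) state, updated in place
    refrac,                 # (n,) int64, updated in place
    ring,                   # (D, n) delayed-delivery buffer, updated in place
    indptr, targets, weights, delays,   # CSR over n + n_ext sources
    ext_steps, ext_src,     # external emissions sorted by absolute step
    seed,
):
    """Advance the network; returns (spike_steps, spike_ids, err_step).

    ``err_step`` is -1 on success, else the first step at which a non-finite
    membrane potential appeared.
    """
    n = V.shape[0]
    D = ring.shape[0]
    cap = 4096
    sp_step = np.empty(cap, np.int64)
    sp_id = np.empty(cap, np.int64)
    nsp = 0
    ep = 0
    n_ext = ext_steps.shape[0]
    while ep < n_ext and ext_steps[ep] < step_start:
        ep += 1
    for s in range(step_start, step_start + n_steps):
        row = s % D
        for i in range(n):
            Isyn[i] += ring[row, i]
            ring[row, i] = 0.0
        while ep < n_ext and ext_steps[ep] == s:
            src = ext_src[ep]
            for e in range(indptr[src], indptr[src + 1]):
                ring[(s + delays[e]) % D, targets[e]] += weights[e]
            ep += 1
        for i in range(n):
            k = pop[i]
            if refrac[i] > 0:
                ia = Ac[k, 0, 0] * Iadap[i] + Ac[k, 0, 1] * Idep[i] + bc[k, 0]
                idp = Ac[k, 1, 0] * Iadap[i] + Ac[k, 1, 1] * Idep[i] + bc[k, 1]
                Iadap[i] = ia
                Idep[i] = idp
                Isyn[i] *= es_syn[k]
                V[i] = Vr[k]
                refrac[i] -= 1
            else:
                v = (A[k, 0, 0] * V[i] + A[k, 0, 1] * Iadap[i]
                     + A[k, 0, 2] * Idep[i] + A[k, 0, 3] * Isyn[i] + b[k, 0])
                ia = (A[k, 1, 0] * V[i] + A[k, 1, 1] * Iadap[i]
                      + A[k, 1, 2] * Idep[i] + A[k, 1, 3] * Isyn[i] + b[k, 1])
                idp = (A[k, 2, 0] * V[i] + A[k, 2, 1] * Iadap[i]
                       + A[k, 2, 2] * Idep[i] + A[k, 2, 3] * Isyn[i] + b[k, 2])
                isy = A[k, 3, 3] * Isyn[i] + b[k, 3]
                if not np.isfinite(v):
                    return sp_step[:nsp], sp_id[:nsp], s
                V[i] = v
                Iadap[i] = ia
                Idep[i] = idp
                Isyn[i] = isy
                lam = lam0[k] * np.exp((v - Vth[k]) / tauV[k])
                p = -np.expm1(-lam * dt)
                if p > 0.0 and _uniform(seed, s, i) < p:
                    V[i] = Vr[k]
                    Iadap[i] = ia + A2[k]
                    Idep[i] = dep_inc[k] * idp + A1[k]
                    refrac[i] = tref_steps[k]
                    if nsp == cap:
                        cap *= 2
                        t1 = np.empty(cap, np.int64)
                        t1[:nsp] = sp_step
                        sp_step = t1
                        t2 = np.empty(cap, np.int64)
                        t2[:nsp] = sp_id
                        sp_id = t2
                    sp_step[nsp] = s
                    sp_id[nsp] = i
                    nsp += 1
                    for e in range(indptr[i], indptr[i + 1]):
                        ring[(s + 1 + delays[e]) % D, targets[e]] += weights[e]
    return sp_step[:nsp].copy(), sp_id[:nsp].copy(), np.int64(-1)
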