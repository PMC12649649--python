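"""Shared independent oracles used by several test modules."""

import numpy as np


def rk4_oracle(state, p, t_end, dt=0.001):
    """Dense-step classic RK4 integration of the free subthreshold ODE."""
    def deriv(x):
        v, ia, idp = x
        return np.array([
            -(v - p.E_L) / p.tau_m + (p.I_e + p.I_stim + idp - ia) / p.C_m,
            p.k_adap * (v - p.E_L) - p.k_2 * ia,
            -p.k_1 * idp,
        ])

    x = np.array([state.V_m, state.I_adap, state.I_dep])
    n = int(round(t_end / dt))
    for _ in range(n):
        k1 = deriv(x)
        k2 = deriv(x + 0.5 * dt * k1)
        k3 = deriv(x + 0.5 * dt * k2)
        k4 = deriv(x + dt * k3)
        x = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return x


def brute_force_bursts(train, min_spikes, isi_max):
    """Enumerate all contiguous subsequences; keep maximal qualifying runs."""
    t = list(train)
    qualifying = []
    for i in range(len(t)):
        for j in range(i + min_spikes - 1, len(t)):
            if all(t[k + 1] - t[k] < isi_max for k in range(i, j)):
                qualifying.append((i, j))
    maximal = [
        (i, j) for (i, j) in qualifying
        if not any((a <= i and j <= b and (a, b) != (i, j))
                   for (a, b) in qualifying)
    ]
    return [(t[i], t[j], j - i + 1) for (i, j) in sorted(maximal)]
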