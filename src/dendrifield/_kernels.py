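"""Compiled inner loops for the ball-and-stick and point neuron simulators.

Everything in this module works in SI units (V, A, S, F, m, s). The public
wrappers in :mod:`dendrifield.bs` and :mod:`dendrifield.point` convert from
the user-facing mV/pA/ms interface.

The cable solver advances the spatially discretized ball-and-stick system one
implicit-Euler step at a time. The grid is node-centered with the soma at
node 0 and the sealed/driven end at node ``n_seg``; both Robin boundary
conditions are folded in via ghost nodes, which attaches half a segment of
cable membrane to each boundary row and keeps the scheme second-order in dx.
The resulting tridiagonal system has constant coefficients (the somatic
exponential term is evaluated explicitly at the previous step), so each step
is a single Thomas solve; during the refractory window the somatic row is
replaced by the Dirichlet clamp V0 = V_r while the cable keeps evolving.
"""

import numpy as np
from numba import njit

#: error codes returned by the kernels
OK = 0
BLOWUP = 1


@njit(cache=True)
def _thomas(lower, diag, upper, rhs, out, cl, cd):
    """Solve a tridiagonal system in place; cl/cd are scratch arrays."""
    n = diag.size
    cd[0] = diag[0]
    cl[0] = rhs[0]
    for i in range(1, n):
        w = lower[i] / cd[i - 1]
        cd[i] = diag[i] - w * upper[i - 1]
        cl[i] = rhs[i] - w * cl[i - 1]
    out[n - 1] = cl[n - 1] / cd[n - 1]
    for i in range(n - 2, -1, -1):
        out[i] = (cl[i] - upper[i] * out[i + 1]) / cd[i]


@njit(cache=True)
def bs_step_loop(
    V,            # (n_nodes,) initial voltage deviation [V], modified in place
    I_s, I_d, E,  # (n_steps+1,) drives sampled on the time grid [A, A, V/m]
    dt, dx,       # [s], [m]
    c_m, g_m, g_i, C_s, G_s,
    Delta_T, V_T, V_r, V_s, T_ref,
    theta,        # time-weighting: 1.0 backward Euler, 0.5 trapezoidal
    v_soma,       # (n_steps+1,) output, somatic voltage [V]
    spike_steps,  # (max_spikes,) output, step index of each spike
    record_full,  # bool: fill v_full
    v_full,       # (n_steps+1, n_nodes) or (1, 1) dummy
):
    """Advance the BS model over the full drive; returns (n_spikes, status, step)."""
    n_nodes = V.size
    n_steps = I_s.size - 1
    ref_steps = int(round(T_ref / dt))
    lif = Delta_T == 0.0
    omt = 1.0 - theta

    a = g_i / dx
    # capacitive (mass) and conductive/coupling (stiffness) diagonals; the
    # boundary rows carry half a segment of cable membrane from the
    # ghost-node elimination plus the lumped somatic terms
    soma_cap = (C_s + 0.5 * c_m * dx) / dt
    soma_k = G_s + 0.5 * g_m * dx + a
    int_cap = c_m * dx / dt
    int_k = g_m * dx + 2.0 * a
    end_cap = 0.5 * c_m * dx / dt
    end_k = 0.5 * g_m * dx + a

    lower = np.empty(n_nodes)
    diag = np.empty(n_nodes)
    upper = np.empty(n_nodes)
    rhs = np.empty(n_nodes)
    cl = np.empty(n_nodes)
    cd = np.empty(n_nodes)
    Vn = np.empty(n_nodes)

    for i in range(n_nodes):
        lower[i] = -theta * a
        upper[i] = -theta * a
        diag[i] = int_cap + theta * int_k
    diag[0] = soma_cap + theta * soma_k
    diag[n_nodes - 1] = end_cap + theta * end_k

    v_soma[0] = V[0]
    if record_full:
        for i in range(n_nodes):
            v_full[0, i] = V[i]

    n_spikes = 0
    ref_count = 0
    guard = V_s + 10.0 * Delta_T

    for n in range(n_steps):
        # RHS: mass*V^n - (1-theta)*K*V^n + theta*b^{n+1} + (1-theta)*b^n
        for i in range(1, n_nodes - 1):
            rhs[i] = int_cap * V[i] - omt * (int_k * V[i] - a * (V[i - 1] + V[i + 1]))
        i = n_nodes - 1
        rhs[i] = (
            end_cap * V[i] - omt * (end_k * V[i] - a * V[i - 1])
            + theta * (I_d[n + 1] + g_i * E[n + 1]) + omt * (I_d[n] + g_i * E[n])
        )
        if ref_count > 0:
            diag[0] = 1.0
            upper[0] = 0.0
            rhs[0] = V_r
        else:
            diag[0] = soma_cap + theta * soma_k
            upper[0] = -theta * a
            rhs[0] = (
                soma_cap * V[0] - omt * (soma_k * V[0] - a * V[1])
                + theta * (I_s[n + 1] - g_i * E[n + 1]) + omt * (I_s[n] - g_i * E[n])
            )
            if not lif:
                # exponential soma current, explicit at the previous step
                rhs[0] += G_s * Delta_T * np.exp((V[0] - V_T) / Delta_T)
        _thomas(lower, diag, upper, rhs, Vn, cl, cd)
        for i in range(n_nodes):
            V[i] = Vn[i]

        if ref_count > 0:
            ref_count -= 1
        else:
            if V[0] >= V_s:
                # V_s is a cutoff: overshoot beyond it is reset anyway
                if n_spikes < spike_steps.size:
                    spike_steps[n_spikes] = n + 1
                n_spikes += 1
                V[0] = V_r
                ref_count = ref_steps
            elif not lif and not np.isfinite(V[0]):
                return n_spikes, BLOWUP, n + 1

        v_soma[n + 1] = V[0]
        if record_full:
            for i in range(n_nodes):
                v_full[n + 1, i] = V[i]

    return n_spikes, OK, n_steps


@njit(cache=True)
def point_step_loop(
    v0,            # initial voltage [V]
    I_tot,         # (n_steps+1,) total input current on the time grid [A]
    dt,
    C, G, alpha,
    Delta_T, V_T, V_r_prime, V_s, T_ref,
    v_out,         # (n_steps+1,) output voltage [V]
    spike_steps,
):
    """Forward-Euler point neuron (LIF for Delta_T == 0, else EIF with scaling alpha)."""
    n_steps = I_tot.size - 1
    ref_steps = int(round(T_ref / dt))
    lif = Delta_T == 0.0
    guard = V_s + 10.0 * Delta_T

    V = v0
    v_out[0] = V
    n_spikes = 0
    ref_count = 0
    for n in range(n_steps):
        if ref_count > 0:
            ref_count -= 1
            v_out[n + 1] = V
            continue
        dv = -G * V + I_tot[n]
        if not lif:
            dv += alpha * G * Delta_T * np.exp((V - V_T) / Delta_T)
        V = V + dt * dv / C
        if V >= V_s:
            # cutoff: any overshoot beyond V_s is reset
            if n_spikes < spike_steps.size:
                spike_steps[n_spikes] = n + 1
            n_spikes += 1
            V = V_r_prime
            ref_count = ref_steps
        elif not lif and not np.isfinite(V):
            return n_spikes, BLOWUP, n + 1
        v_out[n + 1] = V
    return n_spikes, OK, n_steps
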