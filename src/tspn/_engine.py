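"""Compiled exponential-Euler inner loop.

The per-step update is deliberately branch-light so numba can keep the
whole loop in machine code.  Gate descriptors arrive as packed rows:

    col 0: kind (0 absent, 1 voltage-dependent, 2 calcium-dependent)
    col 1: v_half        col 2: slope      col 3: exponent
    col 4: tau_min       col 5: tau_amp
    col 6: tau_v1        col 7: tau_k1     col 8: tau_v2   col 9: tau_k2
    col 10: ca_half      col 11: hill

Voltage advances by exponential Euler towards the conductance-weighted
target; gating variables relax exponentially towards their steady state
evaluated at the midpoint of the voltage step, which markedly improves
spike-time accuracy at the default 0.1 ms step without leaving the
exponential-Euler family.  Calcium-dependent gates are instantaneous
functions of [Ca]; the slow timescale of the calcium-activated current
comes from calcium accumulation itself, whose effective relaxation time
is 1/(lambda * k_removal).
"""

import math

from numba import njit


@njit(cache=True)
def _ipow(x, n):
    out = 1.0
    for _ in range(n):
        out *= x
    return out


@njit(cache=True)
def run_steps(v0, m, h, ca0, g_max, e_rev, act, inact,
              c_m, lam, alpha, k_ca, cal_idx,
              i_inj, g_syn, e_syn, dt, v_out, ca_out):
    """Advance the state over len(i_inj) steps, recording V and Ca.

    Returns (status, v_final, ca_final); status is -1 on success or the
    index of the step at which the state became non-finite / |V|>200 mV.
    ``m`` and ``h`` are updated in place with the final gate values.
    """
    n = i_inj.shape[0]
    nch = g_max.shape[0]
    has_syn = g_syn.shape[0] == n
    v = v0
    ca = ca0
    for t in range(n):
        # instantaneous conductances and currents
        g_tot = 0.0
        g_e = 0.0
        i_cal = 0.0
        for c in range(nch):
            gc = g_max[c]
            if act[c, 0] > 0.5:
                gc *= _ipow(m[c], int(act[c, 3]))
            if inact[c, 0] > 0.5:
                gc *= _ipow(h[c], int(inact[c, 3]))
            g_tot += gc
            g_e += gc * e_rev[c]
            if c == cal_idx:
                i_cal = gc * (v - e_rev[c])
        gs = g_syn[t] if has_syn else 0.0
        g_tot += gs
        g_e += gs * e_syn

        v_out[t] = v
        ca_out[t] = ca

        # voltage: exponential Euler towards conductance-weighted target
        if g_tot > 1e-12:
            v_inf = (g_e + i_inj[t]) / g_tot
            v_new = v_inf + (v - v_inf) * math.exp(-dt * g_tot / c_m)
        else:
            v_new = v + dt * i_inj[t] / c_m
        v_mid = 0.5 * (v + v_new)

        # gate updates (exact exponential relaxation at the midpoint V)
        for c in range(nch):
            k = act[c, 0]
            if k == 1.0:
                xinf = 1.0 / (1.0 + math.exp((v_mid - act[c, 1]) / act[c, 2]))
                tau = act[c, 4]
                if act[c, 5] != 0.0:
                    tau += act[c, 5] / (
                        math.exp((v_mid - act[c, 6]) / act[c, 7])
                        + math.exp(-(v_mid - act[c, 8]) / act[c, 9]))
                m[c] = xinf + (m[c] - xinf) * math.exp(-dt / tau)
            elif k == 2.0:
                if ca <= 0.0:
                    m[c] = 0.0
                else:
                    r = _ipow(ca / act[c, 10], int(act[c, 11]))
                    m[c] = r / (1.0 + r)
            if inact[c, 0] == 1.0:
                xinf = 1.0 / (1.0 + math.exp((v_mid - inact[c, 1]) / inact[c, 2]))
                tau = inact[c, 4]
                if inact[c, 5] != 0.0:
                    tau += inact[c, 5] / (
                        math.exp((v_mid - inact[c, 6]) / inact[c, 7])
                        + math.exp(-(v_mid - inact[c, 8]) / inact[c, 9]))
                h[c] = xinf + (h[c] - xinf) * math.exp(-dt / tau)

        # calcium: exponential relaxation towards -alpha*I_CaL/k_removal
        ca_target = -alpha * i_cal / k_ca
        ca = ca_target + (ca - ca_target) * math.exp(-dt * lam * k_ca)
        if ca < 0.0:
            ca = 0.0

        v = v_new
        if not (math.isfinite(v) and math.isfinite(ca)) or abs(v) > 200.0:
            return t, v, ca
    return -1, v, ca
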