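"""Clock-driven simulation kernel (numba-jitted).

The kernel applies, per step and in a fixed order, exactly the update
rules defined scalar-wise in :mod:`ssanet.neurons` and
:mod:`ssanet.synapses`: Poisson input draws, exponential-transfer synapse
updates, exact-discretization OU noise, Heun-integrated AdEx units.
Spikes of the AdEx populations take effect on their postsynaptic targets
at the next step (one-dt conduction delay, the closest clock-driven
realization of the zero-delay connectivity).

RNG: the kernel consumes a single legacy numpy stream seeded once per
call, making every simulation a pure function of (arrays, seed).  Draw
order per step: A-unit uniforms (sub-population-major), then OU normals
for B, C, D in that order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EXP_ARG_MAX = 30.0


@njit(cache=True, fastmath=True)
def run_network(
    n_steps,
    dt,
    # stimulus: per-step tone index (-1 = gap), per-tone and gap spike probs
    tone_idx,          # (n_steps,) int32
    p_tone,            # (n_tones, n_subpop) float64
    p_gap,             # (n_subpop,) float64
    # architecture flags and sizes
    has_c, has_d,
    n_subpop, n_b, n_c, n_d, in_deg,
    # A->B synapses, flattened (n_subpop * n_b), index k * n_b + j
    ab_tr, ab_td, ab_pu, ab_rec, ab_w, ab_er, ab_dep,
    # A->C synapses, same layout (empty arrays when has_c is False)
    ac_tr, ac_td, ac_pu, ac_rec, ac_w, ac_er, ac_dep,
    # C->B synapses, flattened (n_b * in_deg), index j * in_deg + m
    cb_pre, cb_tr, cb_td, cb_pu, cb_rec, cb_w, cb_er, cb_dep,
    # B->D synapses, flattened (n_b * n_d), index j * n_d + j2
    bd_tr, bd_td, bd_pu, bd_rec, bd_w, bd_er, bd_dep,
    # AdEx parameters (shared by B, C, D units)
    cap, g_l, e_l, d_t, v_t, tau_w, a_w, b_w, v_reset, v_cut,
    # OU noise parameters per population: rows = B, C, D
    g_e0, g_i0, sig_e, sig_i, tau_e, tau_i, e_e, e_i, scale,
    seed,
    # output buffers
    out_unit, out_time, out_pop,
):
    np.random.seed(seed)

    n_ab = n_subpop * n_b
    r_ab = np.ones(n_ab); e_ab = np.zeros(n_ab); i_ab = np.zeros(n_ab); t_ab = np.zeros(n_ab)
    n_ac = n_subpop * n_c if has_c else 0
    r_ac = np.ones(n_ac); e_ac = np.zeros(n_ac); i_ac = np.zeros(n_ac); t_ac = np.zeros(n_ac)
    n_cb = n_b * in_deg if has_c else 0
    r_cb = np.ones(n_cb); e_cb = np.zeros(n_cb); i_cb = np.zeros(n_cb); t_cb = np.zeros(n_cb)
    n_bd = n_b * n_d if has_d else 0
    r_bd = np.ones(n_bd); e_bd = np.zeros(n_bd); i_bd = np.zeros(n_bd); t_bd = np.zeros(n_bd)

    # exponential transfer factors per synapse (full-dt step)
    ab_k_re = -np.expm1(-dt / ab_tr); ab_k_ei = -np.expm1(-dt / ab_td); ab_k_ir = -np.expm1(-dt / ab_rec)
    ac_k_re = -np.expm1(-dt / ac_tr); ac_k_ei = -np.expm1(-dt / ac_td); ac_k_ir = -np.expm1(-dt / ac_rec)
    cb_k_re = -np.expm1(-dt / cb_tr); cb_k_ei = -np.expm1(-dt / cb_td); cb_k_ir = -np.expm1(-dt / cb_rec)
    bd_k_re = -np.expm1(-dt / bd_tr); bd_k_ei = -np.expm1(-dt / bd_td); bd_k_ir = -np.expm1(-dt / bd_rec)

    v_b = np.full(n_b, e_l); w_b = np.zeros(n_b)
    v_c = np.full(n_c, e_l); w_c = np.zeros(n_c)
    v_d = np.full(n_d, e_l); w_d = np.zeros(n_d)
    ge_b = np.full(n_b, g_e0[0]); gi_b = np.full(n_b, g_i0[0])
    ge_c = np.full(n_c, g_e0[1]); gi_c = np.full(n_c, g_i0[1])
    ge_d = np.full(n_d, g_e0[2]); gi_d = np.full(n_d, g_i0[2])

    b_prev = np.zeros(n_b, np.uint8)
    c_prev = np.zeros(n_c, np.uint8)

    dec_e = np.exp(-dt / tau_e)
    dif_e = sig_e * np.sqrt(1.0 - dec_e * dec_e)
    dec_i = np.exp(-dt / tau_i)
    dif_i = sig_i * np.sqrt(1.0 - dec_i * dec_i)

    cap_out = out_unit.shape[0]
    n_out = 0
    overflow = 0

    i_b = np.zeros(n_b)
    i_c = np.zeros(n_c)
    i_d = np.zeros(n_d)

    for step in range(n_steps):
        t_now = (step + 1) * dt
        ti = tone_idx[step]
        for j in range(n_b):
            i_b[j] = 0.0
        for j in range(n_c):
            i_c[j] = 0.0
        for j in range(n_d):
            i_d[j] = 0.0

        # --- population A: Poisson draws feed A->B (and A->C) synapses.
        # C unit j shares the Poisson column of B unit j.
        for k in range(n_subpop):
            pk = p_tone[ti, k] if ti >= 0 else p_gap[k]
            for j in range(n_b):
                sp = np.random.random() < pk
                idx = k * n_b + j
                timer = ab_pu[idx] if sp else t_ab[idx]
                if timer >= dt:
                    t_re = r_ab[idx] * ab_k_re[idx]
                elif timer > 0.0:
                    t_re = r_ab[idx] * -np.expm1(-timer / ab_tr[idx])
                else:
                    t_re = 0.0
                t_ei = e_ab[idx] * ab_k_ei[idx]
                t_ir = i_ab[idx] * ab_k_ir[idx] if ab_dep else i_ab[idx]
                r_ab[idx] += t_ir - t_re
                e_ab[idx] += t_re - t_ei
                i_ab[idx] += t_ei - t_ir
                t_ab[idx] = timer - dt if timer > dt else 0.0
                i_b[j] += ab_w[idx] * e_ab[idx] * (ab_er[idx] - v_b[j])
                if has_c:
                    timer = ac_pu[idx] if sp else t_ac[idx]
                    if timer >= dt:
                        t_re = r_ac[idx] * ac_k_re[idx]
                    elif timer > 0.0:
                        t_re = r_ac[idx] * -np.expm1(-timer / ac_tr[idx])
                    else:
                        t_re = 0.0
                    t_ei = e_ac[idx] * ac_k_ei[idx]
                    t_ir = i_ac[idx] * ac_k_ir[idx] if ac_dep else i_ac[idx]
                    r_ac[idx] += t_ir - t_re
                    e_ac[idx] += t_re - t_ei
                    i_ac[idx] += t_ei - t_ir
                    t_ac[idx] = timer - dt if timer > dt else 0.0
                    i_c[j] += ac_w[idx] * e_ac[idx] * (ac_er[idx] - v_c[j])

        # --- C -> B inhibition (previous-step C spikes)
        if has_c:
            for j in range(n_b):
                for m in range(in_deg):
                    idx = j * in_deg + m
                    sp = c_prev[cb_pre[idx]] == 1
                    timer = cb_pu[idx] if sp else t_cb[idx]
                    if timer >= dt:
                        t_re = r_cb[idx] * cb_k_re[idx]
                    elif timer > 0.0:
                        t_re = r_cb[idx] * -np.expm1(-timer / cb_tr[idx])
                    else:
                        t_re = 0.0
                    t_ei = e_cb[idx] * cb_k_ei[idx]
                    t_ir = i_cb[idx] * cb_k_ir[idx] if cb_dep else i_cb[idx]
                    r_cb[idx] += t_ir - t_re
                    e_cb[idx] += t_re - t_ei
                    i_cb[idx] += t_ei - t_ir
                    t_cb[idx] = timer - dt if timer > dt else 0.0
                    i_b[j] += cb_w[idx] * e_cb[idx] * (cb_er[idx] - v_b[j])

        # --- B -> D (previous-step B spikes)
        if has_d:
            for j in range(n_b):
                sp = b_prev[j] == 1
                for j2 in range(n_d):
                    idx = j * n_d + j2
                    timer = bd_pu[idx] if sp else t_bd[idx]
                    if timer >= dt:
                        t_re = r_bd[idx] * bd_k_re[idx]
                    elif timer > 0.0:
                        t_re = r_bd[idx] * -np.expm1(-timer / bd_tr[idx])
                    else:
                        t_re = 0.0
                    t_ei = e_bd[idx] * bd_k_ei[idx]
                    t_ir = i_bd[idx] * bd_k_ir[idx] if bd_dep else i_bd[idx]
                    r_bd[idx] += t_ir - t_re
                    e_bd[idx] += t_re - t_ei
                    i_bd[idx] += t_ei - t_ir
                    t_bd[idx] = timer - dt if timer > dt else 0.0
                    i_d[j2] += bd_w[idx] * e_bd[idx] * (bd_er[idx] - v_d[j2])

        # --- OU noise currents
        for j in range(n_b):
            ge_b[j] = g_e0[0] + (ge_b[j] - g_e0[0]) * dec_e[0] + dif_e[0] * np.random.standard_normal()
            gi_b[j] = g_i0[0] + (gi_b[j] - g_i0[0]) * dec_i[0] + dif_i[0] * np.random.standard_normal()
            i_b[j] += scale[0] * (ge_b[j] * (e_e[0] - v_b[j]) + gi_b[j] * (e_i[0] - v_b[j]))
        for j in range(n_c):
            ge_c[j] = g_e0[1] + (ge_c[j] - g_e0[1]) * dec_e[1] + dif_e[1] * np.random.standard_normal()
            gi_c[j] = g_i0[1] + (gi_c[j] - g_i0[1]) * dec_i[1] + dif_i[1] * np.random.standard_normal()
            i_c[j] += scale[1] * (ge_c[j] * (e_e[1] - v_c[j]) + gi_c[j] * (e_i[1] - v_c[j]))
        for j in range(n_d):
            ge_d[j] = g_e0[2] + (ge_d[j] - g_e0[2]) * dec_e[2] + dif_e[2] * np.random.standard_normal()
            gi_d[j] = g_i0[2] + (gi_d[j] - g_i0[2]) * dec_i[2] + dif_i[2] * np.random.standard_normal()
            i_d[j] += scale[2] * (ge_d[j] * (e_e[2] - v_d[j]) + gi_d[j] * (e_i[2] - v_d[j]))

        # --- AdEx integration (Heun), spike detection and reset
        for j in range(n_b):
            v = v_b[j]; w = w_b[j]; cur = i_b[j]
            arg = (v - v_t) / d_t
            if arg > _EXP_ARG_MAX:
                arg = _EXP_ARG_MAX
            dv1 = (-g_l * (v - e_l) + g_l * d_t * np.exp(arg) - w + cur) / cap
            dw1 = (a_w * (v - e_l) - w) / tau_w
            vp = v + dt * dv1
            wp = w + dt * dw1
            if vp >= v_cut:
                v_new = vp; w_new = wp
            else:
                arg = (vp - v_t) / d_t
                if arg > _EXP_ARG_MAX:
                    arg = _EXP_ARG_MAX
                dv2 = (-g_l * (vp - e_l) + g_l * d_t * np.exp(arg) - wp + cur) / cap
                dw2 = (a_w * (vp - e_l) - wp) / tau_w
                v_new = v + 0.5 * dt * (dv1 + dv2)
                w_new = w + 0.5 * dt * (dw1 + dw2)
            if v_new >= v_cut:
                v_new = v_reset
                w_new += b_w
                b_prev[j] = 1
                if n_out < cap_out:
                    out_pop[n_out] = 0
                    out_unit[n_out] = j
                    out_time[n_out] = t_now
                    n_out += 1
                else:
                    overflow = 1
            else:
                b_prev[j] = 0
            if not np.isfinite(v_new):
                return -1, overflow  # numerical blow-up
            v_b[j] = v_new; w_b[j] = w_new

        for j in range(n_c):
            v = v_c[j]; w = w_c[j]; cur = i_c[j]
            arg = (v - v_t) / d_t
            if arg > _EXP_ARG_MAX:
                arg = _EXP_ARG_MAX
            dv1 = (-g_l * (v - e_l) + g_l * d_t * np.exp(arg) - w + cur) / cap
            dw1 = (a_w * (v - e_l) - w) / tau_w
            vp = v + dt * dv1
            wp = w + dt * dw1
            if vp >= v_cut:
                v_new = vp; w_new = wp
            else:
                arg = (vp - v_t) / d_t
                if arg > _EXP_ARG_MAX:
                    arg = _EXP_ARG_MAX
                dv2 = (-g_l * (vp - e_l) + g_l * d_t * np.exp(arg) - wp + cur) / cap
                dw2 = (a_w * (vp - e_l) - wp) / tau_w
                v_new = v + 0.5 * dt * (dv1 + dv2)
                w_new = w + 0.5 * dt * (dw1 + dw2)
            if v_new >= v_cut:
                v_new = v_reset
                w_new += b_w
                c_prev[j] = 1
                if n_out < cap_out:
                    out_pop[n_out] = 1
                    out_unit[n_out] = j
                    out_time[n_out] = t_now
                    n_out += 1
                else:
                    overflow = 1
            else:
                c_prev[j] = 0
            if not np.isfinite(v_new):
                return -1, overflow  # numerical blow-up
            v_c[j] = v_new; w_c[j] = w_new

        for j in range(n_d):
            v = v_d[j]; w = w_d[j]; cur = i_d[j]
            arg = (v - v_t) / d_t
            if arg > _EXP_ARG_MAX:
                arg = _EXP_ARG_MAX
            dv1 = (-g_l * (v - e_l) + g_l * d_t * np.exp(arg) - w + cur) / cap
            dw1 = (a_w * (v - e_l) - w) / tau_w
            vp = v + dt * dv1
            wp = w + dt * dw1
            if vp >= v_cut:
                v_new = vp; w_new = wp
            else:
                arg = (vp - v_t) / d_t
                if arg > _EXP_ARG_MAX:
                    arg = _EXP_ARG_MAX
                dv2 = (-g_l * (vp - e_l) + g_l * d_t * np.exp(arg) - wp + cur) / cap
                dw2 = (a_w * (vp - e_l) - wp) / tau_w
                v_new = v + 0.5 * dt * (dv1 + dv2)
                w_new = w + 0.5 * dt * (dw1 + dw2)
            if v_new >= v_cut:
                v_new = v_reset
                w_new += b_w
                if n_out < cap_out:
                    out_pop[n_out] = 2
                    out_unit[n_out] = j
                    out_time[n_out] = t_now
                    n_out += 1
                else:
                    overflow = 1
            if not np.isfinite(v_new):
                return -1, overflow  # numerical blow-up
            v_d[j] = v_new; w_d[j] = w_new

    return n_out, overflow
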