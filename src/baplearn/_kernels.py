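"""Numba-compiled simulation loops.

These kernels implement exactly the per-step dynamics of the reference
functions in :mod:`baplearn.neuron` and :mod:`baplearn.plasticity`, fused
into a single loop for speed: linear filter states (synaptic conductances,
bAP pulse, plasticity traces) advance with exact per-step exponential decay
factors, while the nonlinear membrane and gate ODEs use forward Euler at the
simulation step ``dt``.

Synaptic state (PSP traces, eligibilities, weights) is updated on a coarser
stride ``plast_stride`` (default 0.1-1 ms) since all plasticity time
constants are tens of milliseconds; the zeta weight-scaling factor, which is
the only transcendental per-synapse term, is refreshed every ``zeta_stride``
plasticity steps because weights drift slowly.

Parameters are passed as a flat float64 vector indexed by the module-level
constants below; :mod:`baplearn.simulation` packs it from the dataclasses.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# --- parameter vector layout -----------------------------------------------
DT = 0
C_S = 1; G_LS = 2; G_LSR = 3; V_LS = 4; V_TH = 5; V_RE = 6; V_PEAK = 7; TREF = 8
C_D = 9; G_LD = 10; V_LD = 11; V_ER = 12; V_IR = 13
TAU_ER = 14; TAU_ED = 15; GBAR_E = 16
TAU_IR = 17; TAU_ID = 18; GBAR_I = 19
G_CDS = 20; G_CSDR = 21; M_CSD = 22; TAU_CR = 23; TAU_CD = 24
G_CA = 25; V_CA = 26
TAU_NR = 27; TAU_ND = 28; GBAR_N = 29; V_N = 30; F_CA = 31; MG = 32
TAU_Y = 33; TAU_YBAR = 34; TAU_C = 35; TAU_CBAR = 36; C0 = 37; PHI = 38
TAU_P = 39; PHI_Z = 40; TAU_Z = 41; ETA = 42; TAU_DELTA = 43
T_KAPPA = 44; RHO = 45
N_PARAMS = 46

# variant codes (mirror baplearn.neuron)
SPIKE_TRACE = 0
CALCIUM = 1
CALCIUM_NMDAR = 2

# status codes
OK = 0
DIVERGED = 1
RUNAWAY = 2


@njit(cache=True, inline="always")
def _double_exp_norm(tau_rise, tau_decay):
    tp = tau_decay * tau_rise / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    return np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise)


@njit(cache=True, inline="always")
def _hva_minf_tau(v):
    x = (-27.0 - v) / 3.8
    if abs(x) < 1e-7:
        m_alpha = 0.055 * 3.8
    else:
        m_alpha = 0.055 * 3.8 * x / np.expm1(x)
    m_beta = 0.94 * np.exp((-75.0 - v) / 17.0)
    h_alpha = 0.000457 * np.exp((-13.0 - v) / 50.0)
    h_beta = 0.0065 / (np.exp((-v - 15.0) / 28.0) + 1.0)
    m_inf = m_alpha / (m_alpha + m_beta)
    h_inf = h_alpha / (h_alpha + h_beta)
    tau_m = 1.0 / (m_alpha + m_beta)
    tau_h = 1.0 / (h_alpha + h_beta)
    return m_inf, h_inf, tau_m, tau_h


@njit(cache=True, inline="always")
def _zeta(w_abs, phi_z, tau_z):
    x = (w_abs - phi_z) / tau_z
    z = x * np.exp(1.0 - x)
    if z < 0.0:
        return 0.0
    if z > 1.0:
        return 1.0
    return z


@njit(cache=True)
def run_single_neuron(
    P,                # float64[N_PARAMS]
    variant,          # int
    n_steps,          # int
    ev_step,          # int64[:], sorted ascending
    ev_unit,          # int64[:]
    w,                # float64[n_syn], modified in place copy by caller
    sign,             # float64[n_syn], +-1 Dale identity
    nmda_mask,        # bool[n_syn]
    forced_steps,     # int64[:], sorted; force a somatic spike at these steps
    noise_cur,        # float64[n_steps] dendritic current noise in pA, or len 0
    plast_stride,     # int, membrane steps per plasticity update
    zeta_stride,      # int, plasticity steps per zeta refresh
    snap_stride,      # int, membrane steps per weight snapshot (0 = off)
    rec_stride,       # int, membrane steps per trace sample (0 = off)
    freeze,           # bool: disable plasticity and homeostasis
    kappa0,           # float, initial homeostatic scale
):
    dt = P[DT]
    n_syn = w.shape[0]

    # decay factors (exact exponential for linear states)
    d_er = np.exp(-dt / P[TAU_ER]); d_ed = np.exp(-dt / P[TAU_ED])
    d_ir = np.exp(-dt / P[TAU_IR]); d_id = np.exp(-dt / P[TAU_ID])
    d_cr = np.exp(-dt / P[TAU_CR]); d_cd = np.exp(-dt / P[TAU_CD])
    d_nr = np.exp(-dt / P[TAU_NR]); d_nd = np.exp(-dt / P[TAU_ND])
    norm_e = _double_exp_norm(P[TAU_ER], P[TAU_ED])
    norm_i = _double_exp_norm(P[TAU_IR], P[TAU_ID])
    norm_c = _double_exp_norm(P[TAU_CR], P[TAU_CD])
    norm_n = _double_exp_norm(P[TAU_NR], P[TAU_ND])
    d_y = np.exp(-dt / P[TAU_Y]); a_ybar = np.exp(-dt / P[TAU_YBAR])
    a_cbar = np.exp(-dt / P[TAU_CBAR])
    dt_p = plast_stride * dt
    d_psp = np.exp(-dt_p / P[TAU_P])

    n_ref = int(round(P[TREF] / dt))
    kappa_steps = max(1, int(round(P[T_KAPPA] / dt)))

    # state
    v_s = P[V_LS]; v_d = P[V_LD]
    refr = 0
    xe_r = 0.0; xe_d = 0.0; xi_r = 0.0; xi_d = 0.0
    xc_r = 0.0; xc_d = 0.0; xn_r = 0.0; xn_d = 0.0
    m_gate = 0.0; h_gate = 1.0
    y = 0.0; ybar = 0.0
    c_tr = P[C0]; cbar = P[C0]
    psp = np.zeros(n_syn)
    dwel = np.zeros(n_syn)
    zcache = np.empty(n_syn)
    for i in range(n_syn):
        zcache[i] = _zeta(abs(w[i]), P[PHI_Z], P[TAU_Z])
    kappa = kappa0
    theta = 0.0
    for i in range(n_syn):
        theta += abs(w[i])
    kappa_min = kappa

    # outputs
    max_spk = n_steps // max(n_ref, 1) + 2
    spikes = np.empty(max_spk, dtype=np.int64)
    n_spk = 0
    n_snap = (n_steps // snap_stride + 1) if snap_stride > 0 else 0
    w_snaps = np.zeros((n_snap, n_syn), dtype=np.float32)
    snap_i = 0
    n_kap = n_steps // kappa_steps + 1
    kappa_hist = np.zeros(n_kap)
    kappa_hist[0] = kappa
    kap_i = 1
    n_rec = (n_steps // rec_stride) if rec_stride > 0 else 0
    rec_vs = np.zeros(n_rec); rec_vd = np.zeros(n_rec)
    rec_e = np.zeros(n_rec); rec_gcsd = np.zeros(n_rec)
    rec_tr = np.zeros(n_rec); rec_trbar = np.zeros(n_rec)

    ev_ptr = 0          # conductance fan-in pointer
    psp_ptr = 0         # PSP fan-in pointer (lags to plasticity steps)
    forced_ptr = 0
    n_ev = ev_step.shape[0]
    plast_count = 0
    status = OK
    have_noise = noise_cur.shape[0] == n_steps
    use_boost = P[M_CSD] > 0.0

    for t in range(n_steps):
        if snap_stride > 0 and t % snap_stride == 0:
            for i in range(n_syn):
                w_snaps[snap_i, i] = w[i]
            snap_i += 1

        # --- synaptic conductance filters: decay, then current-step impulses
        xe_r *= d_er; xe_d *= d_ed
        xi_r *= d_ir; xi_d *= d_id
        xc_r *= d_cr; xc_d *= d_cd
        if variant == CALCIUM_NMDAR:
            xn_r *= d_nr; xn_d *= d_nd
        while ev_ptr < n_ev and ev_step[ev_ptr] == t:
            u = ev_unit[ev_ptr]
            a = kappa * abs(w[u])
            if sign[u] > 0.0:
                xe_r += a; xe_d += a
                if variant == CALCIUM_NMDAR and nmda_mask[u]:
                    xn_r += a; xn_d += a
            else:
                xi_r += a; xi_d += a
            ev_ptr += 1
        g_e = P[GBAR_E] * (xe_d - xe_r) / norm_e
        g_i = P[GBAR_I] * (xi_d - xi_r) / norm_i

        # --- soma
        in_refr = refr > 0
        spiked = False
        if in_refr:
            if variant != SPIKE_TRACE:
                v_s += dt * P[G_LSR] * (P[V_LS] - v_s) / P[C_S]
            refr -= 1
        else:
            v_s += dt * (P[G_CDS] * (v_d - v_s) + P[G_LS] * (P[V_LS] - v_s)) / P[C_S]
            if v_s > P[V_TH]:
                spiked = True
        if forced_ptr < forced_steps.shape[0] and forced_steps[forced_ptr] == t:
            spiked = True
            forced_ptr += 1
        if spiked:
            spikes[n_spk] = t
            n_spk += 1
            refr = n_ref
            in_refr = True
            v_s = P[V_RE] if variant == SPIKE_TRACE else P[V_PEAK]
            y += 1.0
            if use_boost:
                xc_r += P[M_CSD]; xc_d += P[M_CSD]

        # --- coupling current into the dendrite
        g_csd = P[G_CSDR]
        if use_boost and in_refr:
            g_csd = P[G_CSDR] + (xc_d - xc_r) / norm_c
        i_csd = g_csd * (v_s - v_d)

        # --- dendritic currents
        i_ca_total = 0.0
        i_nmda = 0.0
        if variant != SPIKE_TRACE:
            m_inf, h_inf, tau_m, tau_h = _hva_minf_tau(v_d)
            m_gate += dt * (m_inf - m_gate) / tau_m
            h_gate += dt * (h_inf - h_gate) / tau_h
            if m_gate < 0.0: m_gate = 0.0
            elif m_gate > 1.0: m_gate = 1.0
            if h_gate < 0.0: h_gate = 0.0
            elif h_gate > 1.0: h_gate = 1.0
            i_ca_total = P[G_CA] * m_gate * m_gate * h_gate * (P[V_CA] - v_d)
            if variant == CALCIUM_NMDAR:
                g_n = P[GBAR_N] * (xn_d - xn_r) / norm_n
                mgb = 1.0 / (1.0 + P[MG] / 3.57 * np.exp(-0.062 * v_d))
                drive = g_n * mgb * (P[V_N] - v_d)
                i_nmda = drive * (1.0 - P[F_CA])
                i_ca_total += drive * P[F_CA]
        i_noise = noise_cur[t] if have_noise else 0.0
        i_dend = (
            P[G_LD] * (P[V_LD] - v_d)
            + g_e * (P[V_ER] - v_d)
            + g_i * (P[V_IR] - v_d)
            + i_csd + i_ca_total + i_nmda + i_noise
        )
        v_d += dt * i_dend / P[C_D]
        # NaN-safe bounds guard (catches numerical divergence immediately)
        if not (-500.0 < v_d < 500.0 and -500.0 < v_s < 500.0):
            status = DIVERGED
            break

        # --- plasticity traces
        if variant == SPIKE_TRACE:
            ybar = a_ybar * ybar + (1.0 - a_ybar) * y
            y *= d_y
            e_sig = y - ybar
        else:
            c_tr += dt * (P[PHI] * i_ca_total - (c_tr - P[C0]) / P[TAU_C])
            cbar = a_cbar * cbar + (1.0 - a_cbar) * c_tr
            e_sig = c_tr - cbar

        # --- synaptic plasticity on the coarse stride
        if t % plast_stride == plast_stride - 1:
            if not freeze:
                plast_count += 1
                refresh = plast_count % zeta_stride == 0
                for i in range(n_syn):
                    psp[i] *= d_psp
                while psp_ptr < n_ev and ev_step[psp_ptr] <= t:
                    u = ev_unit[psp_ptr]
                    psp[u] += abs(w[u]) / P[TAU_P]
                    psp_ptr += 1
                for i in range(n_syn):
                    if refresh:
                        zcache[i] = _zeta(abs(w[i]), P[PHI_Z], P[TAU_Z])
                    pi = e_sig * psp[i] * zcache[i]
                    dwel[i] += dt_p * (pi - dwel[i]) / P[TAU_DELTA]
                    cand = w[i] + P[ETA] * dwel[i] * dt_p
                    if cand * sign[i] <= 0.0:
                        dwel[i] = 0.0
                    else:
                        w[i] = cand

        # --- homeostatic rescaling
        if not freeze and t > 0 and t % kappa_steps == 0:
            theta_star = 0.0
            for i in range(n_syn):
                theta_star += abs(w[i])
            if theta_star > 0.0:
                kappa = kappa * theta / theta_star
                theta = theta_star
            if kap_i < n_kap:
                kappa_hist[kap_i] = kappa
                kap_i += 1
            if kappa < kappa_min:
                kappa_min = kappa

        # --- recording / divergence guard
        if rec_stride > 0 and t % rec_stride == 0:
            j = t // rec_stride
            if j < n_rec:
                rec_vs[j] = v_s; rec_vd[j] = v_d; rec_e[j] = e_sig
                rec_gcsd[j] = g_csd
                if variant == SPIKE_TRACE:
                    rec_tr[j] = y; rec_trbar[j] = ybar
                else:
                    rec_tr[j] = c_tr; rec_trbar[j] = cbar

    return (
        status, spikes[:n_spk], w, w_snaps[:snap_i], kappa_hist[:kap_i],
        kappa, kappa_min, rec_vs, rec_vd, rec_e, rec_gcsd, rec_tr, rec_trbar,
    )


@njit(cache=True)
def run_network(
    P,                 # float64[N_PARAMS], shared parameters (spike-trace variant)
    n_steps,
    c_s_unit,          # float64[N]: per-unit somatic capacitance (E vs I classes)
    c_d_unit,          # float64[N]
    is_exc_unit,       # bool[N]: Dale class of each network unit
    ev_step, ev_unit,  # afferent events
    sign_aff,          # float64[n_aff]
    w_aff,             # float64[N, n_aff], modified in place
    w_rec,             # float64[N, N], modified in place
    mask_rec,          # bool[N, N]: existing recurrent synapses (row=post)
    plast_stride,
    zeta_stride,
    rate_cap_hz,       # population-mean rate cap; exceeded in a 500 ms window -> abort
):
    dt = P[DT]
    n_units = w_aff.shape[0]
    n_aff = w_aff.shape[1]

    d_er = np.exp(-dt / P[TAU_ER]); d_ed = np.exp(-dt / P[TAU_ED])
    d_ir = np.exp(-dt / P[TAU_IR]); d_id = np.exp(-dt / P[TAU_ID])
    norm_e = _double_exp_norm(P[TAU_ER], P[TAU_ED])
    norm_i = _double_exp_norm(P[TAU_IR], P[TAU_ID])
    d_y = np.exp(-dt / P[TAU_Y]); a_ybar = np.exp(-dt / P[TAU_YBAR])
    dt_p = plast_stride * dt
    d_psp = np.exp(-dt_p / P[TAU_P])
    n_ref = int(round(P[TREF] / dt))
    kappa_steps = max(1, int(round(P[T_KAPPA] / dt)))

    v_s = np.full(n_units, P[V_LS])
    v_d = np.full(n_units, P[V_LD])
    refr = np.zeros(n_units, dtype=np.int64)
    xe_r = np.zeros(n_units); xe_d = np.zeros(n_units)
    xi_r = np.zeros(n_units); xi_d = np.zeros(n_units)
    y = np.zeros(n_units); ybar = np.zeros(n_units)
    spiked_prev = np.zeros(n_units, dtype=np.bool_)

    psp_aff = np.zeros((n_units, n_aff))
    psp_rec = np.zeros((n_units, n_units))
    dwel_aff = np.zeros((n_units, n_aff))
    dwel_rec = np.zeros((n_units, n_units))
    z_aff = np.empty((n_units, n_aff))
    z_rec = np.empty((n_units, n_units))
    for n in range(n_units):
        for j in range(n_aff):
            z_aff[n, j] = _zeta(abs(w_aff[n, j]), P[PHI_Z], P[TAU_Z])
        for j in range(n_units):
            z_rec[n, j] = _zeta(abs(w_rec[n, j]), P[PHI_Z], P[TAU_Z])

    kappa = np.ones(n_units)
    theta = np.zeros(n_units)
    for n in range(n_units):
        s = 0.0
        for j in range(n_aff):
            s += abs(w_aff[n, j])
        for j in range(n_units):
            s += abs(w_rec[n, j])
        theta[n] = s
    kappa_min = 1.0

    max_spk = n_units * (n_steps // max(n_ref, 1) + 2)
    out_unit = np.empty(max_spk, dtype=np.int64)
    out_step = np.empty(max_spk, dtype=np.int64)
    n_spk = 0

    win_spikes = np.zeros(n_units, dtype=np.int64)  # per-plast-window spike counts
    cap_window = int(round(500.0 / dt))
    cap_count = 0
    cap_limit = rate_cap_hz * n_units * 0.5  # spikes per 500 ms window

    ev_ptr = 0
    psp_ptr = 0
    n_ev = ev_step.shape[0]
    plast_count = 0
    status = OK

    for t in range(n_steps):
        # conductance decay
        for n in range(n_units):
            xe_r[n] *= d_er; xe_d[n] *= d_ed
            xi_r[n] *= d_ir; xi_d[n] *= d_id
        # afferent fan-in
        while ev_ptr < n_ev and ev_step[ev_ptr] == t:
            u = ev_unit[ev_ptr]
            if sign_aff[u] > 0.0:
                for n in range(n_units):
                    xe_r[n] += kappa[n] * abs(w_aff[n, u])
                    xe_d[n] += kappa[n] * abs(w_aff[n, u])
            else:
                for n in range(n_units):
                    xi_r[n] += kappa[n] * abs(w_aff[n, u])
                    xi_d[n] += kappa[n] * abs(w_aff[n, u])
            ev_ptr += 1
        # recurrent fan-in from the previous step's spikes (0.1 ms lag)
        for j in range(n_units):
            if spiked_prev[j]:
                if is_exc_unit[j]:
                    for n in range(n_units):
                        if mask_rec[n, j]:
                            a = kappa[n] * abs(w_rec[n, j])
                            xe_r[n] += a; xe_d[n] += a
                else:
                    for n in range(n_units):
                        if mask_rec[n, j]:
                            a = kappa[n] * abs(w_rec[n, j])
                            xi_r[n] += a; xi_d[n] += a

        window_spikes = 0
        for n in range(n_units):
            g_e = P[GBAR_E] * (xe_d[n] - xe_r[n]) / norm_e
            g_i = P[GBAR_I] * (xi_d[n] - xi_r[n]) / norm_i
            spk = False
            if refr[n] > 0:
                refr[n] -= 1
            else:
                v_s[n] += dt * (P[G_CDS] * (v_d[n] - v_s[n])
                                + P[G_LS] * (P[V_LS] - v_s[n])) / c_s_unit[n]
                if v_s[n] > P[V_TH]:
                    spk = True
                    v_s[n] = P[V_RE]
                    refr[n] = n_ref
                    y[n] += 1.0
                    out_unit[n_spk] = n
                    out_step[n_spk] = t
                    n_spk += 1
                    window_spikes += 1
                    win_spikes[n] += 1
            spiked_prev[n] = spk
            i_csd = P[G_CSDR] * (v_s[n] - v_d[n])
            i_dend = (
                P[G_LD] * (P[V_LD] - v_d[n])
                + g_e * (P[V_ER] - v_d[n])
                + g_i * (P[V_IR] - v_d[n])
                + i_csd
            )
            v_d[n] += dt * i_dend / c_d_unit[n]
            ybar[n] = a_ybar * ybar[n] + (1.0 - a_ybar) * y[n]
            y[n] *= d_y

        cap_count += window_spikes
        if t % cap_window == cap_window - 1:
            if cap_count > cap_limit:
                status = RUNAWAY
                break
            cap_count = 0

        # plasticity on the coarse stride
        if t % plast_stride == plast_stride - 1:
            plast_count += 1
            refresh = plast_count % zeta_stride == 0
            for n in range(n_units):
                for j in range(n_aff):
                    psp_aff[n, j] *= d_psp
                for j in range(n_units):
                    psp_rec[n, j] *= d_psp
            while psp_ptr < n_ev and ev_step[psp_ptr] <= t:
                u = ev_unit[psp_ptr]
                for n in range(n_units):
                    psp_aff[n, u] += w_aff[n, u] / P[TAU_P]
                psp_ptr += 1
            # recurrent PSPs: all network spikes since the previous stride
            for j in range(n_units):
                if win_spikes[j] > 0:
                    for n in range(n_units):
                        if mask_rec[n, j]:
                            psp_rec[n, j] += win_spikes[j] * w_rec[n, j] / P[TAU_P]
                    win_spikes[j] = 0
            for n in range(n_units):
                e_sig = y[n] - ybar[n]
                for j in range(n_aff):
                    if refresh:
                        z_aff[n, j] = _zeta(abs(w_aff[n, j]), P[PHI_Z], P[TAU_Z])
                    pi = e_sig * psp_aff[n, j] * z_aff[n, j]
                    dwel_aff[n, j] += dt_p * (pi - dwel_aff[n, j]) / P[TAU_DELTA]
                    cand = w_aff[n, j] + P[ETA] * dwel_aff[n, j] * dt_p
                    if cand * sign_aff[j] <= 0.0:
                        dwel_aff[n, j] = 0.0
                    else:
                        w_aff[n, j] = cand
                for j in range(n_units):
                    if not mask_rec[n, j]:
                        continue
                    if refresh:
                        z_rec[n, j] = _zeta(abs(w_rec[n, j]), P[PHI_Z], P[TAU_Z])
                    pi = e_sig * psp_rec[n, j] * z_rec[n, j]
                    dwel_rec[n, j] += dt_p * (pi - dwel_rec[n, j]) / P[TAU_DELTA]
                    s_j = 1.0 if is_exc_unit[j] else -1.0
                    cand = w_rec[n, j] + P[ETA] * dwel_rec[n, j] * dt_p
                    if cand * s_j <= 0.0:
                        dwel_rec[n, j] = 0.0
                    else:
                        w_rec[n, j] = cand

        # homeostatic rescaling, per postsynaptic unit
        if t > 0 and t % kappa_steps == 0:
            for n in range(n_units):
                theta_star = 0.0
                for j in range(n_aff):
                    theta_star += abs(w_aff[n, j])
                for j in range(n_units):
                    theta_star += abs(w_rec[n, j])
                if theta_star > 0.0:
                    kappa[n] = kappa[n] * theta[n] / theta_star
                    theta[n] = theta_star
                if kappa[n] < kappa_min:
                    kappa_min = kappa[n]

    return status, out_unit[:n_spk], out_step[:n_spk], w_aff, w_rec, kappa, kappa_min
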