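"""Compiled inner loop of the cable + plasticity simulation.

One numba-jitted function advances the whole coupled system — compartment
voltages (implicit theta-scheme on the tree via Hines elimination), channel
gates (exponential-Euler steps through precomputed voltage lookup tables),
the submembrane calcium pool, synaptic conductance traces and the
four-pathway plasticity state — with the extracellular quasipotential drive
entering the axial terms as differences of (v + Ve).

The update rules are numerically identical to the vectorised/scalar
reference implementations in :mod:`tmsplast.membrane` and
:mod:`tmsplast.synapses`; tests enforce the agreement.  Everything here is
plain arrays so the kernel stays cacheable and allocation-free in the loop.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .membrane import CA_REST, CA_DEPTH, FARADAY, TAU_CA, E_NA, E_K, E_CA, E_H

# voltage lookup-table range
VMIN, VMAX, NV = -120.0, 70.0, 1901


def build_gate_tables(kin: np.ndarray, dt: float) -> np.ndarray:
    """Per-gate tables of (steady state, 1 - exp(-dt/tau)) on the v grid.

    Shape (12, NV, 2); the two calcium-dependent gates are computed directly
    in the kernel from the calcium concentration.
    """
    v = np.linspace(VMIN, VMAX, NV)
    out = np.empty((12, NV, 2))
    for g in range(12):
        vh, k, tmin, tamp, tvh, tw = kin[g]
        out[g, :, 0] = 1.0 / (1.0 + np.exp(-(v - vh) / k))
        tau = tmin + tamp / (1.0 + ((v - tvh) / tw) ** 2)
        out[g, :, 1] = 1.0 - np.exp(-dt / tau)
    return out


@njit(cache=True)
def _table_lookup(table, v, col):
    x = (v - VMIN) * (NV - 1) / (VMAX - VMIN)
    if x <= 0.0:
        return table[0, col]
    if x >= NV - 1:
        return table[NV - 1, col]
    i = int(x)
    f = x - i
    return table[i, col] + (table[i + 1, col] - table[i, col]) * f


@njit(cache=True)
def simulate(
    # --- cell structure (ordered root-first; parent[i] < i) ---
    parent,            # (n,) int64, -1 at root
    g_pa,              # (n,) µS axial coupling to parent
    c_nf,              # (n,) nF membrane capacitance
    gbar_us,           # (10, n) µS absolute channel conductances
    gca_dens,          # (3, n) S/cm² CaT/CaL/CaN densities (calcium drive)
    gpas_us,           # (n,) µS
    epas,              # (n,) mV
    g_tonic_us,        # (n,) µS tonic GABA-A conductance (e = -75)
    # --- channel state ---
    tables,            # (12, NV, 2) gate lookup tables for this dt
    tables_ax,         # (12, NV, 2) axonal-compartment gate tables
    is_ax,             # (n,) bool: use the axonal tables
    cagk_par,          # (2, 3) kd, hill, tau for the two calcium gates
    na_shift,          # (n,) mV midpoint shift of the Na activation gate
    gates,             # (n, 14) in/out
    ca,                # (n,) in/out
    v,                 # (n,) in/out
    freeze_ca,         # bool
    # --- extracellular drive / injections ---
    ve_unit,           # (n,) mV per unit waveform value
    wave,              # (n_steps + 1,) waveform value per step boundary
    inj_comp, inj_t0, inj_t1, inj_amp,   # current injections (nA)
    # --- excitatory synapses ---
    es_comp,           # (ne,) int64
    es_state,          # (ne, 14) in/out; col 13 is the C state
    es_par,            # (40,) packed parameter vector
    es_events, es_ptr, # flat sorted event times + per-synapse [start, stop]
    snmda_scale,       # float (0 under NMDA blockade)
    force_c_zero, force_na_zero, plasticity_on,
    # --- inhibitory synapses ---
    is_comp, is_w, is_state, is_taur, is_taud, is_erev,
    is_events, is_ptr,
    # --- numerics / recording ---
    dt, n_steps, theta,
    rec_comp,          # (nrec,) int64
    rec_stride,        # int
    rec_out,           # (nrec, n_rec) preallocated
    w_stride,          # int
    w_out,             # (nw, ne, 2) preallocated
):
    """Advance the full system ``n_steps`` of ``dt``.

    Returns 0 on success or 1 + index of the first compartment whose
    voltage became non-finite.
    """
    n = v.shape[0]
    ne = es_comp.shape[0]
    ni = is_comp.shape[0]

    # synapse decay factors (fixed dt)
    tau_a, tau_b = es_par[0], es_par[1]
    e_rev_exc = es_par[2]
    s_ampa, s_nmda = es_par[3], es_par[4] * snmda_scale
    tau_ga, tau_gb = es_par[5], es_par[6]
    m_g = es_par[7]
    a_pre_p, a_pre_m = es_par[8], es_par[9]
    a_post_p, a_post_m = es_par[10], es_par[11]
    tau_ut, th_ut, m_t = es_par[12], es_par[13], es_par[14]
    th_un = es_par[15]
    tau_za, tau_zb, m_z = es_par[16], es_par[17], es_par[18]
    tau_na, tau_nb = es_par[19], es_par[20]
    m_na, m_nb = es_par[21], es_par[22]
    th_nx, th_uc = es_par[23], es_par[24]
    th_cm, th_cp = es_par[25], es_par[26]
    tau_ka, tau_kg = es_par[27], es_par[28]
    m_ka, m_kb, s_kb = es_par[29], es_par[30], es_par[31]
    g_base = es_par[32]
    c_gain = es_par[33]
    tau_c = es_par[34]
    c_usat = es_par[35]
    wpre_lo, wpre_hi = es_par[36], es_par[37]
    wpost_lo, wpost_hi = es_par[38], es_par[39]
    norm_a, norm_g, norm_z = es_par[40], es_par[41], es_par[42]

    dec_ar = np.exp(-dt / tau_a)
    dec_ad = np.exp(-dt / tau_b)
    dec_gr = np.exp(-dt / tau_ga)
    dec_gd = np.exp(-dt / tau_gb)
    dec_zr = np.exp(-dt / tau_za)
    dec_zd = np.exp(-dt / tau_zb)

    dec_ir = np.empty(ni)
    dec_id = np.empty(ni)
    inorm = np.empty(ni)
    for s in range(ni):
        dec_ir[s] = np.exp(-dt / is_taur[s])
        dec_id[s] = np.exp(-dt / is_taud[s])
        tp = (np.log(is_taud[s] / is_taur[s]) * is_taur[s] * is_taud[s]
              / (is_taud[s] - is_taur[s]))
        inorm[s] = np.exp(-tp / is_taud[s]) - np.exp(-tp / is_taur[s])

    eptr = es_ptr[:, 0].copy()
    iptr = is_ptr[:, 0].copy()

    dec_c = 1.0 - np.exp(-dt / tau_c)
    dec_cag0 = 1.0 - np.exp(-dt / cagk_par[0, 2])
    dec_cag1 = 1.0 - np.exp(-dt / cagk_par[1, 2])

    # axial conductance sums
    ax_sum = np.zeros(n)
    for i in range(1, n):
        ax_sum[i] += g_pa[i]
        ax_sum[parent[i]] += g_pa[i]

    ca_k = 1e4 / (2.0 * FARADAY * CA_DEPTH)

    gm = np.empty(n)
    ge = np.empty(n)
    diag = np.empty(n)
    rhs = np.empty(n)
    pre_flag = np.empty(ne, np.int64)
    inh_g = np.empty(ni)

    rec_i = 0
    w_i = 0
    n_inj = inj_comp.shape[0]

    for step in range(n_steps):
        t_new = (step + 1) * dt

        # ---- gating + membrane conductances --------------------------
        for i in range(n):
            vi = v[i]
            tab = tables_ax if is_ax[i] else tables
            # voltage gates (Na activation sees the isoform midpoint shift)
            v_na = vi - na_shift[i]
            inf = _table_lookup(tab[0], v_na, 0)
            a = _table_lookup(tab[0], v_na, 1)
            gates[i, 0] += (inf - gates[i, 0]) * a
            for g in range(1, 12):
                inf = _table_lookup(tab[g], vi, 0)
                a = _table_lookup(tab[g], vi, 1)
                gates[i, g] += (inf - gates[i, g]) * a
            # calcium gates
            ca2 = ca[i] * ca[i]
            inf0 = ca2 / (ca2 + cagk_par[0, 0] * cagk_par[0, 0])
            gates[i, 12] += (inf0 - gates[i, 12]) * dec_cag0
            inf1 = ca2 / (ca2 + cagk_par[1, 0] * cagk_par[1, 0])
            gates[i, 13] += (inf1 - gates[i, 13]) * dec_cag1

            m = gates[i, 0]; h = gates[i, 1]
            a_ = gates[i, 2]; b_ = gates[i, 3]
            nk = gates[i, 4]; km = gates[i, 5]
            ctm = gates[i, 6]; cth = gates[i, 7]
            clm = gates[i, 8]; cnm = gates[i, 9]; cnh = gates[i, 10]
            q = gates[i, 11]; kca = gates[i, 12]; cagk = gates[i, 13]

            g_na = gbar_us[0, i] * m * m * m * h
            g_ka = gbar_us[1, i] * a_ * b_
            g_kdr = gbar_us[2, i] * nk
            g_km = gbar_us[3, i] * km
            g_kca = gbar_us[4, i] * kca
            g_cagk = gbar_us[5, i] * cagk
            g_cat = gbar_us[6, i] * ctm * ctm * cth
            g_cal = gbar_us[7, i] * clm * clm
            g_can = gbar_us[8, i] * cnm * cnh
            g_h = gbar_us[9, i] * q

            g_k = g_ka + g_kdr + g_km + g_kca + g_cagk
            g_ca_tot = g_cat + g_cal + g_can
            gm[i] = (g_na + g_k + g_ca_tot + g_h + gpas_us[i] + g_tonic_us[i])
            ge[i] = (g_na * E_NA + g_k * E_K + g_ca_tot * E_CA + g_h * E_H
                     + gpas_us[i] * epas[i] + g_tonic_us[i] * (-75.0))

            if not freeze_ca:
                ica_dens = (
                    gca_dens[0, i] * ctm * ctm * cth
                    + gca_dens[1, i] * clm * clm
                    + gca_dens[2, i] * cnm * cnh
                ) * (vi - E_CA)
                drive = -ca_k * ica_dens if ica_dens < 0.0 else 0.0
                ca[i] += dt * (drive - (ca[i] - CA_REST) / TAU_CA)
                if ca[i] < CA_REST:
                    ca[i] = CA_REST

        # ---- synaptic conductances -----------------------------------
        for s in range(ne):
            cnt = 0
            while eptr[s] < es_ptr[s, 1] and es_events[eptr[s]] <= t_new:
                cnt += 1
                eptr[s] += 1
            pre_flag[s] = cnt
            es_state[s, 0] = es_state[s, 0] * dec_ar + cnt
            es_state[s, 1] = es_state[s, 1] * dec_ad + cnt
            es_state[s, 2] = es_state[s, 2] * dec_gr + cnt
            es_state[s, 3] = es_state[s, 3] * dec_gd + cnt
            es_state[s, 4] = es_state[s, 4] * dec_zr + cnt
            es_state[s, 5] = es_state[s, 5] * dec_zd + cnt

            ci = es_comp[s]
            u = v[ci]
            a_tr = (es_state[s, 1] - es_state[s, 0]) / norm_a
            g_tr = (es_state[s, 3] - es_state[s, 2]) / norm_g
            bmg = 1.0 / (1.0 + 0.28 * np.exp(-0.062 * u))
            g_syn = (es_state[s, 11] * es_state[s, 12] * g_base
                     * (s_ampa * a_tr + s_nmda * g_tr * bmg))
            if g_syn < 0.0:
                g_syn = 0.0
            gm[ci] += g_syn
            ge[ci] += g_syn * e_rev_exc

        for s in range(ni):
            cnt = 0
            while iptr[s] < is_ptr[s, 1] and is_events[iptr[s]] <= t_new:
                cnt += 1
                iptr[s] += 1
            is_state[s, 0] = is_state[s, 0] * dec_ir[s] + cnt
            is_state[s, 1] = is_state[s, 1] * dec_id[s] + cnt
            g_i = is_w[s] * (is_state[s, 1] - is_state[s, 0]) / inorm[s]
            if g_i < 0.0:
                g_i = 0.0
            inh_g[s] = g_i
            ci = is_comp[s]
            gm[ci] += g_i
            ge[ci] += g_i * is_erev[s]

        # ---- assemble theta-scheme system ----------------------------
        for i in range(n):
            diag[i] = c_nf[i] / dt + theta * (gm[i] + ax_sum[i])
            rhs[i] = (c_nf[i] / dt - (1.0 - theta) * gm[i]) * v[i] + ge[i]

        wv = wave[step + 1]
        for i in range(1, n):
            p = parent[i]
            g = g_pa[i]
            # explicit part of axial current + extracellular drive
            ax = g * (v[p] - v[i])
            rhs[i] += (1.0 - theta) * ax
            rhs[p] -= (1.0 - theta) * ax
            ve_diff = g * (ve_unit[p] - ve_unit[i]) * wv
            rhs[i] += ve_diff
            rhs[p] -= ve_diff

        for k in range(n_inj):
            if inj_t0[k] <= t_new < inj_t1[k]:
                rhs[inj_comp[k]] += inj_amp[k]

        # ---- Hines solve (symmetric tree) ----------------------------
        for i in range(n - 1, 0, -1):
            p = parent[i]
            off = -theta * g_pa[i]
            f = off / diag[i]
            diag[p] -= f * off
            rhs[p] -= f * rhs[i]
        v[0] = rhs[0] / diag[0]
        for i in range(1, n):
            off = -theta * g_pa[i]
            v[i] = (rhs[i] - off * v[parent[i]]) / diag[i]

        for i in range(n):
            if not np.isfinite(v[i]):
                return 1 + i

        # ---- plasticity ----------------------------------------------
        if plasticity_on:
            for s in range(ne):
                u = v[es_comp[s]]
                z_tr = (es_state[s, 5] - es_state[s, 4]) / norm_z
                z_s = m_z * z_tr / (1.0 + m_z * z_tr) if z_tr > 0 else 0.0
                g_tr = (es_state[s, 3] - es_state[s, 2]) / norm_g
                g_s = m_g * g_tr / (1.0 + m_g * g_tr) if g_tr > 0 else 0.0

                if force_c_zero:
                    es_state[s, 13] = 0.0
                else:
                    du = u - th_uc
                    if du < 0.0:
                        du = 0.0
                    elif du > c_usat:
                        du = c_usat
                    drive = c_gain * g_s * du
                    es_state[s, 13] += (drive - es_state[s, 13]) * dec_c
                c = es_state[s, 13]

                dcp = c - th_cp
                dcm = c - th_cm
                dw_post = 0.0
                if dcp > 0:
                    dw_post += a_post_p * dcp
                if dcm > 0:
                    dw_post -= a_post_m * z_s * dcm
                wp = es_state[s, 12] + dt * dw_post
                if wp < wpost_lo:
                    wp = wpost_lo
                elif wp > wpost_hi:
                    wp = wpost_hi
                es_state[s, 12] = wp

                du = u - th_ut
                drv = m_t * du / (1.0 + m_t * du) if du > 0 else 0.0
                es_state[s, 6] += dt * (drv - es_state[s, 6]) / tau_ut
                wpre = es_state[s, 11]
                if pre_flag[s] > 0:
                    wpre -= pre_flag[s] * a_pre_m * es_state[s, 6]

                if force_na_zero:
                    es_state[s, 7] = 0.0
                else:
                    du = u - th_un
                    drv = m_na * du / (1.0 + m_na * du) if du > 0 else 0.0
                    es_state[s, 7] += dt * (drv - es_state[s, 7]) / tau_na
                na_ = es_state[s, 7]
                es_state[s, 8] += dt * (
                    m_nb * na_ / (1.0 + m_nb * na_) - es_state[s, 8]) / tau_nb
                x = na_ * es_state[s, 8] - th_nx
                x = x * z_s if x > 0 else 0.0
                es_state[s, 9] += dt * (
                    m_ka * x / (1.0 + m_ka * x) - es_state[s, 9]) / tau_ka
                kb = s_kb * es_state[s, 9]
                kb = m_kb * kb / (1.0 + m_kb * kb)
                es_state[s, 10] += dt * (kb - es_state[s, 10]) / tau_kg
                wpre += dt * a_pre_p * es_state[s, 10]

                if wpre < wpre_lo:
                    wpre = wpre_lo
                elif wpre > wpre_hi:
                    wpre = wpre_hi
                es_state[s, 11] = wpre

        # ---- recording -----------------------------------------------
        if rec_stride > 0 and (step + 1) % rec_stride == 0:
            if rec_i < rec_out.shape[1]:
                for r in range(rec_comp.shape[0]):
                    rec_out[r, rec_i] = v[rec_comp[r]]
                rec_i += 1
        if w_stride > 0 and (step + 1) % w_stride == 0:
            if w_i < w_out.shape[0]:
                for s in range(ne):
                    w_out[w_i, s, 0] = es_state[s, 11]
                    w_out[w_i, s, 1] = es_state[s, 12]
                w_i += 1

    return 0
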