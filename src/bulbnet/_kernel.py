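"""Fixed-timestep integration kernel for the whole cell forest.

A single numba-compiled routine advances every compartment of every cell
with an implicit (backward-Euler) voltage update solved by Hines
elimination over the tree-structured forest, staggered with Rush-Larsen
exponential gating updates read from precomputed lookup tables.

Synaptic conductances are linear two-state kinetics (dual exponential, or
alpha as a special case) driven by three event sources: a pre-sorted
scheduled event list (odor/sniff inputs, probe conductances), per-cell
Poisson background generated online from a counter RNG, and reciprocal
dendrodendritic events detected as -40 mV upward crossings of the
presynaptic compartment.  Dendrodendritic events also drive the
presynaptic-ISI plasticity rule.  Detected events are applied at the end of
the timestep in which they occur (one-step latency).

Units: mV, ms, nA, uS, nF.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_DIVERGED = 1
STATUS_SPIKE_OVERFLOW = 2


@njit(cache=True, inline="always")
def _rng_next(state):
    # splitmix64; returns (new_state, uniform in (0,1])
    state = state + np.uint64(0x9E3779B97F4A7C15)
    z = state
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    u = (np.float64(z >> np.uint64(11)) + 1.0) / 9007199254740993.0
    return state, u


@njit(cache=True, inline="always")
def _sigmoid(p, mid, slope):
    return 1.0 / (1.0 + np.exp(-(p - mid) / slope))


@njit(cache=True, fastmath=True)
def integrate(
    dt, n_steps, t_start,
    # --- compartments ---
    parent, g_ax, cmdt, d0, g_leak, e_leak,
    gna, gka, gkdr, use_slow, has_kdr, alt_ka,
    ena, ek,
    v, gm, gh, gs, ga, gb, gn, vmax,
    # --- gating tables ---
    v_lo, v_istep, tab_inf, tab_fac,
    # --- current injection ---
    iinj, iinj_on, iinj_off,
    # --- synaptic mechanisms ---
    syn_tgt, syn_fr, syn_fd, syn_inc, syn_erev, syn_nmda, syn_dual, syn_ak,
    synA, synB, mg_conc,
    # --- scheduled events (sorted by step) ---
    ev_step, ev_mech, ev_w,
    # --- background drive ---
    bg_mech, bg_rate, bg_next, bg_state, bg_w,
    # --- reciprocal connections & plasticity ---
    cn_mc, cn_gc, cn_ampa, cn_nmda, cn_gaba,
    p_exc, p_inh, last_exc, last_inh,
    g_exc_max, g_inh_max, sig_mid, sig_slope, p_hi,
    isi_pot, isi_dep, presyn_thresh, plast_on,
    # --- spike recording ---
    cell_soma, spk_cell, spk_time, last_spk, spk_above,
    spike_thresh, spike_refrac,
    # --- probes / snapshots ---
    probe_comp, probe_stride, probe_buf,
    snap_stride, snap_exc, snap_inh,
):
    n = v.shape[0]
    n_mech = syn_tgt.shape[0]
    n_conn = cn_mc.shape[0]
    n_cell = cell_soma.shape[0]
    n_ev = ev_step.shape[0]
    n_probe = probe_comp.shape[0]

    gsyn = np.zeros(n)
    gsyn_e = np.zeros(n)
    diag = np.zeros(n)
    rhs = np.zeros(n)
    above40 = np.zeros(n, np.uint8)
    for i in range(n):
        if v[i] >= presyn_thresh:
            above40[i] = 1

    ev_ptr = 0
    n_spk = 0
    spk_cap = spk_cell.shape[0]

    for k in range(n_steps):
        t = t_start + k * dt

        # probes sample the state at the start of the step
        if n_probe > 0 and k % probe_stride == 0:
            s = k // probe_stride
            for q in range(n_probe):
                probe_buf[q, s] = v[probe_comp[q]]

        # scheduled events due at this step
        while ev_ptr < n_ev and ev_step[ev_ptr] <= k:
            m = ev_mech[ev_ptr]
            synA[m] += ev_w[ev_ptr] * syn_inc[m]
            synB[m] += ev_w[ev_ptr] * syn_inc[m]
            ev_ptr += 1

        # background Poisson events (online, per cell)
        for c in range(n_cell):
            if bg_rate[c] > 0.0:
                while bg_next[c] <= t:
                    m = bg_mech[c]
                    synA[m] += bg_w * syn_inc[m]
                    synB[m] += bg_w * syn_inc[m]
                    st, u = _rng_next(bg_state[c])
                    bg_state[c] = st
                    bg_next[c] += -np.log(u) / bg_rate[c]

        # synaptic conductances: decay states, accumulate onto compartments
        for m in range(n_mech):
            a = synA[m] * syn_fr[m]
            b = synB[m] * syn_fd[m] + synA[m] * syn_ak[m] * syn_fd[m]
            synA[m] = a
            synB[m] = b
            g = b - syn_dual[m] * a
            if g != 0.0:
                tg = syn_tgt[m]
                if syn_nmda[m] == 1:
                    g *= 1.0 / (1.0 + np.exp(-0.062 * v[tg]) * mg_conc / 3.57)
                gsyn[tg] += g
                gsyn_e[tg] += g * syn_erev[m]

        inject = (iinj_on <= t) and (t < iinj_off)

        # gating update + channel currents + matrix assembly
        for i in range(n):
            vi = v[i]
            pos = (vi - v_lo) * v_istep
            if pos < 0.0:
                pos = 0.0
            maxpos = tab_inf.shape[1] - 2.0
            if pos > maxpos:
                pos = maxpos
            j = int(pos)
            fr = pos - j
            o = 6 * alt_ka[i]  # cell-type kinetics variant row offset

            r = o + 0
            inf = tab_inf[r, j] + (tab_inf[r, j + 1] - tab_inf[r, j]) * fr
            fac = tab_fac[r, j] + (tab_fac[r, j + 1] - tab_fac[r, j]) * fr
            gm[i] = inf + (gm[i] - inf) * fac
            r = o + 1
            inf = tab_inf[r, j] + (tab_inf[r, j + 1] - tab_inf[r, j]) * fr
            fac = tab_fac[r, j] + (tab_fac[r, j + 1] - tab_fac[r, j]) * fr
            gh[i] = inf + (gh[i] - inf) * fac
            if use_slow[i] == 1:
                r = o + 2
                inf = tab_inf[r, j] + (tab_inf[r, j + 1] - tab_inf[r, j]) * fr
                fac = tab_fac[r, j] + (tab_fac[r, j + 1] - tab_fac[r, j]) * fr
                gs[i] = inf + (gs[i] - inf) * fac
            r = o + 3
            inf = tab_inf[r, j] + (tab_inf[r, j + 1] - tab_inf[r, j]) * fr
            fac = tab_fac[r, j] + (tab_fac[r, j + 1] - tab_fac[r, j]) * fr
            ga[i] = inf + (ga[i] - inf) * fac
            r = o + 4
            inf = tab_inf[r, j] + (tab_inf[r, j + 1] - tab_inf[r, j]) * fr
            fac = tab_fac[r, j] + (tab_fac[r, j + 1] - tab_fac[r, j]) * fr
            gb[i] = inf + (gb[i] - inf) * fac
            if has_kdr[i] == 1:
                r = o + 5
                inf = tab_inf[r, j] + (tab_inf[r, j + 1] - tab_inf[r, j]) * fr
                fac = tab_fac[r, j] + (tab_fac[r, j + 1] - tab_fac[r, j]) * fr
                gn[i] = inf + (gn[i] - inf) * fac

            m2 = gm[i] * gm[i]
            g_na = gna[i] * m2 * gm[i] * gh[i]
            if use_slow[i] == 1:
                g_na *= gs[i]
            n2 = gn[i] * gn[i]
            g_k = gkdr[i] * n2 * n2 + gka[i] * ga[i] * gb[i]

            dyn = g_na + g_k + gsyn[i]
            diag[i] = d0[i] + cmdt[i] + dyn
            r = cmdt[i] * vi + g_leak[i] * e_leak[i] + g_na * ena + g_k * ek + gsyn_e[i]
            if inject:
                r += iinj[i]
            rhs[i] = r
            gsyn[i] = 0.0
            gsyn_e[i] = 0.0

        # Hines elimination (parents precede children)
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = g_ax[i] / diag[i]
            diag[p] -= f * g_ax[i]
            rhs[p] += f * rhs[i]
        v[0] = rhs[0] / diag[0]
        if vmax[0] < v[0]:
            vmax[0] = v[0]
        for i in range(1, n):
            vi = (rhs[i] + g_ax[i] * v[parent[i]]) / diag[i]
            v[i] = vi
            if vmax[i] < vi:
                vmax[i] = vi

        t_next = t + dt

        # somatic spike detection
        for c in range(n_cell):
            vs = v[cell_soma[c]]
            if vs >= spike_thresh:
                if spk_above[c] == 0 and t_next - last_spk[c] >= spike_refrac:
                    if n_spk >= spk_cap:
                        return STATUS_SPIKE_OVERFLOW, n_spk
                    spk_cell[n_spk] = c
                    spk_time[n_spk] = t_next
                    n_spk += 1
                    last_spk[c] = t_next
                spk_above[c] = 1
            else:
                spk_above[c] = 0

        # presynaptic threshold crossings -> dendrodendritic events
        if n_conn > 0:
            for i in range(n):
                if v[i] >= presyn_thresh:
                    if above40[i] == 1:
                        above40[i] = 3  # already above
                    else:
                        above40[i] = 2  # upward crossing this step
                else:
                    above40[i] = 0
            for q in range(n_conn):
                mc = cn_mc[q]
                if above40[mc] == 2:
                    if plast_on == 1:
                        if last_exc[q] > -1e29:
                            isi = t_next - last_exc[q]
                            if isi < isi_pot:
                                if p_exc[q] < p_hi:
                                    p_exc[q] += 1
                            elif isi <= isi_dep:
                                if p_exc[q] > 0:
                                    p_exc[q] -= 1
                    last_exc[q] = t_next
                    w = g_exc_max * _sigmoid(p_exc[q], sig_mid, sig_slope)
                    m = cn_ampa[q]
                    synA[m] += w * syn_inc[m]
                    synB[m] += w * syn_inc[m]
                    m = cn_nmda[q]
                    synA[m] += w * syn_inc[m]
                    synB[m] += w * syn_inc[m]
                gc = cn_gc[q]
                if above40[gc] == 2:
                    if plast_on == 1:
                        if last_inh[q] > -1e29:
                            isi = t_next - last_inh[q]
                            if isi < isi_pot:
                                if p_inh[q] < p_hi:
                                    p_inh[q] += 1
                            elif isi <= isi_dep:
                                if p_inh[q] > 0:
                                    p_inh[q] -= 1
                    last_inh[q] = t_next
                    w = g_inh_max * _sigmoid(p_inh[q], sig_mid, sig_slope)
                    m = cn_gaba[q]
                    synA[m] += w * syn_inc[m]
                    synB[m] += w * syn_inc[m]
            for i in range(n):
                if above40[i] >= 2:
                    above40[i] = 1

        # weight snapshots
        if snap_stride > 0 and (k + 1) % snap_stride == 0:
            s = (k + 1) // snap_stride - 1
            if s < snap_exc.shape[0]:
                for q in range(n_conn):
                    snap_exc[s, q] = _sigmoid(p_exc[q], sig_mid, sig_slope)
                    snap_inh[s, q] = _sigmoid(p_inh[q], sig_mid, sig_slope)

        # divergence guard
        if k % 200 == 199:
            for i in range(n):
                if not (-200.0 < v[i] < 200.0):
                    return STATUS_DIVERGED, n_spk

    return STATUS_OK, n_spk
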