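"""Numba simulation kernel: implicit cable solver coupled to the plasticity rule.

The membrane equation is integrated with backward Euler.  Channel gates
are advanced with exponential (Rush-Larsen) updates using the voltage at
the beginning of the step; the voltage is then solved implicitly on the
dendritic tree with a Hines-ordered elimination (compartments are
ordered so every parent precedes its children, giving an O(N) exact
solve of the symmetric tree system).  Synaptic conductances are
event-driven difference-of-exponential states; only synapses with
non-negligible conductance are touched each step.

Gate rows (state array): 0 m(Na) 1 h(Na) 2 n(KDRf) 3 ns(KDRs) 4 a(KA)
5 b(KA) 6 ct(CaT) 7 cth(CaT inact) 8 cn(CaN) 9 cnh(CaN inact)
10 cl(CaL) 11 z(SK, Ca-gated) 12 o(BK, V+Ca gated).
Channel conductance rows follow :data:`gcplast.mechanisms.CHANNELS`.
"""

import numpy as np
from numba import njit

NG = 13  # number of gate states
PMAX = 64  # pending presynaptic spikes per synapse awaiting a post event


@njit(cache=True, inline="always")
def _vtrap(x, y):
    # x/(1-exp(-x/y)) with the removable singularity handled
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / y / 2.0)
    return x / (1.0 - np.exp(-x / y))


@njit(cache=True)
def _gate_inf_tau(v, ca, inf, tau):
    """Steady states and time constants of all gates at voltage v (mV), ca (mM)."""
    # Na activation/inactivation (HH-style, threshold near -50 mV)
    am = 0.32 * _vtrap(v + 47.0, 4.0)
    bm = 0.28 * _vtrap(-(v + 20.0), 5.0)
    inf[0] = am / (am + bm)
    tau[0] = 1.0 / (am + bm)
    # Na inactivation: steep around -50 mV so sustained depolarization
    # (400 Hz volleys) drives the soma into depolarization block, while
    # recovery between 100 Hz pulses (~12 ms near rest) stays fast enough
    # for faithful theta-burst following
    inf[1] = 1.0 / (1.0 + np.exp((v + 52.0) / 4.0))
    tau[1] = 2.0 + 10.0 * np.exp(-np.abs(v + 60.0) / 20.0)
    # fast delayed rectifier
    an = 0.032 * _vtrap(v + 45.0, 5.0)
    bn = 0.4 * np.exp(-(v + 50.0) / 40.0)
    inf[2] = an / (an + bn)
    tau[2] = 1.0 / (an + bn)
    # slow delayed rectifier
    inf[3] = 1.0 / (1.0 + np.exp(-(v + 35.0) / 6.0))
    tau[3] = 50.0
    # A-type K: fast activation above rest (small window current), slower inactivation
    inf[4] = 1.0 / (1.0 + np.exp(-(v + 25.0) / 9.0))
    tau[4] = 4.0
    inf[5] = 1.0 / (1.0 + np.exp((v + 60.0) / 6.0))
    tau[5] = 15.0
    # T-type Ca (low threshold)
    inf[6] = 1.0 / (1.0 + np.exp(-(v + 50.0) / 4.0))
    tau[6] = 5.0
    inf[7] = 1.0 / (1.0 + np.exp((v + 75.0) / 5.0))
    tau[7] = 30.0
    # N-type Ca (high threshold, inactivating)
    inf[8] = 1.0 / (1.0 + np.exp(-(v + 20.0) / 5.0))
    tau[8] = 2.0
    inf[9] = 1.0 / (1.0 + np.exp((v + 40.0) / 10.0))
    tau[9] = 80.0
    # L-type Ca (high threshold, non-inactivating)
    inf[10] = 1.0 / (1.0 + np.exp(-(v + 10.0) / 5.0))
    tau[10] = 2.0
    # SK: Ca-dependent
    ca2 = ca * ca
    kd = 0.0005  # mM
    inf[11] = ca2 / (ca2 + kd * kd)
    tau[11] = 10.0
    # BK: voltage- and Ca-dependent
    inf[12] = (1.0 / (1.0 + np.exp(-(v + 10.0) / 10.0))) * (ca / (ca + 0.002))
    tau[12] = 2.0


@njit(cache=True)
def run_sim(
    # geometry / passive (absolute units: mS, µF)
    parent,
    g_ax,
    cm_abs,
    gl_abs,
    e_l,
    e_na,
    e_k,
    e_ca,
    # channel conductances, (9, N) mS; _b takes over at t_switch
    gbar_a,
    gbar_b,
    t_switch,
    # calcium pool
    ca_rest,
    ca_tau,
    ca_fac,
    # synapses
    syn_comp,
    w_init,
    tau_r,
    tau_dsyn,
    e_syn,
    comp_syn_start,
    comp_syn_list,
    # presynaptic spikes (sorted)
    spike_t,
    spike_syn,
    # numerics
    dt,
    n_steps,
    v_init,
    # current injection (set amp=0 to disable)
    iinj_comp,
    iinj_amp,
    iinj_t0,
    iinj_t1,
    # plasticity
    plasticity_on,
    warmup_ms,
    ap0,
    ad0,
    tau_p,
    tau_d,
    tau_c_ms,
    alpha,
    c_floor,
    v_syn_th,
    v_soma_th,
    max_change,
    debounce,
    lapse,
    freeze_ap,
    freeze_ad,
    c_init,
    # recording
    rec_stride,
    probes,
    probe_stride,
):
    N = parent.shape[0]
    M = syn_comp.shape[0]

    v = np.full(N, v_init)
    gates = np.empty((NG, N))
    inf = np.empty(NG)
    tau = np.empty(NG)
    ca = np.full(N, ca_rest)
    for i in range(N):
        _gate_inf_tau(v[i], ca[i], inf, tau)
        for g in range(NG):
            gates[g, i] = inf[g]

    # synapse kinetic states; conductance = w * (B - A) / peak_norm
    A = np.zeros(M)
    B = np.zeros(M)
    fr = np.exp(-dt / tau_r)
    fd = np.exp(-dt / tau_dsyn)
    tpk = (tau_dsyn * tau_r) / (tau_dsyn - tau_r) * np.log(tau_dsyn / tau_r)
    peak_norm = np.exp(-tpk / tau_dsyn) - np.exp(-tpk / tau_r)

    active = np.empty(M, dtype=np.int64)
    n_active = 0
    is_active = np.zeros(M, dtype=np.uint8)

    # plasticity state
    w = w_init.copy()
    w0 = w_init.copy()
    last_post = np.full(M, -1e30)
    last_event_c = np.full(N, -1e30)  # debounce per compartment (shared voltage)
    pend_t = np.zeros((M, PMAX))
    pend_n = np.zeros(M, dtype=np.int64)
    dwp = np.zeros(M)
    dwd = np.zeros(M)
    touched = np.empty(M, dtype=np.int64)
    c_avg = c_init
    a_p = ap0 if freeze_ap else ap0 / max(c_avg, c_floor)
    a_d = ad0 if freeze_ad else ad0 * max(c_avg, c_floor)
    c_decay = np.exp(-dt / tau_c_ms)
    c_inc = (alpha / tau_c_ms) * dt

    # recording buffers
    n_rec = n_steps // rec_stride
    w_rec = np.empty((n_rec, M), dtype=np.float32)
    c_rec = np.empty(n_rec)
    ap_rec = np.empty(n_rec)
    ad_rec = np.empty(n_rec)
    t_rec = np.empty(n_rec)
    P = probes.shape[0]
    n_prec = n_steps // probe_stride if P > 0 else 0
    v_probe = np.empty((n_prec, P))
    tp_rec = np.empty(n_prec)
    soma_spikes = np.empty(200000)
    n_soma = 0
    post_counts = np.zeros(M, dtype=np.int64)

    diag = np.empty(N)
    rhs = np.empty(N)
    g_syn_c = np.zeros(N)
    v_prev = np.empty(N)
    children_g = np.zeros(N)  # sum of axial conductances from children
    for i in range(1, N):
        children_g[parent[i]] += g_ax[i]

    sp = 0  # spike pointer
    K = spike_t.shape[0]
    gbar = gbar_a
    switched = False
    status = 0
    fail_t = -1.0

    for k in range(n_steps):
        t1 = (k + 1) * dt
        if (not switched) and t1 >= t_switch:
            gbar = gbar_b
            switched = True

        n_touch = 0
        # deliver presynaptic spikes in (t1-dt, t1]
        while sp < K and spike_t[sp] <= t1:
            s = spike_syn[sp]
            A[s] += 1.0
            B[s] += 1.0
            if is_active[s] == 0:
                is_active[s] = 1
                active[n_active] = s
                n_active += 1
            if plasticity_on:
                tpre = spike_t[sp]
                if dwp[s] == 0.0 and dwd[s] == 0.0:
                    touched[n_touch] = s
                    n_touch += 1
                if last_post[s] < tpre:
                    if tpre - last_post[s] < 1e30:
                        dwd[s] += np.exp((last_post[s] - tpre) / tau_d)
                # push pending (drop lapsed from the front implicitly later)
                if pend_n[s] < PMAX:
                    pend_t[s, pend_n[s]] = tpre
                    pend_n[s] += 1
                else:
                    # buffer full: drop the oldest (it would lapse first)
                    for q in range(PMAX - 1):
                        pend_t[s, q] = pend_t[s, q + 1]
                    pend_t[s, PMAX - 1] = tpre
            sp += 1

        # synaptic conductance accumulation (active synapses only)
        for i in range(N):
            g_syn_c[i] = 0.0
        j = 0
        while j < n_active:
            s = active[j]
            A[s] *= fr
            B[s] *= fd
            gsb = B[s] - A[s]
            if B[s] < 1e-10:
                A[s] = 0.0
                B[s] = 0.0
                is_active[s] = 0
                n_active -= 1
                active[j] = active[n_active]
                continue
            if gsb > 0.0:
                g_syn_c[syn_comp[s]] += w[s] * gsb / peak_norm
            j += 1

        # gates (Rush-Larsen with start-of-step voltage)
        for i in range(N):
            _gate_inf_tau(v[i], ca[i], inf, tau)
            for g in range(NG):
                gates[g, i] = inf[g] + (gates[g, i] - inf[g]) * np.exp(-dt / tau[g])

        # assemble implicit system
        for i in range(N):
            m = gates[0, i]
            gna = gbar[0, i] * m * m * m * gates[1, i]
            nn = gates[2, i]
            gkf = gbar[1, i] * nn * nn * nn * nn
            gks = gbar[2, i] * gates[3, i] * gates[3, i]
            gka = gbar[3, i] * gates[4, i] * gates[5, i]
            gct = gbar[4, i] * gates[6, i] * gates[6, i] * gates[7, i]
            gcn = gbar[5, i] * gates[8, i] * gates[8, i] * gates[9, i]
            gcl = gbar[6, i] * gates[10, i] * gates[10, i]
            gsk = gbar[7, i] * gates[11, i]
            gbk = gbar[8, i] * gates[12, i]
            gca = gct + gcn + gcl
            gk = gkf + gks + gka + gsk + gbk
            gtot = gna + gk + gca + gl_abs[i] + g_syn_c[i]
            d = cm_abs[i] / dt + gtot + children_g[i]
            r = (
                cm_abs[i] / dt * v[i]
                + gna * e_na
                + gk * e_k
                + gca * e_ca
                + gl_abs[i] * e_l
                + g_syn_c[i] * e_syn
            )
            if parent[i] >= 0:
                d += g_ax[i]
            diag[i] = d
            rhs[i] = r
        if iinj_amp != 0.0 and iinj_t0 <= t1 < iinj_t1:
            rhs[iinj_comp] += iinj_amp

        # Hines solve (children have larger indices than parents)
        for i in range(N - 1, 0, -1):
            p = parent[i]
            f = g_ax[i] / diag[i]
            diag[p] -= f * g_ax[i]
            rhs[p] += f * rhs[i]
        for i in range(N):
            v_prev[i] = v[i]
        v[0] = rhs[0] / diag[0]
        for i in range(1, N):
            v[i] = (rhs[i] + g_ax[i] * v[parent[i]]) / diag[i]

        # calcium pool update (uses new voltage)
        for i in range(N):
            gca = (
                gbar[4, i] * gates[6, i] * gates[6, i] * gates[7, i]
                + gbar[5, i] * gates[8, i] * gates[8, i] * gates[9, i]
                + gbar[6, i] * gates[10, i] * gates[10, i]
            )
            ica = gca * (v[i] - e_ca)  # µA, negative inward
            ca[i] += dt * (-ca_fac[i] * ica - (ca[i] - ca_rest) / ca_tau)
            if ca[i] < 1e-8:
                ca[i] = 1e-8

        if not (np.isfinite(v[0]) and np.isfinite(v[N - 1])):
            status = 1
            fail_t = t1
            break

        # somatic spike detection feeds the global spike-count average
        spiked = v_prev[0] < v_soma_th and v[0] >= v_soma_th
        c_avg *= c_decay
        if spiked:
            c_avg += c_inc
            if n_soma < soma_spikes.shape[0]:
                soma_spikes[n_soma] = t1
                n_soma += 1
        cf = c_avg if c_avg > c_floor else c_floor
        a_p = ap0 if freeze_ap else ap0 / cf
        a_d = ad0 if freeze_ad else ad0 * cf

        # local post events: upward crossings of the dendritic threshold
        if plasticity_on:
            for i in range(N):
                if v_prev[i] < v_syn_th and v[i] >= v_syn_th:
                    if t1 - last_event_c[i] < debounce:
                        continue
                    last_event_c[i] = t1
                    for q in range(comp_syn_start[i], comp_syn_start[i + 1]):
                        s = comp_syn_list[q]
                        post_counts[s] += 1
                        # consume pending pre spikes (pre-centered pairing)
                        for z in range(pend_n[s]):
                            d_pp = t1 - pend_t[s, z]
                            if d_pp > 0.0 and d_pp <= lapse:
                                if dwp[s] == 0.0 and dwd[s] == 0.0:
                                    touched[n_touch] = s
                                    n_touch += 1
                                dwp[s] += np.exp(-d_pp / tau_p)
                        pend_n[s] = 0
                        last_post[s] = t1

            # apply accumulated updates for this step
            if t1 > warmup_ms:
                for q in range(n_touch):
                    s = touched[q]
                    wn = w[s] * (1.0 + a_p * dwp[s] - a_d * dwd[s])
                    lo = w0[s] * (1.0 - max_change)
                    if lo < 1e-12 * w0[s]:
                        lo = 1e-12 * w0[s]
                    hi = w0[s] * (1.0 + max_change)
                    if wn < lo:
                        wn = lo
                    elif wn > hi:
                        wn = hi
                    w[s] = wn
                    dwp[s] = 0.0
                    dwd[s] = 0.0
            else:
                for q in range(n_touch):
                    s = touched[q]
                    dwp[s] = 0.0
                    dwd[s] = 0.0

        if (k + 1) % rec_stride == 0:
            r_i = (k + 1) // rec_stride - 1
            if r_i < n_rec:
                t_rec[r_i] = t1
                c_rec[r_i] = c_avg
                ap_rec[r_i] = a_p
                ad_rec[r_i] = a_d
                for s in range(M):
                    w_rec[r_i, s] = w[s]
        if P > 0 and (k + 1) % probe_stride == 0:
            r_i = (k + 1) // probe_stride - 1
            if r_i < n_prec:
                tp_rec[r_i] = t1
                for q in range(P):
                    v_probe[r_i, q] = v[probes[q]]

    return (
        status,
        fail_t,
        t_rec,
        w_rec,
        c_rec,
        ap_rec,
        ad_rec,
        soma_spikes[:n_soma].copy(),
        post_counts,
        tp_rec,
        v_probe,
        w,
        c_avg,
        v,
    )
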