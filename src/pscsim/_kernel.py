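"""Fixed-step forward-Euler inner loop of the coupled astrocyte/neurone model.

The loop is a single numba-compiled function over packed float64
parameter vectors so a one-minute protocol at a 10 us step (~7 million
steps) runs in seconds.  A pure-Python fallback is used when numba is
unavailable.  Index constants below define the packing; the pack/unpack
logic lives in :mod:`pscsim.model`.

State vector layout::

    y = [V_A, K_PsC, Na_PsC, K_PsECS, Glu_PsECS, V_Neu, n, m, h]
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover
    from numba import njit

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):  # type: ignore
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


# -- packed astro/morphology/constants/neuron parameter indices -------------
P_VM, P_PHI_W, P_G_KIR, P_G_K, P_G_NA, P_K_K, P_K_NA, P_PNKA, P_K_NAI, P_K_KE = range(10)
P_E_KIR_FIXED, P_KIR_OFFSET, P_G_ECS, P_ALPHA, P_BETA, P_R_G, P_S_G, P_PREF = range(10, 18)
P_GLU_PSC, P_H_PSC, P_K_AS, P_NA_AS, P_H_PSECS, P_NA_PSECS, P_K_GECS, P_NA_GECS, P_L_P = range(18, 27)
P_KIR_MODE = 27
P_SA_PS, P_CSA_P, P_SA_ECSL, P_SA_SYN, P_VOL_PSC, P_VOL_PSECS = range(28, 34)
P_RT_F, P_F, P_Q, P_KT_EV, P_EPS, P_C_M = range(34, 40)
P_G_NA_HH, P_G_K_HH, P_G_L_HH, P_E_NA_N, P_E_K_N, P_E_L_N, P_C_M_NEU, P_SHIFT = range(40, 48)
P_G_KNEU, P_E_KNEU, P_PNKA_NEU, P_K_NAI_NEU, P_K_KE_NEU, P_NA_SYN, P_F_REL = range(48, 55)
N_PARAMS = 55

# -- protocol vector indices -------------------------------------------------
R_DT, R_STIM_START, R_STIM_END, R_DRIVE_KIND, R_AMP, R_RATE, R_PULSE_W = range(7)
R_GLU_MODE, R_GLU_CLAMP, R_GLU_FLOOR, R_GLU_PEAK, R_GLU_T0, R_GLU_SIGMA, R_GLU_BASE = range(7, 14)
R_K_CLAMP, R_K_CLAMP_VAL, R_SPIKE_PUFF, R_SPIKE_THR, R_REFRACTORY = range(14, 19)
N_PROTO = 19

# -- stats vector indices ----------------------------------------------------
S_MAX_IK_MEM, S_MAX_IKPF, S_KIR_SIGN_CHANGES, S_MAX_INA_MEM, S_MAX_INAPF, S_SPIKES = range(6)
S_STATUS, S_T_FAIL, S_FAIL_VAR, S_MAX_IK_IN, S_MAX_INA_IN = range(6, 11)
N_STATS = 11

# failure variable codes for S_FAIL_VAR
FAIL_NAMES = {1.0: "K_PsC", 2.0: "Na_PsC", 3.0: "K_PsECS", 4.0: "Glu_PsECS", 5.0: "non-finite state"}


@njit(cache=True)
def _hh_rates_k(v_mv: float):
    x = v_mv + 55.0
    if abs(x) < 1e-7:
        a_n = 0.1
    else:
        a_n = 0.01 * x / (1.0 - math.exp(-x / 10.0))
    b_n = 0.125 * math.exp(-(v_mv + 65.0) / 80.0)
    y = v_mv + 40.0
    if abs(y) < 1e-7:
        a_m = 1.0
    else:
        a_m = 0.1 * y / (1.0 - math.exp(-y / 10.0))
    b_m = 4.0 * math.exp(-(v_mv + 65.0) / 18.0)
    a_h = 0.07 * math.exp(-(v_mv + 65.0) / 20.0)
    b_h = 1.0 / (1.0 + math.exp(-(v_mv + 35.0) / 10.0))
    return (a_n * 1e3, b_n * 1e3, a_m * 1e3, b_m * 1e3, a_h * 1e3, b_h * 1e3)


@njit(cache=True)
def _astro_currents(v_a, k_psc, na_psc, k_psecs, glu, P):
    """All astrocyte currents at one state; efflux-positive convention.

    Returns (I_Kir, I_KB, I_KNKA, I_KEAAT, I_KPF, I_KECSL,
             I_NaB, I_NaNKA, I_NaEAAT, I_NaPF, I_GluEAAT).
    """
    rt_f = P[P_RT_F]
    sa = P[P_SA_PS]

    # Kir
    e_n = rt_f * math.log(k_psecs / k_psc)
    mode = P[P_KIR_MODE]
    if mode == 2.0:
        e_kir = P[P_E_KIR_FIXED]
    elif mode == 1.0:
        e_kir = e_n + P[P_KIR_OFFSET]
    else:
        e_kir = e_n
    i_kir = P[P_G_KIR] * k_psecs * (v_a - e_kir) * sa

    # background channels
    i_kb = P[P_G_K] * (v_a - e_n) * sa
    e_na = rt_f * math.log(P[P_NA_PSECS] / na_psc)
    i_nab = P[P_G_NA] * (v_a - e_na) * sa

    # NKA (K in, Na out; 3:2)
    na15 = na_psc ** 1.5
    hill = na15 / (na15 + P[P_K_NAI] ** 1.5)
    mm = k_psecs / (k_psecs + P[P_K_KE])
    base = P[P_F] * P[P_PNKA] * hill * mm * sa
    i_knka = -2.0 * base
    i_nanka = 3.0 * base

    # EAAT (1 K out per 3 Na + 1 Glu in)
    ratio = ((P[P_NA_PSECS] / na_psc) ** 3 * (k_psc / k_psecs)
             * (P[P_H_PSECS] / P[P_H_PSC]) * (glu / P[P_GLU_PSC]))
    v_rev = 0.5 * rt_f * math.log(ratio)
    i_mg = P[P_PREF] * (-P[P_ALPHA] * (math.exp(-P[P_BETA] * (v_a - v_rev)) - 1.0))
    sat = 1.0 - math.exp(P[P_R_G] * (P[P_S_G] - glu))
    j = -i_mg * sat * sa
    i_keaat = j
    i_naeaat = -3.0 * j
    i_glueaat = j

    # Poole-Frenkel hopping along the process
    i_kpf = 0.0
    v_r = rt_f * math.log(P[P_K_AS] / k_psc)
    dv = v_a - P[P_VM] - v_r
    if dv != 0.0:
        dphi = math.sqrt(P[P_Q] * abs(dv) / (P[P_L_P] * math.pi * P[P_EPS]))
        i_kpf = (P[P_K_K] * (dv / P[P_L_P])
                 * math.exp(-(P[P_PHI_W] - dphi) / P[P_KT_EV]) * P[P_CSA_P])
    i_napf = 0.0
    v_r_na = rt_f * math.log(P[P_NA_AS] / na_psc)
    dv_na = v_a - P[P_VM] - v_r_na
    if dv_na != 0.0:
        dphi = math.sqrt(P[P_Q] * abs(dv_na) / (P[P_L_P] * math.pi * P[P_EPS]))
        i_napf = (P[P_K_NA] * (dv_na / P[P_L_P])
                  * math.exp(-(P[P_PHI_W] - dphi) / P[P_KT_EV]) * P[P_CSA_P])

    # PsECS -> GECS leak
    i_kecsl = P[P_G_ECS] * rt_f * math.log(k_psecs / P[P_K_GECS]) * P[P_SA_ECSL]

    return (i_kir, i_kb, i_knka, i_keaat, i_kpf, i_kecsl,
            i_nab, i_nanka, i_naeaat, i_napf, i_glueaat)


@njit(cache=True)
def integrate(y0, P, proto, n_steps, record_every):
    """Forward-Euler integration of the full coupled system.

    Returns ``(Y, stats)`` where ``Y`` has one row per recorded sample
    (row 0 is the initial state) and ``stats`` collects full-resolution
    extrema over the stimulation window plus a status code.
    """
    dt = proto[R_DT]
    n_rec = n_steps // record_every + 1
    Y = np.empty((n_rec, 9))
    stats = np.zeros(N_STATS)

    v_a, k_psc, na_psc, k_psecs, glu = y0[0], y0[1], y0[2], y0[3], y0[4]
    v_n, gn, gm, gh = y0[5], y0[6], y0[7], y0[8]

    if proto[R_K_CLAMP] == 1.0:
        k_psecs = proto[R_K_CLAMP_VAL]
    if proto[R_GLU_MODE] == 0.0:
        glu = proto[R_GLU_CLAMP]

    Y[0, 0] = v_a
    Y[0, 1] = k_psc
    Y[0, 2] = na_psc
    Y[0, 3] = k_psecs
    Y[0, 4] = glu
    Y[0, 5] = v_n
    Y[0, 6] = gn
    Y[0, 7] = gm
    Y[0, 8] = gh

    f_vol_psc = P[P_F] * P[P_VOL_PSC]
    f_vol_psecs = P[P_F] * P[P_VOL_PSECS]
    cap = P[P_C_M] * P[P_SA_PS]
    f_rel = P[P_F_REL]
    sa_syn = P[P_SA_SYN]
    na15_syn = P[P_NA_SYN] ** 1.5
    hill_neu = na15_syn / (na15_syn + P[P_K_NAI_NEU] ** 1.5)

    period = 1.0 / proto[R_RATE] if proto[R_RATE] > 0.0 else 0.0
    last_spike_t = -1e9
    prev_vn = v_n
    prev_kir_sign = 0.0
    rec = 1

    for i in range(n_steps):
        t = i * dt
        in_stim = proto[R_STIM_START] <= t < proto[R_STIM_END]

        # prescribed glutamate trajectory
        if proto[R_GLU_MODE] == 2.0:
            z = (t - proto[R_GLU_T0]) / proto[R_GLU_SIGMA]
            glu = proto[R_GLU_BASE] + (proto[R_GLU_PEAK] - proto[R_GLU_BASE]) * math.exp(-0.5 * z * z)

        (i_kir, i_kb, i_knka, i_keaat, i_kpf, i_kecsl,
         i_nab, i_nanka, i_naeaat, i_napf, i_glueaat) = _astro_currents(
            v_a, k_psc, na_psc, k_psecs, glu, P)

        # neuronal coupling currents
        i_kneu = f_rel * P[P_G_KNEU] * gn**4 * (v_n - P[P_E_KNEU]) * sa_syn
        mm_neu = k_psecs / (k_psecs + P[P_K_KE_NEU])
        i_knka_neu = 2.0 * P[P_F] * P[P_PNKA_NEU] * hill_neu * mm_neu * f_rel * sa_syn

        i_k_mem = i_kir + i_kb + i_knka + i_keaat
        i_na_mem = i_nab + i_nanka + i_naeaat

        if in_stim:
            a = abs(i_k_mem)
            if a > stats[S_MAX_IK_MEM]:
                stats[S_MAX_IK_MEM] = a
            a = abs(i_kpf)
            if a > stats[S_MAX_IKPF]:
                stats[S_MAX_IKPF] = a
            a = abs(i_na_mem)
            if a > stats[S_MAX_INA_MEM]:
                stats[S_MAX_INA_MEM] = a
            a = abs(i_napf)
            if a > stats[S_MAX_INAPF]:
                stats[S_MAX_INAPF] = a
            # gross influx (sum of the inward-signed channel components)
            a = 0.0
            if i_kir < 0.0:
                a -= i_kir
            if i_kb < 0.0:
                a -= i_kb
            if i_knka < 0.0:
                a -= i_knka
            if i_keaat < 0.0:
                a -= i_keaat
            if a > stats[S_MAX_IK_IN]:
                stats[S_MAX_IK_IN] = a
            a = 0.0
            if i_nab < 0.0:
                a -= i_nab
            if i_nanka < 0.0:
                a -= i_nanka
            if i_naeaat < 0.0:
                a -= i_naeaat
            if a > stats[S_MAX_INA_IN]:
                stats[S_MAX_INA_IN] = a
            s = 0.0
            if i_kir > 0.0:
                s = 1.0
            elif i_kir < 0.0:
                s = -1.0
            if s != 0.0 and prev_kir_sign != 0.0 and s != prev_kir_sign:
                stats[S_KIR_SIGN_CHANGES] += 1.0
            if s != 0.0:
                prev_kir_sign = s
        else:
            prev_kir_sign = 0.0

        # derivatives
        dv_a = -(i_k_mem + i_na_mem) / cap
        dk_psc = -(i_k_mem + i_kpf) / f_vol_psc
        dna_psc = -(i_na_mem + i_napf) / f_vol_psc
        dk_psecs = (i_k_mem - i_kecsl + i_kneu - i_knka_neu) / f_vol_psecs
        dglu = -i_glueaat / f_vol_psecs

        # neurone
        i_app = 0.0
        if in_stim:
            if proto[R_DRIVE_KIND] == 1.0:
                i_app = proto[R_AMP]
            elif proto[R_DRIVE_KIND] == 2.0 and period > 0.0:
                phase = (t - proto[R_STIM_START]) % period
                if phase < proto[R_PULSE_W]:
                    i_app = proto[R_AMP]
        v_mv = (v_n - P[P_SHIFT]) * 1e3
        a_n, b_n, a_m, b_m, a_h, b_h = _hh_rates_k(v_mv)
        i_na_hh = P[P_G_NA_HH] * gm**3 * gh * (v_n - P[P_E_NA_N])
        i_k_hh = P[P_G_K_HH] * gn**4 * (v_n - P[P_E_K_N])
        i_l_hh = P[P_G_L_HH] * (v_n - P[P_E_L_N])
        dv_n = (i_app - i_na_hh - i_k_hh - i_l_hh) / P[P_C_M_NEU]

        # Euler update
        v_a += dt * dv_a
        k_psc += dt * dk_psc
        na_psc += dt * dna_psc
        if proto[R_K_CLAMP] != 1.0:
            k_psecs += dt * dk_psecs
        if proto[R_GLU_MODE] == 1.0:
            glu += dt * dglu
            if glu < proto[R_GLU_FLOOR]:
                glu = proto[R_GLU_FLOOR]
        v_n += dt * dv_n
        gn += dt * (a_n * (1.0 - gn) - b_n * gn)
        gm += dt * (a_m * (1.0 - gm) - b_m * gm)
        gh += dt * (a_h * (1.0 - gh) - b_h * gh)

        # spike detection (for the per-spike glutamate puff and the count)
        if prev_vn < proto[R_SPIKE_THR] <= v_n:
            if (t - last_spike_t) >= proto[R_REFRACTORY]:
                last_spike_t = t
                stats[S_SPIKES] += 1.0
                if proto[R_GLU_MODE] == 1.0 and proto[R_SPIKE_PUFF] > 0.0:
                    glu += proto[R_SPIKE_PUFF]
        prev_vn = v_n

        # validity checks
        if not (math.isfinite(v_a) and math.isfinite(v_n)):
            stats[S_STATUS] = 1.0
            stats[S_T_FAIL] = t
            stats[S_FAIL_VAR] = 5.0
            return Y[:rec], stats
        if k_psc <= 0.0 or na_psc <= 0.0 or k_psecs <= 0.0 or glu <= 0.0:
            stats[S_STATUS] = 1.0
            stats[S_T_FAIL] = t
            if k_psc <= 0.0:
                stats[S_FAIL_VAR] = 1.0
            elif na_psc <= 0.0:
                stats[S_FAIL_VAR] = 2.0
            elif k_psecs <= 0.0:
                stats[S_FAIL_VAR] = 3.0
            else:
                stats[S_FAIL_VAR] = 4.0
            return Y[:rec], stats

        if (i + 1) % record_every == 0:
            Y[rec, 0] = v_a
            Y[rec, 1] = k_psc
            Y[rec, 2] = na_psc
            Y[rec, 3] = k_psecs
            Y[rec, 4] = glu
            Y[rec, 5] = v_n
            Y[rec, 6] = gn
            Y[rec, 7] = gm
            Y[rec, 8] = gh
            rec += 1

    return Y[:rec], stats
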