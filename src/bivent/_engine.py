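"""Fixed-step RK4 core for the closed-loop circulation, numba-compiled.

State vector (mL): [V_lv, V_rv, V_sa, V_sv, V_pa, V_pv].
The right-hand side moves volume between compartments through resistive
paths; the only source term is the maintenance infusion, so classical
Runge-Kutta preserves total blood volume (a linear invariant) to floating
point exactly, net of the infusion.

Valves are smooth soft diodes, Q = softplus(dP; w)/R with width w ~ 0.25
mmHg: strictly non-negative flow, no ODE discontinuities, and a leak that
vanishes as exp(dP/w) when the valve is closed.
"""

import numpy as np
from numba import njit

# parameter-vector layout ------------------------------------------------
P_T = 0  # beat period, s
# LV chamber 1..8: emax, emin, v0, tau1, tau2, n1, n2, inv_norm
P_LV = 1
# RV chamber 9..16
P_RV = 9
P_R_AV = 17
P_R_SART = 18
P_R_SVEN = 19
P_R_TV = 20
P_R_PVALVE = 21
P_R_PART = 22
P_R_PVEN = 23
P_R_MV = 24
P_C_SA = 25
P_C_SV = 26
P_C_PA = 27
P_C_PV = 28
P_VU_SA = 29
P_VU_SV = 30
P_VU_PA = 31
P_VU_PV = 32
P_INFUSION = 33  # mL/s
P_PERI_GAIN = 34
P_PERI_K = 35
P_PERI_VREF = 36
P_PUMP_ON = 37
P_PUMP_MAX = 38  # mL/s at zero head
P_PUMP_SLOPE = 39  # mL/s per mmHg
P_PUMP_VSUC = 40
P_PUMP_WSUC = 41
P_OCC_T0 = 42
P_OCC_DUR = 43
P_OCC_MULT = 44
P_VALVE_W = 45
NPAR = 46

NSTATE = 6  # physical volumes; two flow accumulators are appended below
NAUG = 8  # [V..., int q_pvalve dt, int q_av dt]


@njit(cache=True)
def softplus(x, w):
    z = x / w
    if z > 30.0:
        return x
    if z < -30.0:
        return 0.0
    return w * np.log(1.0 + np.exp(z))


@njit(cache=True)
def activation_nb(tb, T, tau1, tau2, n1, n2, inv_norm):
    """Double-Hill activation, tau1/tau2 as fractions of the period."""
    x1 = (tb / (tau1 * T)) ** n1
    h1 = x1 / (1.0 + x1)
    h2 = 1.0 / (1.0 + (tb / (tau2 * T)) ** n2)
    return inv_norm * h1 * h2


@njit(cache=True)
def _pressures(t, y, p):
    """Instantaneous pressures and elastances.

    Returns (P_lv, P_rv, P_sa, P_sv, P_pa, P_pv, P_peri).
    """
    T = p[P_T]
    tb = t % T
    a_lv = activation_nb(tb, T, p[P_LV + 3], p[P_LV + 4], p[P_LV + 5], p[P_LV + 6], p[P_LV + 7])
    a_rv = activation_nb(tb, T, p[P_RV + 3], p[P_RV + 4], p[P_RV + 5], p[P_RV + 6], p[P_RV + 7])
    e_lv = p[P_LV + 1] + (p[P_LV + 0] - p[P_LV + 1]) * a_lv
    e_rv = p[P_RV + 1] + (p[P_RV + 0] - p[P_RV + 1]) * a_rv
    peri = p[P_PERI_GAIN] * np.exp(p[P_PERI_K] * (y[0] + y[1] - p[P_PERI_VREF]))
    p_lv = e_lv * (y[0] - p[P_LV + 2]) + peri
    p_rv = e_rv * (y[1] - p[P_RV + 2]) + peri
    p_sa = (y[2] - p[P_VU_SA]) / p[P_C_SA]
    p_sv = (y[3] - p[P_VU_SV]) / p[P_C_SV]
    p_pa = (y[4] - p[P_VU_PA]) / p[P_C_PA]
    p_pv = (y[5] - p[P_VU_PV]) / p[P_C_PV]
    return p_lv, p_rv, p_sa, p_sv, p_pa, p_pv, peri


@njit(cache=True)
def _flows(t, y, p):
    """Instantaneous flows (mL/s).

    Returns (q_av, q_sys, q_tv, q_pvalve, q_pul, q_mv, q_pump).
    """
    p_lv, p_rv, p_sa, p_sv, p_pa, p_pv, _ = _pressures(t, y, p)
    w = p[P_VALVE_W]
    q_av = softplus(p_lv - p_sa, w) / p[P_R_AV]
    q_sys = (p_sa - p_sv) / p[P_R_SART]
    m = 1.0
    if p[P_OCC_MULT] != 1.0 and t >= p[P_OCC_T0]:
        f = (t - p[P_OCC_T0]) / p[P_OCC_DUR]
        if f > 1.0:
            f = 1.0
        m = 1.0 + (p[P_OCC_MULT] - 1.0) * f
    q_tv = softplus(p_sv - p_rv, w) / (p[P_R_SVEN] * m + p[P_R_TV])
    q_pvalve = softplus(p_rv - p_pa, w) / p[P_R_PVALVE]
    q_pul = (p_pa - p_pv) / p[P_R_PART]
    q_mv = softplus(p_pv - p_lv, w) / (p[P_R_PVEN] + p[P_R_MV])
    q_pump = 0.0
    if p[P_PUMP_ON] > 0.5:
        q_raw = p[P_PUMP_MAX] - p[P_PUMP_SLOPE] * (p_sa - p_lv)
        q_head = softplus(q_raw, 0.02 * p[P_PUMP_MAX] + 1e-9)
        s = 1.0 / (1.0 + np.exp(-(y[0] - p[P_PUMP_VSUC]) / p[P_PUMP_WSUC]))
        q_pump = q_head * s
    return q_av, q_sys, q_tv, q_pvalve, q_pul, q_mv, q_pump


@njit(cache=True)
def _deriv(t, y, p, dy):
    q_av, q_sys, q_tv, q_pvalve, q_pul, q_mv, q_pump = _flows(t, y, p)
    dy[0] = q_mv - q_av - q_pump
    dy[1] = q_tv - q_pvalve
    dy[2] = q_av + q_pump - q_sys
    dy[3] = q_sys - q_tv + p[P_INFUSION]
    dy[4] = q_pvalve - q_pul
    dy[5] = q_pul - q_mv
    # cumulative flows, integrated to RK4 accuracy (the Swan-Ganz surrogate
    # reads these rather than naively averaging the sampled flow pulse)
    dy[6] = q_pvalve
    dy[7] = q_av + q_pump


@njit(cache=True)
def integrate(y0, p, t0, dt, n_steps, rec_every):
    """RK4 from t0 over n_steps of dt, recording every rec_every steps.

    Returns (t_rec, states_rec[n_rec, 8], chan_rec[n_rec, 10], y_final, ok)
    where state columns are the six volumes plus cumulative pulmonary and
    systemic outflow, and chan columns are P_lv, P_rv, P_sa, P_pa, P_sv,
    q_pump, q_av, q_pvalve, q_mv, P_peri.  ok=False signals a negative
    chamber volume.
    """
    n_rec = n_steps // rec_every + 1
    t_rec = np.empty(n_rec)
    states = np.empty((n_rec, NAUG))
    chans = np.empty((n_rec, 10))
    y = np.zeros(NAUG)
    for j in range(min(y0.size, NAUG)):
        y[j] = y0[j]
    k1 = np.empty(NAUG)
    k2 = np.empty(NAUG)
    k3 = np.empty(NAUG)
    k4 = np.empty(NAUG)
    yt = np.empty(NAUG)
    ok = True
    irec = 0
    for i in range(n_steps + 1):
        if i % rec_every == 0:
            t = t0 + i * dt
            t_rec[irec] = t
            for j in range(NAUG):
                states[irec, j] = y[j]
            p_lv, p_rv, p_sa, p_sv, p_pa, p_pv, peri = _pressures(t, y, p)
            q_av, q_sys, q_tv, q_pvalve, q_pul, q_mv, q_pump = _flows(t, y, p)
            chans[irec, 0] = p_lv
            chans[irec, 1] = p_rv
            chans[irec, 2] = p_sa
            chans[irec, 3] = p_pa
            chans[irec, 4] = p_sv
            chans[irec, 5] = q_pump
            chans[irec, 6] = q_av
            chans[irec, 7] = q_pvalve
            chans[irec, 8] = q_mv
            chans[irec, 9] = peri
            irec += 1
        if i == n_steps:
            break
        t = t0 + i * dt
        _deriv(t, y, p, k1)
        for j in range(NAUG):
            yt[j] = y[j] + 0.5 * dt * k1[j]
        _deriv(t + 0.5 * dt, yt, p, k2)
        for j in range(NAUG):
            yt[j] = y[j] + 0.5 * dt * k2[j]
        _deriv(t + 0.5 * dt, yt, p, k3)
        for j in range(NAUG):
            yt[j] = y[j] + dt * k3[j]
        _deriv(t + dt, yt, p, k4)
        for j in range(NAUG):
            y[j] = y[j] + dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        if y[0] <= 0.0 or y[1] <= 0.0:
            ok = False
            break
    if not ok:
        # truncate records to what was filled
        t_rec = t_rec[:irec]
        states = states[:irec]
        chans = chans[:irec]
    return t_rec, states, chans, y, ok
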