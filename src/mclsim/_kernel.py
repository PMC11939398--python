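"""Numerical kernel: node equations and fixed-step integrators.

The circuit right-hand side is written against a flat float64 parameter
vector so that it can be compiled with numba. The public, typed API in
``circuit.py`` wraps this kernel; the algebra lives in exactly one place
(`_eval`) and is reused both for integration and for deriving the per-sample
pressure/flow record of a finished trajectory.
"""

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


N_STATE = 9
# state layout
IV_LV, IV_RV, IV_LA, IV_RA = 0, 1, 2, 3
IW_AOC, IW_SVC, IW_PAC, IW_PVC = 4, 5, 6, 7
IQ_EC = 8

# parameter vector layout
I_PERIOD = 0
I_EMAX_LV, I_EMIN_LV, I_V0_LV = 1, 2, 3
I_EMAX_RV, I_EMIN_RV, I_V0_RV = 4, 5, 6
I_ALPHA_RL, I_ALPHA_LR = 7, 8
I_PERI_ON, I_PERI_K, I_PERI_V0 = 9, 10, 11
I_R_MV, I_R_AV, I_R_TV, I_R_PV = 12, 13, 14, 15
I_R_UP, I_R_LOW, I_R_PULM, I_R_VR, I_R_PVEN = 16, 17, 18, 19, 20
I_C_LA, I_C_RA, I_CLAMP = 21, 22, 23
I_AOC, I_SVC, I_PAC, I_PVC = 24, 27, 30, 33  # (air_ref, p_abs_ref, w_ref) each
I_EC_ON, I_EC_SPEED = 36, 37
I_EC_C0, I_EC_C1, I_EC_C2 = 38, 39, 40
I_EC_RD, I_EC_RR, I_EC_L, I_EC_ANTE = 41, 42, 43, 44
I_N1, I_N2, I_TAU1, I_TAU2, I_ENORM = 45, 46, 47, 48, 49
I_VLA0, I_VRA0 = 50, 51
I_FEM_POS = 52
N_PARAMS = 53

ATM = 760.0

# auxiliary record layout (per-sample derived quantities)
A_P_LV, A_P_RV, A_P_LA, A_P_RA = 0, 1, 2, 3
A_P_AO, A_P_SV, A_P_PA, A_P_PV = 4, 5, 6, 7
A_Q_MV, A_Q_AV, A_Q_TV, A_Q_PV = 8, 9, 10, 11
A_Q_UP, A_Q_LOW_IN, A_Q_LOW_OUT, A_Q_VR = 12, 13, 14, 15
A_Q_PULM, A_Q_PVLA, A_Q_EC = 16, 17, 18
A_E_NORM, A_P_FEM, A_HEAD = 19, 20, 21
N_AUX = 22

AUX_NAMES = (
    "p_lv", "p_rv", "p_la", "p_ra", "p_ao", "p_sv", "p_pa", "p_pv",
    "q_mv", "q_av", "q_tv", "q_pv", "q_up", "q_low_in", "q_low_out", "q_vr",
    "q_pulm", "q_pvla", "q_ecmo", "e_norm", "p_fem", "pump_head",
)


def double_hill_raw(phi, n1, n2, tau1, tau2):
    """Un-normalised double-Hill activation; phi is beat phase in [0, 1)."""
    a = (phi / tau1) ** n1
    return (a / (1.0 + a)) / (1.0 + (phi / tau2) ** n2)


@njit(cache=False)
def _activation(phi, P):
    a = (phi / P[I_TAU1]) ** P[I_N1]
    raw = (a / (1.0 + a)) / (1.0 + (phi / P[I_TAU2]) ** P[I_N2])
    return raw / P[I_ENORM]


@njit(cache=False)
def _chamber_gauge(w, air_ref, p_abs_ref, w_ref):
    air = air_ref - (w - w_ref)
    return p_abs_ref * air_ref / air - ATM


@njit(cache=False)
def _eval(t, y, P, dy, aux):
    """Evaluate node pressures, branch flows and state derivatives in place."""
    period = P[I_PERIOD]
    phi = (t / period) % 1.0
    en = _activation(phi, P)

    e_lv = P[I_EMIN_LV] + (P[I_EMAX_LV] - P[I_EMIN_LV]) * en
    e_rv = P[I_EMIN_RV] + (P[I_EMAX_RV] - P[I_EMIN_RV]) * en
    p_lv_free = e_lv * (y[IV_LV] - P[I_V0_LV])
    p_rv_free = e_rv * (y[IV_RV] - P[I_V0_RV])
    # actively generated (contraction) components; the septum transmits these,
    # while passive diastolic distension couples through the pericardium only
    p_lv_act = (e_lv - P[I_EMIN_LV]) * (y[IV_LV] - P[I_V0_LV])
    p_rv_act = (e_rv - P[I_EMIN_RV]) * (y[IV_RV] - P[I_V0_RV])

    # pericardial constraint: the sealed enclosure houses the two ventricles
    # (the atria sit outside the heart box), so only ventricular volume loads it
    p_peri = 0.0
    if P[I_PERI_ON] > 0.5:
        v_heart = y[IV_LV] + y[IV_RV]
        if v_heart > P[I_PERI_V0]:
            p_peri = P[I_PERI_K] * (v_heart - P[I_PERI_V0])

    p_lv = p_lv_free + P[I_ALPHA_RL] * p_rv_act + p_peri
    p_rv = p_rv_free + P[I_ALPHA_LR] * p_lv_act + p_peri

    p_la = (y[IV_LA] - P[I_VLA0]) / P[I_C_LA]
    p_ra = (y[IV_RA] - P[I_VRA0]) / P[I_C_RA]
    p_ao = _chamber_gauge(y[IW_AOC], P[I_AOC], P[I_AOC + 1], P[I_AOC + 2])
    p_sv = _chamber_gauge(y[IW_SVC], P[I_SVC], P[I_SVC + 1], P[I_SVC + 2])
    p_pa = _chamber_gauge(y[IW_PAC], P[I_PAC], P[I_PAC + 1], P[I_PAC + 2])
    p_pv = _chamber_gauge(y[IW_PVC], P[I_PVC], P[I_PVC + 1], P[I_PVC + 2])

    # ideal-diode valves
    d = p_la - p_lv
    q_mv = d / P[I_R_MV] if d > 0.0 else 0.0
    d = p_lv - p_ao
    q_av = d / P[I_R_AV] if d > 0.0 else 0.0
    d = p_ra - p_rv
    q_tv = d / P[I_R_TV] if d > 0.0 else 0.0
    d = p_rv - p_pa
    q_pv = d / P[I_R_PV] if d > 0.0 else 0.0

    ec_on = P[I_EC_ON] > 0.5
    ante = P[I_EC_ANTE] > 0.5
    q_ec = y[IQ_EC] if ec_on else 0.0

    # systemic branches; retrograde ECMO return enters an algebraic femoral
    # node on the lower-body branch
    q_up = (p_ao - p_sv) / P[I_R_UP]
    # femoral node sits a fraction of the way down the lower-body branch
    # (the return cannula enters the conduit artery, upstream of the
    # arteriolar resistance)
    r1 = P[I_FEM_POS] * P[I_R_LOW]
    r2 = (1.0 - P[I_FEM_POS]) * P[I_R_LOW]
    q_ret_fem = q_ec if (ec_on and not ante) else 0.0
    p_fem = (p_ao / r1 + p_sv / r2 + q_ret_fem) / (1.0 / r1 + 1.0 / r2)
    q_low_in = (p_ao - p_fem) / r1
    q_low_out = (p_fem - p_sv) / r2

    q_vr = (p_sv - p_ra) / (P[I_R_VR] * P[I_CLAMP])
    q_pulm = (p_pa - p_pv) / P[I_R_PULM]
    q_pvla = (p_pv - p_la) / P[I_R_PVEN]

    dy[IV_LV] = q_mv - q_av
    dy[IV_RV] = q_tv - q_pv
    dy[IV_LA] = q_pvla - q_mv
    dy[IV_RA] = q_vr - q_tv - q_ec
    dy[IW_AOC] = q_av - q_up - q_low_in + (q_ec if (ec_on and ante) else 0.0)
    dy[IW_SVC] = q_up + q_low_out - q_vr
    dy[IW_PAC] = q_pv - q_pulm
    dy[IW_PVC] = q_pulm - q_pvla

    head = 0.0
    if ec_on:
        f = q_ec * 0.06  # L/min
        s = P[I_EC_SPEED]
        head = P[I_EC_C0] * s * s + P[I_EC_C1] * s * f + P[I_EC_C2] * f * abs(f)
        p_ret = p_ao if ante else p_fem
        dy[IQ_EC] = (p_ra + head - p_ret
                     - (P[I_EC_RD] + P[I_EC_RR]) * q_ec) / P[I_EC_L]
    else:
        dy[IQ_EC] = 0.0

    aux[A_P_LV] = p_lv
    aux[A_P_RV] = p_rv
    aux[A_P_LA] = p_la
    aux[A_P_RA] = p_ra
    aux[A_P_AO] = p_ao
    aux[A_P_SV] = p_sv
    aux[A_P_PA] = p_pa
    aux[A_P_PV] = p_pv
    aux[A_Q_MV] = q_mv
    aux[A_Q_AV] = q_av
    aux[A_Q_TV] = q_tv
    aux[A_Q_PV] = q_pv
    aux[A_Q_UP] = q_up
    aux[A_Q_LOW_IN] = q_low_in
    aux[A_Q_LOW_OUT] = q_low_out
    aux[A_Q_VR] = q_vr
    aux[A_Q_PULM] = q_pulm
    aux[A_Q_PVLA] = q_pvla
    aux[A_Q_EC] = q_ec
    aux[A_E_NORM] = en
    aux[A_P_FEM] = p_fem
    aux[A_HEAD] = head


@njit(cache=False)
def rhs(t, y, P):
    dy = np.empty(N_STATE)
    aux = np.empty(N_AUX)
    _eval(t, y, P, dy, aux)
    return dy


@njit(cache=False)
def integrate_rk4(y0, t0, dt, n_steps, P):
    """Classical fixed-step RK4; returns the (n_steps+1, 9) state trajectory."""
    out = np.empty((n_steps + 1, N_STATE))
    y = y0.copy()
    out[0] = y
    k1 = np.empty(N_STATE)
    k2 = np.empty(N_STATE)
    k3 = np.empty(N_STATE)
    k4 = np.empty(N_STATE)
    yt = np.empty(N_STATE)
    aux = np.empty(N_AUX)
    h2 = 0.5 * dt
    for i in range(n_steps):
        t = t0 + i * dt
        _eval(t, y, P, k1, aux)
        for j in range(N_STATE):
            yt[j] = y[j] + h2 * k1[j]
        _eval(t + h2, yt, P, k2, aux)
        for j in range(N_STATE):
            yt[j] = y[j] + h2 * k2[j]
        _eval(t + h2, yt, P, k3, aux)
        for j in range(N_STATE):
            yt[j] = y[j] + dt * k3[j]
        _eval(t + dt, yt, P, k4, aux)
        for j in range(N_STATE):
            y[j] = y[j] + dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        out[i + 1] = y
    return out


@njit(cache=False)
def integrate_euler(y0, t0, dt, n_steps, P, store_every):
    """Forward Euler with sub-sampled storage (refinement oracle for RK4)."""
    n_keep = n_steps // store_every + 1
    out = np.empty((n_keep, N_STATE))
    y = y0.copy()
    out[0] = y
    dy = np.empty(N_STATE)
    aux = np.empty(N_AUX)
    k = 1
    for i in range(n_steps):
        t = t0 + i * dt
        _eval(t, y, P, dy, aux)
        for j in range(N_STATE):
            y[j] = y[j] + dt * dy[j]
        if (i + 1) % store_every == 0:
            out[k] = y
            k += 1
    return out


@njit(cache=False)
def derive_trajectory(t_arr, traj, P):
    """Per-sample pressures/flows for a stored state trajectory."""
    n = t_arr.shape[0]
    aux = np.empty((n, N_AUX))
    dy = np.empty(N_STATE)
    for i in range(n):
        _eval(t_arr[i], traj[i], P, dy, aux[i])
    return aux
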