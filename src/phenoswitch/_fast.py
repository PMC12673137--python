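"""Numba kernels: fixed-step RK4 integration of one inter-impulse segment.

These kernels drive the fast simulation path used heavily by the
calibration routines.  The drug concentration is not part of the ODE
state: between impulses it is the closed-form piecewise-linear decay
``D(t) = max(0, D0 - k_d (t - t0))``, which the caller splits at the
zero-crossing so each segment sees a smooth right-hand side.

PSM1D parameter vector layout (length 13)::

    0 beta  1 n  2 N_max  3 prolif_code  4 hill_rational
    5 alpha_ST0  6 alpha_TS0
    7 mu_ST  8 lam_ST  9 mu_TS  10 lam_TS  11 mu_beta  12 lam_beta

PSM2D parameter vector layout (length 25)::

    0 beta  1 n  2 N_max  3 prolif_code  4 hill_rational
    5 alpha_SAT0  6 alpha_TSA0   7..12 (mu,lam) x (ST, TS, beta) drug A
    13 D50_A
    14 alpha_SNT0 15 alpha_TSN0  16..21 (mu,lam) x (ST, TS, beta) drug N
    22 D50_N
    23 mu_TSN  24 lam_TSN
"""

import numpy as np
from numba import njit

GOMPERTZ_FLOOR = 1e-3


@njit(cache=False)
def prolif_rate(code, rational, beta, n, N_max, N):
    """Per-capita proliferation rate; shared by all kernels."""
    if code == 0:  # exponential
        return beta
    if code == 1:  # logistic
        return beta * (1.0 - N / N_max)
    if code == 2:  # gompertz, capped near N = 0
        Nc = N if N > GOMPERTZ_FLOOR else GOMPERTZ_FLOOR
        return beta * np.log(N_max / Nc)
    # hill
    base = N / N_max
    if base < 0.0:
        base = 0.0
    r = base ** n
    if rational == 1:
        return beta / (1.0 + r)
    return beta * (1.0 - r)


@njit(cache=False)
def _rhs1d(y, D, D50, p, act_st, inh_ts, inh_b, out):
    S, T = y[0], y[1]
    m_st, m_ts, m_b = y[2], y[3], y[4]
    sat = D / (D + D50) if D > 0.0 else 0.0

    a_st = p[5] * (1.0 + m_st) if act_st else p[5]
    a_ts = p[6] / (1.0 + m_ts) if inh_ts else p[6]
    beta = p[0] / (1.0 + m_b) if inh_b else p[0]

    N = S + T
    if N > 0.0:
        P = prolif_rate(int(p[3]), int(p[4]), beta, p[1], p[2], N)
        out[0] = P * S - a_st * S + a_ts * T
        out[1] = P * T + a_st * S - a_ts * T
    else:  # empty dish is absorbing
        out[0] = 0.0
        out[1] = 0.0
    out[2] = p[7] * sat - p[8] * m_st
    out[3] = p[9] * sat - p[10] * m_ts
    out[4] = p[11] * sat - p[12] * m_b


@njit(cache=False)
def integrate_segment_1d(y0, t0, t1, dt, D0, kd, D50, p, act_st, inh_ts, inh_b):
    """RK4 from t0 to t1; returns (times, states) including both endpoints."""
    span = t1 - t0
    nsteps = int(np.ceil(span / dt)) if span > dt else 1
    h = span / nsteps
    ts = np.empty(nsteps + 1)
    ys = np.empty((nsteps + 1, 5))
    k1 = np.empty(5); k2 = np.empty(5); k3 = np.empty(5); k4 = np.empty(5)
    ytmp = np.empty(5)
    y = y0.copy()
    ts[0] = t0
    ys[0] = y
    for i in range(nsteps):
        t = t0 + i * h
        D_a = D0 - kd * (t - t0)
        if D_a < 0.0:
            D_a = 0.0
        D_m = D0 - kd * (t + 0.5 * h - t0)
        if D_m < 0.0:
            D_m = 0.0
        D_b = D0 - kd * (t + h - t0)
        if D_b < 0.0:
            D_b = 0.0
        _rhs1d(y, D_a, D50, p, act_st, inh_ts, inh_b, k1)
        for j in range(5):
            ytmp[j] = y[j] + 0.5 * h * k1[j]
        _rhs1d(ytmp, D_m, D50, p, act_st, inh_ts, inh_b, k2)
        for j in range(5):
            ytmp[j] = y[j] + 0.5 * h * k2[j]
        _rhs1d(ytmp, D_m, D50, p, act_st, inh_ts, inh_b, k3)
        for j in range(5):
            ytmp[j] = y[j] + h * k3[j]
        _rhs1d(ytmp, D_b, D50, p, act_st, inh_ts, inh_b, k4)
        for j in range(5):
            y[j] = y[j] + (h / 6.0) * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        ts[i + 1] = t + h
        ys[i + 1] = y
    ts[nsteps] = t1
    return ts, ys


@njit(cache=False)
def _rhs2d(y, DA, DN, p, tA0, tA1, tA2, tN0, tN1, tN2, out):
    SA, SN, T = y[0], y[1], y[2]
    satA = DA / (DA + p[13]) if DA > 0.0 else 0.0
    satN = DN / (DN + p[22]) if DN > 0.0 else 0.0

    a_sat = p[5] * (1.0 + y[3]) if tA0 else p[5]
    a_tsa = p[6] / (1.0 + y[4]) if tA1 else p[6]
    a_snt = p[14] * (1.0 + y[6]) if tN0 else p[14]
    a_tsn = p[15] * (1.0 + y[9])          # coupling activation by drug A
    if tN1:
        a_tsn = a_tsn / (1.0 + y[7])
    beta = p[0]
    if tA2:
        beta = beta / (1.0 + y[5])
    if tN2:
        beta = beta / (1.0 + y[8])

    N = SA + SN + T
    if N > 0.0:
        P = prolif_rate(int(p[3]), int(p[4]), beta, p[1], p[2], N)
        out[0] = P * SA - a_sat * SA + a_tsa * T
        out[1] = P * SN - a_snt * SN + a_tsn * T
        out[2] = P * T + a_sat * SA + a_snt * SN - (a_tsa + a_tsn) * T
    else:
        out[0] = 0.0
        out[1] = 0.0
        out[2] = 0.0
    out[3] = p[7] * satA - p[8] * y[3]
    out[4] = p[9] * satA - p[10] * y[4]
    out[5] = p[11] * satA - p[12] * y[5]
    out[6] = p[16] * satN - p[17] * y[6]
    out[7] = p[18] * satN - p[19] * y[7]
    out[8] = p[20] * satN - p[21] * y[8]
    out[9] = p[23] * satA - p[24] * y[9]


@njit(cache=False)
def integrate_segment_2d(y0, t0, t1, dt, DA0, kdA, DN0, kdN, p,
                         tA0, tA1, tA2, tN0, tN1, tN2):
    span = t1 - t0
    nsteps = int(np.ceil(span / dt)) if span > dt else 1
    h = span / nsteps
    ts = np.empty(nsteps + 1)
    ys = np.empty((nsteps + 1, 10))
    k1 = np.empty(10); k2 = np.empty(10); k3 = np.empty(10); k4 = np.empty(10)
    ytmp = np.empty(10)
    y = y0.copy()
    ts[0] = t0
    ys[0] = y
    for i in range(nsteps):
        t = t0 + i * h
        DA_a = max(0.0, DA0 - kdA * (t - t0))
        DN_a = max(0.0, DN0 - kdN * (t - t0))
        DA_m = max(0.0, DA0 - kdA * (t + 0.5 * h - t0))
        DN_m = max(0.0, DN0 - kdN * (t + 0.5 * h - t0))
        DA_b = max(0.0, DA0 - kdA * (t + h - t0))
        DN_b = max(0.0, DN0 - kdN * (t + h - t0))
        _rhs2d(y, DA_a, DN_a, p, tA0, tA1, tA2, tN0, tN1, tN2, k1)
        for j in range(10):
            ytmp[j] = y[j] + 0.5 * h * k1[j]
        _rhs2d(ytmp, DA_m, DN_m, p, tA0, tA1, tA2, tN0, tN1, tN2, k2)
        for j in range(10):
            ytmp[j] = y[j] + 0.5 * h * k2[j]
        _rhs2d(ytmp, DA_m, DN_m, p, tA0, tA1, tA2, tN0, tN1, tN2, k3)
        for j in range(10):
            ytmp[j] = y[j] + h * k3[j]
        _rhs2d(ytmp, DA_b, DN_b, p, tA0, tA1, tA2, tN0, tN1, tN2, k4)
        for j in range(10):
            y[j] = y[j] + (h / 6.0) * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        ts[i + 1] = t + h
        ys[i + 1] = y
    ts[nsteps] = t1
    return ts, ys
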