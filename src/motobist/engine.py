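"""Compiled Dormand-Prince 5(4) integrator for the motoneuron ODE system.

The hysteresis sweeps integrate tens of simulated seconds per parameter point,
so the inner loop is JIT-compiled with numba.  The readable reference
right-hand side lives in :mod:`motobist.model`; the two are held consistent by
a dedicated equivalence test.

Step control is the standard embedded 5(4) pair with error-proportional step
adaptation; dense output on the fixed sampling grid uses cubic Hermite
interpolation between accepted steps (the step size is capped so the
interpolation error stays far below the solver tolerance).  After each
accepted step gates are clamped to [0, 1] and calcium floored at zero, since
the calcium balance can transiently undershoot numerically.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Dormand-Prince 5(4) tableau
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_A = np.zeros((7, 7))
_A[1, 0] = 1 / 5
_A[2, :2] = (3 / 40, 9 / 40)
_A[3, :3] = (44 / 45, -56 / 15, 32 / 9)
_A[4, :4] = (19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729)
_A[5, :5] = (9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656)
_A[6, :6] = (35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84)
_B = _A[6].copy()  # 5th-order solution weights (FSAL)
_E = np.array([71 / 57600, 0.0, -71 / 16695, 71 / 1920,
               -17253 / 339200, 22 / 525, -1 / 40])  # b5 - b4

# parameter vector layout mirrors motobist.model.pack_params
from .model import (  # noqa: E402
    N_PACKED, P_ALPHA, P_C, P_ECA, P_ECAN, P_EK, P_EL, P_ENA, P_F, P_GCAL,
    P_GCAN, P_GKCA, P_GKDR, P_GKV12, P_GL, P_GNAF, P_GNAP, P_KCAN, P_KCICR,
    P_KD, P_TAUCA, P_TAUCALH, P_TAUCALM,
)


@njit(cache=True, error_model="numpy")
def _program_value(t, seg_ends, seg_v0, seg_v1):
    n = seg_ends.shape[0]
    t0 = 0.0
    for i in range(n):
        t1 = seg_ends[i]
        if t <= t1 or i == n - 1:
            if t > t1:
                return seg_v1[i]
            dur = t1 - t0
            if dur <= 0.0:
                return seg_v1[i]
            frac = (t - t0) / dur
            return seg_v0[i] + frac * (seg_v1[i] - seg_v0[i])
        t0 = t1
    return seg_v1[n - 1]


@njit(cache=True, error_model="numpy")
def _rhs(t, y, p, seg_ends, seg_v0, seg_v1, dy):
    V = y[0]
    h_naf = y[1]
    m_kdr = y[2]
    m_kv = y[3]
    h_kv = y[4]
    m_cal = y[5]
    h_cal = y[6]
    Ca = y[7]

    E_K = p[P_EK]

    m_naf = 1.0 / (1.0 + np.exp(-(V + 35.0) / 7.8))
    m_nap = 1.0 / (1.0 + np.exp(-(V + 53.0) / 3.0))

    I_NaF = p[P_GNAF] * m_naf * m_naf * m_naf * h_naf * (V - p[P_ENA])
    I_NaP = p[P_GNAP] * m_nap * (V - p[P_ENA])
    mk2 = m_kdr * m_kdr
    I_Kdr = p[P_GKDR] * mk2 * mk2 * (V - E_K)
    I_Kv12 = p[P_GKV12] * m_kv * h_kv * (V - E_K)
    I_CaL = p[P_GCAL] * m_cal * h_cal * (V - p[P_ECA])
    I_CAN = p[P_GCAN] * Ca / (Ca + p[P_KCAN]) * (V - p[P_ECAN])
    I_KCa = p[P_GKCA] * Ca / (Ca + p[P_KD]) * (V - E_K)
    I_L = p[P_GL] * (V - p[P_EL])

    I_inj = _program_value(t, seg_ends, seg_v0, seg_v1)

    dy[0] = (-(I_NaF + I_NaP + I_Kdr + I_Kv12 + I_CaL + I_CAN + I_KCa + I_L)
             + I_inj) / p[P_C]

    h_naf_inf = 1.0 / (1.0 + np.exp((V + 55.0) / 7.0))
    tau_naf = 30.0 / (np.exp((V + 50.0) / 15.0) + np.exp(-(V + 50.0) / 16.0))
    dy[1] = (h_naf_inf - h_naf) / tau_naf

    m_kdr_inf = 1.0 / (1.0 + np.exp(-(V + 28.0) / 15.0))
    tau_kdr = 7.0 / (np.exp((V + 40.0) / 40.0) + np.exp(-(V + 40.0) / 50.0))
    dy[2] = (m_kdr_inf - m_kdr) / tau_kdr

    m_kv_inf = 1.0 / (1.0 + np.exp(-(V + 46.0) / 6.9))
    tau_kv_m = 2.44 + 18.387 / (np.exp(-(V - 25.645) / 21.633)
                                + np.exp((V + 4.42) / 45.9))
    dy[3] = (m_kv_inf - m_kv) / tau_kv_m

    h_kv_inf = 1.0 / (1.0 + np.exp((V + 54.0) / 7.1))
    tau_kv_h = 74.74 / (0.00015 * np.exp(-(V + 13.0) / 15.0)
                        + 0.06 / (1.0 + np.exp(-(V + 68.0) / 12.0)))
    dy[4] = (h_kv_inf - h_kv) / tau_kv_h

    m_cal_inf = 1.0 / (1.0 + np.exp(-(V + 27.5) / 5.7))
    dy[5] = (m_cal_inf - m_cal) / p[P_TAUCALM]

    h_cal_inf = 1.0 / (1.0 + np.exp((V + 52.4) / 5.2))
    dy[6] = (h_cal_inf - h_cal) / p[P_TAUCALH]

    dy[7] = -p[P_F] * p[P_ALPHA] * I_CaL + p[P_KCICR] * Ca - Ca / p[P_TAUCA]


@njit(cache=True, error_model="numpy")
def integrate_dp54(
    y0,
    t_end,
    p,
    seg_ends,
    seg_v0,
    seg_v1,
    rtol,
    atol,
    sample_dt,
    max_step,
):
    """Integrate from t=0 to t_end, sampling every ``sample_dt`` ms.

    Returns (t_samples, y_samples[n, 8], n_accepted, n_rejected, status)
    where status 0 = ok, 1 = step-size underflow, 2 = non-finite state.
    """
    n_var = 8
    n_samp = int(np.floor(t_end / sample_dt + 1e-9)) + 1
    ts = np.empty(n_samp)
    ys = np.empty((n_samp, n_var))
    for i in range(n_samp):
        ts[i] = i * sample_dt
    ts[n_samp - 1] = min(ts[n_samp - 1], t_end)

    y = y0.copy()
    t = 0.0
    ys[0] = y
    isamp = 1

    k = np.empty((7, n_var))
    ytmp = np.empty(n_var)
    ynew = np.empty(n_var)
    err = np.empty(n_var)

    _rhs(t, y, p, seg_ends, seg_v0, seg_v1, k[0])

    # segment boundaries to land on exactly (waveform kinks/jumps)
    n_bound = seg_ends.shape[0]

    h = 1e-3
    n_acc = 0
    n_rej = 0
    status = 0
    h_min = 1e-12

    while t < t_end:
        if h > max_step:
            h = max_step
        if t + h > t_end:
            h = t_end - t
        # do not step across a program segment boundary
        for ib in range(n_bound):
            b = seg_ends[ib]
            if b > t + 1e-12 and t + h > b:
                h = b - t
                break

        # stages (k[0] is FSAL from the previous accepted step)
        for s in range(1, 7):
            for j in range(n_var):
                acc = 0.0
                for q in range(s):
                    acc += _A[s, q] * k[q, j]
                ytmp[j] = y[j] + h * acc
            _rhs(t + _C[s] * h, ytmp, p, seg_ends, seg_v0, seg_v1, k[s])

        for j in range(n_var):
            acc = 0.0
            eacc = 0.0
            for s in range(7):
                acc += _B[s] * k[s, j]
                eacc += _E[s] * k[s, j]
            ynew[j] = y[j] + h * acc
            err[j] = h * eacc

        # weighted RMS error norm
        enorm = 0.0
        bad = False
        for j in range(n_var):
            if not np.isfinite(ynew[j]):
                bad = True
                break
            sc = atol + rtol * max(abs(y[j]), abs(ynew[j]))
            e = err[j] / sc
            enorm += e * e
        if not bad:
            enorm = np.sqrt(enorm / n_var)

        if bad:
            h *= 0.25
            n_rej += 1
            if h < h_min:
                status = 2
                break
            continue

        if enorm <= 1.0:
            # accepted: fill samples in (t, t+h] by cubic Hermite interpolation
            t_new = t + h
            # k[6] = f(t+h, y5) is the FSAL derivative at the right endpoint
            while isamp < n_samp and ts[isamp] <= t_new + 1e-12:
                theta = (ts[isamp] - t) / h
                th2 = theta * theta
                th3 = th2 * theta
                h00 = 2 * th3 - 3 * th2 + 1
                h10 = th3 - 2 * th2 + theta
                h01 = -2 * th3 + 3 * th2
                h11 = th3 - th2
                for j in range(n_var):
                    ys[isamp, j] = (h00 * y[j] + h10 * h * k[0, j]
                                    + h01 * ynew[j] + h11 * h * k[6, j])
                isamp += 1
            t = t_new
            for j in range(n_var):
                y[j] = ynew[j]
            # physical clamps: gates in [0,1], Ca >= 0
            for j in range(1, 7):
                if y[j] < 0.0:
                    y[j] = 0.0
                elif y[j] > 1.0:
                    y[j] = 1.0
            if y[7] < 0.0:
                y[7] = 0.0
            for j in range(n_var):
                k[0, j] = k[6, j]
            n_acc += 1
            if enorm == 0.0:
                fac = 5.0
            else:
                fac = 0.9 * enorm ** -0.2
                if fac > 5.0:
                    fac = 5.0
                elif fac < 0.2:
                    fac = 0.2
            h *= fac
        else:
            n_rej += 1
            fac = 0.9 * enorm ** -0.2
            if fac < 0.1:
                fac = 0.1
            h *= fac
            if h < h_min:
                status = 1
                break

    # clamp stored samples the same way the state is clamped
    for i in range(n_samp):
        for j in range(1, 7):
            if ys[i, j] < 0.0:
                ys[i, j] = 0.0
            elif ys[i, j] > 1.0:
                ys[i, j] = 1.0
        if ys[i, 7] < 0.0:
            ys[i, 7] = 0.0

    return ts, ys, y, n_acc, n_rej, status
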