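"""Compiled fixed-substep integrator for the sleep-wake/pacemaker system.

The flip-flop voltages relax on a 10-s time scale while every other state
variable evolves over hours, so the system is stiff for explicit solvers.
The integrator exploits the conditional linearity of the stiff equations:
V_v, V_m and H obey scalar linear ODEs once their nonlinear inputs are
frozen, and are advanced with an exponential predictor-corrector (the linear
decay treated exactly, the inputs to second order); the photoreceptor pool n
is updated exactly at frozen light; the pacemaker pair (x, x_c) takes an
explicit midpoint (RK2) step.  Light is piecewise constant per epoch and
gated to zero whenever the model is asleep (eyes closed).  Wake/sleep
transitions (sign changes of V_m - V_v) are located by linear interpolation
inside the substep and the substep is re-integrated in two pieces around the
crossing, so the light gating switches at the transition itself rather than
at the next substep boundary.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


# parameter-vector layout (see model.ModelParams.to_array)
I_TAU_C, I_DELTA_D, I_QMAX, I_THETA, I_SIGMA = 0, 1, 2, 3, 4
I_TAU_V, I_TAU_M, I_NU_VM, I_NU_MV, I_NU_VH = 5, 6, 7, 8, 9
I_NU_VC, I_A_V, I_A_M, I_CHI, I_MU = 10, 11, 12, 13, 14
I_ALPHA0, I_BETA, I_I0, I_P, I_G = 15, 16, 17, 18, 19
I_K, I_B, I_Q, I_MU_P, I_F = 20, 21, 22, 23, 24
I_CX, I_CXC = 25, 26
N_PARAMS = 27


@njit(cache=True)
def _rhs(y, I, pp):
    """Full right-hand side (h^-1 units); reference form cross-checked by
    tests against the pure-Python derivatives."""
    V_v, V_m, H, x, xc, n = y
    Qmax, theta, sigma = pp[I_QMAX], pp[I_THETA], pp[I_SIGMA]
    Q_v = Qmax / (1.0 + math.exp((theta - V_v) / sigma))
    Q_m = Qmax / (1.0 + math.exp((theta - V_m) / sigma))
    C = 0.5 * (1.0 + pp[I_CX] * x + pp[I_CXC] * xc)
    D_v = pp[I_NU_VH] * H + pp[I_NU_VC] * C + pp[I_A_V] - pp[I_DELTA_D]
    tau_v_h = pp[I_TAU_V] / 3600.0
    tau_m_h = pp[I_TAU_M] / 3600.0
    dV_v = (-V_v + pp[I_NU_VM] * Q_m + D_v) / tau_v_h
    dV_m = (-V_m + pp[I_NU_MV] * Q_v + pp[I_A_M]) / tau_m_h
    dH = (-H + pp[I_MU] * Q_m) / pp[I_CHI]
    alpha = pp[I_ALPHA0] * (I / pp[I_I0]) ** pp[I_P] if I > 0.0 else 0.0
    dn = 60.0 * (alpha * (1.0 - n) - pp[I_BETA] * n)
    Bhat = pp[I_G] * alpha * (1.0 - n)
    B = Bhat * (1.0 - pp[I_B] * x) * (1.0 - pp[I_B] * xc)
    omega2 = (24.0 / (pp[I_F] * pp[I_TAU_C])) ** 2
    pi12 = math.pi / 12.0
    mu_p = pp[I_MU_P]
    dx = pi12 * (xc + mu_p * (x / 3.0 + 4.0 * x**3 / 3.0 - 256.0 * x**7 / 105.0) + B)
    dxc = pi12 * (pp[I_Q] * B * xc - x * (omega2 + pp[I_K] * B))
    out = np.empty(6)
    out[0], out[1], out[2], out[3], out[4], out[5] = dV_v, dV_m, dH, dx, dxc, dn
    return out


@njit(cache=True, inline="always")
def _advance(V_v, V_m, H, x, xc, n, alpha, dt, pp, omega2):
    """One step of size dt at a fixed retinal drive alpha."""
    pi12 = math.pi / 12.0
    mu_p, q, k, b = pp[I_MU_P], pp[I_Q], pp[I_K], pp[I_B]
    beta = pp[I_BETA]
    # pacemaker: midpoint step with the photoreceptor fraction frozen
    Bhat = pp[I_G] * alpha * (1.0 - n)
    B1 = Bhat * (1.0 - b * x) * (1.0 - b * xc)
    k1x = pi12 * (xc + mu_p * (x / 3.0 + 4.0 * x**3 / 3.0 - 256.0 * x**7 / 105.0) + B1)
    k1c = pi12 * (q * B1 * xc - x * (omega2 + k * B1))
    xm = x + 0.5 * dt * k1x
    xcm = xc + 0.5 * dt * k1c
    B2 = Bhat * (1.0 - b * xm) * (1.0 - b * xcm)
    k2x = pi12 * (
        xcm + mu_p * (xm / 3.0 + 4.0 * xm**3 / 3.0 - 256.0 * xm**7 / 105.0) + B2
    )
    k2c = pi12 * (q * B2 * xcm - xm * (omega2 + k * B2))
    x = x + dt * k2x
    xc = xc + dt * k2c
    # photoreceptor pool: exact at frozen alpha
    rate = 60.0 * (alpha + beta)
    ninf = alpha / (alpha + beta)
    n = ninf + (n - ninf) * math.exp(-rate * dt)
    Cdrv = 0.5 * (1.0 + pp[I_CX] * x + pp[I_CXC] * xc)
    # flip-flop + homeostat: exponential predictor-corrector
    Qmax, theta, sigma = pp[I_QMAX], pp[I_THETA], pp[I_SIGMA]
    dec_v = math.exp(-dt * 3600.0 / pp[I_TAU_V])
    dec_m = math.exp(-dt * 3600.0 / pp[I_TAU_M])
    dec_H = math.exp(-dt / pp[I_CHI])
    Dv_const = pp[I_A_V] - pp[I_DELTA_D]
    Q_v0 = Qmax / (1.0 + math.exp((theta - V_v) / sigma))
    Q_m0 = Qmax / (1.0 + math.exp((theta - V_m) / sigma))
    H_p = pp[I_MU] * Q_m0 + (H - pp[I_MU] * Q_m0) * dec_H
    Vv_inf0 = pp[I_NU_VM] * Q_m0 + pp[I_NU_VH] * H_p + pp[I_NU_VC] * Cdrv + Dv_const
    Vm_inf0 = pp[I_NU_MV] * Q_v0 + pp[I_A_M]
    Vv_p = Vv_inf0 + (V_v - Vv_inf0) * dec_v
    Vm_p = Vm_inf0 + (V_m - Vm_inf0) * dec_m
    Q_v1 = Qmax / (1.0 + math.exp((theta - Vv_p) / sigma))
    Q_m1 = Qmax / (1.0 + math.exp((theta - Vm_p) / sigma))
    Qm_avg = 0.5 * (Q_m0 + Q_m1)
    Qv_avg = 0.5 * (Q_v0 + Q_v1)
    Hinf = pp[I_MU] * Qm_avg
    H = Hinf + (H - Hinf) * dec_H
    Vv_inf = pp[I_NU_VM] * Qm_avg + pp[I_NU_VH] * H + pp[I_NU_VC] * Cdrv + Dv_const
    Vm_inf = pp[I_NU_MV] * Qv_avg + pp[I_A_M]
    V_v = Vv_inf + (V_v - Vv_inf) * dec_v
    V_m = Vm_inf + (V_m - Vm_inf) * dec_m
    return V_v, V_m, H, x, xc, n


@njit(cache=True)
def _integrate(y0, lux, epoch_h, n_sub, pp):
    """Integrate over ``len(lux)`` epochs of available light.

    Returns
    -------
    traj : (n_epochs + 1, 6) states at epoch left edges (plus final state)
    wake : (n_epochs + 1,) wake flag at the same instants
    trans_t, trans_dir : transition times (h since start) and directions
        (+1 wake onset, -1 sleep onset)
    ok : False if the state went non-finite.
    """
    n_e = lux.shape[0]
    traj = np.empty((n_e + 1, 6))
    wake_arr = np.empty(n_e + 1, np.bool_)
    cap = 4 * n_e + 8
    trans_t = np.empty(cap)
    trans_dir = np.empty(cap, np.int8)
    n_tr = 0
    ok = True

    dt = epoch_h / n_sub
    omega2 = (24.0 / (pp[I_F] * pp[I_TAU_C])) ** 2
    V_v, V_m, H, x, xc, n = y0[0], y0[1], y0[2], y0[3], y0[4], y0[5]
    wake = V_m > V_v

    for e in range(n_e):
        traj[e, 0], traj[e, 1], traj[e, 2] = V_v, V_m, H
        traj[e, 3], traj[e, 4], traj[e, 5] = x, xc, n
        wake_arr[e] = wake
        I_avail = lux[e]
        if I_avail > 0.0:
            alpha_on = pp[I_ALPHA0] * (I_avail / pp[I_I0]) ** pp[I_P]
        else:
            alpha_on = 0.0

        for s in range(n_sub):
            g_old = V_m - V_v
            alpha = alpha_on if wake else 0.0
            nV_v, nV_m, nH, nx, nxc, nn = _advance(
                V_v, V_m, H, x, xc, n, alpha, dt, pp, omega2
            )
            g_new = nV_m - nV_v
            if (g_new > 0.0) != wake:
                # locate the crossing, then re-integrate the substep in two
                # pieces so the light gate switches at the transition itself
                frac = g_old / (g_old - g_new) if g_old != g_new else 0.5
                if frac < 1e-6:
                    frac = 1e-6
                elif frac > 1.0 - 1e-6:
                    frac = 1.0 - 1e-6
                t_tr = (e * n_sub + s + frac) * dt
                mV_v, mV_m, mH, mx, mxc, mn = _advance(
                    V_v, V_m, H, x, xc, n, alpha, frac * dt, pp, omega2
                )
                new_wake = not wake
                alpha2 = alpha_on if new_wake else 0.0
                nV_v, nV_m, nH, nx, nxc, nn = _advance(
                    mV_v, mV_m, mH, mx, mxc, mn, alpha2, (1.0 - frac) * dt, pp, omega2
                )
                if n_tr < cap:
                    trans_t[n_tr] = t_tr
                    trans_dir[n_tr] = 1 if new_wake else -1
                    n_tr += 1
                wake = new_wake
            V_v, V_m, H, x, xc, n = nV_v, nV_m, nH, nx, nxc, nn
        if not (
            math.isfinite(V_v)
            and math.isfinite(V_m)
            and math.isfinite(H)
            and math.isfinite(x)
            and math.isfinite(xc)
            and math.isfinite(n)
        ):
            ok = False
            break

    traj[n_e, 0], traj[n_e, 1], traj[n_e, 2] = V_v, V_m, H
    traj[n_e, 3], traj[n_e, 4], traj[n_e, 5] = x, xc, n
    wake_arr[n_e] = wake
    return traj, wake_arr, trans_t[:n_tr], trans_dir[:n_tr], ok
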