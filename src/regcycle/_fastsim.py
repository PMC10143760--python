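"""Compiled stiff integrator for high-volume simulation work.

An L-stable Rosenbrock 2(3) pair (ode23s form) with the analytic Jacobian,
jitted end to end with numba so there is no per-step Python overhead, plus
an explicit Dormand-Prince 4(5) fallback.  Used by the Saltelli sampling
loop and the bifurcation-sweep envelopes, where tens of thousands of stiff
relaxation-oscillation simulations must stay affordable; the reference
integration path (`dynamics.simulate`) remains LSODA at tight tolerance.
"""

from __future__ import annotations

import numba as nb
import numpy as np

from .model import ConnectionMask, ParameterSet, SystemInputs

__all__ = ["fast_timecourse"]


# ---------------------------------------------------------------------------
# compiled integrator for the many thousands of draw-by-draw simulations
# the Saltelli scheme needs: an adaptive Dormand-Prince (RK45) pair with PI
# step control, jitted end to end so there is no per-step Python overhead
# ---------------------------------------------------------------------------

@nb.njit(cache=True)
def _rhs_flat(x, pa, mk, stress, mtor_total, ulk1_total, ampk_total):
    u, a, m, r = x[0], x[1], x[2], x[3]
    act_u = (pa[0] + mk[1] * pa[1] * a + mk[3] * pa[2] * r
             + mk[10] * pa[3] * stress)
    inact_u = pa[5] + mk[7] * pa[6] * m
    act_a = pa[8] + mk[0] * pa[9] * stress
    inact_a = pa[11] + mk[5] * pa[12] * u + mk[9] * pa[13] * m
    act_m = pa[15]
    inact_m = (pa[17] + mk[8] * pa[18] * a + mk[6] * pa[19] * u
               + mk[4] * pa[20] * r)
    out = np.empty(4)
    out[0] = (act_u * (ulk1_total - u) / (pa[4] + ulk1_total - u)
              - inact_u * u / (pa[7] + u))
    out[1] = (act_a * (ampk_total - a) / (pa[10] + ampk_total - a)
              - inact_a * a / (pa[14] + a))
    out[2] = (act_m * (mtor_total - m) / (pa[16] + mtor_total - m)
              - inact_m * m / (pa[21] + m))
    out[3] = pa[22] + mk[2] * pa[23] * a - pa[24] * r
    return out


@nb.njit(cache=True)
def _integrate_dopri(pa, mk, stress, mtor_total, ulk1_total, ampk_total,
                     x0, t_grid, rtol, atol, max_steps):
    """Adaptive RK45 (Dormand-Prince) onto a fixed output grid."""
    n_out = t_grid.shape[0]
    out = np.empty((n_out, 4))
    out[0] = x0
    x = x0.copy()
    t = t_grid[0]
    dt = 1e-3
    k = np.empty((7, 4))
    # Dormand-Prince tableau
    c2, c3, c4, c5 = 0.2, 0.3, 0.8, 8.0 / 9.0
    a21 = 0.2
    a31, a32 = 3.0 / 40.0, 9.0 / 40.0
    a41, a42, a43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
    a51, a52, a53, a54 = (19372.0 / 6561.0, -25360.0 / 2187.0,
                          64448.0 / 6561.0, -212.0 / 729.0)
    a61, a62, a63, a64, a65 = (9017.0 / 3168.0, -355.0 / 33.0,
                               46732.0 / 5247.0, 49.0 / 176.0,
                               -5103.0 / 18656.0)
    b1, b3, b4, b5, b6 = (35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0,
                          -2187.0 / 6784.0, 11.0 / 84.0)
    e1, e3, e4, e5, e6, e7 = (71.0 / 57600.0, -71.0 / 16695.0,
                              71.0 / 1920.0, -17253.0 / 339200.0,
                              22.0 / 525.0, -1.0 / 40.0)
    i_out = 1
    n_steps = 0
    while i_out < n_out:
        t_target = t_grid[i_out]
        while t < t_target:
            if n_steps >= max_steps:
                return out[:i_out], -1
            if t + dt > t_target:
                dt_use = t_target - t
            else:
                dt_use = dt
            k[0] = _rhs_flat(x, pa, mk, stress, mtor_total,
                             ulk1_total, ampk_total)
            k[1] = _rhs_flat(x + dt_use * a21 * k[0], pa, mk, stress,
                             mtor_total, ulk1_total, ampk_total)
            k[2] = _rhs_flat(x + dt_use * (a31 * k[0] + a32 * k[1]), pa, mk,
                             stress, mtor_total, ulk1_total, ampk_total)
            k[3] = _rhs_flat(x + dt_use * (a41 * k[0] + a42 * k[1]
                                           + a43 * k[2]), pa, mk, stress,
                             mtor_total, ulk1_total, ampk_total)
            k[4] = _rhs_flat(x + dt_use * (a51 * k[0] + a52 * k[1]
                                           + a53 * k[2] + a54 * k[3]),
                             pa, mk, stress, mtor_total, ulk1_total,
                             ampk_total)
            k[5] = _rhs_flat(x + dt_use * (a61 * k[0] + a62 * k[1]
                                           + a63 * k[2] + a64 * k[3]
                                           + a65 * k[4]), pa, mk, stress,
                             mtor_total, ulk1_total, ampk_total)
            x5 = x + dt_use * (b1 * k[0] + b3 * k[2] + b4 * k[3]
                               + b5 * k[4] + b6 * k[5])
            k[6] = _rhs_flat(x5, pa, mk, stress, mtor_total, ulk1_total,
                             ampk_total)
            err_v = dt_use * (e1 * k[0] + e3 * k[2] + e4 * k[3]
                              + e5 * k[4] + e6 * k[5] + e7 * k[6])
            sc0 = atol + rtol * max(abs(x[0]), abs(x5[0]))
            sc1 = atol + rtol * max(abs(x[1]), abs(x5[1]))
            sc2 = atol + rtol * max(abs(x[2]), abs(x5[2]))
            sc3 = atol + rtol * max(abs(x[3]), abs(x5[3]))
            err = np.sqrt(0.25 * ((err_v[0] / sc0) ** 2
                                  + (err_v[1] / sc1) ** 2
                                  + (err_v[2] / sc2) ** 2
                                  + (err_v[3] / sc3) ** 2))
            n_steps += 1
            if err <= 1.0 or dt_use <= 1e-10:
                t += dt_use
                x = x5
                fac = 2.0 if err == 0.0 else min(
                    2.0, max(0.2, 0.9 * err ** (-0.2)))
                dt = max(1e-10, dt_use * fac)
            else:
                dt = max(1e-10, dt_use * max(0.2, 0.9 * err ** (-0.2)))
        out[i_out] = x
        i_out += 1
    return out, 0


@nb.njit(cache=True)
def _jac_flat(x, pa, mk, stress, mtor_total, ulk1_total, ampk_total):
    u, a, m, r = x[0], x[1], x[2], x[3]
    act_u = (pa[0] + mk[1] * pa[1] * a + mk[3] * pa[2] * r
             + mk[10] * pa[3] * stress)
    inact_u = pa[5] + mk[7] * pa[6] * m
    act_a = pa[8] + mk[0] * pa[9] * stress
    inact_a = pa[11] + mk[5] * pa[12] * u + mk[9] * pa[13] * m
    act_m = pa[15]
    inact_m = (pa[17] + mk[8] * pa[18] * a + mk[6] * pa[19] * u
               + mk[4] * pa[20] * r)
    J = np.zeros((4, 4))
    fu = ulk1_total - u
    Fa_u = fu / (pa[4] + fu)
    dFa_u = -pa[4] / (pa[4] + fu) ** 2
    Fi_u = u / (pa[7] + u)
    dFi_u = pa[7] / (pa[7] + u) ** 2
    fa = ampk_total - a
    Fa_a = fa / (pa[10] + fa)
    dFa_a = -pa[10] / (pa[10] + fa) ** 2
    Fi_a = a / (pa[14] + a)
    dFi_a = pa[14] / (pa[14] + a) ** 2
    fm = mtor_total - m
    Fa_m = fm / (pa[16] + fm)
    dFa_m = -pa[16] / (pa[16] + fm) ** 2
    Fi_m = m / (pa[21] + m)
    dFi_m = pa[21] / (pa[21] + m) ** 2
    J[0, 0] = act_u * dFa_u - inact_u * dFi_u
    J[0, 1] = mk[1] * pa[1] * Fa_u
    J[0, 2] = -mk[7] * pa[6] * Fi_u
    J[0, 3] = mk[3] * pa[2] * Fa_u
    J[1, 0] = -mk[5] * pa[12] * Fi_a
    J[1, 1] = act_a * dFa_a - inact_a * dFi_a
    J[1, 2] = -mk[9] * pa[13] * Fi_a
    J[2, 0] = -mk[6] * pa[19] * Fi_m
    J[2, 1] = -mk[8] * pa[18] * Fi_m
    J[2, 2] = act_m * dFa_m - inact_m * dFi_m
    J[2, 3] = -mk[4] * pa[20] * Fi_m
    J[3, 1] = mk[2] * pa[23]
    J[3, 3] = -pa[24]
    return J


@nb.njit(cache=True, inline="always")
def _lu4(W, piv):
    """In-place LU factorisation with partial pivoting of a 4x4 matrix."""
    for k in range(4):
        p = k
        mx = abs(W[k, k])
        for i in range(k + 1, 4):
            if abs(W[i, k]) > mx:
                mx = abs(W[i, k])
                p = i
        piv[k] = p
        if p != k:
            for j in range(4):
                tmp = W[k, j]
                W[k, j] = W[p, j]
                W[p, j] = tmp
        for i in range(k + 1, 4):
            W[i, k] /= W[k, k]
            lik = W[i, k]
            for j in range(k + 1, 4):
                W[i, j] -= lik * W[k, j]


@nb.njit(cache=True, inline="always")
def _lu4_solve(W, piv, b, out):
    for i in range(4):
        out[i] = b[i]
    for k in range(4):
        p = piv[k]
        if p != k:
            tmp = out[k]
            out[k] = out[p]
            out[p] = tmp
        for i in range(k + 1, 4):
            out[i] -= W[i, k] * out[k]
    for i in range(3, -1, -1):
        for j in range(i + 1, 4):
            out[i] -= W[i, j] * out[j]
        out[i] /= W[i, i]


@nb.njit(cache=True)
def _integrate_rosenbrock(pa, mk, stress, mtor_total, ulk1_total,
                          ampk_total, x0, t_grid, rtol, atol, max_steps):
    """L-stable Rosenbrock 2(3) pair (ode23s form) with analytic Jacobian.

    Steps are accuracy- rather than stability-limited, which is what makes
    the many thousands of stiff relaxation-oscillation simulations of a
    Saltelli run affordable.
    """
    d = 1.0 / (2.0 + np.sqrt(2.0))
    e32 = 6.0 + np.sqrt(2.0)
    n_out = t_grid.shape[0]
    out = np.empty((n_out, 4))
    out[0] = x0
    x = x0.copy()
    t = t_grid[0]
    dt = 1e-3
    eye = np.eye(4)
    piv = np.zeros(4, dtype=np.int64)
    k1 = np.empty(4)
    k2 = np.empty(4)
    k3 = np.empty(4)
    rhs2 = np.empty(4)
    i_out = 1
    n_steps = 0
    while i_out < n_out:
        t_target = t_grid[i_out]
        while t < t_target:
            if n_steps >= max_steps:
                return out[:i_out], -1
            dt_use = dt if t + dt <= t_target else t_target - t
            f0 = _rhs_flat(x, pa, mk, stress, mtor_total, ulk1_total,
                           ampk_total)
            J = _jac_flat(x, pa, mk, stress, mtor_total, ulk1_total,
                          ampk_total)
            W = eye - dt_use * d * J
            _lu4(W, piv)
            _lu4_solve(W, piv, f0, k1)
            f1 = _rhs_flat(x + 0.5 * dt_use * k1, pa, mk, stress,
                           mtor_total, ulk1_total, ampk_total)
            for _i in range(4):
                rhs2[_i] = f1[_i] - k1[_i]
            _lu4_solve(W, piv, rhs2, k2)
            for _i in range(4):
                k2[_i] += k1[_i]
            x_new = x + dt_use * k2
            f2 = _rhs_flat(x_new, pa, mk, stress, mtor_total, ulk1_total,
                           ampk_total)
            for _i in range(4):
                rhs2[_i] = (f2[_i] - e32 * (k2[_i] - f1[_i])
                            - 2.0 * (k1[_i] - f0[_i]))
            _lu4_solve(W, piv, rhs2, k3)
            err = 0.0
            for i in range(4):
                sc = atol + rtol * max(abs(x[i]), abs(x_new[i]))
                e = (dt_use / 6.0) * (k1[i] - 2.0 * k2[i] + k3[i]) / sc
                err += e * e
            err = np.sqrt(0.25 * err)
            n_steps += 1
            if err <= 1.0 or dt_use <= 1e-11:
                t += dt_use
                x = x_new
                fac = 5.0 if err == 0.0 else min(
                    5.0, max(0.2, 0.9 * err ** (-1.0 / 3.0)))
                dt = max(1e-11, dt_use * fac)
            else:
                dt = max(1e-11, dt_use * max(0.2, 0.9 * err ** (-1.0 / 3.0)))
        out[i_out] = x
        i_out += 1
    return out, 0


def _simulate_fast(params: ParameterSet, inputs: SystemInputs,
                   mask: ConnectionMask, x0, t_end: float, step: float,
                   rtol: float = 1e-6, atol: float = 1e-9):
    t_eval = np.arange(0.0, t_end + 0.5 * step, step)
    y, status = _integrate_rosenbrock(
        params.as_array(), mask.as_array(), inputs.stress,
        inputs.mtor_total, params.ulk1_total, params.ampk_total,
        np.asarray(x0, dtype=float), t_eval, rtol, atol, 5_000_000)
    if status != 0:
        raise RuntimeError("integration exceeded the step budget")
    return t_eval, y


def fast_timecourse(params: ParameterSet, mask: ConnectionMask,
                    inputs: SystemInputs, x0, t_end: float, step: float,
                    rtol: float = 1e-6, atol: float = 1e-9,
                    t_start: float = 0.0):
    """Integrate onto a fixed grid with the compiled Rosenbrock scheme."""
    t_eval = np.arange(t_start, t_end + 0.5 * step, step)
    y, status = _integrate_rosenbrock(
        params.as_array(), mask.as_array(), inputs.stress,
        inputs.mtor_total, params.ulk1_total, params.ampk_total,
        np.asarray(x0, dtype=float), t_eval, rtol, atol, 5_000_000)
    if status != 0:
        raise RuntimeError("integration exceeded the step budget")
    return t_eval, y
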