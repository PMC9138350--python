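"""Compiled fast paths for the forward and backward (adjoint) RKF45 solves.

These kernels mirror, operation for operation, the reference implementations
in :mod:`myoexo.dynamics` (rhs, analytic Jacobians, adaptive RKF45 with
cubic-Hermite dense output) and :mod:`myoexo.adjoint` (augmented
adjoint/gradient backward pass); the test suite asserts the two paths agree.
Muscle constants arrive as a packed (n_muscles, 15) array, activations and
the measured reference velocity as a uniform grid of cubic-spline segments.

If numba is unavailable the module still imports; callers must check
``HAVE_NUMBA`` and fall back to the reference path.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


# packed muscle-parameter column indices
(C_L, C_FMAX, C_LS, C_R, C_LMT0, C_COSA, C_GAMMA, C_KPE, C_EPSPE, C_FTOE,
 C_KTOE, C_KLIN, C_EPSTOE, C_VMAX, C_B) = range(15)

STATUS_OK = 0
STATUS_UNDERFLOW = 1
STATUS_NONFINITE = 2
STATUS_MAXSTEPS = 3

# Fehlberg 4(5) tableau
_C2, _C3, _C4, _C5, _C6 = 0.25, 0.375, 12.0 / 13.0, 1.0, 0.5
_B5 = np.array([16 / 135, 0.0, 6656 / 12825, 28561 / 56430, -9 / 50, 2 / 55])
_B4 = np.array([25 / 216, 0.0, 1408 / 2565, 2197 / 4104, -1 / 5, 0.0])
_A21 = 0.25
_A31, _A32 = 3 / 32, 9 / 32
_A41, _A42, _A43 = 1932 / 2197, -7200 / 2197, 7296 / 2197
_A51, _A52, _A53, _A54 = 439 / 216, -8.0, 3680 / 513, -845 / 4104
_A61, _A62, _A63, _A64, _A65 = -8 / 27, 2.0, -3544 / 2565, 1859 / 4104, -11 / 40


def pack_muscles(muscles) -> np.ndarray:
    """Pack MuscleParams into the (n, 15) array the kernels consume."""
    P = np.empty((len(muscles), 15))
    for i, m in enumerate(muscles):
        P[i] = (m.L_star, m.F_max, m.l_slack, m.moment_arm, m.l_mt0,
                np.cos(m.pennation), m.gamma, m.k_pe, m.eps_pe, m.f_toe,
                m.k_toe, m.k_lin, m.eps_toe, m.V_max, m.b_fv)
    return P


def pack_exo(exo) -> np.ndarray:
    return np.array([exo.J, exo.B, exo.K, exo.tau_g, exo.theta_r])


@njit(cache=True)
def _interp_grid(t, g_t0, g_dt, grid, col):
    """Linear interpolation of column ``col`` of a uniform grid."""
    nt = grid.shape[0]
    s = (t - g_t0) / g_dt
    i = int(np.floor(s))
    if i < 0:
        i = 0
    if i > nt - 2:
        i = nt - 2
    w = s - i
    if w < 0.0:
        w = 0.0
    if w > 1.0:
        w = 1.0
    return grid[i, col] * (1.0 - w) + grid[i + 1, col] * w


@njit(cache=True)
def _ref_spline(t, r_t0, r_dt, r_coef):
    """Piecewise-cubic (spline) evaluation of the measured velocity."""
    nseg = r_coef.shape[1]
    i = int(np.floor((t - r_t0) / r_dt))
    if i < 0:
        i = 0
    if i > nseg - 1:
        i = nseg - 1
    u = t - (r_t0 + i * r_dt)
    return ((r_coef[0, i] * u + r_coef[1, i]) * u + r_coef[2, i]) * u \
        + r_coef[3, i]


@njit(cache=True)
def _rhs(t, x, out, P, E, g_t0, g_dt, a_grid, te_col, r_t0, r_dt, r_coef):
    """Coupled muscle-joint rhs plus the running-loss quadrature state.

    ``a_grid`` columns: one per muscle, then one tau_e column (index
    ``te_col``).  The last state is q with q' = (theta_dot - ref)^2, so the
    trajectory loss q(T) is error-controlled by the integrator.  Returns
    tau_h.
    """
    n = P.shape[0]
    J, B, K, taug, thr = E[0], E[1], E[2], E[3], E[4]
    theta = x[n]
    theta_dot = x[n + 1]
    d = theta - thr
    tau_h = 0.0
    for i in range(n):
        a = _interp_grid(t, g_t0, g_dt, a_grid, i)
        L, Fmax, ls = P[i, C_L], P[i, C_FMAX], P[i, C_LS]
        r, lmt0, cosa = P[i, C_R], P[i, C_LMT0], P[i, C_COSA]
        l = x[i]
        lmt = lmt0 - r * d
        eps = (lmt - L * l * cosa - ls) / ls
        ftoe, ktoe, klin, epstoe = (P[i, C_FTOE], P[i, C_KTOE],
                                    P[i, C_KLIN], P[i, C_EPSTOE])
        if eps <= 0.0:
            fse = 0.0
        elif eps <= epstoe:
            fse = ftoe * np.expm1(ktoe * eps / epstoe) / np.expm1(ktoe)
        else:
            fse = klin * (eps - epstoe) + ftoe
        fpe = np.expm1(P[i, C_KPE] * (l - 1.0) / P[i, C_EPSPE]) \
            / np.expm1(P[i, C_KPE])
        fce = fse / cosa - fpe
        if fce < 0.0:
            fce = 0.0
        fl = np.exp(-((l - 1.0) ** 2) / P[i, C_GAMMA])
        out[i] = (0.25 + 0.75 * a) * P[i, C_VMAX] * (fce - a * fl) / P[i, C_B]
        tau_h += r * Fmax * fse
    te = _interp_grid(t, g_t0, g_dt, a_grid, te_col)
    out[n] = theta_dot
    out[n + 1] = (tau_h + te - B * theta_dot - K * d - taug * np.sin(d)) / J
    dv = theta_dot - _ref_spline(t, r_t0, r_dt, r_coef)
    out[n + 2] = dv * dv
    return tau_h


@njit(cache=True)
def _forward_rkf45(x0, t0, t1, rtol, atol, P, E, g_t0, g_dt, a_grid, te_col,
                   r_t0, r_dt, r_coef, max_steps):
    """Adaptive RKF45 forward solve; returns accepted nodes and rhs values."""
    nx = x0.size
    ts = np.empty(max_steps)
    xs = np.empty((max_steps, nx))
    fs = np.empty((max_steps, nx))
    k = np.empty((6, nx))
    xi = np.empty(nx)
    x = x0.copy()
    f = np.empty(nx)
    _rhs(t0, x, f, P, E, g_t0, g_dt, a_grid, te_col, r_t0, r_dt, r_coef)
    ts[0] = t0
    xs[0] = x
    fs[0] = f
    m = 1
    # initial step guess
    d0 = 0.0
    d1 = 0.0
    for j in range(nx):
        sc = atol + rtol * abs(x[j])
        d0 += (x[j] / sc) ** 2
        d1 += (f[j] / sc) ** 2
    d0 = np.sqrt(d0 / nx)
    d1 = np.sqrt(d1 / nx)
    h = 0.01 * d0 / d1 if (d0 > 1e-5 and d1 > 1e-5) else 1e-4
    if h > t1 - t0:
        h = t1 - t0
    h_min = 1e-13 * max(abs(t0), abs(t1), 1.0)
    t = t0
    while t < t1:
        if h > t1 - t:
            h = t1 - t
        if h < h_min:
            return STATUS_UNDERFLOW, m, t, ts, xs, fs
        for j in range(nx):
            k[0, j] = f[j]
        for j in range(nx):
            xi[j] = x[j] + h * _A21 * k[0, j]
        _rhs(t + _C2 * h, xi, k[1], P, E, g_t0, g_dt, a_grid, te_col, r_t0, r_dt, r_coef)
        for j in range(nx):
            xi[j] = x[j] + h * (_A31 * k[0, j] + _A32 * k[1, j])
        _rhs(t + _C3 * h, xi, k[2], P, E, g_t0, g_dt, a_grid, te_col, r_t0, r_dt, r_coef)
        for j in range(nx):
            xi[j] = x[j] + h * (_A41 * k[0, j] + _A42 * k[1, j]
                                + _A43 * k[2, j])
        _rhs(t + _C4 * h, xi, k[3], P, E, g_t0, g_dt, a_grid, te_col, r_t0, r_dt, r_coef)
        for j in range(nx):
            xi[j] = x[j] + h * (_A51 * k[0, j] + _A52 * k[1, j]
                                + _A53 * k[2, j] + _A54 * k[3, j])
        _rhs(t + _C5 * h, xi, k[4], P, E, g_t0, g_dt, a_grid, te_col, r_t0, r_dt, r_coef)
        for j in range(nx):
            xi[j] = x[j] + h * (_A61 * k[0, j] + _A62 * k[1, j]
                                + _A63 * k[2, j] + _A64 * k[3, j]
                                + _A65 * k[4, j])
        _rhs(t + _C6 * h, xi, k[5], P, E, g_t0, g_dt, a_grid, te_col, r_t0, r_dt, r_coef)
        enorm = 0.0
        for j in range(nx):
            x5j = x[j]
            errj = 0.0
            for q in range(6):
                x5j += h * _B5[q] * k[q, j]
                errj += h * (_B5[q] - _B4[q]) * k[q, j]
            xi[j] = x5j
            amax = abs(x[j])
            if abs(x5j) > amax:
                amax = abs(x5j)
            sc = atol + rtol * amax
            enorm += (errj / sc) ** 2
        enorm = np.sqrt(enorm / nx)
        if not np.isfinite(enorm):
            return STATUS_NONFINITE, m, t, ts, xs, fs
        if enorm > 1.0:
            fac = 0.9 * enorm ** -0.2
            if fac < 0.2:
                fac = 0.2
            h *= fac
            continue
        if enorm > 0.0:
            fac = 0.9 * enorm ** -0.2
            if fac > 5.0:
                fac = 5.0
            if fac < 0.2:
                fac = 0.2
        else:
            fac = 5.0
        t += h
        for j in range(nx):
            x[j] = xi[j]
        _rhs(t, x, f, P, E, g_t0, g_dt, a_grid, te_col, r_t0, r_dt, r_coef)
        if m >= max_steps:
            return STATUS_MAXSTEPS, m, t, ts, xs, fs
        ts[m] = t
        xs[m] = x
        fs[m] = f
        m += 1
        h *= fac
    return STATUS_OK, m, t1, ts, xs, fs


@njit(cache=True)
def _hermite_eval(tq, ts, xs, fs, m, out):
    """Cubic-Hermite dense evaluation at tq over accepted nodes [0, m)."""
    lo, hi = 0, m - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if ts[mid] <= tq:
            lo = mid
        else:
            hi = mid
    h = ts[lo + 1] - ts[lo]
    s = (tq - ts[lo]) / h if h > 0 else 0.0
    h00 = (1 + 2 * s) * (1 - s) ** 2
    h10 = s * (1 - s) ** 2
    h01 = s * s * (3 - 2 * s)
    h11 = s * s * (s - 1)
    for j in range(xs.shape[1]):
        out[j] = (h00 * xs[lo, j] + h * h10 * fs[lo, j]
                  + h01 * xs[lo + 1, j] + h * h11 * fs[lo + 1, j])


@njit(cache=True)
def _adjoint_rhs(s, y, dy, t1, ts, xs, fs, m, P, E, g_t0, g_dt, a_grid,
                 te_col, r_t0, r_dt, r_coef, xbuf):
    """Backward augmented rhs: d(lambda, grad)/ds at reversed time s.

    Fuses the analytic Jacobian-transpose products of the reference
    implementation; the forward state comes from the Hermite cache, the
    measured velocity from the (r_t0, r_dt, r_coef) spline segments.
    """
    n = P.shape[0]
    t = t1 - s
    _hermite_eval(t, ts, xs, fs, m, xbuf)
    J, B, K, taug, thr = E[0], E[1], E[2], E[3], E[4]
    theta = xbuf[n]
    zdot = xbuf[n + 1]
    d = theta - thr
    lam_th = y[n]
    lam_td = y[n + 1]
    acc_th = 0.0  # d acc/d theta accumulated over muscles
    dlam_th = 0.0
    for i in range(n):
        a = _interp_grid(t, g_t0, g_dt, a_grid, i)
        L, Fmax, ls = P[i, C_L], P[i, C_FMAX], P[i, C_LS]
        r, lmt0, cosa = P[i, C_R], P[i, C_LMT0], P[i, C_COSA]
        l = xbuf[i]
        lmt = lmt0 - r * d
        eps = (lmt - L * l * cosa - ls) / ls
        ftoe, ktoe, klin, epstoe = (P[i, C_FTOE], P[i, C_KTOE],
                                    P[i, C_KLIN], P[i, C_EPSTOE])
        if eps <= 0.0:
            fse = 0.0
            dfse = 0.0
        elif eps <= epstoe:
            ex = np.exp(ktoe * eps / epstoe)
            den = np.expm1(ktoe)
            fse = ftoe * (ex - 1.0) / den
            dfse = ftoe * (ktoe / epstoe) * ex / den
        else:
            fse = klin * (eps - epstoe) + ftoe
            dfse = klin
        kpe, epspe = P[i, C_KPE], P[i, C_EPSPE]
        expe = np.exp(kpe * (l - 1.0) / epspe)
        denpe = np.expm1(kpe)
        fpe = (expe - 1.0) / denpe
        dfpe = (kpe / epspe) * expe / denpe
        fce = fse / cosa - fpe
        active = 1.0 if fce > 0.0 else 0.0
        fl = np.exp(-((l - 1.0) ** 2) / P[i, C_GAMMA])
        dfl = -2.0 * (l - 1.0) / P[i, C_GAMMA] * fl
        cv = (0.25 + 0.75 * a) * P[i, C_VMAX] / P[i, C_B]
        e_l = -L * cosa / ls
        e_th = -r / ls
        e_L = -l * cosa / ls
        e_ls = -(eps + 1.0) / ls
        dv_dl = cv * (active * (dfse * e_l / cosa - dfpe) - a * dfl)
        dv_dth = cv * active * dfse * e_th / cosa
        dacc_dl = r * Fmax * dfse * e_l / J
        acc_th += r * Fmax * dfse * e_th
        lam_l = y[i]
        # (A^T lambda)_l_i
        dy[i] = dv_dl * lam_l + dacc_dl * lam_td
        dlam_th += dv_dth * lam_l
        # gradient quadrature rows (L*, F_max, l_slack) for muscle i
        base = n + 2 + 3 * i
        dv_dL = cv * active * dfse * e_L / cosa
        dv_dls = cv * active * dfse * e_ls / cosa
        dy[base] = dv_dL * lam_l + (r * Fmax * dfse * e_L / J) * lam_td
        dy[base + 1] = (r * fse / J) * lam_td
        dy[base + 2] = dv_dls * lam_l + (r * Fmax * dfse * e_ls / J) * lam_td
    dacc_dth = (acc_th - K - taug * np.cos(d)) / J
    ref = _ref_spline(t, r_t0, r_dt, r_coef)
    dy[n] = dlam_th + dacc_dth * lam_td
    dy[n + 1] = lam_th + (-B / J) * lam_td + 2.0 * (zdot - ref)


@njit(cache=True)
def _backward_rkf45(t0, t1, rtol, atol, ts, xs, fs, m, P, E, g_t0, g_dt,
                    a_grid, te_col, r_t0, r_dt, r_coef, max_steps):
    """Adaptive RKF45 for the augmented adjoint system over s in [0, t1-t0].

    Returns (status, t_fail, yT, lam_min, lam_max); yT holds lambda(0) in the
    first n+2 slots and the accumulated gradient in the remaining 3n.
    """
    n = P.shape[0]
    ny = (n + 2) + 3 * n
    y = np.zeros(ny)
    k = np.empty((6, ny))
    yi = np.empty(ny)
    f = np.empty(ny)
    xbuf = np.empty(xs.shape[1])
    s_end = t1 - t0
    _adjoint_rhs(0.0, y, f, t1, ts, xs, fs, m, P, E, g_t0, g_dt, a_grid,
                 te_col, r_t0, r_dt, r_coef, xbuf)
    h = 1e-4 if s_end > 1e-4 else s_end
    h_min = 1e-13 * max(abs(s_end), 1.0)
    s = 0.0
    lam_min, lam_max = 0.0, 0.0
    steps = 0
    while s < s_end:
        if h > s_end - s:
            h = s_end - s
        if h < h_min:
            return STATUS_UNDERFLOW, t1 - s, y, lam_min, lam_max
        if steps > max_steps:
            return STATUS_MAXSTEPS, t1 - s, y, lam_min, lam_max
        steps += 1
        for j in range(ny):
            k[0, j] = f[j]
        for j in range(ny):
            yi[j] = y[j] + h * _A21 * k[0, j]
        _adjoint_rhs(s + _C2 * h, yi, k[1], t1, ts, xs, fs, m, P, E, g_t0,
                     g_dt, a_grid, te_col, r_t0, r_dt, r_coef, xbuf)
        for j in range(ny):
            yi[j] = y[j] + h * (_A31 * k[0, j] + _A32 * k[1, j])
        _adjoint_rhs(s + _C3 * h, yi, k[2], t1, ts, xs, fs, m, P, E, g_t0,
                     g_dt, a_grid, te_col, r_t0, r_dt, r_coef, xbuf)
        for j in range(ny):
            yi[j] = y[j] + h * (_A41 * k[0, j] + _A42 * k[1, j]
                                + _A43 * k[2, j])
        _adjoint_rhs(s + _C4 * h, yi, k[3], t1, ts, xs, fs, m, P, E, g_t0,
                     g_dt, a_grid, te_col, r_t0, r_dt, r_coef, xbuf)
        for j in range(ny):
            yi[j] = y[j] + h * (_A51 * k[0, j] + _A52 * k[1, j]
                                + _A53 * k[2, j] + _A54 * k[3, j])
        _adjoint_rhs(s + _C5 * h, yi, k[4], t1, ts, xs, fs, m, P, E, g_t0,
                     g_dt, a_grid, te_col, r_t0, r_dt, r_coef, xbuf)
        for j in range(ny):
            yi[j] = y[j] + h * (_A61 * k[0, j] + _A62 * k[1, j]
                                + _A63 * k[2, j] + _A64 * k[3, j]
                                + _A65 * k[4, j])
        _adjoint_rhs(s + _C6 * h, yi, k[5], t1, ts, xs, fs, m, P, E, g_t0,
                     g_dt, a_grid, te_col, r_t0, r_dt, r_coef, xbuf)
        enorm = 0.0
        for j in range(ny):
            y5j = y[j]
            errj = 0.0
            for q in range(6):
                y5j += h * _B5[q] * k[q, j]
                errj += h * (_B5[q] - _B4[q]) * k[q, j]
            yi[j] = y5j
            amax = abs(y[j])
            if abs(y5j) > amax:
                amax = abs(y5j)
            sc = atol + rtol * amax
            enorm += (errj / sc) ** 2
        enorm = np.sqrt(enorm / ny)
        if not np.isfinite(enorm):
            return STATUS_NONFINITE, t1 - s, y, lam_min, lam_max
        if enorm > 1.0:
            fac = 0.9 * enorm ** -0.2
            if fac < 0.2:
                fac = 0.2
            h *= fac
            continue
        if enorm > 0.0:
            fac = 0.9 * enorm ** -0.2
            if fac > 5.0:
                fac = 5.0
            if fac < 0.2:
                fac = 0.2
        else:
            fac = 5.0
        s += h
        for j in range(ny):
            y[j] = yi[j]
        for j in range(n + 2):
            if y[j] < lam_min:
                lam_min = y[j]
            if y[j] > lam_max:
                lam_max = y[j]
        _adjoint_rhs(s, y, f, t1, ts, xs, fs, m, P, E, g_t0, g_dt, a_grid,
                     te_col, r_t0, r_dt, r_coef, xbuf)
        h *= fac
    return STATUS_OK, t0, y, lam_min, lam_max
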