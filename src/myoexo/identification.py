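"""Identification of the exoskeleton inertial parameters K, J and B.

The stiffness K is identified from a static protocol (the joint held at a
series of angles with no human torque), where the motion equation reduces to

    tau_e(t_i) = K (theta_i - theta_r) + tau_g sin(theta_i - theta_r),

so y_i = tau_e_i - tau_g sin(theta_i - theta_r) regressed on
(theta_i - theta_r) gives K in closed form.

J and B come from a dynamic protocol (the exoskeleton driving the joint
through slow movement cycles):

    y(t_i) = tau_e_i - tau_g sin(.) - K (.) = J theta_dd_i + B theta_d_i,

a linear least-squares problem in (J, B).  Because the encoder measures
position with noise, velocity and acceleration are obtained by fitting a
truncated Fourier series to theta(t) and differentiating the fit
analytically.  The least-squares problems are linear in the parameters;
a Levenberg-Marquardt path over the same residuals is retained as an
optional solver for parity with iterative practice and reaches the same
optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .dynamics import ExoParams

__all__ = [
    "StaticRecord",
    "DynamicRecord",
    "FourierFit",
    "fourier_smooth",
    "identify_stiffness",
    "identify_inertia_damping",
    "identification_report",
]


@dataclass(frozen=True)
class StaticRecord:
    """Held angles (rad) and the motor torque (N m) at each hold."""

    theta: np.ndarray
    tau_e: np.ndarray

    def __post_init__(self):
        th = np.asarray(self.theta, dtype=float)
        te = np.asarray(self.tau_e, dtype=float)
        object.__setattr__(self, "theta", th)
        object.__setattr__(self, "tau_e", te)
        if th.shape != te.shape or th.ndim != 1:
            raise ValueError("theta and tau_e must be 1-D and equal length")
        if np.unique(th).size < 2:
            raise ValueError("need at least 2 distinct hold angles")


@dataclass(frozen=True)
class DynamicRecord:
    """Uniformly sampled encoder angle and motor torque during movement."""

    t: np.ndarray
    theta: np.ndarray
    tau_e: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float))
        object.__setattr__(self, "tau_e", np.asarray(self.tau_e, dtype=float))
        dt = np.diff(t)
        if t.ndim != 1 or t.size < 4 or np.any(dt <= 0) \
                or not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("t must be 1-D, uniform, increasing")


@dataclass(frozen=True)
class FourierFit:
    """Truncated Fourier series with analytic derivatives.

    theta(t) = a0 + sum_k a_k cos(k w t) + b_k sin(k w t), w = 2 pi / period.
    """

    a0: float
    a: np.ndarray
    b: np.ndarray
    omega: float

    def _eval(self, t, order):
        t = np.asarray(t, dtype=float)
        k = np.arange(1, self.a.size + 1)
        kw = k * self.omega
        arg = np.multiply.outer(t, kw)
        if order == 0:
            return self.a0 + np.cos(arg) @ self.a + np.sin(arg) @ self.b
        if order == 1:
            return -np.sin(arg) @ (kw * self.a) + np.cos(arg) @ (kw * self.b)
        if order == 2:
            return -np.cos(arg) @ (kw**2 * self.a) - np.sin(arg) @ (kw**2 * self.b)
        raise ValueError("order must be 0, 1 or 2")

    def theta(self, t):
        return self._eval(t, 0)

    def theta_dot(self, t):
        return self._eval(t, 1)

    def theta_ddot(self, t):
        return self._eval(t, 2)


def fourier_smooth(t, theta_samples, n_harmonics=8, base_period=None) -> FourierFit:
    """Least-squares truncated Fourier fit to noisy encoder angles.

    ``base_period`` defaults to the record duration.  The fit's analytic
    derivatives provide the smooth angular velocity and acceleration used in
    the dynamic identification.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(theta_samples, dtype=float)
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    duration = t[-1] - t[0]
    period = float(base_period) if base_period is not None else float(duration)
    if duration < period - 1e-12:
        raise ValueError("record shorter than the base period")
    ncoef = 1 + 2 * n_harmonics
    if ncoef > t.size:
        raise ValueError(
            f"{ncoef} Fourier coefficients but only {t.size} samples")
    omega = 2 * np.pi / period
    k = np.arange(1, n_harmonics + 1)
    arg = np.multiply.outer(t, k * omega)
    X = np.hstack([np.ones((t.size, 1)), np.cos(arg), np.sin(arg)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return FourierFit(a0=float(coef[0]), a=coef[1 : 1 + n_harmonics],
                      b=coef[1 + n_harmonics :], omega=omega)


def identify_stiffness(rec: StaticRecord, m, r_cm, theta_r,
                       g=9.81) -> float:
    """Closed-form least-squares estimate of the joint stiffness K.

    Regresses y_i = tau_e_i - m g r_cm sin(theta_i - theta_r) on
    (theta_i - theta_r) without intercept.  Warns (does not fail) if the
    estimate is negative.
    """
    d = rec.theta - theta_r
    if np.allclose(d, d[0]):
        raise ValueError("all hold angles equal: K unidentifiable")
    y = rec.tau_e - m * g * r_cm * np.sin(d)
    K = float(np.dot(d, y) / np.dot(d, d))
    if K < 0:
        import warnings

        warnings.warn(f"identified stiffness K={K:.4g} is negative")
    return K


def identify_inertia_damping(rec: DynamicRecord, K, m, r_cm, theta_r,
                             g=9.81, n_harmonics=8, base_period=None,
                             method="lstsq"):
    """Least-squares estimate of (J, B) from a dynamic record.

    Smooths the encoder angle with :func:`fourier_smooth`, then solves
    ``y = J theta_dd + B theta_d`` for J and B.  ``method`` is ``"lstsq"``
    (closed form) or ``"lm"`` (Levenberg-Marquardt over the same residuals;
    identical optimum).
    """
    fit = fourier_smooth(rec.t, rec.theta, n_harmonics=n_harmonics,
                         base_period=base_period)
    th = fit.theta(rec.t)
    thd = fit.theta_dot(rec.t)
    thdd = fit.theta_ddot(rec.t)
    if np.max(np.abs(thdd)) < 1e-12:
        raise ValueError("no acceleration in record: J unidentifiable")
    d = th - theta_r
    y = rec.tau_e - m * g * r_cm * np.sin(d) - K * d
    X = np.column_stack([thdd, thd])
    if method == "lstsq":
        sol, *_ = np.linalg.lstsq(X, y, rcond=None)
        J, B = float(sol[0]), float(sol[1])
    elif method == "lm":
        res = least_squares(lambda p: X @ p - y, x0=[0.05, 1.0], method="lm")
        J, B = float(res.x[0]), float(res.x[1])
    else:
        raise ValueError(f"unknown method {method!r}")
    if J <= 0:
        raise ValueError(f"identified inertia J={J:.4g} not positive")
    return J, B


def identification_report(static: StaticRecord, dynamic: DynamicRecord,
                          exo_known: ExoParams, **kw) -> dict:
    """Run both identifications; returns {K, J, B, residuals, n_samples}."""
    K = identify_stiffness(static, exo_known.m, exo_known.r_cm,
                           exo_known.theta_r, g=exo_known.g)
    J, B = identify_inertia_damping(dynamic, K, exo_known.m, exo_known.r_cm,
                                    exo_known.theta_r, g=exo_known.g, **kw)
    d_s = static.theta - exo_known.theta_r
    res_s = static.tau_e - exo_known.m * exo_known.g * exo_known.r_cm \
        * np.sin(d_s) - K * d_s
    return {
        "K": K, "J": J, "B": B,
        "residuals": {"static_rms": float(np.sqrt(np.mean(res_s**2)))},
        "n_samples": {"static": int(static.theta.size),
                      "dynamic": int(dynamic.t.size)},
    }
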