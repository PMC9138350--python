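"""Rigid-body joint model, coupled muscle-joint ODE, and RKF45 integration.

The exoskeleton-plus-shank is a damped pendulum-like joint:

    J theta_dd + B theta_d + dEp/dtheta = tau_e + tau_h,
    Ep = 1/2 K (theta - theta_r)^2 - tau_g cos(theta - theta_r),
    tau_g = m g r_cm,

with rotational inertia J, viscous damping B, spring stiffness K, and gravity
torque tau_g about the rest angle theta_r (pi/2 by convention; theta = 0 is
full extension, increasing with flexion, radians throughout).

Coupled to n muscles the state is x = (l_1..l_n, theta, theta_d):

    dl_j/dt     = v_j(l_j, theta, a_j(t))        (force-velocity inversion)
    dtheta/dt   = theta_d
    dtheta_d/dt = (tau_h + tau_e - B theta_d - dEp/dtheta) / J

Integration uses the Runge-Kutta-Fehlberg embedded 4(5) pair with adaptive
step control, advancing with the 5th-order solution, and cubic-Hermite dense
output on the accepted steps (the dense cache is what the adjoint's backward
pass interpolates).

``MuscleJointSystem`` packs the per-muscle constants into arrays and provides
the rhs together with hand-derived analytic Jacobians with respect to the
state and to the calibrated parameters omega = (L*, F_max, l_slack) per
muscle; the rhs is complex-safe so tests can cross-check the Jacobians by
complex-step differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .muscle import MuscleParams, isometric_equilibrium_length

__all__ = [
    "ExoParams",
    "SimState",
    "Trajectory",
    "IntegrationError",
    "potential_torque",
    "forward_accel",
    "MuscleJointSystem",
    "integrate",
    "simulate",
    "default_exo_params",
]

G_GRAVITY = 9.81


@dataclass(frozen=True)
class ExoParams:
    """Inertial constants of the single-joint exoskeleton."""

    J: float = 0.07      # rotational inertia (kg m^2)
    B: float = 1.5       # viscous damping (N m s / rad)
    K: float = 1.27      # stiffness (N m / rad)
    m: float = 5.5       # mass (kg)
    r_cm: float = 0.16   # center-of-mass arm (m)
    theta_r: float = np.pi / 2  # rest angle (rad)
    g: float = G_GRAVITY

    def __post_init__(self):
        if self.J <= 0:
            raise ValueError("inertia J must be positive")
        for f in ("B", "K", "m", "r_cm"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")

    @property
    def tau_g(self) -> float:
        """Gravitational torque scale m g r_cm (N m)."""
        return self.m * self.g * self.r_cm


def default_exo_params() -> ExoParams:
    """Identified knee-exoskeleton constants (J, B, K, m, r_cm)."""
    return ExoParams()


@dataclass(frozen=True)
class SimState:
    """ODE state: per-muscle normalized fiber lengths + joint angle/velocity."""

    l: np.ndarray
    theta: float
    theta_dot: float

    def __post_init__(self):
        l = np.atleast_1d(np.asarray(self.l, dtype=float))
        object.__setattr__(self, "l", l)
        if np.any(l <= 0) or not np.all(np.isfinite(l)):
            raise ValueError("fiber lengths must be positive and finite")
        if not (np.isfinite(self.theta) and np.isfinite(self.theta_dot)):
            raise ValueError("joint state must be finite")

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.l, [self.theta, self.theta_dot]])

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "SimState":
        x = np.asarray(x, dtype=float)
        return cls(l=x[:-2], theta=float(x[-2]), theta_dot=float(x[-1]))


def potential_torque(theta, p: ExoParams):
    """Restoring torque dEp/dtheta = K (theta-theta_r) + tau_g sin(theta-theta_r)."""
    d = theta - p.theta_r
    return p.K * d + p.tau_g * np.sin(d)


def forward_accel(tau_h, theta, theta_dot, p: ExoParams, tau_e=0.0):
    """Angular acceleration (tau_h + tau_e - B theta_d - dEp/dtheta) / J."""
    return (tau_h + tau_e - p.B * theta_dot - potential_torque(theta, p)) / p.J


# -- packed muscle arrays and vectorised rhs ---------------------------------


class _MusclePack:
    """Per-muscle constants packed into arrays for the vectorised rhs."""

    __slots__ = ("n", "L", "Fmax", "ls", "r", "lmt0", "cosa", "gamma", "kpe",
                 "epspe", "ftoe", "ktoe", "klin", "epstoe", "Vmax", "b")

    def __init__(self, muscles):
        get = lambda f: np.array([getattr(m, f) for m in muscles], dtype=float)
        self.n = len(muscles)
        self.L = get("L_star")
        self.Fmax = get("F_max")
        self.ls = get("l_slack")
        self.r = get("moment_arm")
        self.lmt0 = get("l_mt0")
        self.cosa = np.cos(get("pennation"))
        self.gamma = get("gamma")
        self.kpe = get("k_pe")
        self.epspe = get("eps_pe")
        self.ftoe = get("f_toe")
        self.ktoe = get("k_toe")
        self.klin = get("k_lin")
        self.epstoe = get("eps_toe")
        self.Vmax = get("V_max")
        self.b = get("b_fv")


def _re(x):
    return x.real if np.iscomplexobj(x) else x


class MuscleJointSystem:
    """The coupled muscle-joint ODE for a fixed muscle set and joint model.

    ``omega_vector``/``with_omega`` expose the calibrated parameters
    (L*, F_max, l_slack per muscle, SI units, flattened muscle-major) that the
    fitting machinery updates.
    """

    def __init__(self, muscles: list[MuscleParams], exo: ExoParams):
        self.muscles = list(muscles)
        self.exo = exo
        self._p = _MusclePack(self.muscles)

    @property
    def n_muscles(self) -> int:
        return self._p.n

    @property
    def n_states(self) -> int:
        return self._p.n + 2

    @property
    def n_params(self) -> int:
        return 3 * self._p.n

    def omega_vector(self) -> np.ndarray:
        """Flattened (L*, F_max, l_slack) per muscle, SI units."""
        p = self._p
        return np.column_stack([p.L, p.Fmax, p.ls]).ravel()

    def with_omega(self, omega: np.ndarray) -> "MuscleJointSystem":
        omega = np.asarray(omega, dtype=float).reshape(self._p.n, 3)
        ms = [m.with_omega(L_star=o[0], F_max=o[1], l_slack=o[2])
              for m, o in zip(self.muscles, omega)]
        return MuscleJointSystem(ms, self.exo)

    # -- elementary terms (complex-safe, vectorised over muscles) ------------

    def _terms(self, l, theta, a):
        p = self._p
        theta_rel = theta - self.exo.theta_r
        lmt = p.lmt0 - p.r * theta_rel
        lt = lmt - p.L * l * p.cosa
        eps = (lt - p.ls) / p.ls
        re = _re(eps)
        toe = p.ftoe * np.expm1(p.ktoe * eps / p.epstoe) / np.expm1(p.ktoe)
        lin = p.klin * (eps - p.epstoe) + p.ftoe
        fse = np.where(re > p.epstoe, lin, toe)
        fse = np.where(re > 0.0, fse, 0.0 * eps)
        dtoe = p.ftoe * (p.ktoe / p.epstoe) * np.exp(p.ktoe * eps / p.epstoe) \
            / np.expm1(p.ktoe)
        dfse = np.where(re > p.epstoe, p.klin + 0.0 * eps, dtoe)
        dfse = np.where(re > 0.0, dfse, 0.0 * eps)
        fpe = np.expm1(p.kpe * (l - 1.0) / p.epspe) / np.expm1(p.kpe)
        fce_raw = fse / p.cosa - fpe
        active = _re(fce_raw) > 0.0
        fce = np.where(active, fce_raw, 0.0 * fce_raw)
        fl = np.exp(-((l - 1.0) ** 2) / p.gamma)
        gain = 0.25 + 0.75 * a
        v = gain * p.Vmax * (fce - a * fl) / p.b
        tau_h = np.sum(p.r * p.Fmax * fse)
        return dict(eps=eps, fse=fse, dfse=dfse, fpe=fpe, fce=fce,
                    active=active, fl=fl, gain=gain, v=v, tau_h=tau_h)

    def tau_h(self, x, a) -> float:
        """Muscle joint torque for state vector x and activations a."""
        t = self._terms(x[:-2], x[-2], np.asarray(a, dtype=float))
        return float(t["tau_h"])

    def rhs(self, t, x, activations, tau_e=None):
        """d(state)/dt; ``activations`` maps t -> per-muscle a(t) array."""
        a = np.asarray(activations(_re(t)), dtype=float)
        te = 0.0 if tau_e is None else float(tau_e(_re(t)))
        l, theta, theta_dot = x[:-2], x[-2], x[-1]
        tm = self._terms(l, theta, a)
        acc = (tm["tau_h"] + te - self.exo.B * theta_dot
               - self.exo.K * (theta - self.exo.theta_r)
               - self.exo.tau_g * np.sin(theta - self.exo.theta_r)) / self.exo.J
        out = np.empty_like(x)
        out[:-2] = tm["v"]
        out[-2] = theta_dot
        out[-1] = acc
        return out

    # -- analytic Jacobians (cross-checked against complex step in tests) ----

    def jacobians(self, t, x, activations, want_omega=True):
        """Return (A, F_omega): d rhs/d state and d rhs/d omega at (t, x)."""
        p, exo = self._p, self.exo
        a = np.asarray(activations(t), dtype=float)
        l, theta, theta_dot = x[:-2], x[-2], x[-1]
        tm = self._terms(l, theta, a)
        n = p.n
        s = tm["active"].astype(float)
        dfse = tm["dfse"]
        # strain partials
        e_l = -p.L * p.cosa / p.ls
        e_th = -p.r / p.ls
        dfpe = (p.kpe / p.epspe) * np.exp(p.kpe * (l - 1.0) / p.epspe) \
            / np.expm1(p.kpe)
        dfl = -2.0 * (l - 1.0) / p.gamma * tm["fl"]
        cv = tm["gain"] * p.Vmax / p.b
        A = np.zeros((n + 2, n + 2))
        dv_dl = cv * (s * (dfse * e_l / p.cosa - dfpe) - a * dfl)
        A[np.arange(n), np.arange(n)] = dv_dl
        A[:n, n] = cv * s * dfse * e_th / p.cosa
        A[n, n + 1] = 1.0
        rF = p.r * p.Fmax
        A[n + 1, :n] = rF * dfse * e_l / exo.J
        d = theta - exo.theta_r
        A[n + 1, n] = (np.sum(rF * dfse * e_th) - exo.K
                       - exo.tau_g * np.cos(d)) / exo.J
        A[n + 1, n + 1] = -exo.B / exo.J
        if not want_omega:
            return A, None
        e_L = -l * p.cosa / p.ls
        e_ls = -(tm["eps"] + 1.0) / p.ls
        Fw = np.zeros((n + 2, 3 * n))
        idx = np.arange(n)
        Fw[idx, 3 * idx] = cv * s * dfse * e_L / p.cosa
        Fw[idx, 3 * idx + 2] = cv * s * dfse * e_ls / p.cosa
        Fw[n + 1, 3 * idx] = rF * dfse * e_L / exo.J
        Fw[n + 1, 3 * idx + 1] = p.r * tm["fse"] / exo.J
        Fw[n + 1, 3 * idx + 2] = rF * dfse * e_ls / exo.J
        return A, Fw

    # -- initial conditions --------------------------------------------------

    def initial_state(self, theta0: float, theta_dot0: float = 0.0,
                      a0=None) -> SimState:
        """Isometric fiber equilibrium at theta0 for activation ``a0``.

        ``a0`` defaults to zero (fully passive); passing the activation at
        the start of the record avoids a startup transient the model does
        not intend.
        """
        rel = theta0 - self.exo.theta_r
        a0 = np.zeros(self.n_muscles) if a0 is None else np.asarray(a0)
        l0 = np.array([isometric_equilibrium_length(rel, m, a)
                       for m, a in zip(self.muscles, a0)])
        return SimState(l=l0, theta=theta0, theta_dot=theta_dot0)

    def initial_state_sensitivity(self, theta0: float, a0=None) -> np.ndarray:
        """d x0 / d omega by implicit differentiation of the equilibrium.

        Only the fiber-length components depend on omega (through L* and
        l_slack); theta and theta_dot come from the measurement.
        """
        p = self._p
        a0 = np.zeros(p.n) if a0 is None else np.asarray(a0, dtype=float)
        x0 = self.initial_state(theta0, 0.0, a0).as_vector()
        l = x0[:-2]
        tm = self._terms(l, theta0, a0)
        dfse = tm["dfse"]
        dfpe = (p.kpe / p.epspe) * np.exp(p.kpe * (l - 1.0) / p.epspe) \
            / np.expm1(p.kpe)
        dfl = -2.0 * (l - 1.0) / p.gamma * tm["fl"]
        e_l = -p.L * p.cosa / p.ls
        e_L = -l * p.cosa / p.ls
        e_ls = -(tm["eps"] + 1.0) / p.ls
        G_l = dfse * e_l - (dfpe + a0 * dfl) * p.cosa
        out = np.zeros((p.n + 2, 3 * p.n))
        idx = np.arange(p.n)
        out[idx, 3 * idx] = -dfse * e_L / G_l
        out[idx, 3 * idx + 2] = -dfse * e_ls / G_l
        return out


# -- Runge-Kutta-Fehlberg 4(5) ----------------------------------------------


class IntegrationError(RuntimeError):
    """Raised when the adaptive step size underflows; carries the time."""

    def __init__(self, t, msg=""):
        super().__init__(msg or f"integration failed at t={t:.6g}")
        self.t = t


_RKF_C = np.array([0.0, 1 / 4, 3 / 8, 12 / 13, 1.0, 1 / 2])
_RKF_A = [
    np.array([]),
    np.array([1 / 4]),
    np.array([3 / 32, 9 / 32]),
    np.array([1932 / 2197, -7200 / 2197, 7296 / 2197]),
    np.array([439 / 216, -8.0, 3680 / 513, -845 / 4104]),
    np.array([-8 / 27, 2.0, -3544 / 2565, 1859 / 4104, -11 / 40]),
]
_RKF_B5 = np.array([16 / 135, 0.0, 6656 / 12825, 28561 / 56430, -9 / 50, 2 / 55])
_RKF_B4 = np.array([25 / 216, 0.0, 1408 / 2565, 2197 / 4104, -1 / 5, 0.0])


@dataclass
class OdeSolution:
    """Accepted RKF45 steps with cubic-Hermite dense evaluation."""

    ts: np.ndarray
    xs: np.ndarray   # (n_steps, n_states)
    fs: np.ndarray   # rhs at the nodes

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        tq = np.atleast_1d(t)
        idx = np.clip(np.searchsorted(self.ts, tq, side="right") - 1, 0,
                      len(self.ts) - 2)
        t0, t1 = self.ts[idx], self.ts[idx + 1]
        h = t1 - t0
        s = np.where(h > 0, (tq - t0) / np.where(h == 0, 1.0, h), 0.0)
        h00 = (1 + 2 * s) * (1 - s) ** 2
        h10 = s * (1 - s) ** 2
        h01 = s * s * (3 - 2 * s)
        h11 = s * s * (s - 1)
        x0, x1 = self.xs[idx], self.xs[idx + 1]
        f0, f1 = self.fs[idx], self.fs[idx + 1]
        out = (h00[:, None] * x0 + (h * h10)[:, None] * f0
               + h01[:, None] * x1 + (h * h11)[:, None] * f1)
        return out[0] if scalar else out


def integrate(rhs, x0, t_span, rtol=1e-6, atol=1e-8, max_step=np.inf,
              first_step=None, fixed_step=None, t_eval=None):
    """Adaptive RKF45 from t_span[0] to t_span[1].

    Returns ``(solution, x_eval)`` where ``solution`` is the dense
    :class:`OdeSolution` and ``x_eval`` the states at ``t_eval`` (None if no
    grid was requested).  ``fixed_step`` disables step control (convergence
    studies).  Raises :class:`IntegrationError` on step-size underflow.
    """
    if rtol <= 0 or atol <= 0:
        raise ValueError("rtol and atol must be positive")
    t0, t1 = float(t_span[0]), float(t_span[1])
    if t1 <= t0:
        raise ValueError("t_span must be increasing")
    x = np.asarray(x0, dtype=float).copy()
    f = rhs(t0, x)
    ts, xs, fs = [t0], [x.copy()], [np.asarray(f, dtype=float).copy()]
    if fixed_step is not None:
        h = float(fixed_step)
    else:
        if first_step is not None:
            h = float(first_step)
        else:
            scale = atol + rtol * np.abs(x)
            d0 = np.sqrt(np.mean((x / scale) ** 2))
            d1 = np.sqrt(np.mean((f / scale) ** 2))
            h = 0.01 * d0 / d1 if (d0 > 1e-5 and d1 > 1e-5) else 1e-4
        h = min(h, max_step, t1 - t0)
    h_min = 1e-13 * max(abs(t0), abs(t1), 1.0)
    t = t0
    k = np.empty((6, x.size))
    while t < t1:
        h = min(h, t1 - t)
        if h < h_min:
            raise IntegrationError(t, f"step size underflow at t={t:.6g}")
        k[0] = f
        for i in range(1, 6):
            xi = x + h * (_RKF_A[i] @ k[:i])
            k[i] = rhs(t + _RKF_C[i] * h, xi)
        x5 = x + h * (_RKF_B5 @ k)
        if fixed_step is None:
            err = h * ((_RKF_B5 - _RKF_B4) @ k)
            scale = atol + rtol * np.maximum(np.abs(x), np.abs(x5))
            enorm = np.sqrt(np.mean((err / scale) ** 2))
            if not np.isfinite(enorm):
                raise IntegrationError(t, f"non-finite state at t={t:.6g}")
            if enorm > 1.0:
                h *= max(0.2, 0.9 * enorm ** -0.2)
                continue
            fac = 0.9 * enorm ** -0.2 if enorm > 0 else 5.0
            h_next = min(h * min(5.0, max(0.2, fac)), max_step)
        else:
            h_next = h
        t += h
        x = x5
        f = np.asarray(rhs(t, x), dtype=float)
        ts.append(t)
        xs.append(x.copy())
        fs.append(f.copy())
        h = h_next
    sol = OdeSolution(np.array(ts), np.array(xs), np.array(fs))
    return sol, (sol(np.asarray(t_eval, dtype=float)) if t_eval is not None else None)


# -- high-level trajectory container and simulation --------------------------


@dataclass
class Trajectory:
    """Uniformly sampled simulation/measurement record."""

    t: np.ndarray
    theta: np.ndarray
    theta_dot: np.ndarray
    l: np.ndarray | None = None        # (n_samples, n_muscles)
    tau_h: np.ndarray | None = None
    tau_e: np.ndarray | None = None
    muscle_names: tuple[str, ...] = ()
    dense: OdeSolution | None = field(default=None, repr=False)

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])

    def to_dataframe(self):
        import pandas as pd

        data = {"time_s": self.t, "theta_rad": self.theta,
                "theta_dot_rad_s": self.theta_dot}
        if self.tau_e is not None:
            data["tau_e_Nm"] = self.tau_e
        if self.tau_h is not None:
            data["tau_h_Nm"] = self.tau_h
        if self.l is not None:
            names = self.muscle_names or tuple(
                f"m{i}" for i in range(self.l.shape[1]))
            for i, nm in enumerate(names):
                data[f"l_{nm}"] = self.l[:, i]
        return pd.DataFrame(data)

    @classmethod
    def from_dataframe(cls, df) -> "Trajectory":
        lcols = [c for c in df.columns if c.startswith("l_")]
        return cls(
            t=df["time_s"].to_numpy(),
            theta=df["theta_rad"].to_numpy(),
            theta_dot=df["theta_dot_rad_s"].to_numpy(),
            l=df[lcols].to_numpy() if lcols else None,
            tau_h=df["tau_h_Nm"].to_numpy() if "tau_h_Nm" in df else None,
            tau_e=df["tau_e_Nm"].to_numpy() if "tau_e_Nm" in df else None,
            muscle_names=tuple(c[2:] for c in lcols),
        )


def simulate(system: MuscleJointSystem, activations, t_span, theta0,
             theta_dot0=0.0, tau_e=None, fs_out=100.0, rtol=1e-6, atol=1e-8,
             x0=None) -> Trajectory:
    """Forward-simulate the coupled system on a uniform output grid.

    ``activations`` maps t -> per-muscle activation array; ``tau_e`` (optional)
    maps t -> assist torque.  ``x0`` overrides the default passive-equilibrium
    initial state.
    """
    if x0 is None:
        x0 = system.initial_state(theta0, theta_dot0,
                                  a0=activations(t_span[0])).as_vector()
    t_eval = t_span[0] + np.arange(
        int(round((t_span[1] - t_span[0]) * fs_out)) + 1) / fs_out
    sol, xe = integrate(lambda t, x: system.rhs(t, x, activations, tau_e),
                        x0, t_span, rtol=rtol, atol=atol, t_eval=t_eval)
    n = system.n_muscles
    tau_h = np.array([system.tau_h(x, activations(t))
                      for t, x in zip(t_eval, xe)])
    tau_e_arr = (np.array([tau_e(t) for t in t_eval])
                 if tau_e is not None else np.zeros_like(t_eval))
    return Trajectory(
        t=t_eval, theta=xe[:, n], theta_dot=xe[:, n + 1], l=xe[:, :n],
        tau_h=tau_h, tau_e=tau_e_arr,
        muscle_names=tuple(m.name for m in system.muscles), dense=sol,
    )
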