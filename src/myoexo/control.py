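"""PID assist-torque control and closed-loop co-simulation.

The exoskeleton motor applies the assist torque

    tau_e(t) = Kp e(t) + Ki int_0^t e(mu) dmu + Kd de/dt,

where e(t) = theta_target(t) - theta(t).  The digital controller runs at a
fixed control rate (100 Hz default) with:

* derivative on the measurement through a first-order low-pass (10 Hz
  default) to avoid derivative kick on target steps;
* output saturation at +/- tau_max with conditional anti-windup (the
  integral freezes while the actuator is saturated);
* zero-order hold of tau_e between control ticks while the continuous plant
  (muscles + joint) is integrated with the adaptive RKF45 solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import MuscleJointSystem, Trajectory, integrate

__all__ = ["PidGains", "PidState", "pid_step", "closed_loop_simulate"]


@dataclass(frozen=True)
class PidGains:
    Kp: float = 0.0     # N m / rad
    Ki: float = 0.0     # N m / (rad s)
    Kd: float = 0.0     # N m s / rad
    tau_max: float = 30.0  # actuator saturation (N m)

    def __post_init__(self):
        if self.Kp < 0 or self.Ki < 0 or self.Kd < 0:
            raise ValueError("PID gains must be non-negative")
        if self.tau_max <= 0:
            raise ValueError("tau_max must be positive")


@dataclass
class PidState:
    """Mutable controller memory between ticks."""

    integral: float = 0.0
    d_filtered: float = 0.0


def pid_step(error, error_integral, error_derivative, gains: PidGains) -> float:
    """Saturated PID law on pre-computed error terms (stateless form)."""
    if not np.all(np.isfinite([error, error_integral, error_derivative])):
        raise ValueError("non-finite PID inputs")
    tau = (gains.Kp * error + gains.Ki * error_integral
           + gains.Kd * error_derivative)
    return float(np.clip(tau, -gains.tau_max, gains.tau_max))


def closed_loop_simulate(target, system: MuscleJointSystem, gains: PidGains,
                         t_span, activations=None, theta0=None,
                         theta_dot0=0.0, control_rate_hz=100.0,
                         derivative_cutoff_hz=10.0, rtol=1e-6, atol=1e-8,
                         ) -> Trajectory:
    """Co-simulate the PID-assisted plant tracking ``target`` theta*(t).

    ``target`` maps t -> desired angle (rad).  ``activations`` (optional)
    maps t -> per-muscle activation; default is a passive subject.  Returns
    the trajectory on the controller's tick grid, with the applied tau_e and
    the muscle torque tau_h logged.  Saturation events are recorded in
    ``trajectory.saturated`` (attribute added to the returned object).
    """
    n = system.n_muscles
    if activations is None:
        activations = lambda t: np.zeros(n)
    if theta0 is None:
        theta0 = float(target(t_span[0]))
    dt_c = 1.0 / control_rate_hz
    n_ticks = int(round((t_span[1] - t_span[0]) * control_rate_hz))
    x = system.initial_state(theta0, theta_dot0).as_vector()
    st = PidState()
    alpha_d = dt_c / (dt_c + 1.0 / (2 * np.pi * derivative_cutoff_hz))
    prev_err = float(target(t_span[0])) - x[n]
    ts = [t_span[0]]
    xs = [x.copy()]
    taus_e = []
    saturated = []
    for k in range(n_ticks):
        t_k = t_span[0] + k * dt_c
        err = float(target(t_k)) - x[n]
        raw_d = (err - prev_err) / dt_c
        st.d_filtered += alpha_d * (raw_d - st.d_filtered)
        prev_err = err
        trial_integral = st.integral + err * dt_c
        tau_unsat = (gains.Kp * err + gains.Ki * trial_integral
                     + gains.Kd * st.d_filtered)
        tau_cmd = float(np.clip(tau_unsat, -gains.tau_max, gains.tau_max))
        if tau_cmd == tau_unsat:
            st.integral = trial_integral  # anti-windup: freeze when saturated
        sat = tau_cmd != tau_unsat
        sol, _ = integrate(
            lambda t, xx: system.rhs(t, xx, activations,
                                     tau_e=lambda _t: tau_cmd),
            x, (t_k, t_k + dt_c), rtol=rtol, atol=atol)
        x = sol.xs[-1].copy()
        ts.append(t_k + dt_c)
        xs.append(x.copy())
        taus_e.append(tau_cmd)
        saturated.append(sat)
    ts = np.array(ts)
    xs = np.array(xs)
    tau_e_arr = np.array(taus_e + [taus_e[-1]])
    tau_h = np.array([system.tau_h(xx, activations(t))
                      for t, xx in zip(ts, xs)])
    traj = Trajectory(t=ts, theta=xs[:, n], theta_dot=xs[:, n + 1],
                      l=xs[:, :n], tau_h=tau_h, tau_e=tau_e_arr,
                      muscle_names=tuple(m.name for m in system.muscles))
    traj.saturated = np.array(saturated)
    return traj
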