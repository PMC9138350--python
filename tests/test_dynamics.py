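"""Rigid-body joint terms, the coupled ODE, and the RKF45 integrator."""

import numpy as np
import pytest

from myoexo import _kernels
from myoexo.dynamics import (ExoParams, MuscleJointSystem, SimState,
                             forward_accel, integrate, potential_torque,
                             simulate)
from myoexo.muscle import MuscleParams


def zero_act(n):
    return lambda t: np.zeros(n)


class TestPotentialTorque:
    def test_rest_angle_is_equilibrium(self, exo):
        assert potential_torque(exo.theta_r, exo) == 0.0

    def test_identified_constants_at_quarter_turn(self, exo):
        # K (theta-theta_r) + m g r_cm sin(theta-theta_r) at 90 deg past rest
        val = potential_torque(exo.theta_r + np.pi / 2, exo)
        expected = 1.27 * np.pi / 2 + 5.5 * 9.81 * 0.16
        assert val == pytest.approx(expected, abs=1e-9)
        assert val == pytest.approx(10.63, abs=0.01)

    def test_vanishes_without_stiffness_and_mass(self):
        p = ExoParams(K=0.0, m=0.0)
        th = np.linspace(-1, 4, 50)
        assert np.allclose(potential_torque(th, p), 0.0)


class TestForwardAccel:
    def test_rest_is_stationary(self, exo):
        assert forward_accel(0.0, exo.theta_r, 0.0, exo) == 0.0

    def test_torque_to_inertia_ratio(self):
        p = ExoParams(J=0.07, B=0.0, K=0.0, m=0.0)
        assert forward_accel(0.7, p.theta_r, 0.0, p) == pytest.approx(10.0)

    def test_static_balance(self, exo):
        th = exo.theta_r + 0.3
        tau_h = potential_torque(th, exo)
        assert forward_accel(tau_h, th, 0.0, exo) == pytest.approx(0.0, abs=1e-12)

    def test_assist_torque_enters_additively(self, exo):
        th = exo.theta_r + 0.1
        a1 = forward_accel(1.0, th, 0.2, exo, tau_e=0.5)
        a2 = forward_accel(1.5, th, 0.2, exo, tau_e=0.0)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_rejects_nonpositive_inertia(self):
        with pytest.raises(ValueError, match="inertia"):
            ExoParams(J=0.0)


class TestOdeRhs:
    def test_passive_rest_is_global_fixed_point(self, knee_system, exo):
        x0 = knee_system.initial_state(exo.theta_r).as_vector()
        f = knee_system.rhs(0.0, x0, zero_act(8))
        assert np.max(np.abs(f)) < 1e-10

    def test_doubling_inertia_halves_acceleration_only(self, knee_system, exo):
        rng = np.random.default_rng(0)
        x = knee_system.initial_state(exo.theta_r + 0.2).as_vector()
        x[:8] *= 1 + 0.03 * rng.uniform(-1, 1, 8)
        act = lambda t: np.full(8, 0.2)
        f1 = knee_system.rhs(0.0, x, act)
        sys2 = MuscleJointSystem(knee_system.muscles,
                                 ExoParams(J=2 * exo.J))
        f2 = sys2.rhs(0.0, x, act)
        assert f2[-1] == pytest.approx(f1[-1] / 2, rel=1e-12)
        assert np.allclose(f2[:-1], f1[:-1])

    def test_single_muscle_manual_composition(self, exo):
        from myoexo.muscle import (contraction_velocity,
                                   equilibrium_fiber_force, path_length)
        from myoexo.muscle import MuscleState
        m = MuscleParams.from_cm("ext", 10.0, 800.0, 20.0, 0.04, channel="X")
        sys1 = MuscleJointSystem([m], exo)
        l, th, thd, a = 0.97, exo.theta_r + 0.1, 0.3, 0.4
        x = np.array([l, th, thd])
        f = sys1.rhs(0.0, x, lambda t: np.array([a]))
        l_mt = path_length(th - exo.theta_r, m)
        f_ce, f_se, F = equilibrium_fiber_force(MuscleState(l, a), l_mt, m)
        v = contraction_velocity(l, f_ce, a, m)
        acc = forward_accel(m.moment_arm * F, th, thd, exo)
        assert f[0] == pytest.approx(v, rel=1e-12)
        assert f[1] == thd
        assert f[2] == pytest.approx(acc, rel=1e-12)

    def test_analytic_jacobians_match_complex_step(self, knee_system, exo):
        rng = np.random.default_rng(5)
        x = knee_system.initial_state(exo.theta_r).as_vector()
        x[:8] *= 1 + 0.05 * rng.standard_normal(8)
        x[8] += 0.25
        x[9] = 0.4
        act = lambda t: 0.05 + 0.2 * np.abs(np.sin(np.arange(8) + t))
        A, Fw = knee_system.jacobians(0.0, x, act)
        h = 1e-30
        for j in range(10):
            xp = x.astype(complex)
            xp[j] += 1j * h
            col = np.imag(knee_system.rhs(0.0, xp, act)) / h
            assert np.allclose(A[:, j], col, rtol=1e-9, atol=1e-9)
        om = knee_system.omega_vector()
        for j in range(24):
            d = 1e-7 * om[j]
            o1, o2 = om.copy(), om.copy()
            o1[j] -= d
            o2[j] += d
            col = (knee_system.with_omega(o2).rhs(0.0, x, act)
                   - knee_system.with_omega(o1).rhs(0.0, x, act)) / (2 * d)
            assert np.allclose(Fw[:, j], col, rtol=5e-5,
                               atol=1e-6 * np.max(np.abs(Fw)))

    def test_compiled_rhs_matches_reference(self, knee_system, exo):
        rng = np.random.default_rng(9)
        P = _kernels.pack_muscles(knee_system.muscles)
        E = _kernels.pack_exo(exo)
        tg = np.linspace(0, 1, 101)
        a_grid = np.column_stack([0.05 + 0.2 * np.abs(np.sin(tg + i))
                                  for i in range(8)] + [np.zeros(tg.size)])
        r_coef = np.zeros((4, 100))
        act = lambda t: np.array([np.interp(t, tg, a_grid[:, i])
                                  for i in range(8)])
        for _ in range(5):
            x = knee_system.initial_state(exo.theta_r).as_vector()
            x[:8] *= 1 + 0.1 * rng.uniform(-1, 1, 8)
            x[8] += rng.uniform(-0.3, 0.3)
            x[9] = rng.uniform(-1, 1)
            t = rng.uniform(0.05, 0.95)
            out = np.empty(11)
            _kernels._rhs(t, np.append(x, 0.0), out, P, E, 0.0, 0.01,
                          a_grid, 8, 0.0, 0.01, r_coef)
            ref = knee_system.rhs(t, x, act)
            assert np.allclose(out[:10], ref, rtol=1e-12, atol=1e-12)


class TestIntegrator:
    def test_small_oscillation_frequency(self, exo):
        # undamped muscle-free joint: omega^2 = (K + tau_g) / J
        p = ExoParams(B=0.0)
        sys0 = MuscleJointSystem([], p)
        amp = np.radians(2.0)
        x0 = np.array([p.theta_r + amp, 0.0])
        sol, xe = integrate(lambda t, x: sys0.rhs(t, x, zero_act(0)),
                            x0, (0.0, 3.0), rtol=1e-9, atol=1e-11,
                            t_eval=np.linspace(0, 3, 3001))
        th = xe[:, 0] - p.theta_r
        crossings = np.where(np.diff(np.sign(th)) != 0)[0]
        period = 2 * np.mean(np.diff(crossings)) * 1e-3
        w_meas = 2 * np.pi / period
        w_theory = np.sqrt((p.K + p.tau_g) / p.J)
        assert w_meas == pytest.approx(w_theory, rel=0.01)

    def test_dissipation_inequality(self, exo):
        sys0 = MuscleJointSystem([], exo)
        x0 = np.array([exo.theta_r + 0.5, 0.0])
        t_eval = np.linspace(0, 3, 301)
        _, xe = integrate(lambda t, x: sys0.rhs(t, x, zero_act(0)),
                          x0, (0.0, 3.0), rtol=1e-9, atol=1e-11,
                          t_eval=t_eval)
        d = xe[:, 0] - exo.theta_r
        energy = (0.5 * exo.J * xe[:, 1] ** 2 + 0.5 * exo.K * d**2
                  - exo.tau_g * np.cos(d))
        assert np.all(np.diff(energy) <= 1e-10)

    def test_energy_balance_matches_damping_power(self, exo):
        sys0 = MuscleJointSystem([], exo)
        x0 = np.array([exo.theta_r + 0.4, 0.0])
        t_eval = np.linspace(0, 2, 2001)
        _, xe = integrate(lambda t, x: sys0.rhs(t, x, zero_act(0)),
                          x0, (0.0, 2.0), rtol=1e-10, atol=1e-12,
                          t_eval=t_eval)
        d = xe[:, 0] - exo.theta_r
        energy = (0.5 * exo.J * xe[:, 1] ** 2 + 0.5 * exo.K * d**2
                  - exo.tau_g * np.cos(d))
        dissipated = np.trapezoid(exo.B * xe[:, 1] ** 2, t_eval)
        assert energy[0] - energy[-1] == pytest.approx(dissipated, rel=1e-6)

    def test_fifth_order_convergence_with_fixed_step(self, exo):
        p = ExoParams(B=0.2)
        sys0 = MuscleJointSystem([], p)
        x0 = np.array([p.theta_r + 0.3, 0.0])
        rhs = lambda t, x: sys0.rhs(t, x, zero_act(0))
        ref, _ = integrate(rhs, x0, (0.0, 1.0), rtol=1e-12, atol=1e-14)
        errs = []
        for h in (0.02, 0.01, 0.005):
            sol, _ = integrate(rhs, x0, (0.0, 1.0), fixed_step=h)
            errs.append(np.max(np.abs(sol.xs[-1] - ref.xs[-1])))
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders > 4.2) and np.all(orders < 6.0)

    def test_tolerance_refinement_bounds_endpoint_shift(self, exo):
        sys0 = MuscleJointSystem([], exo)
        x0 = np.array([exo.theta_r + 0.4, 0.0])
        rhs = lambda t, x: sys0.rhs(t, x, zero_act(0))
        coarse, _ = integrate(rhs, x0, (0.0, 2.0), rtol=1e-6, atol=1e-8)
        fine, _ = integrate(rhs, x0, (0.0, 2.0), rtol=5e-7, atol=5e-9)
        shift = np.max(np.abs(coarse.xs[-1] - fine.xs[-1]))
        assert shift < 1e-6 * np.max(np.abs(coarse.xs[-1])) + 1e-8

    def test_rejects_nonpositive_tolerances(self):
        with pytest.raises(ValueError, match="positive"):
            integrate(lambda t, x: -x, np.array([1.0]), (0.0, 1.0), rtol=0.0)

    def test_dense_output_matches_nodes(self, exo):
        sys0 = MuscleJointSystem([], exo)
        x0 = np.array([exo.theta_r + 0.3, 0.0])
        sol, _ = integrate(lambda t, x: sys0.rhs(t, x, zero_act(0)),
                           x0, (0.0, 1.0), rtol=1e-8, atol=1e-10)
        mid = 0.5 * (sol.ts[:-1] + sol.ts[1:])
        vals = sol(mid)
        assert vals.shape == (mid.size, 2)
        assert np.allclose(sol(sol.ts), sol.xs, atol=1e-12)


class TestSimulate:
    def test_forward_simulation_is_deterministic(self, knee_experiment):
        fix = knee_experiment
        traj2 = simulate(fix.system, fix.activations, (0.0, 4.0),
                         fix.exo.theta_r, fs_out=100.0, rtol=1e-7, atol=1e-9)
        assert np.array_equal(traj2.theta, fix.trajectory.theta)
        assert np.array_equal(traj2.l, fix.trajectory.l)

    def test_simstate_vector_round_trip(self):
        s = SimState(l=np.array([1.0, 0.9]), theta=1.2, theta_dot=-0.3)
        s2 = SimState.from_vector(s.as_vector())
        assert np.array_equal(s.l, s2.l)
        assert s.theta == s2.theta and s.theta_dot == s2.theta_dot

    def test_trajectory_dataframe_round_trip(self, knee_experiment):
        df = knee_experiment.trajectory.to_dataframe()
        from myoexo.dynamics import Trajectory
        back = Trajectory.from_dataframe(df)
        assert np.allclose(back.theta, knee_experiment.trajectory.theta)
        assert back.muscle_names == knee_experiment.trajectory.muscle_names
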