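"""Trajectory loss, adjoint gradients, and the calibration loop."""

import numpy as np
import pytest

from myoexo.adjoint import (FitProblem, adjoint_gradient, fit_parameters,
                            forward_solve, trajectory_loss)
from myoexo.dynamics import ExoParams, MuscleJointSystem, simulate
from myoexo.muscle import MuscleParams


def central_fd(problem, omega, i, h_rel):
    h = h_rel * omega[i]
    o1, o2 = omega.copy(), omega.copy()
    o1[i] -= h
    o2[i] += h
    return (forward_solve(o2, problem)[0] - forward_solve(o1, problem)[0]) / (2 * h)


def richardson_fd(problem, omega, h_rel=5e-4):
    """Central differences at h and 2h, Richardson-extrapolated."""
    g1 = np.array([central_fd(problem, omega, i, h_rel)
                   for i in range(omega.size)])
    g2 = np.array([central_fd(problem, omega, i, 2 * h_rel)
                   for i in range(omega.size)])
    return (4 * g1 - g2) / 3


class TestTrajectoryLoss:
    def test_perfect_prediction_has_zero_loss(self):
        t = np.linspace(0, 2, 201)
        y = np.sin(t)
        assert trajectory_loss(y, y, t) == 0.0

    def test_constant_offset_closed_form(self):
        t = np.linspace(0, 3, 3001)
        c = 0.4
        val = trajectory_loss(np.full(t.size, c), np.zeros(t.size), t)
        assert val == pytest.approx(c**2 * 3.0, rel=1e-9)

    def test_sine_against_zero_integrates_to_pi(self):
        t = np.linspace(0, 2 * np.pi, 20001)
        assert trajectory_loss(np.sin(t), np.zeros(t.size), t) == pytest.approx(
            np.pi, rel=1e-6)

    def test_grid_mismatch_rejected(self):
        t = np.linspace(0, 1, 11)
        with pytest.raises(ValueError, match="mismatch"):
            trajectory_loss(np.zeros(10), np.zeros(11), t)


class TestForwardSolve:
    def test_generating_parameters_reproduce_reference(self, knee_problem):
        loss, _ = forward_solve(knee_problem.system.omega_vector(),
                                knee_problem)
        assert loss < 1e-6

    def test_perturbed_parameters_increase_loss(self, knee_problem):
        om = knee_problem.system.omega_vector() * 1.1
        loss, _ = forward_solve(om, knee_problem)
        assert loss > 1e-4

    def test_vanishing_strength_gives_passive_trajectory(self, knee_experiment):
        fix = knee_experiment
        om = fix.system.omega_vector().copy()
        om[1::3] = 1e-6  # F_max ~ 0 for every muscle
        prob_a = FitProblem(system=fix.system, activations=fix.activations,
                            reference=fix.trajectory, rtol=1e-7, atol=1e-9)
        zeros = lambda t: np.zeros(8)
        prob_b = FitProblem(system=fix.system, activations=zeros,
                            reference=fix.trajectory, rtol=1e-7, atol=1e-9)
        _, sol_a = forward_solve(om, prob_a)
        _, sol_b = forward_solve(om, prob_b)
        grid = np.linspace(0, 4, 101)
        assert np.allclose(sol_a(grid)[:, 8], sol_b(grid)[:, 8], atol=1e-5)

    def test_compiled_and_reference_paths_agree(self, one_muscle_problem):
        fix_fast = one_muscle_problem
        slow = FitProblem(system=fix_fast.system,
                          activations=fix_fast.activations,
                          reference=fix_fast.reference,
                          rtol=1e-9, atol=1e-11, fast=False)
        fast = FitProblem(system=fix_fast.system,
                          activations=fix_fast.activations,
                          reference=fix_fast.reference,
                          rtol=1e-9, atol=1e-11, fast=True)
        om = fix_fast.system.omega_vector() * np.array([1.1, 0.9, 0.97])
        l_f, g_f = adjoint_gradient(om, fast)
        l_s, g_s = adjoint_gradient(om, slow)
        assert l_f == pytest.approx(l_s, rel=1e-6)
        assert np.allclose(g_f, g_s, rtol=1e-4,
                           atol=1e-7 * np.max(np.abs(g_s)))


class TestAdjointGradient:
    def test_matches_finite_differences_one_muscle(self, one_muscle_problem):
        rng = np.random.default_rng(2)
        om_true = one_muscle_problem.system.omega_vector()
        for _ in range(3):
            om = om_true * (1 + rng.uniform(-0.2, 0.2, 3))
            _, g = adjoint_gradient(om, one_muscle_problem)
            gfd = richardson_fd(one_muscle_problem, om)
            scale = np.maximum(np.abs(gfd), 1e-6 * np.max(np.abs(gfd)))
            assert np.all(np.abs(g - gfd) / scale < 1e-3)

    def test_near_zero_gradient_at_generating_optimum(self, knee_problem):
        om_true = knee_problem.system.omega_vector()
        _, g0 = adjoint_gradient(om_true, knee_problem)
        _, g1 = adjoint_gradient(om_true * 1.05, knee_problem)
        assert np.max(np.abs(g0 * om_true)) < 1e-3 * np.max(np.abs(g1 * om_true))

    def test_duplicated_muscles_share_gradient_components(self, exo):
        m = MuscleParams.from_cm("twin", 10.0, 500.0, 20.0, 0.04, channel="X")
        sys2 = MuscleJointSystem([m, m], exo)
        act = lambda t: np.full(2, 0.05 + 0.2 * np.sin(np.pi * t / 2) ** 2)
        ref = simulate(sys2, act, (0.0, 2.0), exo.theta_r, fs_out=100,
                       rtol=1e-8, atol=1e-10)
        prob = FitProblem(system=sys2, activations=act, reference=ref,
                          rtol=1e-8, atol=1e-10)
        om = sys2.omega_vector() * np.tile([1.08, 0.92, 0.98], 2)
        _, g = adjoint_gradient(om, prob)
        assert np.allclose(g[:3], g[3:], rtol=1e-9)

    def test_initial_state_sensitivity_matches_finite_differences(
            self, one_muscle_problem):
        sysw = one_muscle_problem.system
        th0, _ = one_muscle_problem.initial_joint_state()
        a0 = one_muscle_problem.gridded_activations(0.0)
        S = sysw.initial_state_sensitivity(th0, a0=a0)
        om = sysw.omega_vector()
        for j in range(3):
            d = 1e-7 * om[j]
            o1, o2 = om.copy(), om.copy()
            o1[j] -= d
            o2[j] += d
            l1 = sysw.with_omega(o1).initial_state(th0, 0.0, a0).l
            l2 = sysw.with_omega(o2).initial_state(th0, 0.0, a0).l
            fd = (l2 - l1) / (2 * d)
            assert np.allclose(S[0, j], fd[0], rtol=1e-5, atol=1e-8)

    def test_descent_direction(self, one_muscle_problem):
        om = one_muscle_problem.system.omega_vector() * np.array([1.1, 1.1, 0.95])
        loss, g = adjoint_gradient(om, one_muscle_problem)
        step = 1e-4 / np.max(np.abs(g * om))
        loss2, _ = forward_solve(om * np.exp(-step * g * om), one_muscle_problem)
        assert loss2 < loss


class TestFitParameters:
    def test_two_evaluations_per_iteration(self, one_muscle_problem):
        r = fit_parameters(one_muscle_problem, max_iter=3, lr=1e-3)
        assert np.all(r.eval_counts == 2)

    def test_start_at_truth_stays_at_truth(self, one_muscle_problem):
        # gradient-proportional (sgd) updates leave the optimum untouched
        om_true = one_muscle_problem.system.omega_vector()
        r = fit_parameters(one_muscle_problem, omega0=om_true, max_iter=5,
                           lr=1e-3, optimizer="sgd")
        assert np.all(r.loss_history < 1e-9)
        assert np.allclose(r.omega_hat, om_true, rtol=1e-6)

    def test_recovers_perturbed_parameters(self, one_muscle_problem):
        om0 = one_muscle_problem.system.omega_vector() * np.array(
            [1.2, 0.8, 0.96])
        r = fit_parameters(one_muscle_problem, omega0=om0, max_iter=150,
                           lr=2e-2, record_omega=True)
        assert r.loss_history[-1] < 1e-2 * r.loss_history[0]
        # velocity-matching quality: fitted trajectory close to reference
        loss, sol = forward_solve(r.omega_hat, one_muscle_problem)
        ref = one_muscle_problem.reference
        zdot = sol(ref.t)[:, -2]
        rms_err = np.sqrt(np.mean((zdot - ref.theta_dot) ** 2))
        rms_sig = np.sqrt(np.mean(ref.theta_dot**2))
        assert rms_err < 0.05 * rms_sig

    def test_rejects_bad_optimizer_and_lr(self, one_muscle_problem):
        with pytest.raises(ValueError):
            fit_parameters(one_muscle_problem, optimizer="bfgs")
        with pytest.raises(ValueError):
            fit_parameters(one_muscle_problem, lr=0.0)

    def test_parameters_stay_positive_and_bounded(self, one_muscle_problem):
        om0 = one_muscle_problem.system.omega_vector() * np.array(
            [3.0, 0.3, 1.5])
        r = fit_parameters(one_muscle_problem, omega0=om0, max_iter=30,
                           lr=5e-2, record_omega=True)
        assert np.all(r.omega_history > 0)
        nominal = one_muscle_problem.system.omega_vector()
        assert np.all(r.omega_history <= 30.0 * nominal * (1 + 1e-9))
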