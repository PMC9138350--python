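"""Hill-type muscle-tendon curves, series equilibrium, and joint torque."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myoexo.muscle import (KNEE_CHANNEL_MAP, MuscleParams, MuscleState,
                           active_force_length, c1_tendon_slope,
                           contraction_velocity, default_knee_muscles,
                           equilibrium_fiber_force,
                           isometric_equilibrium_length,
                           passive_equilibrium_length, passive_force_length,
                           path_length, tendon_force_strain, total_torque)


def simple_muscle(**kw):
    base = dict(name="m", L_star=0.10, F_max=1000.0, l_slack=0.20,
                moment_arm=0.04, l_mt0=0.30)
    base.update(kw)
    return MuscleParams(**base)


class TestActiveForceLength:
    def test_peak_at_optimal_length(self):
        assert active_force_length(1.0, 0.45) == 1.0

    def test_one_width_from_peak(self):
        g = 0.45
        assert active_force_length(1 + np.sqrt(g), g) == pytest.approx(
            np.exp(-1.0), abs=1e-14)

    def test_direct_evaluation(self):
        assert active_force_length(0.8, 0.45) == pytest.approx(
            np.exp(-0.04 / 0.45), abs=1e-14)

    def test_rejects_nonpositive_width(self):
        with pytest.raises(ValueError):
            active_force_length(1.0, 0.0)

    def test_unimodal_with_peak_at_one(self):
        l = np.linspace(0.4, 1.8, 201)
        f = active_force_length(l, 0.45)
        assert np.argmax(f) == np.argmin(np.abs(l - 1.0))
        assert np.all(np.diff(f[l < 1.0]) > 0)
        assert np.all(np.diff(f[l > 1.0]) < 0)


class TestPassiveForceLength:
    def test_zero_at_optimal_length(self):
        assert passive_force_length(1.0, 5.0, 0.6) == 0.0

    def test_unity_at_strain_scale(self):
        assert passive_force_length(1.6, 5.0, 0.6) == pytest.approx(1.0, abs=1e-14)

    def test_direct_evaluation(self):
        assert passive_force_length(1.3, 5.0, 0.6) == pytest.approx(
            np.expm1(2.5) / np.expm1(5.0), abs=1e-12)

    def test_monotone_nondecreasing(self):
        l = np.linspace(0.5, 1.8, 200)
        assert np.all(np.diff(passive_force_length(l, 5.0, 0.6)) > 0)

    def test_rejects_nonpositive_shape(self):
        with pytest.raises(ValueError):
            passive_force_length(1.0, -1.0, 0.6)


class TestTendonForceStrain:
    def test_zero_at_zero_strain(self):
        assert tendon_force_strain(0.0) == 0.0

    def test_slack_side_transmits_nothing(self):
        assert np.all(tendon_force_strain(np.array([-0.5, -0.01])) == 0.0)

    def test_continuity_anchor_at_toe_end(self):
        f_toe, eps_toe = 0.33, 0.02
        lo = tendon_force_strain(eps_toe - 1e-12, f_toe=f_toe, eps_toe=eps_toe)
        hi = tendon_force_strain(eps_toe + 1e-12, f_toe=f_toe, eps_toe=eps_toe)
        assert lo == pytest.approx(f_toe, abs=1e-9)
        assert hi == pytest.approx(f_toe, abs=1e-9)

    def test_toe_region_direct_evaluation(self):
        # 0.33 * (e^{1.5}-1) / (e^3-1)
        val = tendon_force_strain(0.01, f_toe=0.33, k_toe=3.0, eps_toe=0.02)
        assert val == pytest.approx(0.33 * np.expm1(1.5) / np.expm1(3.0),
                                    abs=1e-12)
        assert val == pytest.approx(0.060202, abs=1e-5)

    def test_default_linear_slope_matches_toe_end_slope(self):
        # C1 junction: slope continuous across eps_toe
        eps_toe = 0.02
        d = 1e-7
        lo = tendon_force_strain(eps_toe - d)
        hi = tendon_force_strain(eps_toe + d)
        slope_lo = (tendon_force_strain(eps_toe) - lo) / d
        slope_hi = (hi - tendon_force_strain(eps_toe)) / d
        assert slope_hi == pytest.approx(slope_lo, rel=1e-3)
        assert c1_tendon_slope() == pytest.approx(
            0.33 * 150 * np.exp(3.0) / np.expm1(3.0), abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-0.1, 0.2))
    def test_nondecreasing(self, eps):
        d = 1e-6
        assert tendon_force_strain(eps + d) >= tendon_force_strain(eps)


class TestContractionVelocity:
    def test_isometric_equilibrium_is_stationary(self):
        m = simple_muscle()
        a = 0.4
        fl = active_force_length(1.1, m.gamma)
        assert contraction_velocity(1.1, a * fl, a, m) == pytest.approx(0.0, abs=1e-14)

    def test_fully_active_scaling(self):
        m = simple_muscle(V_max=10.0, b_fv=1.0)
        v = contraction_velocity(1.0, 1.0 + 0.1, 1.0, m)
        assert v == pytest.approx(1.0, abs=1e-12)

    def test_quiescent_gain_is_one_quarter(self):
        m = simple_muscle(V_max=10.0, b_fv=1.0)
        assert contraction_velocity(1.0, 0.05, 0.0, m) == pytest.approx(
            0.25 * 10 * 0.05, abs=1e-12)


class TestEquilibriumFiberForce:
    def test_slack_tendon_transmits_no_force(self):
        m = simple_muscle()
        st_ = MuscleState(l=1.0, activation=0.0)
        f_ce, f_se, F = equilibrium_fiber_force(st_, m.l_slack * 0.9, m)
        assert f_se == 0.0 and F == 0.0

    def test_equilibrium_identity_no_pennation(self):
        m = simple_muscle()
        # pick a state with taut tendon; check f_ce + f_pe = f_se / cos(a)
        l_mt = m.l_slack * 1.015 + m.L_star * 1.0
        st_ = MuscleState(l=1.0, activation=0.5)
        f_ce, f_se, F = equilibrium_fiber_force(st_, l_mt, m)
        f_pe = passive_force_length(1.0, m.k_pe, m.eps_pe)
        assert f_ce + f_pe == pytest.approx(f_se, abs=1e-12)
        assert F == pytest.approx(f_se * m.F_max, abs=1e-9)

    def test_toe_region_force_composition(self):
        m = simple_muscle(F_max=2260.0, f_toe=0.33, k_toe=3.0, eps_toe=0.02)
        # tendon strain exactly 1%: l_t = 1.01 l_slack
        l_mt = 1.01 * m.l_slack + m.L_star * 1.0
        _, f_se, F = equilibrium_fiber_force(MuscleState(1.0, 0.0), l_mt, m)
        assert f_se == pytest.approx(0.060202, abs=1e-5)
        assert F == pytest.approx(0.33 * np.expm1(1.5) / np.expm1(3.0) * 2260,
                                  abs=0.01)

    def test_negative_ce_demand_clamped(self):
        # slack tendon + stretched fiber: equilibrium would need compression
        m = simple_muscle()
        st_ = MuscleState(l=1.4, activation=0.0)
        f_ce, f_se, _ = equilibrium_fiber_force(st_, m.l_slack * 0.5, m)
        assert f_se == 0.0 and f_ce == 0.0


class TestPathLengthAndTorque:
    def test_rest_angle_gives_reference_length(self):
        m = simple_muscle(l_mt0=0.45)
        assert path_length(0.0, m) == 0.45

    def test_extensor_path_shortens_with_flexion(self):
        m = simple_muscle(l_mt0=0.45, moment_arm=0.04)
        assert path_length(0.5, m) == pytest.approx(0.43, abs=1e-12)

    def test_flexor_path_lengthens_with_flexion(self):
        m = simple_muscle(l_mt0=0.45, moment_arm=-0.04)
        assert path_length(0.5, m) == pytest.approx(0.47, abs=1e-12)

    def test_all_slack_torque_is_zero(self):
        muscles = default_knee_muscles()
        states = [MuscleState(1.0, 0.0) for _ in muscles]
        assert total_torque(states, 0.0, muscles) == pytest.approx(0.0, abs=1e-9)

    def test_antagonist_cancellation(self):
        ext = simple_muscle(moment_arm=0.04)
        flex = simple_muscle(moment_arm=-0.04)
        states = [MuscleState(0.95, 0.5), MuscleState(0.95, 0.5)]
        tau = total_torque(states, 0.0, [ext, flex])
        assert tau == pytest.approx(0.0, abs=1e-9)

    def test_rejects_mismatched_lists(self):
        with pytest.raises(ValueError, match="mismatch"):
            total_torque([MuscleState(1.0, 0.0)], 0.0, default_knee_muscles())


class TestEquilibriumSolve:
    def test_passive_rest_state_is_slack_onset(self):
        m = simple_muscle()
        assert passive_equilibrium_length(0.0, m) == pytest.approx(1.0, abs=1e-9)

    def test_active_equilibrium_balances_tendon_and_fiber(self):
        m = simple_muscle()
        a = 0.3
        l_eq = isometric_equilibrium_length(0.0, m, activation=a)
        eps = (path_length(0.0, m) - m.L_star * l_eq - m.l_slack) / m.l_slack
        f_se = tendon_force_strain(eps, m.f_toe, m.k_toe, m.k_lin, m.eps_toe)
        f_m = (passive_force_length(l_eq, m.k_pe, m.eps_pe)
               + a * active_force_length(l_eq, m.gamma))
        assert f_se == pytest.approx(f_m, abs=1e-12)

    def test_fiber_dynamics_relax_to_isometric_fixed_point(self):
        # integrate dl/dt = v at constant activation and fixed path length
        m = simple_muscle()
        a = 0.4
        l = 1.2
        l_mt = path_length(0.0, m)
        dt = 1e-4
        for _ in range(40000):
            f_ce, _, _ = equilibrium_fiber_force(MuscleState(l, a), l_mt, m)
            l += dt * contraction_velocity(l, f_ce, a, m)
        f_ce, _, _ = equilibrium_fiber_force(MuscleState(l, a), l_mt, m)
        assert f_ce == pytest.approx(a * active_force_length(l, m.gamma),
                                     rel=1e-6)
        assert l == pytest.approx(isometric_equilibrium_length(0.0, m, a),
                                  rel=1e-6)


def test_force_velocity_inverse_round_trip():
    # Solve the force-velocity relation for f_ce from v and recover v
    m = simple_muscle()
    rng = np.random.default_rng(1)
    for _ in range(20):
        l = rng.uniform(0.7, 1.3)
        a = rng.uniform(0.05, 1.0)
        f_ce = rng.uniform(0.0, 1.2)
        v = contraction_velocity(l, f_ce, a, m)
        f_back = a * active_force_length(l, m.gamma) \
            + v * m.b_fv / ((0.25 + 0.75 * a) * m.V_max)
        assert abs(f_back - f_ce) <= 1e-10 * max(1.0, abs(f_ce))


def test_default_knee_model_structure():
    muscles = default_knee_muscles()
    assert len(muscles) == 8
    by_channel = {}
    for m in muscles:
        by_channel.setdefault(m.channel, []).append(m.name)
    assert set(by_channel) == {"RF", "VM", "ST", "BF"}
    for ch, names in KNEE_CHANNEL_MAP.items():
        assert tuple(by_channel[ch]) == names
    for m in muscles:
        sign = 1 if m.channel in ("RF", "VM") else -1
        assert np.sign(m.moment_arm) == sign
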