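"""Pendulum dynamics, reaction forces, admissible torque and integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stsbalance import (
    InertiaProfile,
    PendulumState,
    admissible_torque_range,
    angular_acceleration,
    map_to_state,
    margin_policy,
    reaction_forces,
    simulate,
    step,
)
from stsbalance.pendulum import G_ACCEL


def brute_force_torque_range(state, profile, subject, n=40001):
    """Independent oracle: scan the physiological tau interval and test every
    physical constraint directly (division-form CoP, no affine rewriting)."""
    taus = np.linspace(-subject.tau_df_max, subject.tau_pf_max, n)
    ok = np.zeros(n, dtype=bool)
    for i, tau in enumerate(taus):
        alpha = angular_acceleration(state, float(tau), profile)
        fx, fz = reaction_forces(state, alpha, profile)
        if fz <= 0 or abs(fx) > subject.mu * fz:
            continue
        cop = (tau - fx * subject.ankle_height) / fz
        ok[i] = -subject.d_heel <= cop <= subject.d_toe
    if not ok.any():
        return None
    return float(taus[ok][0]), float(taus[ok][-1])


class TestAngularAcceleration:
    def test_gravity_balancing_torque_gives_zero(self, const_profile):
        st_ = PendulumState(1.2, 0.0)
        tau = const_profile.mass * G_ACCEL * const_profile.a4 * np.cos(1.2)
        assert angular_acceleration(st_, tau, const_profile, "simple") == pytest.approx(0.0, abs=1e-12)

    @given(theta=st.floats(0.5, 2.6), omega=st.floats(-3, 3), tau=st.floats(-100, 200))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_variable_reduces_to_simple_for_constant_l(self, theta, omega, tau):
        prof = InertiaProfile.constant(0.9, 70.0, 0.2, 2.9)
        s = PendulumState(theta, omega)
        a_simple = angular_acceleration(s, tau, prof, "simple")
        a_var = angular_acceleration(s, tau, prof, "variable")
        assert a_var == pytest.approx(a_simple, rel=1e-10, abs=1e-10)

    def test_simple_model_requires_constant_profile(self, var_profile):
        with pytest.raises(ValueError, match="constant"):
            angular_acceleration(PendulumState(1.5, 0.0), 0.0, var_profile, "simple")

    def test_momentum_theorem_along_trajectory(self, subject, var_profile):
        """d(I*omega)/dt equals the net ankle+gravity torque (finite-diff
        oracle for the variable-inertia equation of motion)."""
        policy = margin_policy(subject, var_profile)
        state0 = map_to_state(1.8, 0.4, subject, var_profile)
        res = simulate(state0, policy, var_profile, subject, 1e-3, 600)
        L = var_profile.inertia(res.theta) * res.omega
        dL = (L[2:] - L[:-2]) / (res.time[2:] - res.time[:-2])
        tau_node = 0.5 * (res.tau[1:] + res.tau[:-1])
        grav = (var_profile.mass * G_ACCEL * var_profile.l(res.theta[1:-1])
                * np.cos(res.theta[1:-1]))
        resid = np.abs(dL - (tau_node - grav))
        assert resid.max() < 1e-4 * np.max(np.abs(tau_node - grav))


class TestReactionForces:
    def test_static_upright(self, const_profile):
        fx, fz = reaction_forces(PendulumState(np.pi / 2, 0.0), 0.0, const_profile)
        assert fx == pytest.approx(0.0, abs=1e-9)
        assert fz == pytest.approx(const_profile.mass * G_ACCEL)

    @given(theta=st.floats(0.5, 2.5), alpha=st.floats(-10, 10))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_circular_motion_limit(self, theta, alpha):
        """Constant l, omega=0: point-mass circular-motion formulas."""
        prof = InertiaProfile.constant(0.9, 70.0, 0.2, 2.9)
        fx, fz = reaction_forces(PendulumState(theta, 0.0), alpha, prof)
        l, m = prof.a4, prof.mass
        assert fx == pytest.approx(-m * l * np.sin(theta) * alpha, rel=1e-10, abs=1e-8)
        assert fz == pytest.approx(m * (G_ACCEL + l * np.cos(theta) * alpha),
                                   rel=1e-10, abs=1e-8)

    def test_impulse_momentum(self, subject, var_profile):
        """Integral of Fx over a simulated interval equals m * delta(u_dot)."""
        policy = margin_policy(subject, var_profile)
        state0 = map_to_state(1.6, 0.35, subject, var_profile)
        res = simulate(state0, policy, var_profile, subject, 5e-4, 1000)
        from stsbalance.pendulum import _kinematic_coeffs

        fxs = []
        for th, om, tau in zip(res.theta, res.omega, np.append(res.tau, res.tau[-1])):
            alpha = angular_acceleration(PendulumState(th, om), tau, var_profile)
            fx, _ = reaction_forces(PendulumState(th, om), alpha, var_profile)
            fxs.append(fx)
        impulse = np.trapezoid(fxs, res.time)
        _, B0, _, _ = _kinematic_coeffs(res.theta[0], var_profile)
        _, B1, _, _ = _kinematic_coeffs(res.theta[-1], var_profile)
        dp = var_profile.mass * (B1 * res.omega[-1] - B0 * res.omega[0])
        assert impulse == pytest.approx(dp, rel=5e-3, abs=1e-2)


class TestAdmissibleTorqueRange:
    def test_contains_equilibrium_torque(self, subject, const_profile):
        # CM over the BOS: holding still is admissible
        s = PendulumState(1.45, 0.0)
        tau_eq = const_profile.mass * G_ACCEL * const_profile.a4 * np.cos(1.45)
        rng = admissible_torque_range(s, const_profile, subject)
        assert rng.feasible and rng.contains(tau_eq)

    @pytest.mark.parametrize("theta,omega", [
        (1.2, 0.0), (1.2, -1.5), (1.8, -0.8), (2.1, -2.0), (1.5, 1.0), (2.3, 0.5),
    ])
    def test_matches_brute_force_scan(self, subject, var_profile, theta, omega):
        s = PendulumState(theta, omega)
        rng = admissible_torque_range(s, var_profile, subject)
        brute = brute_force_torque_range(s, var_profile, subject)
        tau_step = (subject.tau_pf_max + subject.tau_df_max) / 40000
        if brute is None:
            assert (not rng.feasible) or (rng.tau_hi - rng.tau_lo) < 2 * tau_step
        else:
            assert rng.feasible
            assert rng.tau_lo == pytest.approx(brute[0], abs=2 * tau_step)
            assert rng.tau_hi == pytest.approx(brute[1], abs=2 * tau_step)

    def test_zero_friction_collapses_horizontal_force(self, subject, const_profile):
        from dataclasses import replace

        sub0 = replace(subject, mu=0.0)
        s = PendulumState(1.9, -1.0)  # needs horizontal force to brake
        rng = admissible_torque_range(s, const_profile, sub0)
        brute = brute_force_torque_range(s, const_profile, sub0, n=100001)
        if brute is None:
            assert (not rng.feasible) or (rng.tau_hi - rng.tau_lo) < 0.05
        else:
            assert rng.tau_hi - rng.tau_lo == pytest.approx(brute[1] - brute[0], abs=0.05)

    def test_zero_torque_limits_dominate(self, subject, const_profile):
        from dataclasses import replace

        sub0 = replace(subject, tau_pf_max=0.0, tau_df_max=0.0)
        rng = admissible_torque_range(PendulumState(1.5, 0.0), const_profile, sub0)
        if rng.feasible:
            assert rng.tau_lo == pytest.approx(0.0, abs=1e-12)
            assert rng.tau_hi == pytest.approx(0.0, abs=1e-12)

    @given(theta=st.floats(1.1, 2.3), omega=st.floats(-2.5, 1.5),
           scale=st.floats(1.05, 3.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_relaxing_limits_never_shrinks_interval(self, subject, var_profile,
                                                    theta, omega, scale):
        from dataclasses import replace

        s = PendulumState(theta, omega)
        r0 = admissible_torque_range(s, var_profile, subject)
        bigger = replace(subject, mu=subject.mu * scale,
                         tau_pf_max=subject.tau_pf_max * scale,
                         tau_df_max=subject.tau_df_max * scale)
        r1 = admissible_torque_range(s, var_profile, bigger)
        if r0.feasible:
            assert r1.feasible
            assert r1.tau_lo <= r0.tau_lo + 1e-9
            assert r1.tau_hi >= r0.tau_hi - 1e-9

    def test_outside_domain_raises(self, subject, var_profile):
        with pytest.raises(ValueError, match="domain"):
            admissible_torque_range(PendulumState(0.1, 0.0), var_profile, subject)


class TestIntegration:
    def test_zero_torque_energy_conservation(self, unconstrained_subject):
        prof = InertiaProfile.constant(0.9, 70.0, 0.2, 2.9)
        res = simulate(PendulumState(np.pi / 2 + 0.05, 0.0), lambda s: 0.0,
                       prof, unconstrained_subject, 1e-4, 10000)
        assert res.status == "ok" and res.clamped == 0
        energy = 0.5 * prof.a4**2 * res.omega**2 + G_ACCEL * prof.a4 * np.sin(res.theta)
        assert np.max(np.abs(energy - energy[0])) / abs(energy[0]) < 1e-8

    def test_gravity_balancing_policy_holds_state(self, subject, const_profile):
        s0 = PendulumState(1.4, 0.0)
        tau_eq = const_profile.mass * G_ACCEL * const_profile.a4 * np.cos(1.4)
        s1 = step(s0, lambda s: tau_eq, const_profile, subject, 1e-3)
        assert s1.theta == pytest.approx(s0.theta, abs=1e-12)
        assert s1.omega == pytest.approx(0.0, abs=1e-12)

    def test_fourth_order_convergence(self, unconstrained_subject):
        prof = InertiaProfile.constant(0.9, 70.0, 0.2, 2.9)
        s0 = PendulumState(1.8, -0.5)

        def final(dt, n):
            r = simulate(s0, lambda s: 10.0, prof, unconstrained_subject, dt, n)
            return np.array([r.theta[-1], r.omega[-1]])

        ref = final(5e-4, 1000)
        e1 = np.linalg.norm(final(2e-3, 250) - ref)
        e2 = np.linalg.norm(final(1e-3, 500) - ref)
        order = np.log2(e1 / e2)
        assert 3.5 < order < 4.6

    def test_infeasibility_is_labeled(self, subject, const_profile):
        # far posterior at rest: backward fall that no ankle torque can stop
        s0 = map_to_state(2.9, 0.0, subject, const_profile)
        res = simulate(s0, lambda s: 0.0, const_profile, subject, 1e-3, 3000)
        assert res.status in ("slip", "tip", "torque-limit", "contact", "domain")

    def test_clamping_is_counted(self, subject, const_profile):
        s0 = PendulumState(1.4, 0.0)
        res = simulate(s0, lambda s: 1e5, const_profile, subject, 1e-3, 10)
        assert res.clamped == 10
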