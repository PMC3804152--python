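"""Balance-map boundaries, zero-torque curve, classification, similarity."""

from dataclasses import replace

import numpy as np
import pytest

from stsbalance import (
    InertiaProfile,
    admissible_torque_range,
    classify_state,
    compute_balance_map,
    make_inertia_profile,
    map_similarity,
    map_to_state,
    region_area,
    state_to_map,
    validity_velocity,
    zero_torque_curve,
)
from stsbalance.pendulum import G_ACCEL


def closed_form_zero_torque_v(x, subject, length):
    """Energy conservation to the upright rest state for the simple model:
    0.5*l^2*omega^2 + g*l*sin(theta) = g*l."""
    u = subject.d_toe - np.asarray(x) * subject.foot_length
    theta = np.arccos(np.clip(u / length, -1.0, 1.0))
    omega = np.sqrt(2.0 * G_ACCEL * (1.0 - np.sin(theta)) / length)
    return length * np.sin(theta) * omega / subject.height


class TestCoordinates:
    def test_roundtrip_exact(self, subject, var_profile):
        for x, v in [(0.3, 0.1), (1.5, 0.4), (2.0, -0.2)]:
            s = map_to_state(x, v, subject, var_profile)
            x2, v2 = state_to_map(s, subject, var_profile)
            assert x2 == pytest.approx(x, abs=1e-9)
            assert v2 == pytest.approx(v, abs=1e-9)


class TestBoundaries:
    def test_terminal_conditions(self, subject, map_simple):
        assert float(map_simple.upper_at(0.0)) == pytest.approx(0.0, abs=1e-6)
        assert float(map_simple.lower_at(1.0)) == pytest.approx(0.0, abs=1e-6)

    def test_boundary_order_and_zero_torque_inside(self, map_var):
        m = (np.isfinite(map_var.v_upper) & np.isfinite(map_var.v_lower)
             & np.isfinite(map_var.v_zero))
        assert np.all(map_var.v_lower[m] <= map_var.v_upper[m] + 1e-12)
        inner = m & (map_var.x > 0.15) & (map_var.x < 1.9)
        assert np.all(map_var.v_zero[inner] < map_var.v_upper[inner])
        assert np.all(map_var.v_zero[inner] > map_var.v_lower[inner])

    def test_constant_profile_reduction(self, subject, const_profile, map_simple):
        bmap_v = compute_balance_map(subject, const_profile, model="variable")
        for a, b in [(bmap_v.v_upper, map_simple.v_upper),
                     (bmap_v.v_lower, map_simple.v_lower),
                     (bmap_v.v_zero, map_simple.v_zero)]:
            m = np.isfinite(a) & np.isfinite(b)
            assert m.sum() > 300
            assert np.max(np.abs(a[m] - b[m])) < 1e-6

    def test_raising_dorsiflexion_lowers_lower_boundary(self, subject, var_profile):
        weak = replace(subject, tau_df_max=0.4 * subject.mass)
        b_weak = compute_balance_map(subject=weak, profile=var_profile)
        b_strong = compute_balance_map(subject=subject, profile=var_profile)
        m = (np.isfinite(b_weak.v_lower) & np.isfinite(b_strong.v_lower)
             & (b_weak.x > 1.05))
        assert np.all(b_strong.v_lower[m] <= b_weak.v_lower[m] + 1e-9)

    def test_grid_refinement_convergence(self, subject, var_profile):
        coarse = compute_balance_map(subject, var_profile, n_theta=200)
        mid = compute_balance_map(subject, var_profile, n_theta=400)
        fine = compute_balance_map(subject, var_profile, n_theta=1600)
        m = (np.isfinite(coarse.v_upper) & np.isfinite(mid.v_upper)
             & np.isfinite(fine.v_upper))
        e_coarse = np.max(np.abs(coarse.v_upper[m] - fine.v_upper[m]))
        e_mid = np.max(np.abs(mid.v_upper[m] - fine.v_upper[m]))
        assert e_mid < e_coarse
        assert e_mid < 1e-4

    def test_region_sandwich_states_are_controllable(self, subject, var_profile, map_var):
        """Every state strictly inside the boundaries admits a torque."""
        rng = np.random.default_rng(5)
        count = 0
        while count < 50:
            x = rng.uniform(0.0, 1.9)
            v = rng.uniform(-0.3, 0.8)
            lo = float(map_var.lower_at(x))
            hi = float(map_var.upper_at(x))
            if not (lo + 0.02 < v < hi - 0.02):
                continue
            count += 1
            s = map_to_state(x, v, subject, var_profile)
            assert admissible_torque_range(s, var_profile, subject).feasible


class TestZeroTorque:
    def test_matches_closed_form_simple_model(self, subject, const_profile, map_simple):
        x_eq = subject.d_toe / subject.foot_length
        m = np.isfinite(map_simple.v_zero) & (map_simple.x > x_eq + 0.02)
        v_cf = closed_form_zero_torque_v(map_simple.x[m], subject, const_profile.a4)
        assert np.max(np.abs(map_simple.v_zero[m] - v_cf)) < 1e-6

    def test_zero_velocity_at_equilibrium_ordinate(self, subject, map_simple):
        x_eq = subject.d_toe / subject.foot_length
        assert abs(float(map_simple.zero_at(x_eq))) < 1e-3

    def test_eps_robustness(self, subject, var_profile):
        x1, v1 = zero_torque_curve(subject, var_profile, eps=1e-6)
        x2, v2 = zero_torque_curve(subject, var_profile, eps=5e-7)
        c1 = np.isin(np.round(x1, 14), np.round(x2, 14))
        c2 = np.isin(np.round(x2, 14), np.round(x1, 14))
        assert c1.sum() > 1000
        assert np.max(np.abs(v1[c1] - v2[c2])) < 1e-8

    def test_equilibrium_outside_domain_raises(self, subject):
        prof = InertiaProfile.constant(0.9, subject.mass, 1.8, 2.6)
        with pytest.raises(ValueError, match="equilibrium"):
            zero_torque_curve(subject, prof)


class TestClassifyState:
    def test_boundary_point_is_unstable(self, map_var):
        x = 1.0
        v_on = float(map_var.upper_at(x))
        assert classify_state(x, v_on, 0.0, map_var) == "unstable"

    def test_interior_point_is_stable(self, map_var):
        assert classify_state(1.0, 0.2, 0.0, map_var) == "stable"

    def test_error_bar_must_fit(self, map_var):
        x = 1.0
        v = float(map_var.upper_at(x)) - 0.01
        assert classify_state(x, v, 0.0, map_var) == "stable"
        # wide error bar reaches past the boundary at larger x
        assert classify_state(x, v, 0.3, map_var) == "unstable"

    def test_outside_range_raises(self, map_var):
        with pytest.raises(ValueError, match="outside"):
            classify_state(5.0, 0.1, 0.0, map_var)


class TestAreaMonotonicity:
    @pytest.mark.parametrize("param", ["mu", "tau_pf_max", "tau_df_max"])
    def test_area_grows_with_constraint_relaxation(self, subject, var_profile, param):
        areas = []
        for f in (0.5, 1.0, 1.5):
            sub = replace(subject, **{param: getattr(subject, param) * f})
            bmap = compute_balance_map(sub, var_profile)
            # fixed window: coverage ends differ between parameter levels
            areas.append(region_area(bmap, x_window=(-0.2, 1.9)))
        assert areas[0] <= areas[1] + 1e-9 <= areas[2] + 2e-9


class TestSimilarity:
    def test_self_similarity_is_one(self, map_var):
        v = np.linspace(0.0, 0.4, 20)
        sim = map_similarity(map_var, map_var, v)
        assert np.nanmax(np.abs(sim - 1.0)) < 1e-12

    def test_width_at_zero_velocity_is_bos(self, map_var):
        assert float(map_var.tolerance_width(np.array(0.0))) == pytest.approx(1.0, abs=0.01)

    def test_validity_velocity_decreases_with_variation(self, subject):
        vstars = []
        for var in (0.1, 0.25, 0.4):
            prof = make_inertia_profile(subject, var)
            bm_var = compute_balance_map(subject, prof, model="variable")
            bm_simple = compute_balance_map(subject, prof, model="simple")
            vstar = validity_velocity(bm_simple, bm_var, threshold=0.85)
            assert np.isfinite(vstar) and vstar > 0
            vstars.append(vstar)
        assert vstars[0] > vstars[1] > vstars[2]
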