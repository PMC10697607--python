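"""Hydrodynamic forces, torques and coefficient correlations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctenoswim import (BeatParams, Morphometry, build_body,
                       build_rotation_matrix, default_coefficients,
                       net_force, propulsive_torque, body_drag,
                       added_mass_force, opposing_torque, row_force,
                       tip_state, phase_offset)
from ctenoswim.hydro import (FluidProperties, ctene_force, prolate_added_mass,
                             stokes_shape_factors, stokes_torque_ratios)
from ctenoswim.kinematics import PlateState
from ctenoswim.geometry import CtenePlacement


def _sphere_body():
    return build_body(Morphometry(L_B=6.0e-3, d_B=6.0e-3))


def _placement(lam=0.3, eps=0.4, r=(0.001, 0.002, 0.0)):
    return CtenePlacement(row_id=0, k=1, r_prime=np.array(r), lam=lam, eps=eps)


class TestPlateForce:
    def test_stationary_plates_give_zero(self, fluid, coeffs):
        st_ = PlateState(0.0, 0.5e-3, 0.0, 0.0, 0.25e-3)
        F = row_force([_placement()] * 3, [st_] * 3, np.zeros(3), np.eye(3),
                      fluid, coeffs)
        assert np.allclose(F, 0.0)

    def test_single_plate_static_body_closed_form(self, fluid, coeffs):
        """|F| = (rho w / 2) y_A C_A u^2, directed opposite u."""
        u_tip, y_A, w = 0.08, 0.45e-3, 0.25e-3
        st_ = PlateState(x_A=0.0, y_A=y_A, x_A_dot=u_tip, y_A_dot=0.0, w=w)
        pl = _placement(lam=math.pi / 2, eps=0.0)  # u along +y
        F = ctene_force(pl, st_, np.zeros(3), np.eye(3), fluid, coeffs)
        C_A = coeffs.C_A(u_tip * y_A / fluid.nu)
        expected = fluid.rho * w / 2 * y_A * C_A * u_tip**2
        assert F[1] == pytest.approx(-expected, rel=1e-12)
        assert abs(F[0]) < 1e-15 * expected and abs(F[2]) < 1e-15 * expected

    def test_cycle_average_thrust_points_oral(self, morph, fluid, coeffs):
        """With Ta = Sa = 0.3 the stroke asymmetry yields net oral-ward
        (+x) thrust on a static body — the propulsion mechanism."""
        beat = BeatParams(f=30.0)
        pl = _placement(lam=0.6, eps=0.0, r=(-0.002, 0.002, 0.0))
        tgrid = np.linspace(0, 1 / 30.0, 4000, endpoint=False)
        F = np.zeros(3)
        for t in tgrid:
            s = tip_state(t, beat, morph.l)
            F += ctene_force(pl, s, np.zeros(3), np.eye(3), fluid, coeffs)
        F /= len(tgrid)
        assert F[0] > 0
        assert abs(F[0]) > 10 * abs(F[2])

    def test_reversed_stroke_thrust_points_aboral(self, morph, fluid, coeffs):
        beat = BeatParams(f=30.0, direction=-1)
        pl = _placement(lam=0.6, eps=0.0)
        tgrid = np.linspace(0, 1 / 30.0, 4000, endpoint=False)
        F = sum(ctene_force(pl, tip_state(t, beat, morph.l), np.zeros(3),
                            np.eye(3), fluid, coeffs) for t in tgrid)
        assert F[0] < 0


class TestNetForceAndTorque:
    def test_mirror_pair_lateral_cancellation(self, morph, fluid, coeffs):
        beat = BeatParams(f=30.0)
        t = 0.011
        s = tip_state(t, beat, morph.l)
        pl_a = _placement(lam=0.6, eps=0.4, r=(-0.002, 0.002, 0.001))
        pl_b = _placement(lam=0.6, eps=-0.4, r=(-0.002, 0.002, -0.001))
        Fa = ctene_force(pl_a, s, np.zeros(3), np.eye(3), fluid, coeffs)
        Fb = ctene_force(pl_b, s, np.zeros(3), np.eye(3), fluid, coeffs)
        F = net_force([Fa, Fb])
        assert abs(F[2]) < 1e-12 * np.linalg.norm(Fa)
        assert F[0] == pytest.approx(2 * Fa[0], rel=1e-12)

    def test_net_force_equals_per_ctene_sum(self, placements, morph, fluid,
                                            coeffs, rng):
        """Row-wise accumulation equals brute-force per-ctene accumulation."""
        beat = BeatParams(f=30.0)
        R = build_rotation_matrix(*rng.normal(0, 0.5, 3))
        vel = rng.normal(0, 0.01, 3)
        t = 0.0173
        forces = []
        for pl in placements:
            s = tip_state(t, beat, morph.l, phase_offset(pl.k, beat))
            forces.append(ctene_force(pl, s, vel, R, fluid, coeffs))
        brute = np.sum(forces, axis=0)
        by_rows = np.zeros(3)
        for row_id in range(8):
            row = [pl for pl in placements if pl.row_id == row_id]
            states = [tip_state(t, beat, morph.l, phase_offset(pl.k, beat))
                      for pl in row]
            by_rows += row_force(row, states, vel, R, fluid, coeffs)
        assert np.allclose(by_rows, brute, rtol=1e-10, atol=1e-20)

    def test_torque_zero_for_central_force(self, coeffs):
        pl = _placement(r=(0.0, 0.002, 0.0))
        F_body = np.array([0.0, 3e-6, 0.0])  # parallel to r'
        T = propulsive_torque([pl], [F_body], np.eye(3))
        assert np.allclose(T, 0.0)

    def test_torque_full_symmetry_cancels(self, placements, morph, fluid,
                                          coeffs):
        """All eight rows beating identically produce no net torque."""
        beat = BeatParams(f=30.0)
        t = 0.0234
        forces = [ctene_force(pl, tip_state(t, beat, morph.l,
                                            phase_offset(pl.k, beat)),
                              np.zeros(3), np.eye(3), fluid, coeffs)
                  for pl in placements]
        T = propulsive_torque(placements, forces, np.eye(3))
        scale = np.abs(forces).max() * morph.L_B
        assert np.linalg.norm(T) < 1e-12 * scale * len(placements)

    def test_one_sided_rows_turn_away_from_active_side(self, placements,
                                                       morph, fluid, coeffs):
        """Rows active in the +y/+z quadrant torque the nose toward the
        opposite quadrant (outside rows beat faster during a turn)."""
        beat = BeatParams(f=30.0)
        active = [pl for pl in placements if pl.row_id in (0, 1)]
        tgrid = np.linspace(0, 1 / 30.0, 2000, endpoint=False)
        T = np.zeros(3)
        for t in tgrid:
            forces = [ctene_force(pl, tip_state(t, beat, morph.l,
                                                phase_offset(pl.k, beat)),
                                  np.zeros(3), np.eye(3), fluid, coeffs)
                      for pl in active]
            T += propulsive_torque(active, forces, np.eye(3))
        T /= len(tgrid)
        # thrust +x applied at +y,+z => torque turns oral axis toward -y,-z:
        # positive pitch-rate (nose toward -z) has T_y > 0; nose toward -y
        # has T_z < 0
        assert T[1] > 0 and T[2] < 0


class TestBodyDrag:
    def test_zero_velocity(self, body, fluid, coeffs):
        assert np.allclose(body_drag(np.zeros(3), np.eye(3), body, fluid,
                                     coeffs), 0.0)

    def test_axial_closed_form(self, body, fluid, coeffs):
        U = 0.015
        F = body_drag(np.array([U, 0, 0]), np.eye(3), body, fluid, coeffs)
        re = U * body.d_e / fluid.nu
        expected = 0.5 * fluid.rho * math.pi * body.a**2 * \
            coeffs.C_B_par(re) * U**2
        assert F[0] == pytest.approx(-expected, rel=1e-12)
        assert F[1] == F[2] == 0.0

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(st.lists(st.floats(-0.05, 0.05), min_size=3, max_size=3),
           st.lists(st.floats(-3, 3), min_size=3, max_size=3))
    def test_dissipativity(self, v, angles):
        body = build_body(Morphometry())
        fluid = FluidProperties()
        coeffs = default_coefficients(body)
        v = np.array(v)
        R = build_rotation_matrix(*angles)
        F = body_drag(v, R, body, fluid, coeffs)
        assert float(F @ v) <= 1e-25

    def test_frame_consistency(self, body, fluid, coeffs, rng):
        """Rotating the whole problem leaves the body-frame force invariant."""
        v = rng.normal(0, 0.01, 3)
        R = build_rotation_matrix(0.7, -0.4, 0.2)
        F_rot = body_drag(R.T @ v, R, body, fluid, coeffs)
        F_id = body_drag(v, np.eye(3), body, fluid, coeffs)
        assert np.allclose(R @ F_rot, F_id, rtol=1e-12, atol=1e-20)


class TestAddedMass:
    def test_zero_acceleration(self, body, fluid, coeffs):
        assert np.allclose(added_mass_force(np.zeros(3), np.eye(3), body,
                                            fluid, coeffs), 0.0)

    def test_sphere_half_coefficient(self, fluid):
        body = _sphere_body()
        coeffs = default_coefficients(body)
        acc = np.array([0.3, -0.2, 0.5])
        F = added_mass_force(acc, build_rotation_matrix(0.3, 0.2, 0.1),
                             body, fluid, coeffs)
        assert np.allclose(F, -0.5 * fluid.rho * body.V * acc, rtol=1e-12)

    def test_prolate_axial_below_lateral(self, body, coeffs):
        assert coeffs.C_m_par < coeffs.C_m_perp
        # Lamb closed forms at b/a = 1.2787
        cm_par, cm_perp = prolate_added_mass(body.aspect_ratio)
        assert cm_par == pytest.approx(coeffs.C_m_par)
        assert 0.0 < cm_par < 0.5 < cm_perp < 1.0


class TestOpposingTorque:
    def test_zero_rotation(self, body, fluid, coeffs):
        assert np.allclose(opposing_torque(np.zeros(3), body, fluid, coeffs),
                           0.0)

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(st.lists(st.floats(-20, 20), min_size=3, max_size=3))
    def test_opposes_each_component(self, w):
        body = build_body(Morphometry())
        coeffs = default_coefficients(body)
        T = opposing_torque(np.array(w), body, FluidProperties(), coeffs)
        for Ti, wi in zip(T, w):
            if wi != 0:
                assert Ti * wi <= 0
        assert float(T @ np.array(w)) <= 0

    def test_quadratic_scaling_at_fixed_coefficient(self, body, fluid):
        """Doubling omega quadruples the torque when C_R is held fixed."""
        from ctenoswim.hydro import CoefficientModel
        const = CoefficientModel(
            name="const", C_A=lambda re: 2.0,
            C_B_par=lambda re: 1.0, C_B_perp=lambda re: 1.0,
            C_m_par=0.5, C_m_perp=0.5,
            C_R_par=lambda re: 3.0, C_R_perp=lambda re: 3.0)
        w = np.array([1.0, -2.0, 0.5])
        T1 = opposing_torque(w, body, fluid, const)
        T2 = opposing_torque(2 * w, body, fluid, const)
        assert np.allclose(T2, 4 * T1, rtol=1e-12)


class TestDefaultCoefficients:
    def test_sphere_stokes_limit(self, fluid):
        coeffs = default_coefficients(_sphere_body())
        re = 0.01
        assert coeffs.C_B_par(re) == pytest.approx(24.0 / re, rel=0.05)
        assert coeffs.C_B_perp(re) == pytest.approx(24.0 / re, rel=0.05)

    def test_sphere_degeneracy(self):
        coeffs = default_coefficients(_sphere_body())
        for re in (5.0, 50.0, 500.0):
            assert coeffs.C_B_par(re) == pytest.approx(coeffs.C_B_perp(re))
            assert coeffs.C_R_par(re) == pytest.approx(coeffs.C_R_perp(re))
        assert coeffs.C_m_par == coeffs.C_m_perp == pytest.approx(0.5)

    def test_body_drag_monotone_decreasing_in_re(self, coeffs):
        values = [coeffs.C_B_par(re) for re in (10.0, 100.0, 1000.0)]
        assert values[0] > values[1] > values[2]
        values = [coeffs.C_B_perp(re) for re in (10.0, 100.0, 1000.0)]
        assert values[0] > values[1] > values[2]

    def test_all_coefficients_nonnegative(self, coeffs):
        for re in (1.0, 30.0, 900.0):
            for fn in (coeffs.C_A, coeffs.C_B_par, coeffs.C_B_perp,
                       coeffs.C_R_par, coeffs.C_R_perp):
                assert fn(re) >= 0

    def test_shape_factors_sphere_limit(self):
        assert stokes_shape_factors(1.0) == (1.0, 1.0)
        assert stokes_torque_ratios(1.0) == (1.0, 1.0)
        kp, kt = stokes_shape_factors(1.5)
        assert 0 < kp < kt  # axial drag below transverse for prolate
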