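"""Closed-form profiles and hemodynamic post-processing."""

import numpy as np
import pytest
import scipy.integrate

import stenoflow as sf
from stenoflow.analytics import observed_order
from tests.conftest import MU_REF, STRAIGHT_GEOM, STRAIGHT_PM


class TestAnalyticProfiles:
    def test_no_slip_at_the_wall(self):
        assert sf.analytic_poiseuille(1.0, 4.0, 1.0, 1.0) == 0.0
        assert sf.analytic_mhd_pipe_profile(1.0, 1.0, 1.0, 1.0, 10.0) == pytest.approx(
            0.0, abs=1e-15
        )

    def test_poiseuille_centerline_value(self):
        assert sf.analytic_poiseuille(0.0, 4.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_poiseuille_flow_rate_quadrature(self):
        G, mu, R = 4.0, 1.0, 1.0
        r = np.linspace(0, R, 20001)
        Q = scipy.integrate.trapezoid(
            2 * np.pi * r * sf.analytic_poiseuille(r, G, mu, R), r
        )
        assert Q == pytest.approx(np.pi * G * R**4 / (8 * mu), rel=1e-8)

    def test_hartmann_profile_centerline_bessel_value(self):
        # u(0) = (G R^2/(mu Ha^2)) (1 - 1/I0(Ha)) at Ha = 10
        from scipy.special import i0

        expected = (1.0 / 100.0) * (1.0 - 1.0 / i0(10.0))
        assert sf.analytic_mhd_pipe_profile(0.0, 1.0, 1.0, 1.0, 10.0) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(9.9964e-3, rel=1e-4)

    def test_small_hartmann_limit_recovers_poiseuille(self):
        r = np.linspace(0.0, 1.0, 33)
        u_ha = sf.analytic_mhd_pipe_profile(r, 4.0, 1.0, 1.0, 0.01)
        u_p = sf.analytic_poiseuille(r, 4.0, 1.0, 1.0)
        assert np.max(np.abs(u_ha - u_p)) / np.max(u_p) < 1e-3

    def test_negative_hartmann_rejected(self):
        with pytest.raises(ValueError):
            sf.analytic_mhd_pipe_profile(0.5, 1.0, 1.0, 1.0, -1.0)


class TestWallShearStress:
    def test_zero_flow_gives_zero_stress(self):
        mesh, _ = sf.make_fixture("tiny_stenosis", 0)
        state = sf.SimState.zeros(mesh.n_cells, 0.056)
        wp = sf.wall_shear_stress(state, mesh)
        assert np.all(wp.tau == 0.0)

    def test_poiseuille_wall_stress(self, straight_tube_solutions):
        solver, state = straight_tube_solutions[0.0]
        wp = sf.wall_shear_stress(state, solver.mesh)
        G = STRAIGHT_PM / STRAIGHT_GEOM.L_vessel
        mid = np.argmin(np.abs(wp.z - 0.025))
        assert wp.tau[mid] == pytest.approx(G * STRAIGHT_GEOM.R0 / 2.0, rel=0.02)

    def test_stress_peaks_near_throat_and_drops_after(self, stenosis50_steady):
        sc, solver, state = stenosis50_steady
        wp = sf.wall_shear_stress(state, solver.mesh, sc.fluid.carreau)
        z_peak = wp.z[np.argmax(np.abs(wp.tau))]
        throat = sc.geometry.throat_z
        assert abs(z_peak - throat) < 0.35 * sc.geometry.L0
        # drastic post-throat drop: far-downstream stress well below the peak
        post = np.abs(wp.tau[wp.z > throat + 0.75 * sc.geometry.L0])
        assert np.max(post) < 0.3 * wp.tau_max


class TestFlowResistance:
    def test_straight_tube_matches_poiseuille_law(self, straight_tube_solutions):
        solver, state = straight_tube_solutions[0.0]
        _, lamz, lam = sf.flow_resistance(state, solver.mesh, p_inlet=STRAIGHT_PM)
        expected = 8.0 * MU_REF * STRAIGHT_GEOM.L_vessel / (np.pi * STRAIGHT_GEOM.R0**4)
        assert lam == pytest.approx(expected, rel=0.02)

    def test_cumulative_resistance_nondecreasing(self, straight_tube_solutions):
        solver, state = straight_tube_solutions[0.0]
        _, lamz, lam = sf.flow_resistance(state, solver.mesh, p_inlet=STRAIGHT_PM)
        assert np.all(np.diff(lamz) > -1e-6 * abs(lam))

    def test_zero_flow_resistance_flagged_undefined(self):
        mesh, _ = sf.make_fixture("tiny_stenosis", 0)
        state = sf.SimState.zeros(mesh.n_cells, 0.056)
        with pytest.raises(FloatingPointError):
            sf.flow_resistance(state, mesh)


class TestRecirculation:
    def test_unidirectional_flow_gives_empty_descriptor(self, straight_tube_solutions):
        solver, state = straight_tube_solutions[0.0]
        rz = sf.detect_recirculation(state, solver.mesh)
        assert not rz.present
        assert rz.extent == 0.0

    def test_empty_whenever_no_reverse_velocity(self):
        mesh, payload = sf.make_fixture("tiny_stenosis", 0)
        state = sf.SimState.zeros(mesh.n_cells, 0.056)
        state.u_z[:] = 0.1  # uniformly forward
        assert not sf.detect_recirculation(state, mesh).present

    def test_synthetic_reverse_patch_detected(self):
        mesh, _ = sf.make_fixture("tiny_stenosis", 0)
        state = sf.SimState.zeros(mesh.n_cells, 0.056)
        uz = state.u_z.reshape(mesh.nz, mesh.nr)
        uz[:, :] = 0.1
        throat_i = int(np.argmin(np.abs(mesh.zc[:, 0] - mesh.geom.throat_z)))
        uz[throat_i + 2 : throat_i + 5, -2:] = -0.02
        rz = sf.detect_recirculation(state, mesh)
        assert rz.present
        assert rz.max_reverse_velocity == pytest.approx(0.02)
        assert rz.z_start > mesh.geom.throat_z


class TestGridStudy:
    def test_levels_below_three_rejected(self):
        with pytest.raises(ValueError):
            sf.grid_convergence_study(lambda nz, nr: None, levels=2)

    def test_observed_order_of_factor_two_sequence(self):
        errs = np.array([0.4, 0.1, 0.0])  # exact second-order halving chain
        assert observed_order(errs) == pytest.approx(2.0)
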