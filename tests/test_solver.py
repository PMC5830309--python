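"""SIMPLE solver behaviour: oracles, conservation, limits, time stepping."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

import stenoflow as sf
from tests.conftest import MU_REF, STRAIGHT_GEOM, STRAIGHT_PM, straight_tube_solver


class TestStraightTubeOracles:
    def test_poiseuille_profile(self, straight_tube_solutions, poiseuille_exact):
        solver, state = straight_tube_solutions[0.0]
        tr = sf.probe_trace(state, solver.mesh, 0.025, "u_z")
        exact = poiseuille_exact(tr.r)
        err = np.max(np.abs(tr.values - exact)) / np.max(np.abs(exact))
        assert err < 0.01

    @pytest.mark.parametrize("Ha", [1.0, 5.0, 10.0])
    def test_hartmann_damped_profile(self, straight_tube_solutions, Ha):
        solver, state = straight_tube_solutions[Ha]
        tr = sf.probe_trace(state, solver.mesh, 0.025, "u_z")
        G = STRAIGHT_PM / STRAIGHT_GEOM.L_vessel
        exact = sf.analytic_mhd_pipe_profile(tr.r, G, MU_REF, STRAIGHT_GEOM.R0, Ha)
        err = np.max(np.abs(tr.values - exact)) / np.max(np.abs(exact))
        assert err < 0.02

    def test_centerline_velocity_nonincreasing_in_hartmann(self, straight_tube_solutions):
        u0 = [np.max(straight_tube_solutions[ha][1].u_z) for ha in (0.0, 1.0, 5.0, 10.0)]
        assert all(b <= a * (1 + 1e-12) for a, b in zip(u0, u0[1:]))

    def test_zero_field_limit_identical_to_unmagnetized_solver(self):
        s1 = straight_tube_solver(0.0, nr=8, nz=12)
        props = sf.FluidProps(carreau=sf.CarreauParams.newtonian(MU_REF))
        mag_off = sf.MagneticConfig()  # B0 = 0 entirely
        s2 = sf.SimpleSolver(
            sf.build_mesh(STRAIGHT_GEOM, 12, 8),
            props,
            mag_off,
            sf.SolverConfig(steady=True),
            sf.PulsatilePressure(Pm=STRAIGHT_PM, eps=0.0),
        )
        st1, _ = s1.steady_solve()
        st2, _ = s2.steady_solve()
        assert np.array_equal(st1.u_z, st2.u_z)
        assert np.array_equal(st1.p, st2.p)


class TestConservation:
    def test_mass_imbalance_below_tolerance(self, stenosis50_steady):
        _, solver, _ = stenosis50_steady
        flux = solver._flux
        div = flux.cell_divergence(solver.disc)
        m_in = np.sum(np.abs(flux.boundary["inlet"]))
        assert np.max(np.abs(div)) / m_in < 1e-6
        assert abs(flux.boundary_total("inlet") + flux.boundary_total("outlet")) / m_in < 1e-6

    def test_mechanical_energy_balance(self, stenosis50_steady_ho):
        _, solver, state = stenosis50_steady_ho
        audit = sf.mechanical_energy_audit(solver, state)
        assert audit["rel_gap"] < 0.02

    def test_numerical_dissipation_shrinks_under_refinement(self, stenosis50_steady):
        # the upwind scheme's spurious dissipation shows up as the audit
        # gap; it must decrease on a finer grid
        sc, solver, state = stenosis50_steady
        gap_coarse = sf.mechanical_energy_audit(solver, state)["rel_gap"]
        solver_f = sf.make_solver(sc, nz=96, nr=32)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state_f, _ = solver_f.steady_solve()
        gap_fine = sf.mechanical_energy_audit(solver_f, state_f)["rel_gap"]
        assert gap_fine < gap_coarse

    def test_thermal_energy_balance_with_joule_heating(self, straight_tube_solutions):
        solver, state = straight_tube_solutions[5.0]
        audit = sf.thermal_energy_audit(solver, state)
        assert audit["joule"] > 0.0
        assert audit["rel_gap"] < 0.01

    def test_adiabatic_walls_carry_no_heat_flux(self, straight_tube_solutions):
        solver, state = straight_tube_solutions[0.0]
        # wall is zero-gradient: its conductive flux is identically absent,
        # so the audit's boundary conduction comes from the inlet only
        audit = sf.thermal_energy_audit(solver, state)
        assert audit["rel_gap"] < 0.01


class TestLimitsAndFixedPoints:
    def test_zero_driving_pressure_stays_quiescent(self):
        props = sf.FluidProps()
        solver = sf.SimpleSolver(
            sf.build_mesh(STRAIGHT_GEOM, 12, 8),
            props,
            sf.MagneticConfig(),
            sf.SolverConfig(steady=True),
            sf.PulsatilePressure(Pm=0.0, eps=0.0),
        )
        state, report = solver.steady_solve()
        assert np.all(state.u_z == 0.0)
        assert np.all(state.u_r == 0.0)
        assert np.allclose(state.T, solver.cfg.T_inlet)

    def test_converged_state_is_a_fixed_point(self, straight_tube_solutions):
        solver, state = straight_tube_solutions[0.0]
        st2, report = solver.simple_iterate(state.copy(), t=0.0, dt=None)
        assert report.converged
        assert report.outer_iterations <= 20

    def test_shear_thinning_flattens_the_profile(self):
        # at matched mean velocity the Carreau centre-to-mean ratio is
        # strictly below the Newtonian parabolic value
        def center_to_mean(props, Pm):
            solver = sf.SimpleSolver(
                sf.build_mesh(STRAIGHT_GEOM, 16, 24),
                props,
                sf.MagneticConfig(),
                sf.SolverConfig(steady=True),
                sf.PulsatilePressure(Pm=Pm, eps=0.0),
            )
            st, _ = solver.steady_solve()
            tr = sf.probe_trace(st, solver.mesh, 0.025, "u_z")
            Q = sf.flow_rate_profile(st, solver.mesh)[1][8]
            return tr.values[0] / (Q / (np.pi * STRAIGHT_GEOM.R0**2)), Q

        r_car, Q_car = center_to_mean(sf.FluidProps(), 2.0)
        r_newt, _ = center_to_mean(
            sf.FluidProps(carreau=sf.CarreauParams.newtonian(MU_REF)), 2.0
        )
        assert r_car < r_newt

    def test_viscosity_stays_within_carreau_bounds(self, stenosis50_steady):
        _, _, state = stenosis50_steady
        c = sf.BLOOD_CARREAU
        assert np.all(state.mu >= c.mu_inf - 1e-12)
        assert np.all(state.mu <= c.mu1 + 1e-12)


@pytest.fixture(scope="module")
def short_run():
    sc = sf.preset("paper_case_50pct")
    sc = replace(
        sc,
        solver=replace(sc.solver, dt=0.025, t_end=0.25),
        outputs=replace(sc.outputs, snapshot_times=(0.0, 0.25)),
    )
    return sf.run_simulation(sc, nz=32, nr=12)


class TestTimeStepping:
    def test_pulsatile_run_is_deterministic(self, short_run):
        sc = short_run.scenario
        res2 = sf.run_simulation(sc, nz=32, nr=12)
        assert np.array_equal(short_run.final_state.u_z, res2.final_state.u_z)
        assert np.array_equal(short_run.final_state.T, res2.final_state.T)

    def test_snapshots_present_and_ordered(self, short_run):
        assert len(short_run.snapshots) == 2
        assert short_run.snapshot_times == sorted(short_run.snapshot_times)

    def test_probe_traces_cover_all_stations(self, short_run):
        stations = {round(tr.z, 4) for tr in short_run.probes}
        assert len(stations) == 3

    def test_time_step_refinement_first_order(self):
        # halving dt moves the t = 0.5 s centreline velocity by O(dt)
        sc0 = sf.preset("paper_case_50pct")
        vals = []
        for dt in (0.05, 0.025, 0.0125):
            sc = replace(
                sc0,
                solver=replace(sc0.solver, dt=dt, t_end=0.5),
                outputs=replace(sc0.outputs, snapshot_times=(0.5,)),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sf.run_simulation(sc, nz=32, nr=12)
            uz = res.final_state.u_z.reshape(32, 12)
            vals.append(uz[16, 0])
        d1, d2 = abs(vals[0] - vals[1]), abs(vals[1] - vals[2])
        assert d2 < d1  # error shrinks with dt
        assert d1 / d2 > 1.4  # consistent with first-order stepping

    def test_divergence_raises_with_diagnostics(self):
        # a corrupted (non-finite) state must abort with diagnostics, not
        # loop silently to the iteration cap
        solver = straight_tube_solver(0.0, nr=8, nz=12, max_outer=50)
        state = solver.initial_state()
        state.p[3] = np.nan
        with pytest.raises(sf.SolverDivergence) as exc:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                solver.simple_iterate(state, t=0.0, dt=None)
        assert exc.value.history  # residual trace attached
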