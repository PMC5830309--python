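"""Stenosis profile and axisymmetric mesh metrics."""

import numpy as np
import pytest
import scipy.integrate
from hypothesis import given
from hypothesis import strategies as st

import stenoflow as sf
from stenoflow.geometry import build_mesh, refine_mesh, stenosis_radius

BASE = sf.StenosisGeometry(R0=0.01, L_vessel=0.07, d=0.00588, L0=0.02824, delta=0.005)


class TestStenosisRadius:
    @pytest.mark.parametrize(
        "z_frac, expected_over_R0",
        [
            ("upstream", 1.0),  # unobstructed branch
            ("throat", 0.5),  # 50 % blockage at the throat
            ("three_quarter", 0.75),  # cosine branch: 1 - delta/(2 R0)
        ],
    )
    def test_printed_profile_values(self, z_frac, expected_over_R0):
        z = {
            "upstream": 0.5 * BASE.d,
            "throat": BASE.d + 0.5 * BASE.L0,
            "three_quarter": BASE.d + 0.75 * BASE.L0,
        }[z_frac]
        assert stenosis_radius(z, BASE) == pytest.approx(expected_over_R0 * BASE.R0, rel=1e-12)

    def test_continuous_at_branch_joints(self):
        eps = 1e-9 * BASE.L_vessel
        for zj in (BASE.d, BASE.d + 0.5 * BASE.L0, BASE.d + BASE.L0):
            jump = abs(stenosis_radius(zj + eps, BASE) - stenosis_radius(zj - eps, BASE))
            assert jump < 1e-6 * BASE.R0

    def test_outside_vessel_raises(self):
        with pytest.raises(ValueError):
            stenosis_radius(-0.01, BASE)
        with pytest.raises(ValueError):
            stenosis_radius(BASE.L_vessel + 0.01, BASE)

    @given(
        bf=st.floats(0.0, 0.9),
        zfrac=st.floats(0.0, 1.0),
        sym=st.booleans(),
    )
    def test_radius_bounded_by_profile_range(self, bf, zfrac, sym):
        geom = sf.StenosisGeometry(
            R0=0.01, L_vessel=0.07, d=0.01, L0=0.03, delta=bf * 0.01, symmetric=sym
        )
        r = stenosis_radius(zfrac * geom.L_vessel, geom)
        assert geom.R0 - geom.delta - 1e-15 <= r <= geom.R0 + 1e-15

    def test_zero_height_profile_is_uniform(self):
        geom = sf.StenosisGeometry(R0=0.01, L_vessel=0.07, d=0.01, L0=0.03, delta=0.0)
        z = np.linspace(0, geom.L_vessel, 101)
        assert np.all(stenosis_radius(z, geom) == geom.R0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            sf.StenosisGeometry(R0=0.01, L_vessel=0.07, d=0.01, L0=0.03, delta=0.01)
        with pytest.raises(ValueError):
            sf.StenosisGeometry(R0=0.01, L_vessel=0.07, d=0.06, L0=0.03, delta=0.002)


class TestBuildMesh:
    def test_straight_tube_columns_uniform(self):
        geom = sf.StenosisGeometry(R0=0.01, L_vessel=0.08, d=0.02, L0=0.02, delta=0.0)
        mesh = build_mesh(geom, 8, 4)
        vol = mesh.vol
        assert np.allclose(vol, vol[0, :][None, :], rtol=1e-12)

    def test_min_wall_radius_matches_profile(self):
        mesh = build_mesh(BASE, 48, 8)
        assert np.min(mesh.wall_radius_faces()) == pytest.approx(
            0.5 * BASE.R0, abs=BASE.R0 * BASE.L_vessel / 48 / BASE.L0
        )

    def test_total_volume_matches_quadrature(self):
        mesh = build_mesh(BASE, 48, 8)
        z = np.linspace(0, BASE.L_vessel, 40001)
        v_exact = scipy.integrate.trapezoid(stenosis_radius(z, BASE) ** 2 / 2.0, z)
        assert abs(mesh.vol.sum() - v_exact) / v_exact < 0.005

    @given(bf=st.floats(0.0, 0.8), nz=st.integers(4, 12), nr=st.integers(4, 8))
    def test_metric_identity_closed_cells(self, bf, nz, nr):
        geom = sf.StenosisGeometry(R0=0.01, L_vessel=0.07, d=0.01, L0=0.04, delta=bf * 0.01)
        mesh = build_mesh(geom, nz, nr)
        scale = np.max(np.abs(mesh.zf_Az))
        assert np.max(np.abs(mesh.closed_cell_area_sums())) < 1e-12 * scale

    def test_axis_faces_have_zero_area(self):
        mesh = build_mesh(BASE, 16, 4)
        assert np.all(mesh.rf_Az[:, 0] == 0.0)
        assert np.all(mesh.rf_Ar[:, 0] == 0.0)

    def test_degenerate_and_tiny_grids_rejected(self):
        with pytest.raises(ValueError):
            build_mesh(BASE, 3, 8)
        with pytest.raises(ValueError):
            build_mesh(BASE, 8, 3)


class TestRefineMesh:
    def test_counts_double(self):
        mesh = build_mesh(BASE, 8, 4)
        fine = refine_mesh(mesh, 2)
        assert (fine.nz, fine.nr) == (16, 8)

    def test_bilinear_mode_conserves_volume_exactly(self):
        mesh = build_mesh(BASE, 8, 4)
        fine = refine_mesh(mesh, 2, resample_wall=False)
        child = fine.vol.reshape(8, 2, 4, 2).sum(axis=(1, 3))
        assert np.max(np.abs(child - mesh.vol)) < 1e-12 * np.max(mesh.vol)

    def test_resampled_mode_tracks_wall_curve(self):
        mesh = build_mesh(BASE, 8, 4)
        fine = refine_mesh(mesh, 2, resample_wall=True)
        assert np.allclose(fine.rv[:, -1], stenosis_radius(fine.zv, BASE), rtol=0, atol=1e-15)

    def test_point_count_grows_fourfold_per_level(self):
        mesh = build_mesh(BASE, 8, 4)
        fine = refine_mesh(mesh, 2)
        assert fine.n_cells == 4 * mesh.n_cells

    def test_factor_below_two_rejected(self):
        mesh = build_mesh(BASE, 8, 4)
        with pytest.raises(ValueError):
            refine_mesh(mesh, 1)
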