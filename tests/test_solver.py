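"""Harmonic solver: structure, oracles, conservation, and convergence."""

import numpy as np
import pytest

import basilar as b
from basilar.solver import StimulusSpec, SolverSettings, assemble_system
from tests.conftest import make_uniform_geometry, make_uniform_params

UNCOUPLED = SolverSettings(longitudinal_coupling=False, viscous_walls=False)


class TestAssembly:
    def test_uniform_undamped_system_is_symmetric_tridiagonal(self, mat):
        geom = make_uniform_geometry(n=60)
        params = make_uniform_params(geom, beta=0.0)
        a_mat, b_vec, _ = assemble_system(
            geom, params, None, 500.0, UNCOUPLED, mat
        )
        dense = a_mat.toarray()
        assert np.allclose(dense, dense.T)  # symmetric
        off = np.triu(np.abs(dense), 2)
        assert off.max() == 0.0  # no entries beyond the first off-diagonal
        assert b_vec[0] != 0 and np.all(b_vec[1:] == 0)

    def test_zero_occlusion_assembly_identical_to_healthy(self, default_geom, mat):
        params = b.partition_params(default_geom, mat)
        occ0 = b.place_electrode(default_geom, b.ElectrodeSpec(insertion_angle=0.0), mat)
        a_h, b_h, _ = assemble_system(default_geom, params, None, 1000.0, None, mat)
        a_0, b_0, _ = assemble_system(default_geom, params, occ0, 1000.0, None, mat)
        assert (a_h != a_0).nnz == 0
        assert np.array_equal(b_h, b_0)

    def test_grid_mismatch_rejected(self, default_geom, mat):
        other = b.build_geometry(grid=b.GridSpec(dx=0.05))
        params = b.partition_params(other, mat)
        with pytest.raises(ValueError, match="grids"):
            assemble_system(default_geom, params, None, 1000.0, None, mat)

    def test_two_node_system_matches_hand_solution(self, mat):
        """Hand-assembled 2x2 finite-volume system, solved independently."""
        geom = make_uniform_geometry(n=2, L=0.5, thickness=10.0, width=0.2, area=1.0)
        params = make_uniform_params(geom, stiffness=1e8, mass=0.01, beta=1e-5)
        f = 1000.0
        z_h = 1e9 + 5e8j  # explicit helicotrema impedance
        settings = SolverSettings(
            longitudinal_coupling=False, viscous_walls=False, helicotrema=z_h
        )
        stim = StimulusSpec(frequencies=(f,), stapes_displacement=1e-8)

        # independent hand assembly from the line equations
        omega = 2 * np.pi * f
        rho = mat.fluid.density
        dx = 0.5e-3
        area = 1e-6
        w = 0.2e-3
        z_series = 1j * omega * rho * (1 / area + 1 / area)
        g = 1.0 / (z_series * dx)
        z_p = (1e8 * (1 + 1j * omega * 1e-5) - omega**2 * 0.01) / (1j * omega)
        u_s = 1j * omega * 1e-8 * 0.8e-6
        half = dx / 2
        a_hand = np.array(
            [
                [g + half * w / z_p, -g],
                [-g, g + half * w / z_p + 1 / z_h],
            ],
            dtype=complex,
        )
        p_hand = np.linalg.solve(a_hand, np.array([u_s, 0.0]))
        u_hand = -p_hand / (1j * omega * z_p)

        resp = b.solve_harmonic(geom, mat, stim=stim, settings=settings, params=params)
        assert np.allclose(resp.u[0], u_hand, rtol=1e-12)


class TestPhysicalProperties:
    def test_linearity_of_the_drive(self, default_geom, mat):
        stim1 = StimulusSpec(stapes_displacement=1e-8)
        stim2 = StimulusSpec(stapes_displacement=2e-8)
        u1 = b.solve_harmonic(default_geom, mat, stim=stim1).u
        u2 = b.solve_harmonic(default_geom, mat, stim=stim2).u
        assert np.abs(u2 - 2 * u1).max() <= 1e-12 * np.abs(u2).max()

    def test_zero_occlusion_solve_bit_identical_to_healthy(
        self, default_geom, mat, healthy_response
    ):
        occ0 = b.place_electrode(default_geom, b.ElectrodeSpec(insertion_angle=0.0), mat)
        resp0 = b.solve_harmonic(default_geom, mat, occ=occ0)
        assert np.array_equal(resp0.u, healthy_response.u)

    def test_closed_form_transmission_line_limit(self, mat):
        """Uniform duct, constant partition, matched apex: |u| must match the
        independently coded decaying-wave solution within 5% in L2."""
        geom = make_uniform_geometry(n=367, L=18.3, width=0.2, area=1.0)
        params = make_uniform_params(geom, stiffness=1e8, mass=0.01, beta=4e-6)
        f = 2000.0
        omega = 2 * np.pi * f
        rho = mat.fluid.density
        # closed form, written from the line equations (not the solver code):
        area, w = 1e-6, 0.2e-3
        z_series = 2j * omega * rho / area
        z_p = (1e8 * (1 + 1j * omega * 4e-6) - omega**2 * 0.01) / (1j * omega)
        gamma = np.sqrt(z_series * (w / z_p))
        gamma = gamma if gamma.real > 0 else -gamma
        z_c = np.sqrt(z_series / (w / z_p))
        u_s_vol = 1j * omega * 1e-8 * 0.8e-6
        x_m = geom.x_grid * 1e-3
        p_exact = z_c * u_s_vol * np.exp(-gamma * x_m)
        u_exact = -p_exact / (1j * omega * z_p)

        stim = StimulusSpec(frequencies=(f,), stapes_displacement=1e-8)
        resp = b.solve_harmonic(
            geom, mat, stim=stim, settings=UNCOUPLED, params=params
        )
        err = np.linalg.norm(np.abs(resp.u[0]) - np.abs(u_exact)) / np.linalg.norm(
            np.abs(u_exact)
        )
        assert err < 0.05

    def test_discrete_power_balance(self, healthy_response):
        for d in healthy_response.diagnostics:
            assert d.power_input > 0
            assert d.power_balance_error < 0.01

    def test_power_balance_with_electrode(self, default_geom, mat):
        occ = b.place_electrode(default_geom, b.ElectrodeSpec(insertion_angle=900.0), mat)
        resp = b.solve_harmonic(default_geom, mat, occ=occ)
        for d in resp.diagnostics:
            assert d.power_balance_error < 0.01

    def test_grid_convergence_of_peaks(self, mat, healthy_tuning):
        fine = b.build_geometry(grid=b.GridSpec(dx=0.0125))
        tun_f = b.extract_tuning(b.solve_harmonic(fine, mat))
        loc_shift = np.abs(tun_f.peak_location - healthy_tuning.peak_location)
        assert loc_shift.max() < 0.01 * 18.3
        mag_change = np.abs(tun_f.peak_magnitude / healthy_tuning.peak_magnitude - 1)
        assert mag_change.max() < 0.02

    def test_tonotopic_ordering_and_magnitude_trend(self, healthy_tuning):
        # lower frequency -> more apical peak, smaller normalized magnitude
        assert np.all(np.diff(healthy_tuning.peak_location) < 0)
        assert np.all(np.diff(healthy_tuning.peak_magnitude) > 0)

    def test_acoustic_formulation_close_to_incompressible(self, default_geom, mat,
                                                          healthy_tuning):
        resp = b.solve_harmonic(
            default_geom, mat, settings=SolverSettings(formulation="acoustic")
        )
        tun = b.extract_tuning(resp)
        assert np.abs(tun.peak_location - healthy_tuning.peak_location).max() <= 0.1
        assert np.allclose(
            tun.peak_magnitude, healthy_tuning.peak_magnitude, rtol=0.05
        )

    def test_deterministic_repeat(self, default_geom, mat, healthy_response):
        again = b.solve_harmonic(default_geom, mat)
        assert np.array_equal(again.u, healthy_response.u)


class TestValidation:
    def test_stimulus_requires_sorted_positive_frequencies(self):
        with pytest.raises(ValueError, match="sorted"):
            StimulusSpec(frequencies=(1000.0, 400.0))
        with pytest.raises(ValueError, match="positive"):
            StimulusSpec(frequencies=(-1.0,))
        with pytest.raises(ValueError, match="at least one"):
            StimulusSpec(frequencies=())

    def test_per_frequency_amplitude_table(self):
        stim = StimulusSpec(
            frequencies=(400.0, 1000.0),
            stapes_displacement={400.0: 1e-8, 1000.0: 2e-8},
        )
        assert stim.amplitude(1000.0) == 2e-8
        with pytest.raises(KeyError):
            stim.amplitude(2000.0)

    def test_solver_settings_validation(self):
        with pytest.raises(ValueError, match="tolerance"):
            SolverSettings(tolerance=1e-5)
        with pytest.raises(ValueError, match="formulation"):
            SolverSettings(formulation="time-domain")
        with pytest.raises(ValueError, match="helicotrema"):
            SolverSettings(helicotrema="open")
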