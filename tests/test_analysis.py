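"""Normalization, smoothing, peak extraction, Greenwood map, and deltas."""

import numpy as np
import pytest

import basilar as b
from basilar.analysis import (
    GreenwoodMap,
    TuningResult,
    delta_frame,
    find_peak,
    normalize_response,
    smooth_profile,
)
from basilar.solver import BMResponse


def _toy_response(u, u_s=1e-8, freqs=None):
    u = np.atleast_2d(np.asarray(u, complex))
    n_f, n_x = u.shape
    freqs = np.asarray(freqs if freqs is not None else np.arange(1, n_f + 1) * 1000.0)
    return BMResponse(
        frequencies=freqs,
        x_grid=np.linspace(0.0, 18.3, n_x),
        u=u,
        stapes_displacement=np.full(n_f, u_s),
    )


class TestNormalize:
    def test_unit_profile_when_u_equals_stapes(self):
        resp = _toy_response(np.full(50, 1e-8 + 0j))
        assert np.allclose(normalize_response(resp), 1.0)

    def test_invariant_under_drive_scaling(self, default_geom, mat):
        r1 = b.solve_harmonic(default_geom, mat, stim=b.StimulusSpec(stapes_displacement=1e-8))
        r2 = b.solve_harmonic(default_geom, mat, stim=b.StimulusSpec(stapes_displacement=5e-8))
        assert np.allclose(normalize_response(r1), normalize_response(r2), rtol=1e-12)

    def test_cross_check_against_raw_peaks(self, healthy_response):
        norm = normalize_response(healthy_response)
        raw = np.abs(healthy_response.u)
        for i, amp in enumerate(healthy_response.stapes_displacement):
            assert norm[i].max() == pytest.approx(raw[i].max() / amp, rel=1e-12)

    def test_zero_stapes_rejected(self):
        resp = _toy_response(np.ones(10), u_s=0.0)
        with pytest.raises(ValueError, match="stapes"):
            normalize_response(resp)


class TestSmoothing:
    def test_constant_profile_unchanged(self):
        prof = np.full(200, 3.7)
        assert np.allclose(smooth_profile(prof, dx=0.05, window=0.2), 3.7)

    def test_single_spike_becomes_plateau(self):
        prof = np.zeros(201)
        prof[100] = 5.0
        out = smooth_profile(prof, dx=0.05, window=0.2)  # 5-node window
        m = 5
        assert out[100] == pytest.approx(5.0 / m)
        assert np.allclose(out[98:103], 5.0 / m)

    def test_short_wavelength_attenuation_matches_filter_response(self):
        dx, window = 0.01, 0.21  # m = 21 nodes
        m = 21
        lam = 0.068  # mm, much shorter than the window
        x = np.arange(2000) * dx
        prof = np.cos(2 * np.pi * x / lam)
        out = smooth_profile(prof, dx=dx, window=window)
        # closed-form moving-average (Dirichlet) gain at this wavelength
        gain = np.sin(np.pi * m * dx / lam) / (m * np.sin(np.pi * dx / lam))
        interior = slice(m, len(x) - m)
        assert np.allclose(out[interior], gain * prof[interior], atol=1e-9)

    def test_window_below_grid_step_rejected(self):
        with pytest.raises(ValueError, match="window"):
            smooth_profile(np.ones(100), dx=0.05, window=0.01)


class TestFindPeak:
    def test_unimodal_bump(self):
        x = np.linspace(0.0, 18.3, 367)
        prof = np.exp(-((x - 7.0) ** 2))
        loc, val = find_peak(prof, x)
        assert abs(loc - 7.0) <= x[1] - x[0]
        assert val == prof.max()

    def test_tie_breaks_toward_base(self):
        x = np.linspace(0.0, 10.0, 101)
        prof = np.zeros(101)
        prof[[30, 70]] = 1.0
        loc, _ = find_peak(prof, x)
        assert loc == x[30]

    def test_all_zero_profile_flagged(self):
        with pytest.raises(ValueError, match="zero"):
            find_peak(np.zeros(10), np.arange(10.0))

    def test_extreme_frequencies_order_on_healthy_run(self, healthy_tuning):
        freqs = healthy_tuning.frequencies
        x_of = dict(zip(freqs, healthy_tuning.peak_location))
        assert x_of[10000.0] < x_of[400.0]


class TestGreenwood:
    def test_chinchilla_preset_shape(self):
        gmap = GreenwoodMap()
        assert gmap.frequency_at(0.0) > gmap.frequency_at(18.3)
        # monotone and invertible across the duct
        x = np.linspace(0.0, 18.3, 50)
        f = gmap.frequency_at(x)
        assert np.all(np.diff(f) < 0)
        assert np.allclose(gmap.position_of(f), x)

    def test_round_trip_locations_give_zero_error(self):
        gmap = GreenwoodMap()
        freqs = np.array([400.0, 1000.0, 4000.0])
        locs = np.array([gmap.position_of(f) for f in freqs])
        tuning = TuningResult(freqs, locs, np.ones(3))
        out = b.compare_greenwood(tuning, gmap)
        assert np.allclose(out.location_error, 0.0, atol=1e-12)
        assert out.rms_location_error == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_gives_rms_equal_to_offset(self):
        gmap = GreenwoodMap()
        freqs = np.array([400.0, 1000.0, 4000.0])
        locs = np.array([gmap.position_of(f) for f in freqs]) + 0.5
        out = b.compare_greenwood(TuningResult(freqs, locs, np.ones(3)), gmap)
        assert out.rms_location_error == pytest.approx(0.5)

    def test_out_of_range_frequency_flagged_not_fatal(self):
        gmap = GreenwoodMap()
        tuning = TuningResult(
            np.array([5.0, 1000.0]), np.array([18.0, 11.0]), np.ones(2)
        )
        out = b.compare_greenwood(tuning, gmap)
        assert np.isnan(out.greenwood_location[0])
        assert np.isfinite(out.greenwood_location[1])

    def test_invertibility_guard(self):
        with pytest.raises(ValueError, match="k"):
            GreenwoodMap(k=1.0)

    def test_healthy_run_tracks_species_map(self, healthy_tuning):
        # regression bound frozen from the calibrated healthy model
        assert healthy_tuning.rms_location_error < 0.05 * 18.3


class TestResidualHearingDelta:
    def test_identical_runs_give_exact_zero(self, healthy_tuning):
        d = b.residual_hearing_delta(healthy_tuning, healthy_tuning)
        assert np.all(d.location_shift == 0.0)
        assert np.all(d.magnitude_change_db == 0.0)

    def test_doubled_magnitude_is_six_db(self):
        freqs = np.array([400.0, 1000.0])
        a = TuningResult(freqs, np.array([10.0, 8.0]), np.array([2.0, 3.0]))
        c = TuningResult(freqs, np.array([10.0, 8.0]), np.array([4.0, 6.0]))
        d = b.residual_hearing_delta(a, c)
        assert np.allclose(d.magnitude_change_db, 6.02, atol=0.005)
        assert np.all(d.location_shift == 0.0)

    def test_antisymmetry(self, healthy_tuning, default_geom, mat):
        occ = b.place_electrode(default_geom, b.ElectrodeSpec(insertion_angle=900.0), mat)
        implanted = b.extract_tuning(b.solve_harmonic(default_geom, mat, occ=occ))
        fwd = b.residual_hearing_delta(healthy_tuning, implanted)
        rev = b.residual_hearing_delta(implanted, healthy_tuning)
        assert np.allclose(fwd.location_shift, -rev.location_shift)
        assert np.allclose(fwd.magnitude_change_db, -rev.magnitude_change_db)

    def test_mismatched_frequencies_rejected(self, healthy_tuning):
        other = TuningResult(np.array([500.0]), np.array([10.0]), np.array([1.0]))
        with pytest.raises(ValueError, match="frequencies"):
            b.residual_hearing_delta(healthy_tuning, other)

    def test_delta_frame_layout(self, sweep_results):
        frame = delta_frame(list(sweep_results.values()))
        assert len(frame) == 5 * 7
        assert list(frame.columns) == ["angle_deg", "frequency_Hz", "dx_mm", "ddB"]
        assert frame["angle_deg"].is_monotonic_increasing
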