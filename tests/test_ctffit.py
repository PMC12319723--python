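"""Thon-ring fitting: profiles, background, defocus search, fit resolution."""

import dataclasses

import numpy as np
import pytest

from tiltps import (CtfFitResult, FrequencyGrid, InvalidParameterError,
                    OpticsParams, PowerSpectrum, ctf_image, ctf_value,
                    equiphase_average, fit_defocus, fit_resolution,
                    radial_average, refine_astigmatism, score_defocus,
                    subtract_background)
from tiltps.ctffit import (_model_curve, background_window_bins,
                           read_diagnostics, write_diagnostics)
from tiltps.optics import phase_shift_chi


def model_spectrum(optics, defocus_a, n=512, mode="amplitude",
                   defocus2_a=None, astig_angle_rad=0.0, noise=None, rng=None):
    """Noise-free (optionally astigmatic / noisy) model |CTF| spectrum."""
    grid = FrequencyGrid(n=n, pixel_size_a=optics.pixel_size_a)
    if defocus2_a is None:
        img = np.abs(ctf_image(optics, grid, defocus_a))
    else:
        c = n // 2
        idx = np.arange(n, dtype=float) - c
        phi = np.arctan2(idx[:, None], idx[None, :])
        dmean = 0.5 * (defocus_a + defocus2_a)
        ddiff = 0.5 * (defocus_a - defocus2_a)
        dloc = dmean + ddiff * np.cos(2 * (phi - astig_angle_rad))
        img = np.abs(ctf_value(optics, grid.values, dloc))
    if mode == "power":
        img = img * img
    if noise:
        img = img + noise * rng.standard_normal(img.shape)
    return PowerSpectrum(values=img, weights=np.ones_like(img),
                         pixel_size_a=optics.pixel_size_a, mode=mode)


class TestRadialAverage:
    def test_impulse_ring(self, optics):
        n = 128
        c = n // 2
        idx = np.arange(n) - c
        r = np.rint(np.hypot(idx[:, None], idx[None, :])).astype(int)
        vals = (r == 50).astype(float)
        ps = PowerSpectrum(values=vals, weights=np.ones_like(vals),
                           pixel_size_a=optics.pixel_size_a)
        prof = radial_average(ps)
        assert prof.values[50] == pytest.approx(1.0)
        others = np.delete(prof.values, 50)
        assert np.all(others == 0)

    def test_constant_spectrum(self, optics):
        ps = PowerSpectrum(values=np.ones((128, 128)),
                           weights=np.ones((128, 128)),
                           pixel_size_a=optics.pixel_size_a)
        prof = radial_average(ps)
        assert np.allclose(prof.values[prof.valid], 1.0)

    def test_matches_1d_model_at_low_k(self, optics):
        ps = model_spectrum(optics, 20_000.0, n=256, mode="power")
        prof = radial_average(ps)
        bins = np.arange(5, 30)
        expected = ctf_value(optics, prof.k[bins], 20_000.0) ** 2
        np.testing.assert_allclose(prof.values[bins], expected, atol=0.05)

    def test_zero_weight_bins_marked_missing(self, optics):
        vals = np.ones((64, 64))
        w = np.ones((64, 64))
        w[:] = 0  # nothing accumulated at all
        ps = PowerSpectrum(values=vals * 0, weights=w,
                           pixel_size_a=optics.pixel_size_a)
        prof = radial_average(ps)
        assert not prof.valid.any()


class TestBackgroundSubtraction:
    def test_pure_decay_suppressed(self):
        x = np.exp(-np.arange(256) / 80.0)
        resid = subtract_background(x, window_bins=9)
        assert np.max(np.abs(resid)) < 0.05 * (x.max() - x.min())

    def test_flat_zero_profile(self):
        assert np.allclose(subtract_background(np.zeros(64)), 0.0)

    def test_oscillation_phase_preserved(self):
        t = np.arange(512)
        osc = np.cos(2 * np.pi * t / 20.0)
        profile = np.exp(-t / 200.0) * 2 + 0.5 * osc**2
        resid = subtract_background(profile, window_bins=15)
        # upward zero-crossings of the oscillation survive within 1 bin
        ref = osc**2 - 0.5
        for arr in (resid - resid.mean(),):
            ref_cross = np.where(np.diff(np.sign(ref[50:450])) > 0)[0]
            got_cross = np.where(np.diff(np.sign(arr[50:450] - arr[50:450].mean())) > 0)[0]
            for rc in ref_cross:
                assert np.min(np.abs(got_cross - rc)) <= 1

    def test_short_profile_rejected(self):
        with pytest.raises(InvalidParameterError):
            subtract_background(np.zeros(8))


class TestScore:
    def test_self_correlation_is_one(self, optics):
        k = np.linspace(0.02, 0.3, 400)
        model = _model_curve(optics, k, 30_000.0, "amplitude")
        assert score_defocus(model, k, optics, 30_000.0,
                             (0.02, 0.3)) == pytest.approx(1.0, abs=1e-9)

    def test_negated_model_scores_minus_one(self, optics):
        k = np.linspace(0.02, 0.3, 400)
        model = _model_curve(optics, k, 30_000.0, "amplitude")
        assert score_defocus(-model, k, optics, 30_000.0,
                             (0.02, 0.3)) == pytest.approx(-1.0, abs=1e-9)

    def test_affine_invariance(self, optics, rng):
        k = np.linspace(0.02, 0.3, 400)
        resid = rng.standard_normal(400)
        s1 = score_defocus(resid, k, optics, 25_000.0, (0.02, 0.3))
        s2 = score_defocus(3.7 * resid + 11.0, k, optics, 25_000.0, (0.02, 0.3))
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_true_defocus_beats_neighbours(self, optics):
        k = np.linspace(0.04, 0.25, 600)
        model = _model_curve(optics, k, 30_000.0, "amplitude")
        band = (0.04, 0.25)
        s_true = score_defocus(model, k, optics, 30_000.0, band)
        assert s_true > score_defocus(model, k, optics, 27_000.0, band)
        assert s_true > score_defocus(model, k, optics, 33_000.0, band)

    def test_empty_band_rejected(self, optics):
        with pytest.raises(InvalidParameterError):
            score_defocus(np.ones(10), np.linspace(0.02, 0.1, 10), optics,
                          30_000.0, (0.5, 0.6))


class TestFitDefocus:
    def test_noise_free_recovery_within_one_percent(self, optics):
        ps = model_spectrum(optics, 30_000.0)
        result = fit_defocus(ps, optics)
        assert abs(result.defocus_a - 30_000.0) < 300.0
        assert result.cross_correlation > 0.9

    def test_moderate_noise_recovery_within_three_percent(self, optics, rng):
        ps = model_spectrum(optics, 42_000.0, noise=0.3, rng=rng)
        result = fit_defocus(ps, optics)
        assert abs(result.defocus_a - 42_000.0) / 42_000.0 < 0.03

    def test_deterministic(self, optics):
        ps = model_spectrum(optics, 27_500.0)
        r1 = fit_defocus(ps, optics)
        r2 = fit_defocus(ps, optics)
        assert r1 == r2  # bit-identical dataclasses

    def test_power_mode(self, optics):
        ps = model_spectrum(optics, 30_000.0, mode="power")
        result = fit_defocus(ps, optics)
        assert abs(result.defocus_a - 30_000.0) < 300.0

    def test_degenerate_search_rejected(self, optics):
        ps = model_spectrum(optics, 30_000.0, n=128)
        from tiltps.errors import FitFailureError
        with pytest.raises(FitFailureError):
            fit_defocus(ps, optics, search=(50_000.0, 10_000.0, 100.0))

    def test_result_defocus_within_search_range(self):
        with pytest.raises(InvalidParameterError):
            CtfFitResult(defocus_a=90_000.0, cross_correlation=0.5,
                         fit_resolution_a=3.0, search_range_a=(5_000.0, 80_000.0))


class TestFitResolution:
    def test_exact_model_reaches_nyquist(self, optics):
        ps = model_spectrum(optics, 30_000.0)
        result = fit_defocus(ps, optics)
        assert result.fit_resolution_a == pytest.approx(
            2 * optics.pixel_size_a, rel=0.15)

    def test_degrades_with_noise(self, optics, rng):
        # white noise whose amplitude ramps with k erodes the rings from the
        # high-frequency end first
        from tiltps import FrequencyGrid, ctf_image
        grid = FrequencyGrid(n=512, pixel_size_a=optics.pixel_size_a)
        clean = np.abs(ctf_image(optics, grid, 30_000.0))
        ramp = grid.values / optics.nyquist
        res = []
        for noise in (0.0, 4.0, 12.0):
            img = clean + noise * ramp * rng.standard_normal(clean.shape)
            ps = PowerSpectrum(values=img, weights=np.ones_like(img),
                               pixel_size_a=optics.pixel_size_a)
            r = fit_defocus(ps, optics)
            res.append(fit_resolution(ps, optics, r))
        assert all(a <= b for a, b in zip(res, res[1:]))
        assert res[-1] > res[0]

    def test_never_beats_physical_nyquist(self, optics):
        ps = model_spectrum(optics, 30_000.0)
        r = fit_defocus(ps, optics)
        assert r.fit_resolution_a >= 2 * optics.pixel_size_a


class TestEquiphase:
    def test_matches_radial_average_without_astigmatism(self, optics):
        ps = model_spectrum(optics, 30_000.0, n=256)
        result = fit_defocus(ps, optics)
        eq = equiphase_average(ps, optics, result)
        prof = radial_average(ps)
        np.testing.assert_allclose(eq.values, prof.values, atol=1e-9)
        chi = phase_shift_chi(optics, prof.k, result.defocus_a)
        np.testing.assert_allclose(eq.chi, chi)

    def test_constant_spectrum_constant_profile(self, optics):
        ps = PowerSpectrum(values=np.ones((128, 128)),
                           weights=np.ones((128, 128)),
                           pixel_size_a=optics.pixel_size_a)
        result = CtfFitResult(defocus_a=30_000.0, cross_correlation=1.0,
                              fit_resolution_a=3.0,
                              search_range_a=(5_000.0, 80_000.0),
                              defocus1_a=31_000.0, defocus2_a=29_000.0,
                              astig_angle_rad=0.3)
        eq = equiphase_average(ps, optics, result)
        assert np.allclose(eq.values[eq.valid], 1.0)

    def test_astigmatic_spectrum_deeper_troughs(self, optics):
        # synthetic astigmatic model spectrum; the equiphase average follows
        # the elliptical rings while the circular average smears them
        d1, d2, ang = 32_000.0, 28_000.0, 0.4
        ps = model_spectrum(optics, d1, n=512, defocus2_a=d2,
                            astig_angle_rad=ang)
        result = CtfFitResult(defocus_a=30_000.0, cross_correlation=1.0,
                              fit_resolution_a=3.0,
                              search_range_a=(5_000.0, 80_000.0),
                              defocus1_a=d1, defocus2_a=d2,
                              astig_angle_rad=ang)
        eq = equiphase_average(ps, optics, result)
        prof = radial_average(ps)
        sel = slice(40, 160)
        # ring contrast: peak-to-trough span over the oscillating band
        assert (eq.values[sel].max() - eq.values[sel].min()) > \
               1.5 * (prof.values[sel].max() - prof.values[sel].min())


class TestAstigmatismRefinement:
    def test_recovers_synthetic_astigmatism(self, optics):
        d1, d2, ang = 31_500.0, 28_500.0, 0.5
        ps = model_spectrum(optics, d1, n=256, defocus2_a=d2,
                            astig_angle_rad=ang)
        scalar = fit_defocus(ps, optics)
        refined = refine_astigmatism(ps, optics, scalar)
        assert refined.defocus1_a == pytest.approx(d1, rel=0.02)
        assert refined.defocus2_a == pytest.approx(d2, rel=0.02)
        assert abs(refined.astig_angle_rad - ang) < 0.1


class TestDiagnostics:
    def test_round_trip(self, tmp_path):
        results = [
            CtfFitResult(defocus_a=30_000.0, cross_correlation=0.9,
                         fit_resolution_a=4.5, search_range_a=(5e3, 8e4)),
            CtfFitResult(defocus_a=31_000.0, cross_correlation=0.8,
                         fit_resolution_a=6.5, search_range_a=(5e3, 8e4),
                         defocus1_a=32_000.0, defocus2_a=30_000.0,
                         astig_angle_rad=0.25),
        ]
        path = tmp_path / "diag.txt"
        write_diagnostics(results, path)
        arr = read_diagnostics(path)
        assert arr.shape == (2, 7)
        assert arr[0, 1] == pytest.approx(30_000.0)
        assert arr[1, 1] == pytest.approx(32_000.0)
        assert arr[1, 3] == pytest.approx(np.degrees(0.25), abs=1e-4)
        assert arr[1, 6] == pytest.approx(6.5)

    def test_fit_panel_written(self, tmp_path, optics):
        from tiltps.ctffit import plot_fit_panel
        ps = model_spectrum(optics, 30_000.0, n=128)
        result = fit_defocus(ps, optics)
        out = tmp_path / "panel.png"
        plot_fit_panel(ps, optics, result, out)
        assert out.stat().st_size > 0


def test_background_window_tracks_ring_spacing(optics):
    k = np.linspace(0.01, 0.3, 300)
    w = background_window_bins(optics, 30_000.0, k, k[1] - k[0])
    # rings get denser with k, so the window must shrink (monotone non-increasing
    # until clipped)
    assert w[10] >= w[100] >= w[250]
    assert w.min() >= 3
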