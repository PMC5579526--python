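import numpy as np
import pytest

import serdslab as sl
from serdslab.synthetic_data import Band, BandSet, FluorescenceModel

from numpy.polynomial import polynomial as P


class TestFixtures:
    def test_lipid_has_ch_stretch_envelope_band(self):
        bands = sl.lipid_like_fixture()
        assert any(2800 <= b.center_cm1 <= 3100 for b in bands.bands)

    def test_protein_has_narrow_phenylalanine_line(self):
        bands = sl.protein_like_fixture()
        narrow = [b for b in bands.bands if abs(b.center_cm1 - 1003) < 5]
        assert narrow and narrow[0].fwhm_cm1 <= 12

    @pytest.mark.parametrize("factory", [
        sl.lipid_like_fixture, sl.protein_like_fixture,
        sl.collagen_like_fixture, sl.bone_like_fixture])
    def test_fixtures_are_deterministic(self, factory):
        assert factory() == factory()

    def test_heterogeneous_bandwidths(self):
        for bands in (sl.lipid_like_fixture(), sl.protein_like_fixture()):
            widths = [b.fwhm_cm1 for b in bands.bands]
            assert max(widths) / min(widths) > 4  # order-of-magnitude spread


class TestPureSpectrum:
    def test_single_band_peak_value(self, grid):
        bands = BandSet((Band(1450.0, 30.0, 100.0),))
        s = sl.synth_pure_spectrum(bands, grid)
        assert s.intensity.max() == pytest.approx(100.0)
        assert s.axis[np.argmax(s.intensity)] == pytest.approx(1450.0, abs=2.0)

    def test_additivity_against_per_band_oracle(self, grid):
        bands = sl.lipid_like_fixture()
        s = sl.synth_pure_spectrum(bands, grid)
        oracle = np.zeros(grid.size)
        for b in bands.bands:
            oracle = oracle + b.profile(grid)
        np.testing.assert_allclose(s.intensity, oracle, rtol=1e-12)

    def test_band_outside_grid_rejected(self, grid):
        with pytest.raises(ValueError):
            sl.synth_pure_spectrum(BandSet((Band(5000.0, 20.0, 10.0),)), grid)

    def test_empty_band_set_rejected(self):
        with pytest.raises(ValueError):
            BandSet(())


class TestFluorescence:
    def test_multiple_of_max_band_exact(self, grid, lipid_pure):
        wl = sl.raman_shift_to_wavelength(grid, 785.0)
        f = sl.synth_fluorescence(sl.default_fluorescence(5.0), lipid_pure, wl)
        assert f.intensity.max() == pytest.approx(
            5.0 * lipid_pure.intensity.max(), rel=1e-12)

    def test_scale_zero_gives_flat_zero(self, grid, lipid_pure):
        wl = sl.raman_shift_to_wavelength(grid, 785.0)
        f = sl.synth_fluorescence(sl.default_fluorescence(0.0), lipid_pure, wl)
        np.testing.assert_allclose(f.intensity, 0.0)

    def test_absolute_mode_matches_polyval_oracle(self):
        coeffs = (5.0, -0.004, 1e-6)
        model = FluorescenceModel(coeffs, scale_mode="absolute", scale=2.0)
        wl = np.linspace(850, 1000, 200)
        f = sl.synth_fluorescence(model, None, wl)
        # Horner evaluation, independent of numpy's polyval
        horner = np.zeros_like(wl)
        for c in reversed(coeffs):
            horner = horner * wl + c
        np.testing.assert_allclose(f.intensity, 2.0 * horner, rtol=1e-12)

    def test_negative_polynomial_rejected(self):
        model = FluorescenceModel((-10.0, 0.0), scale_mode="absolute", scale=1.0)
        with pytest.raises(ValueError):
            sl.synth_fluorescence(model, None, np.linspace(850, 1000, 50))


class TestAcquisition:
    def test_noise_off_equals_pure_on_detector(self):
        bands = sl.lipid_like_fixture()
        cfg = sl.AcquisitionConfig(noise=False)
        acq = sl.simulate_acquisition(bands, None, cfg)
        shift_frame = sl.wavelength_to_raman_shift(acq.axis, cfg.excitation_nm)
        oracle = np.zeros(acq.axis.size)
        for b in bands.bands:
            oracle = oracle + b.profile(shift_frame)
        np.testing.assert_allclose(acq.intensity, oracle, rtol=1e-12)

    def test_poisson_mean_and_variance(self):
        # 2000 independent draws at a pixel with expected counts ~400
        bands = BandSet((Band(1450.0, 30.0, 400.0),))
        cfg0 = sl.AcquisitionConfig(noise=False)
        noiseless = sl.simulate_acquisition(bands, None, cfg0)
        px = int(np.argmax(noiseless.intensity))
        mean = noiseless.intensity[px]
        draws = np.array([
            sl.simulate_acquisition(bands, None,
                                    sl.AcquisitionConfig(noise=True, seed=s)
                                    ).intensity[px]
            for s in range(2000)])
        assert abs(draws.mean() - mean) < 3 * np.sqrt(mean) / np.sqrt(2000)
        assert abs(draws.var() - mean) < 0.2 * mean

    def test_gaussian_noise_model_variance(self):
        bands = BandSet((Band(1450.0, 30.0, 400.0),))
        cfg = sl.AcquisitionConfig(noise=True, seed=5, noise_model="gaussian")
        acq = sl.simulate_acquisition(bands, None, cfg)
        assert not np.allclose(acq.intensity,
                               sl.simulate_acquisition(
                                   bands, None,
                                   sl.AcquisitionConfig(noise=False)).intensity)

    def test_raman_moves_fluorescence_stays(self):
        """The defining shifted-excitation asymmetry: on the reference shift
        axis the band maxima displace by the excitation shift while the
        wavelength-frame background is bitwise unchanged."""
        bands = BandSet((Band(1450.0, 30.0, 100.0),))
        fl = sl.default_fluorescence(5.0)
        a1 = sl.simulate_acquisition(bands, fl, sl.AcquisitionConfig(
            excitation_nm=785.0, noise=False))
        a2 = sl.simulate_acquisition(bands, fl, sl.AcquisitionConfig(
            excitation_nm=787.0, noise=False))
        b1 = sl.simulate_acquisition(bands, None, sl.AcquisitionConfig(
            excitation_nm=785.0, noise=False))
        b2 = sl.simulate_acquisition(bands, None, sl.AcquisitionConfig(
            excitation_nm=787.0, noise=False))
        # fluorescence part identical in the wavelength frame
        np.testing.assert_allclose(a1.intensity - b1.intensity,
                                   a2.intensity - b2.intensity, rtol=1e-12)
        # band maxima displaced by the expected amount on the 785-relative axis
        g = sl.canonical_grid()
        r1, r2 = sl.series_to_reference_axis([b1, b2], g)
        d = g[np.argmax(r2.intensity)] - g[np.argmax(r1.intensity)]
        expected = sl.excitation_shift_to_raman_displacement(785.0, 787.0)
        assert d == pytest.approx(expected, abs=2.0)


class TestSeries:
    def test_five_excitations_five_spectra(self):
        series = sl.simulate_serds_series(
            sl.lipid_like_fixture(), None, [784, 784.5, 785, 785.5, 786],
            sl.AcquisitionConfig(noise=False))
        assert len(series) == 5

    def test_identical_frames_cancel_exactly(self):
        series = sl.simulate_serds_series(
            sl.lipid_like_fixture(), sl.default_fluorescence(8.0),
            [785.0, 787.0], sl.AcquisitionConfig(noise=False))
        reg = sl.series_to_reference_axis(series)
        diff = reg[1].intensity - reg[0].intensity
        off_band = reg[0].axis < 950  # no lipid bands below 950 cm^-1
        assert np.abs(diff[off_band]).max() < 1e-9

    def test_bleaching_scales_each_frame(self):
        excitations = [785.0, 785.5, 786.0]
        bleached = sl.simulate_serds_series(
            sl.lipid_like_fixture(), None, excitations,
            sl.AcquisitionConfig(noise=False), bleach_factor=0.95)
        plain = sl.simulate_serds_series(
            sl.lipid_like_fixture(), None, excitations,
            sl.AcquisitionConfig(noise=False))
        for i, (b, p) in enumerate(zip(bleached, plain)):
            np.testing.assert_allclose(b.intensity, 0.95**i * p.intensity,
                                       rtol=1e-12)

    def test_duplicate_excitations_rejected(self):
        with pytest.raises(ValueError):
            sl.simulate_serds_series(sl.lipid_like_fixture(), None,
                                     [785.0, 785.0], sl.AcquisitionConfig())

    def test_noisy_expectation_matches_noiseless(self):
        """Monte-Carlo: the pixel-mean over seeds stays in a 3-sigma band."""
        bands = BandSet((Band(1450.0, 30.0, 500.0),))
        clean = sl.simulate_serds_series(bands, None, [785.0, 786.0],
                                         sl.AcquisitionConfig(noise=False))[0]
        reps = np.vstack([
            sl.simulate_serds_series(bands, None, [785.0, 786.0],
                                     sl.AcquisitionConfig(noise=True, seed=s)
                                     )[0].intensity
            for s in range(200)])
        px = int(np.argmax(clean.intensity))
        se = np.sqrt(clean.intensity[px] / 200)
        assert abs(reps[:, px].mean() - clean.intensity[px]) < 3 * se

    def test_independent_child_seeds(self):
        series = sl.simulate_serds_series(
            sl.lipid_like_fixture(), None, [785.0, 785.2],
            sl.AcquisitionConfig(noise=True, seed=1))
        assert not np.array_equal(series[0].intensity, series[1].intensity)
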