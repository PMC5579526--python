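import numpy as np
import pytest
from hypothesis import given, strategies as st

import serdslab as sl
from serdslab.serds_processing import SerdsPair

from conftest import gaussian_spectrum


def _noiseless_pair(shift_nm=2.0, power2=1.0, fluor_scale=5.0):
    fl = sl.default_fluorescence(fluor_scale) if fluor_scale else None
    series = sl.simulate_serds_series(
        sl.lipid_like_fixture(), fl, [785.0, 785.0 + shift_nm],
        sl.AcquisitionConfig(noise=False), power_factors=[1.0, power2])
    reg = sl.series_to_reference_axis(series)
    return SerdsPair(s1=reg[1], s2=reg[0])


class TestNormalizations:
    def test_area_constant_spectrum(self):
        s = sl.Spectrum(axis=np.arange(100.0), intensity=np.full(100, 7.0))
        out = sl.area_normalize(s)
        np.testing.assert_allclose(out.intensity, 0.01)

    def test_area_scale_invariance_and_unit_sum(self, lipid_pure):
        a = sl.area_normalize(lipid_pure)
        b = sl.area_normalize(lipid_pure.with_intensity(7 * lipid_pure.intensity))
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-12)
        assert a.intensity.sum() == pytest.approx(1.0, abs=1e-12)

    def test_area_zero_sum_rejected(self):
        s = sl.Spectrum(axis=np.arange(10.0), intensity=np.zeros(10))
        with pytest.raises(ValueError):
            sl.area_normalize(s)

    def test_zscore_moments(self, lipid_pure):
        out = sl.zscore_normalize(lipid_pure)
        assert out.intensity.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.intensity.std() == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(0.1, 50), st.floats(-100, 100))
    def test_zscore_affine_invariance(self, a, b):
        s = gaussian_spectrum()
        t = s.with_intensity(a * s.intensity + b)
        np.testing.assert_allclose(sl.zscore_normalize(t).intensity,
                                   sl.zscore_normalize(s).intensity, atol=1e-8)

    def test_zscore_sd_convention_flag(self):
        s = sl.Spectrum(axis=np.arange(8.0),
                        intensity=np.array([0, 2] * 4, dtype=float))
        pop = sl.zscore_normalize(s, ddof=0)
        samp = sl.zscore_normalize(s, ddof=1)
        np.testing.assert_allclose(pop.intensity,
                                   np.array([-1, 1] * 4, dtype=float))
        ratio = samp.intensity[1] / pop.intensity[1]
        assert ratio == pytest.approx(np.sqrt(7 / 8))
        assert pop.meta["zscore_ddof"] == 0 and samp.meta["zscore_ddof"] == 1

    def test_zscore_constant_rejected(self):
        s = sl.Spectrum(axis=np.arange(10.0), intensity=np.full(10, 3.0))
        with pytest.raises(ValueError):
            sl.zscore_normalize(s)


class TestSubtractionOptimize:
    def test_proportional_pair_recovers_factor(self):
        s = gaussian_spectrum(baseline=lambda x: 0.01 * x)
        pair = SerdsPair(s1=s.with_intensity(2.0 * s.intensity), s2=s)
        assert sl.subtraction_optimize(pair) == pytest.approx(2.0, abs=1e-4)

    def test_identical_pair_gives_unity(self, lipid_pure):
        pair = SerdsPair(s1=lipid_pure, s2=lipid_pure)
        assert sl.subtraction_optimize(pair) == pytest.approx(1.0, abs=1e-4)

    def test_matches_exhaustive_grid_oracle(self):
        pair = _noiseless_pair(power2=0.9)
        x_opt = sl.subtraction_optimize(pair)
        xs = np.linspace(0.2, 5.0, 100_000)
        aucs = np.concatenate([
            np.trapezoid(
                np.abs(pair.s1.intensity[None, :]
                       - chunk[:, None] * pair.s2.intensity),
                pair.s1.axis, axis=1)
            for chunk in np.array_split(xs, 50)])
        assert abs(x_opt - xs[np.argmin(aucs)]) < 1e-3

    def test_zero_s2_rejected(self, lipid_pure):
        z = lipid_pure.with_intensity(np.zeros(len(lipid_pure)))
        with pytest.raises(ValueError):
            sl.subtraction_optimize(SerdsPair(s1=lipid_pure, s2=z))


class TestSerdsDifference:
    @pytest.mark.parametrize("method, atol", [
        ("raw", 1e-9), ("area", 1e-9), ("zscore", 1e-9),
        ("subopt", 1e-2),  # x* located to ~1e-7, leaves ~1e-4 of 1000 counts
    ])
    def test_self_difference_is_zero(self, lipid_pure, method, atol):
        pair = SerdsPair(s1=lipid_pure, s2=lipid_pure)
        res = sl.serds_difference(pair, method)
        np.testing.assert_allclose(res.difference.intensity, 0.0, atol=atol)

    def test_axis_mismatch_directs_to_resample(self, lipid_pure):
        other = sl.resample_to_grid(lipid_pure, lipid_pure.axis[:-5])
        with pytest.raises(ValueError, match="resample"):
            SerdsPair(s1=lipid_pure, s2=other)

    def test_identical_background_frames_cancel(self):
        pair = _noiseless_pair(shift_nm=2.0)
        res = sl.serds_difference(pair, "raw")
        off_band = pair.s1.axis < 950
        assert np.abs(res.difference.intensity[off_band]).max() < 1e-9

    def test_power_drift_breaks_raw_but_not_subopt(self):
        """With a 10% power mismatch plain subtraction leaves background;
        subtraction optimisation removes >10x more of it."""
        pair = _noiseless_pair(shift_nm=2.0, power2=0.9)
        off_band = pair.s1.axis < 950
        raw = sl.serds_difference(pair, "raw")
        sub = sl.serds_difference(pair, "subopt")
        raw_resid = np.abs(raw.difference.intensity[off_band]).max()
        sub_resid = np.abs(sub.difference.intensity[off_band]).max()
        assert raw_resid > 10 * sub_resid
        # s1 (the longer-excitation frame) carries the 0.9 power factor
        assert sub.opt_factor == pytest.approx(0.9, rel=0.05)

    def test_raw_linearity(self):
        s = gaussian_spectrum()
        t = gaussian_spectrum(center=1600)
        pair1 = SerdsPair(s1=s, s2=t)
        pair2 = SerdsPair(s1=s.with_intensity(3 * s.intensity),
                          s2=t.with_intensity(3 * t.intensity))
        d1 = sl.serds_difference(pair1, "raw").difference.intensity
        d2 = sl.serds_difference(pair2, "raw").difference.intensity
        np.testing.assert_allclose(d2, 3 * d1, rtol=1e-12)

    def test_pair_orientation_normalized(self):
        series = sl.simulate_serds_series(
            sl.lipid_like_fixture(), None, [785.0, 787.0],
            sl.AcquisitionConfig(noise=False))
        reg = sl.series_to_reference_axis(series)
        pair = SerdsPair(s1=reg[0], s2=reg[1])  # wrong order on purpose
        assert pair.s1.meta["acquisition_excitation_nm"] == 787.0
        assert pair.shift_nm == pytest.approx(2.0)


class TestResidualPolynomial:
    def test_zero_background_unchanged(self):
        s = gaussian_spectrum()
        res = sl.SerdsResult(difference=s, method=sl.SerdsMethod.raw)
        out = sl.residual_polynomial_correct(res, degree=3)
        assert out.residual_baseline_removed
        np.testing.assert_allclose(out.difference.intensity, s.intensity,
                                   atol=1e-9)

    def test_known_cubic_removed(self):
        s = gaussian_spectrum()
        cubic = 1e-8 * (s.axis - 1800) ** 3 + 0.002 * s.axis - 1.0
        res = sl.SerdsResult(difference=s.with_intensity(s.intensity + cubic),
                             method=sl.SerdsMethod.raw)
        out = sl.residual_polynomial_correct(res, degree=3)
        off_band = np.abs(s.axis - 1450) > 120
        err = out.difference.intensity - s.intensity
        assert np.abs(err[off_band]).max() < 1e-6

    def test_degree_zero_removes_offset(self):
        s = gaussian_spectrum()
        res = sl.SerdsResult(difference=s.with_intensity(s.intensity + 25.0),
                             method=sl.SerdsMethod.raw)
        out = sl.residual_polynomial_correct(res, degree=0)
        off_band = np.abs(s.axis - 1450) > 120
        assert np.abs(out.difference.intensity - s.intensity)[off_band].max() < 0.5

    def test_degree_limits(self):
        s = gaussian_spectrum()
        res = sl.SerdsResult(difference=s, method=sl.SerdsMethod.raw)
        with pytest.raises(ValueError):
            sl.residual_polynomial_correct(res, degree=8)
        short = sl.Spectrum(axis=np.arange(30.0), intensity=np.arange(30.0) ** 2)
        with pytest.raises(ValueError):
            sl.residual_polynomial_correct(
                sl.SerdsResult(difference=short, method=sl.SerdsMethod.raw),
                degree=5)
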