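import numpy as np
import pytest

from volca.errors import DegenerateFitError, DetectionError, ParameterError
from volca.io import MovieMeta
from volca.optics import (
    BeamProfileSeries,
    chromatic_shift,
    fit_beam_waist,
    fit_gaussian_1d,
    fit_gaussian_2d,
    measure_psf,
    profile_series_widths,
    rayleigh_length,
)
from volca.synth import make_bead_stack, make_beam_profile_series


def gauss1d(x, d, A, x0, sigma):
    return d + A * np.exp(-((x - x0) ** 2) / (2 * sigma**2))


class TestGaussian1D:
    def test_noiseless_recovery(self):
        x = np.linspace(-10, 10, 81)
        y = gauss1d(x, 1.5, 10.0, 0.7, 2.0)
        fit = fit_gaussian_1d(x, y)
        assert fit.sigma == pytest.approx(2.0, abs=1e-6)
        assert fit.x0 == pytest.approx(0.7, abs=1e-6)
        assert fit.A == pytest.approx(10.0, rel=1e-6)

    def test_translation_equivariance(self):
        x = np.linspace(-10, 10, 81)
        y = gauss1d(x, 0.0, 5.0, 0.0, 1.5)
        f0 = fit_gaussian_1d(x, y)
        f1 = fit_gaussian_1d(x + 3.0, y)
        assert f1.x0 - f0.x0 == pytest.approx(3.0, abs=1e-8)
        assert f1.sigma == pytest.approx(f0.sigma, abs=1e-8)

    def test_offset_shift(self):
        x = np.linspace(-8, 8, 65)
        y = gauss1d(x, 0.5, 4.0, 1.0, 1.2)
        f0 = fit_gaussian_1d(x, y)
        f1 = fit_gaussian_1d(x, y + 2.5)
        assert f1.d - f0.d == pytest.approx(2.5, abs=1e-8)
        assert f1.sigma == pytest.approx(f0.sigma, abs=1e-8)

    def test_bias_below_2_percent_at_snr_20(self):
        x = np.linspace(-10, 10, 101)
        clean = gauss1d(x, 1.0, 10.0, 0.0, 2.0)
        rng = np.random.default_rng(0)
        sigmas = [fit_gaussian_1d(x, clean + rng.normal(0, 0.5, x.size)).sigma
                  for _ in range(40)]
        assert np.mean(sigmas) == pytest.approx(2.0, rel=0.02)

    def test_constant_profile_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_gaussian_1d(np.arange(10.0), np.ones(10))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ParameterError):
            fit_gaussian_1d(np.arange(4.0), np.arange(4.0))


class TestGaussian2D:
    def _image(self, sx, sy, theta=0.0, shape=(41, 41)):
        y, x = np.mgrid[: shape[0], : shape[1]].astype(float)
        xc, yc = (shape[1] - 1) / 2, (shape[0] - 1) / 2
        xr = (x - xc) * np.cos(theta) + (y - yc) * np.sin(theta)
        yr = -(x - xc) * np.sin(theta) + (y - yc) * np.cos(theta)
        return 0.5 + 7.0 * np.exp(-(xr**2) / (2 * sx**2) - (yr**2) / (2 * sy**2))

    def test_axis_aligned_recovery(self):
        fit = fit_gaussian_2d(self._image(3.0, 1.0), fix_theta_zero=True)
        assert fit.sigma_x == pytest.approx(3.0, abs=1e-6)
        assert fit.sigma_y == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_gaussian_gives_equal_sigmas(self):
        fit = fit_gaussian_2d(self._image(2.0, 2.0), fix_theta_zero=True)
        assert fit.sigma_x == pytest.approx(fit.sigma_y, rel=1e-8)

    def test_rotation_by_90_degrees_swaps_sigmas(self):
        img = self._image(3.0, 1.0)
        f0 = fit_gaussian_2d(img, fix_theta_zero=True)
        f90 = fit_gaussian_2d(np.rot90(img), fix_theta_zero=True)
        assert f90.sigma_x == pytest.approx(f0.sigma_y, abs=1e-6)
        assert f90.sigma_y == pytest.approx(f0.sigma_x, abs=1e-6)

    def test_rotated_fit_recovers_angle_consistent_widths(self):
        img = self._image(3.0, 1.0, theta=0.4)
        fit = fit_gaussian_2d(img, fix_theta_zero=False)
        widths = sorted([fit.sigma_x, fit.sigma_y])
        assert widths == pytest.approx([1.0, 3.0], abs=1e-5)
        a, b, c = fit.abc
        # rotation identities tie (a, b, c) to the fitted parameters
        assert a > 0 and c > 0 and a * c - b**2 > 0


class TestBeamWaist:
    def test_recovery_from_synthetic_series(self):
        positions = np.linspace(-80, 80, 17)
        images = make_beam_profile_series(2.7, 54.0, positions, noise=0.0)
        series = profile_series_widths(images, positions, wavelength_um=0.561)
        w0, xr, x0 = fit_beam_waist(series)
        assert w0 == pytest.approx(2.7, rel=1e-4)
        assert xr == pytest.approx(54.0, rel=1e-4)
        assert abs(x0) < 1e-3

    def test_hyperbola_identities(self):
        w0, xr, x0 = 2.0, 30.0, 5.0
        w = lambda x: w0 * np.sqrt(1 + ((x - x0) / xr) ** 2)
        assert w(x0) == pytest.approx(w0)
        assert w(x0 + xr) == pytest.approx(w0 * np.sqrt(2))

    def test_reversal_symmetry(self):
        positions = np.linspace(-60, 60, 13)
        w = 2.5 * np.sqrt(1 + (positions / 40.0) ** 2)
        s_fwd = BeamProfileSeries(positions, w / 2)
        s_rev = BeamProfileSeries(np.sort(-positions), (w / 2)[::-1])
        w0f, xrf, _ = fit_beam_waist(s_fwd)
        w0r, xrr, _ = fit_beam_waist(s_rev)
        assert w0r == pytest.approx(w0f, rel=1e-8)
        assert xrr == pytest.approx(xrf, rel=1e-8)

    def test_too_few_positions_rejected(self):
        with pytest.raises(ParameterError):
            profile_series_widths([np.zeros((8, 8))], [0.0])


class TestRayleighLength:
    def test_hand_value(self):
        # n pi w0^2 / lambda = 1.33 * pi * 4 / 0.561
        assert rayleigh_length(2.0, 0.561, 1.33) == pytest.approx(29.79, abs=0.01)

    def test_scaling_laws(self):
        base = rayleigh_length(1.5, 0.561, 1.33)
        assert rayleigh_length(3.0, 0.561, 1.33) == pytest.approx(4 * base)
        assert rayleigh_length(1.5, 0.561, 1.0) == pytest.approx(base / 1.33)

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            rayleigh_length(-1.0, 0.561, 1.33)


class TestMeasurePSF:
    # fine sampling for PSF work, anisotropic to exercise unit conversion
    psf_meta = MovieMeta(voxel_size=(0.5, 0.325, 0.325), frame_interval=0.5,
                         plane_exposure=0.01, n_planes=32)

    def test_recovers_20x_psf_scale(self):
        # lateral 0.9 um / axial 1.7 um, the 20x objective regime
        positions = [(8.0, 6.0, 6.0), (8.0, 14.0, 6.0), (8.0, 6.0, 14.0), (8.0, 14.0, 14.0)]
        stack = make_bead_stack((1.7, 0.9, 0.9), positions, self.psf_meta,
                                shape=(32, 64, 64), noise=0.5, seed=1)
        psf = measure_psf(stack, n_beads=4, meta=self.psf_meta)
        assert psf.n_beads == 4
        np.testing.assert_allclose(psf.mean, [1.7, 0.9, 0.9], rtol=0.05)

    def test_single_bead_reports_zero_sd(self):
        stack = make_bead_stack((1.7, 0.9, 0.9), [(8.0, 10.0, 10.0)], self.psf_meta,
                                shape=(32, 64, 64), noise=0.0)
        psf = measure_psf(stack, n_beads=1, meta=self.psf_meta)
        assert psf.n_beads == 1
        np.testing.assert_array_equal(psf.sd, 0.0)

    def test_anisotropic_voxels_converted_to_um(self):
        # same physical PSF measured at two samplings must agree in um
        meta2 = MovieMeta(voxel_size=(0.25, 0.65, 0.65), frame_interval=1.0,
                          plane_exposure=0.01, n_planes=64)
        s1 = make_bead_stack((1.7, 0.9, 0.9), [(8.0, 10.0, 10.0)], self.psf_meta,
                             shape=(32, 64, 64))
        s2 = make_bead_stack((1.7, 0.9, 0.9), [(8.0, 10.0, 10.0)], meta2,
                             shape=(64, 32, 32))
        p1 = measure_psf(s1, 1, self.psf_meta)
        p2 = measure_psf(s2, 1, meta2)
        np.testing.assert_allclose(p1.mean, p2.mean, rtol=0.05)

    def test_empty_stack_raises(self):
        with pytest.raises(DetectionError):
            measure_psf(np.zeros((16, 16, 16)), 1, self.psf_meta)


class TestChromaticShift:
    meta = MovieMeta(voxel_size=(0.5, 0.325, 0.325), frame_interval=0.5,
                     plane_exposure=0.01, n_planes=32)

    def _field(self, offset=(0.0, 0.0, 0.0)):
        positions = [(6.0, 5.0, 5.0), (10.0, 14.0, 8.0), (7.0, 8.0, 16.0)]
        moved = [tuple(np.add(p, offset)) for p in positions]
        return make_bead_stack((1.0, 0.6, 0.6), moved, self.meta, shape=(32, 64, 64))

    def test_identical_stacks_zero_shift(self):
        a = self._field()
        np.testing.assert_allclose(chromatic_shift(a, a.copy(), self.meta), 0.0, atol=1e-9)

    def test_one_micron_axial_shift_recovered(self):
        a, b = self._field(), self._field((1.0, 0.0, 0.0))
        dz, dy, dx = chromatic_shift(a, b, self.meta, n_beads=3)
        assert dz == pytest.approx(1.0, abs=0.1)
        assert abs(dy) < 0.1 and abs(dx) < 0.1

    def test_unmatched_fields_raise(self):
        a = self._field()
        b = make_bead_stack((1.0, 0.6, 0.6), [(25.0, 30.0, 30.0)], self.meta,
                            shape=(64, 128, 128))
        with pytest.raises(DetectionError):
            chromatic_shift(a, b[:32, :64, :64] * 0 + np.median(a), self.meta)
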