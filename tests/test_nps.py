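"""NPS estimation: detrending, 2D spectrum, radial rebin, f_av."""

import numpy as np
import pytest

from ctiq.nps import (
    NPS2D,
    NPSRadial,
    average_frequency,
    compute_nps_2d,
    detrend_roi,
    noise_magnitude,
    radial_rebin,
)
from ctiq.phantom import NoiseModel, SceneSpec, generate_uniform_stack
from ctiq.nps import quadrant_rois
from ctiq.stack import ImageStack, SquareROI


def _white_stack(sigma=10.0, n_slices=40, size=512, spacing=0.5, seed=4):
    scene = SceneSpec(image_size_pixels=size, pixel_spacing_mm=spacing,
                      n_slices=n_slices, noise=NoiseModel(sigma, "white", seed=seed))
    return generate_uniform_stack(scene)


class TestDetrend:
    def test_quadratic_surface_residual_is_zero(self):
        y, x = np.mgrid[0:32, 0:32]
        patch = 3.0 + 0.5 * x - 0.2 * y + 0.01 * x * x - 0.02 * x * y + 0.03 * y * y
        res = detrend_roi(patch)
        assert np.max(np.abs(res)) < 1e-9 * np.max(np.abs(patch))

    def test_linear_ramp_residual_is_zero(self):
        y, x = np.mgrid[0:16, 0:16]
        res = detrend_roi(10.0 + 2.0 * x + 3.0 * y)
        assert np.max(np.abs(res)) < 1e-9 * 100

    def test_residual_sums_to_zero(self, rng):
        res = detrend_roi(rng.normal(0, 5, (24, 24)))
        assert abs(res.sum()) < 1e-8 * 24 * 24 * 5

    def test_white_noise_dof_correction(self, rng):
        # residual variance ≈ sigma^2 (1 - 6/N): Monte-Carlo over patches
        n = 16 * 16
        ratios = [
            detrend_roi(rng.normal(0, 1, (16, 16))).var() for _ in range(400)
        ]
        assert np.mean(ratios) == pytest.approx(1 - 6 / n, abs=0.01)

    def test_too_small_patch_rejected(self):
        with pytest.raises(ValueError):
            detrend_roi(np.zeros((4, 4)))


class TestComputeNPS2D:
    def test_constant_stack_gives_zero(self, constant_stack):
        nps = compute_nps_2d(constant_stack, [SquareROI(32, 32, 16)])
        assert np.max(np.abs(nps.values)) < 1e-18

    def test_white_noise_level(self):
        # mean 2D NPS ≈ sigma^2 dx dy at 160 ROI instances
        stack = _white_stack()
        nps = compute_nps_2d(stack, quadrant_rois(stack, 128))
        assert nps.values.mean() == pytest.approx(25.0, rel=0.05)

    def test_brute_force_dft_equivalence(self, rng):
        """Single 16x16 ROI: FFT path equals an explicit Fourier-sum oracle."""
        img = rng.normal(0, 5, (1, 16, 16))
        stack = ImageStack(img, 0.7, 0.6)
        roi = SquareROI(8, 8, 16)
        nps = compute_nps_2d(stack, [roi], correct_detrend_bias=False)
        patch = detrend_roi(roi.extract(stack, 0))
        n = 16
        ks = np.arange(n)
        brute = np.zeros((n, n), dtype=complex)
        for ky in range(n):
            for kx in range(n):
                phase = np.exp(
                    -2j * np.pi * (np.outer(ks * ky, np.ones(n)) / n
                                   + np.outer(np.ones(n), ks * kx) / n)
                )
                brute[ky, kx] = (patch * phase).sum()
        expected = np.fft.fftshift(np.abs(brute) ** 2) * (0.7 * 0.6) / (n * n)
        assert np.allclose(nps.values, expected, rtol=1e-10, atol=1e-12)

    def test_spectral_linearity(self):
        a = compute_nps_2d(_white_stack(sigma=5, n_slices=10, size=256),
                           quadrant_rois(_white_stack(sigma=5, n_slices=1, size=256), 64))
        b = compute_nps_2d(_white_stack(sigma=10, n_slices=10, size=256),
                           quadrant_rois(_white_stack(sigma=10, n_slices=1, size=256), 64))
        assert b.values.mean() / a.values.mean() == pytest.approx(4.0, rel=0.1)

    def test_requires_rois(self, constant_stack):
        with pytest.raises(ValueError):
            compute_nps_2d(constant_stack, [])

    def test_slice_range_validated(self, constant_stack):
        with pytest.raises(ValueError):
            compute_nps_2d(constant_stack, [SquareROI(32, 32, 16)], (0, 99))


class TestRadialRebin:
    def _analytic_nps2d(self, fn, n=64, step=0.02):
        axis = (np.arange(n) - n // 2) * step
        fy, fx = np.meshgrid(axis, axis, indexing="ij")
        return NPS2D(values=fn(np.hypot(fy, fx)), freq_step_x=step, freq_step_y=step)

    def test_rotationally_symmetric_profile_recovered(self):
        g = lambda r: np.exp(-r / 0.3)
        nps = self._analytic_nps2d(g)
        radial = radial_rebin(nps)
        # bin means of g at sampled radii agree with g at bin centers
        assert np.max(np.abs(radial.values - g(radial.freq))) < 0.05

    def test_flat_input_flat_profile(self):
        nps = self._analytic_nps2d(lambda r: np.ones_like(r))
        radial = radial_rebin(nps)
        assert np.allclose(radial.values, 1.0)

    def test_single_bin_is_grand_mean(self):
        nps = self._analytic_nps2d(lambda r: r)
        nyq = nps.nyquist
        radial = radial_rebin(nps, bin_width=2 * nyq)
        fy, fx = np.meshgrid(nps.freq_y, nps.freq_x, indexing="ij")
        rho = np.hypot(fy, fx)
        expected = nps.values[rho <= nyq].mean()
        assert radial.values.size == 1
        assert radial.values[0] == pytest.approx(expected)

    def test_corner_frequencies_excluded(self):
        nps = self._analytic_nps2d(lambda r: np.ones_like(r))
        radial = radial_rebin(nps)
        assert radial.freq.max() <= nps.nyquist + 1e-12


class TestNoiseMagnitude:
    def test_white_noise_recovery(self):
        stack = _white_stack()
        nps = compute_nps_2d(stack, quadrant_rois(stack, 128))
        assert noise_magnitude(nps) == pytest.approx(10.0, abs=0.3)

    def test_zero_spectrum(self):
        nps = NPS2D(np.zeros((16, 16)), 0.1, 0.1)
        assert noise_magnitude(nps) == 0.0

    def test_homogeneity(self, rng):
        vals = rng.uniform(0, 2, (16, 16))
        a = noise_magnitude(NPS2D(vals, 0.1, 0.1))
        b = noise_magnitude(NPS2D(4 * vals, 0.1, 0.1))
        assert b == pytest.approx(2 * a)


class TestAverageFrequency:
    def test_flat_profile_half_nyquist(self):
        stack = _white_stack()
        nps = compute_nps_2d(stack, quadrant_rois(stack, 128))
        radial = radial_rebin(nps)
        assert average_frequency(radial) == pytest.approx(1.0 / (2 * 0.5) / 2, rel=0.02)

    def test_single_nonzero_bin(self):
        radial = NPSRadial(
            freq=np.array([0.1, 0.2, 0.3]),
            values=np.array([0.0, 5.0, 0.0]),
            counts=np.array([4, 4, 4]),
        )
        assert average_frequency(radial) == pytest.approx(0.2, abs=0.02)

    def test_analytic_ramp(self):
        f = np.linspace(0.005, 1.0, 200)
        radial = NPSRadial(freq=f, values=f.copy(), counts=np.full(f.size, 9))
        assert average_frequency(radial) == pytest.approx(2.0 / 3.0, rel=0.01)

    def test_scale_invariance(self):
        f = np.linspace(0.005, 1.0, 100)
        v = np.exp(-f / 0.2) * f
        a = average_frequency(NPSRadial(f, v, np.full(f.size, 9)))
        b = average_frequency(NPSRadial(f, 7.3 * v, np.full(f.size, 9)))
        assert a == pytest.approx(b)

    def test_all_zero_profile_errors(self):
        radial = NPSRadial(np.array([0.1, 0.2]), np.zeros(2), np.array([4, 4]))
        with pytest.raises(ValueError):
            average_frequency(radial)


class TestParsevalConservation:
    def test_noise_magnitude_matches_detrended_sd(self):
        stack = _white_stack()
        rois = quadrant_rois(stack, 128)
        nps = compute_nps_2d(stack, rois, correct_detrend_bias=False)
        from ctiq.nps import detrend_roi

        sq = 0.0
        n = 0
        for k in range(stack.n_slices):
            for roi in rois:
                r = detrend_roi(roi.extract(stack, k))
                sq += (r**2).sum()
                n += r.size
        ensemble_sd = np.sqrt(sq / n)
        assert noise_magnitude(nps) == pytest.approx(ensemble_sd, rel=0.01)
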