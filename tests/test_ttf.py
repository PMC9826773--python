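"""Circular-edge TTF: center finding, ESF, LSF, transfer function."""

import numpy as np
import pytest
from scipy.stats import norm

from ctiq.stack import CircularROI
from ctiq.ttf import (
    DetectionError,
    EdgeProfile,
    LSFProfile,
    compute_ttf,
    esf_to_lsf,
    estimate_center,
    extract_esf,
    lsf_to_ttf,
    ttf_at_fraction,
)
from tests.conftest import make_disk_stack

CENTER_PX = 127.5
ROI = CircularROI(CENTER_PX, CENTER_PX, 22.0)
TRUE_CENTER_MM = 256 * 0.488 / 2


def gaussian_ttf50(sigma_b: float) -> float:
    return float(np.sqrt(np.log(2) / 2) / (np.pi * sigma_b))


class TestEstimateCenter:
    def test_noiseless_disk_subpixel(self):
        stack = make_disk_stack(0.5)
        cx, cy = estimate_center(stack, ROI)
        assert abs(cx - TRUE_CENTER_MM) < 0.1 * 0.488
        assert abs(cy - TRUE_CENTER_MM) < 0.1 * 0.488

    def test_tracks_fractional_shift(self):
        shift = 3.3 * 0.488
        stack = make_disk_stack(0.5, center_offset_mm=(shift, 0.0))
        cx, cy = estimate_center(stack, CircularROI(CENTER_PX, CENTER_PX + 3.3, 22.0))
        assert abs(cx - (TRUE_CENTER_MM + shift)) < 0.1 * 0.488
        assert abs(cy - TRUE_CENTER_MM) < 0.1 * 0.488

    def test_zero_contrast_raises(self):
        stack = make_disk_stack(0.5, contrast=0.0)
        with pytest.raises(DetectionError):
            estimate_center(stack, ROI)


class TestExtractESF:
    def test_step_edge_confined(self):
        stack = make_disk_stack(0.0, contrast=80.0)
        esf = extract_esf(stack, ROI, (TRUE_CENTER_MM, TRUE_CENTER_MM),
                          bin_width_mm=0.1)
        inside = esf.esf_hu[esf.radius_mm < 12.2]
        outside = esf.esf_hu[esf.radius_mm > 12.8]
        assert np.allclose(inside, 80.0, atol=1e-9)
        assert np.allclose(outside, 0.0, atol=1e-9)

    def test_gaussian_edge_matches_normal_cdf(self):
        sigma_b = 0.5
        stack = make_disk_stack(sigma_b, contrast=100.0)
        esf = extract_esf(stack, ROI, (TRUE_CENTER_MM, TRUE_CENTER_MM),
                          bin_width_mm=0.05)
        band = (esf.radius_mm > 10.5) & (esf.radius_mm < 14.5)
        expected = 100.0 * norm.cdf((12.5 - esf.radius_mm[band]) / sigma_b)
        assert np.max(np.abs(esf.esf_hu[band] - expected)) < 2.0

    def test_bin_refinement_stability(self):
        stack = make_disk_stack(0.5, contrast=100.0)
        esf1 = extract_esf(stack, ROI, (TRUE_CENTER_MM, TRUE_CENTER_MM),
                           bin_width_mm=0.1)
        esf2 = extract_esf(stack, ROI, (TRUE_CENTER_MM, TRUE_CENTER_MM),
                           bin_width_mm=0.05)
        common = np.interp(esf1.radius_mm, esf2.radius_mm, esf2.esf_hu)
        band = (esf1.radius_mm > 5) & (esf1.radius_mm < 20)
        # residual is bin-discretization only (noiseless): ~2% of contrast
        assert np.max(np.abs(esf1.esf_hu[band] - common[band])) < 2.0


class TestEsfToLsf:
    def test_step_esf_single_impulse(self):
        r = np.arange(0.05, 20, 0.1)
        esf = EdgeProfile(r, np.where(r < 10, 100.0, 0.0), np.ones(r.size), 0.1)
        lsf = esf_to_lsf(esf, smooth=False)
        peak = np.argmax(lsf.lsf)
        assert abs(r[peak] - 10.0) < 0.2
        off_edge = np.abs(r - 10.0) > 0.3
        assert np.max(np.abs(lsf.lsf[off_edge])) < 1e-9

    def test_gaussian_esf_gives_gaussian_lsf(self):
        sigma_b = 0.5
        r = np.arange(0.05, 25, 0.05)
        esf = EdgeProfile(r, 100 * norm.cdf((12.5 - r) / sigma_b),
                          np.ones(r.size), 0.05)
        lsf = esf_to_lsf(esf, smooth=False)
        # second-moment width of the (positive) LSF
        w = lsf.lsf / lsf.lsf.sum()
        mu = (w * r).sum()
        sd = np.sqrt((w * (r - mu) ** 2).sum())
        assert sd == pytest.approx(sigma_b, rel=0.05)

    def test_constant_esf_zero_lsf(self):
        r = np.arange(0.05, 10, 0.1)
        esf = EdgeProfile(r, np.full(r.size, 55.0), np.ones(r.size), 0.1)
        assert np.max(np.abs(esf_to_lsf(esf, smooth=False).lsf)) < 1e-9

    def test_peak_sign_positive(self):
        stack = make_disk_stack(0.5)
        esf = extract_esf(stack, ROI, (TRUE_CENTER_MM, TRUE_CENTER_MM))
        lsf = esf_to_lsf(esf)
        assert lsf.lsf.max() > abs(lsf.lsf.min())

    def test_too_few_bins(self):
        esf = EdgeProfile(np.arange(3.0), np.zeros(3), np.ones(3), 1.0)
        with pytest.raises(ValueError):
            esf_to_lsf(esf)


class TestLsfToTtf:
    def test_impulse_lsf_is_unity(self):
        r = np.arange(0.05, 20, 0.1)
        lsf = np.zeros(r.size)
        lsf[100] = 50.0
        res = lsf_to_ttf(LSFProfile(r, lsf, 0.1), taper=False,
                         baseline_correct=False, correct_kernels=False)
        assert np.allclose(res.ttf, 1.0, atol=1e-9)

    def test_gaussian_lsf_fourier_pair(self):
        sigma_b = 0.5
        r = np.arange(0.025, 25, 0.05)
        lsf = norm.pdf(r, loc=12.5, scale=sigma_b)
        res = lsf_to_ttf(LSFProfile(r, lsf, 0.05), correct_kernels=False)
        expected = np.exp(-2 * np.pi**2 * sigma_b**2 * res.freq_mm_inv**2)
        band = expected > 0.2
        assert np.max(np.abs(res.ttf[band] - expected[band])) < 0.02

    def test_scaling_invariance(self):
        r = np.arange(0.025, 25, 0.05)
        lsf = norm.pdf(r, loc=12.5, scale=0.4)
        a = lsf_to_ttf(LSFProfile(r, lsf, 0.05))
        b = lsf_to_ttf(LSFProfile(r, 13.7 * lsf, 0.05))
        assert np.allclose(a.ttf, b.ttf)

    def test_zero_sum_lsf_raises(self):
        r = np.arange(0.05, 10, 0.1)
        with pytest.raises(ValueError):
            lsf_to_ttf(LSFProfile(r, np.zeros(r.size), 0.1))

    def test_normalized_at_zero_frequency(self):
        stack = make_disk_stack(0.5)
        res = compute_ttf(stack, ROI, smooth=False)
        assert res.ttf[0] == pytest.approx(1.0, abs=1e-6)
        assert res.freq_mm_inv[0] == 0.0


class TestTtfAtFraction:
    def test_gaussian_closed_form(self):
        stack = make_disk_stack(0.5)
        res = compute_ttf(stack, ROI, smooth=False)
        assert ttf_at_fraction(res, 0.5) == pytest.approx(0.3748, abs=0.01)

    def test_doubling_sigma_halves_ttf50(self):
        r1 = compute_ttf(make_disk_stack(0.4), ROI, smooth=False)
        r2 = compute_ttf(make_disk_stack(0.8), ROI, smooth=False)
        assert ttf_at_fraction(r1, 0.5) / ttf_at_fraction(r2, 0.5) == pytest.approx(
            2.0, rel=0.02
        )

    def test_fraction_one_is_zero_frequency(self):
        res = compute_ttf(make_disk_stack(0.5), ROI, smooth=False)
        assert ttf_at_fraction(res, 1.0) == 0.0

    def test_never_crossing_raises(self):
        from ctiq.ttf import TTFResult

        res = TTFResult(np.linspace(0, 1, 50), np.full(50, 0.9), 100.0, 1)
        with pytest.raises(ValueError):
            ttf_at_fraction(res, 0.5)


class TestEndToEndRecovery:
    @pytest.mark.parametrize("sigma_b", [0.3, 0.5, 0.8])
    def test_noiseless_recovery_within_3pct(self, sigma_b):
        stack = make_disk_stack(sigma_b)
        res = compute_ttf(stack, ROI, smooth=False)
        assert ttf_at_fraction(res, 0.5) == pytest.approx(
            gaussian_ttf50(sigma_b), rel=0.03
        )

    def test_noisy_recovery_within_10pct(self):
        stack = make_disk_stack(0.5, noise_sigma=20.0, n_slices=20, seed=5)
        res = compute_ttf(stack, ROI)
        assert ttf_at_fraction(res, 0.5) == pytest.approx(
            gaussian_ttf50(0.5), rel=0.10
        )

    def test_invariance_to_offset_and_contrast_scale(self):
        base = compute_ttf(make_disk_stack(0.5, contrast=120.0), ROI, smooth=False)
        shifted = make_disk_stack(0.5, contrast=240.0)
        shifted.voxels += 1000.0  # global HU offset
        other = compute_ttf(shifted, ROI, smooth=False)
        assert ttf_at_fraction(base, 0.5) == pytest.approx(
            ttf_at_fraction(other, 0.5), rel=1e-3
        )

    def test_measured_contrast_reported(self):
        res = compute_ttf(make_disk_stack(0.5, contrast=120.0), ROI, smooth=False)
        assert res.insert_contrast_hu == pytest.approx(120.0, abs=1.0)
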