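"""Noise power spectrum estimation from uniform-region stacks.

The 2D NPS is the ensemble average of detrended ROI periodograms,

    NPS_2D(fx, fy) = (dx*dy)/(Lx*Ly) * (1/N) * sum_i |FFT2{ROI_i - FIT_i}|^2,

where FIT_i is a per-ROI second-order polynomial surface (removes slow HU
drifts so only stochastic noise enters the spectrum) and N counts every
(ROI x slice) instance averaged.  From it we derive

* the radially rebinned 1D NPS,
* the noise magnitude  sqrt(integral of the 2D NPS)  — the standard
  deviation of the detrended noise, by Parseval, and
* the average spatial frequency f_av = int f NPS(f) df / int NPS(f) df,
  a scalar noise-texture descriptor (lower = blotchier noise).

Conventions: no window or taper beyond detrending; radial bins default to
one 2D frequency step; the radial range and f_av quadrature are capped at
the axis Nyquist frequency (corner samples beyond it are excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stack import ImageStack, SquareROI

__all__ = [
    "NPS2D",
    "NPSRadial",
    "NPSResult",
    "detrend_roi",
    "compute_nps_2d",
    "radial_rebin",
    "noise_magnitude",
    "average_frequency",
    "compute_nps",
]


@dataclass
class NPS2D:
    """2D NPS samples (HU^2 mm^2) on an fftshift-ed frequency grid."""

    values: np.ndarray
    freq_step_x: float
    freq_step_y: float

    @property
    def freq_x(self) -> np.ndarray:
        n = self.values.shape[1]
        return (np.arange(n) - n // 2) * self.freq_step_x

    @property
    def freq_y(self) -> np.ndarray:
        n = self.values.shape[0]
        return (np.arange(n) - n // 2) * self.freq_step_y

    @property
    def nyquist(self) -> float:
        """Axis Nyquist frequency (the smaller of the two axes)."""
        ny = self.values.shape[0] // 2 * self.freq_step_y
        nx = self.values.shape[1] // 2 * self.freq_step_x
        return min(nx, ny)


@dataclass
class NPSRadial:
    freq: np.ndarray
    values: np.ndarray
    counts: np.ndarray


@dataclass
class NPSResult:
    nps2d: NPS2D
    radial: NPSRadial
    noise_magnitude: float
    f_av: float
    n_rois_total: int
    meta: dict | None = None


def _design_matrix(n_rows: int, n_cols: int) -> np.ndarray:
    """Second-order 2D polynomial basis on centered, normalized coordinates."""
    y = np.linspace(-1.0, 1.0, n_rows)
    x = np.linspace(-1.0, 1.0, n_cols)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    cols = [np.ones_like(xx), xx, yy, xx * xx, xx * yy, yy * yy]
    return np.stack([c.ravel() for c in cols], axis=1)


def detrend_roi(roi_pixels: np.ndarray, _cache: dict = {}) -> np.ndarray:
    """Residual of a least-squares second-order polynomial surface fit."""
    roi_pixels = np.asarray(roi_pixels, dtype=float)
    if roi_pixels.ndim != 2 or min(roi_pixels.shape) < 8:
        raise ValueError("ROI patch must be 2D and at least 8x8")
    shape = roi_pixels.shape
    if shape not in _cache:
        a = _design_matrix(*shape)
        _cache[shape] = (a, np.linalg.pinv(a))
    a, pinv = _cache[shape]
    coef = pinv @ roi_pixels.ravel()
    if not np.all(np.isfinite(coef)):
        raise np.linalg.LinAlgError("degenerate polynomial fit")
    return roi_pixels - (a @ coef).reshape(shape)


def _detrend_attenuation(shape: tuple[int, int], _cache: dict = {}) -> np.ndarray:
    """Expected fraction of white-noise power surviving detrending, per
    2D frequency (fftshift-ed).

    Projecting out the 6-dim quadratic surface removes power concentrated
    at the lowest frequencies (the first radial bin loses ~40%).  For an
    orthonormal basis Q of the fit space, the surviving fraction at DFT
    bin k is ``1 - sum_j |FFT(q_j)_k|^2 / N``; dividing the averaged
    periodogram by it removes the low-frequency notch the fit introduces.
    The DC bin survives with fraction 0 (the constant term absorbs it
    entirely) and cannot be corrected; it is left as measured (~0).
    """
    if shape not in _cache:
        a = _design_matrix(*shape)
        q, _ = np.linalg.qr(a)
        n = a.shape[0]
        absorbed = np.zeros(shape)
        for j in range(q.shape[1]):
            absorbed += np.abs(np.fft.fft2(q[:, j].reshape(shape))) ** 2
        _cache[shape] = np.fft.fftshift(1.0 - absorbed / n)
    return _cache[shape]


def compute_nps_2d(
    stack: ImageStack,
    rois: list[SquareROI],
    slice_range: tuple[int, int] | None = None,
    correct_detrend_bias: bool = True,
) -> NPS2D:
    """Average detrended periodogram over all (ROI x slice) instances.

    ``slice_range`` is a half-open (start, stop) slice-index interval;
    all ROIs must share one side length.  With ``correct_detrend_bias``
    the spectrum is divided by the expected detrending attenuation (see
    :func:`_detrend_attenuation`); bins attenuated below 20% (the DC bin)
    are left uncorrected.
    """
    if not rois:
        raise ValueError("need at least one ROI")
    sides = {r.side_pixels for r in rois}
    if len(sides) > 1:
        raise ValueError("all ROIs must share one side length")
    side = sides.pop()
    for r in rois:
        r.validate(stack)
    if slice_range is None:
        slice_range = (0, stack.n_slices)
    start, stop = slice_range
    if not (0 <= start < stop <= stack.n_slices):
        raise ValueError(f"slice_range {slice_range} outside stack")
    dx, dy = stack.pixel_spacing_x, stack.pixel_spacing_y
    lx, ly = side * dx, side * dy
    acc = np.zeros((side, side))
    n_instances = 0
    for k in range(start, stop):
        for roi in rois:
            patch = detrend_roi(roi.extract(stack, k))
            acc += np.abs(np.fft.fft2(patch)) ** 2
            n_instances += 1
    # |FFT| here is numpy's unscaled DFT; the physical FT carries a factor
    # dx*dy, so (dx dy)/(Lx Ly) * |FT|^2  ==  (dx dy)/(Nx Ny) * |DFT|^2.
    nps = np.fft.fftshift(acc) * (dx * dy) / (side * side) / n_instances
    if correct_detrend_bias:
        r = _detrend_attenuation((side, side))
        nps = np.where(r > 0.2, nps / np.maximum(r, 0.2), nps)
    return NPS2D(values=nps, freq_step_x=1.0 / lx, freq_step_y=1.0 / ly)


def radial_rebin(nps2d: NPS2D, bin_width: float | None = None) -> NPSRadial:
    """Mean of 2D NPS samples per radial-frequency bin.

    Samples beyond the axis Nyquist (grid corners) are excluded; the
    zero-frequency sample lands in the first bin; empty bins are dropped.
    """
    if bin_width is None:
        bin_width = max(nps2d.freq_step_x, nps2d.freq_step_y)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    fy, fx = np.meshgrid(nps2d.freq_y, nps2d.freq_x, indexing="ij")
    rho = np.hypot(fy, fx).ravel()
    vals = nps2d.values.ravel()
    keep = rho <= nps2d.nyquist + 1e-12
    rho, vals = rho[keep], vals[keep]
    idx = np.floor(rho / bin_width).astype(int)
    n_bins = idx.max() + 1
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    nonempty = counts > 0
    centers = (np.arange(n_bins) + 0.5) * bin_width
    # The last bin is truncated by the Nyquist cap; place its coordinate at
    # the cap rather than beyond it.
    centers = np.minimum(centers, nps2d.nyquist)
    return NPSRadial(
        freq=centers[nonempty],
        values=sums[nonempty] / counts[nonempty],
        counts=counts[nonempty],
    )


def noise_magnitude(nps2d: NPS2D) -> float:
    """Standard deviation of the detrended noise implied by the spectrum:
    the square root of the integrated 2D NPS (Parseval)."""
    total = nps2d.values.sum() * nps2d.freq_step_x * nps2d.freq_step_y
    return float(np.sqrt(max(total, 0.0)))


def average_frequency(radial: NPSRadial) -> float:
    """Trapezoidal quadrature of f_av over the binned radial profile.

    The profile is extended to f = 0 with its edge value so the quadrature
    runs over the full [0, Nyquist] band.  A leading bin holding only the
    zero-frequency sample is skipped: detrending absorbs the DC term
    entirely, so that sample carries no spectral information.
    """
    freq = radial.freq
    values = radial.values
    counts = radial.counts
    if freq.size and counts[0] == 1 and freq.size > 1 and freq[0] < freq[1] - freq[0]:
        freq, values, counts = freq[1:], values[1:], counts[1:]
    if freq.size < 2:
        raise ValueError("need at least 2 radial bins")
    if freq[0] > 0:
        freq = np.concatenate([[0.0], freq])
        values = np.concatenate([[values[0]], values])
    den = np.trapezoid(values, freq)
    if den <= 0:
        raise ValueError("all-zero NPS profile: f_av undefined")
    num = np.trapezoid(freq * values, freq)
    return float(num / den)


def compute_nps(
    stack: ImageStack,
    rois: list[SquareROI],
    slice_range: tuple[int, int] | None = None,
    bin_width: float | None = None,
) -> NPSResult:
    """Full NPS pipeline: 2D spectrum, radial profile, magnitude, f_av."""
    nps2d = compute_nps_2d(stack, rois, slice_range)
    radial = radial_rebin(nps2d, bin_width)
    if slice_range is None:
        slice_range = (0, stack.n_slices)
    return NPSResult(
        nps2d=nps2d,
        radial=radial,
        noise_magnitude=noise_magnitude(nps2d),
        f_av=average_frequency(radial),
        n_rois_total=len(rois) * (slice_range[1] - slice_range[0]),
        meta={
            "noise_magnitude_definition": "sqrt(integral of 2D NPS)",
            "slice_range": list(slice_range),
            "n_rois": len(rois),
        },
    )


def quadrant_rois(stack: ImageStack, side_pixels: int = 128) -> list[SquareROI]:
    """Four square ROIs tiling the central region, one per quadrant."""
    _, n_rows, n_cols = stack.shape
    cr, cc = n_rows // 2, n_cols // 2
    h = side_pixels // 2
    return [
        SquareROI(cr - h, cc - h, side_pixels),
        SquareROI(cr - h, cc + h, side_pixels),
        SquareROI(cr + h, cc - h, side_pixels),
        SquareROI(cr + h, cc + h, side_pixels),
    ]
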