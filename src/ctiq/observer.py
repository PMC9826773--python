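"""Non-prewhitening model observer with eye filter (NPWE).

The detectability index d' summarizes how well an observer that applies a
template matched to the expected signal — without prewhitening the noise —
can detect a disk-shaped low-contrast lesion, given the imaging system's
resolution (TTF), its noise spectrum (NPS), and the human visual system's
contrast sensitivity (eye filter E):

    d'^2 = [ integral |W|^2 TTF^2 E^2 du dv ]^2
           -----------------------------------------
           integral |W|^2 TTF^2 NPS^k E^4 du dv

with the task function W the Fourier modulus of the
signal-present-minus-absent hypothesis — for a uniform disk of radius R
and contrast C,  W(rho) = C * pi R^2 * |2 J1(2 pi R rho) / (2 pi R rho)|.

``nps_exponent`` k defaults to 1 (the standard NPWE denominator, linear in
the noise power); k = 2 is available as a configuration switch for
compatibility with formulations that square the NPS.

The eye filter acts on angular frequency (cycles/degree on the retina):
``E(rho_deg) = rho_deg^1.5 * exp(-c * rho_deg^2)``, normalized to a peak
of 1, with c chosen so the peak sits at 4 cycles/degree.  Image-plane
frequencies are converted to angular frequencies through a display model
(zoom, monitor pixel pitch, reconstruction field of view, viewing
distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import j1

from .nps import NPSResult
from .ttf import TTFResult

__all__ = [
    "TaskSpec",
    "DisplayModel",
    "FrequencyGrid",
    "DPrimeResult",
    "task_function",
    "eye_filter",
    "frequency_conversion",
    "dprime_npwe",
]


@dataclass(frozen=True)
class TaskSpec:
    """Disk-detection task: lesion diameter and contrast."""

    diameter_mm: float
    contrast_hu: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be > 0")


@dataclass(frozen=True)
class DisplayModel:
    """Viewing conditions for the eye filter.

    The display magnification is ``M = zoom * display_pixel_mm /
    image_pixel_mm`` with the image pixel implied by the reconstruction
    field of view over a 512 matrix; displayed frequency is ``f_image / M``
    and angular frequency ``f_disp * viewing_distance_mm * pi / 180``.
    """

    zoom: float = 1.5
    viewing_distance_mm: float = 500.0
    display_fov_mm: float = 300.0
    display_pixel_mm: float = 0.05
    matrix: int = 512

    def __post_init__(self) -> None:
        for name in ("zoom", "viewing_distance_mm", "display_fov_mm", "display_pixel_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def image_pixel_mm(self) -> float:
        return self.display_fov_mm / self.matrix

    @property
    def magnification(self) -> float:
        return self.zoom * self.display_pixel_mm / self.image_pixel_mm


@dataclass(frozen=True)
class EyeFilterParams:
    """E(rho) = rho**exponent * exp(-c * rho**2), peak normalized to 1."""

    exponent: float = 1.5
    peak_cyc_per_deg: float = 4.0

    @property
    def c(self) -> float:
        # dE/drho = 0  =>  rho_peak^2 = exponent / (2 c)
        return self.exponent / (2.0 * self.peak_cyc_per_deg**2)


@dataclass
class FrequencyGrid:
    """Cartesian (u, v) spatial-frequency grid, symmetric about zero."""

    u: np.ndarray
    v: np.ndarray
    step_u: float
    step_v: float

    @classmethod
    def for_pixel(cls, pixel_mm: float, n: int = 256) -> "FrequencyGrid":
        """Grid spanning +/- the Nyquist frequency of a pixel size (DFT
        sampling: zero frequency is on the grid)."""
        nyq = 1.0 / (2.0 * pixel_mm)
        step = 2.0 * nyq / n
        axis = (np.arange(n) - n // 2) * step
        u, v = np.meshgrid(axis, axis, indexing="xy")
        return cls(u=u, v=v, step_u=step, step_v=step)

    @property
    def rho(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass
class DPrimeResult:
    d_prime: float
    task: TaskSpec
    components: dict = field(default_factory=dict)


def task_function(task: TaskSpec, grid: FrequencyGrid) -> np.ndarray:
    """|Fourier transform| of a uniform disk of the task's size/contrast.

    W(rho) = C * pi R^2 * |2 J1(2 pi R rho)/(2 pi R rho)|, W(0) = C pi R^2
    (units HU * mm^2).
    """
    radius = task.diameter_mm / 2.0
    arg = 2.0 * np.pi * radius * grid.rho
    jinc = np.ones_like(arg)
    nz = arg > 0
    jinc[nz] = 2.0 * j1(arg[nz]) / arg[nz]
    return task.contrast_hu * np.pi * radius**2 * np.abs(jinc)


def frequency_conversion(display: DisplayModel, f_image: np.ndarray | float) -> np.ndarray | float:
    """Image-plane frequency (mm^-1) to angular frequency (cycles/degree)."""
    m = display.magnification
    if m <= 0:
        raise ValueError("nonpositive display magnification")
    f_disp = np.asarray(f_image, dtype=float) / m
    out = f_disp * display.viewing_distance_mm * np.pi / 180.0
    return float(out) if np.isscalar(f_image) else out


def eye_filter(
    display: DisplayModel,
    grid: FrequencyGrid,
    params: EyeFilterParams = EyeFilterParams(),
) -> np.ndarray:
    """Eye-filter values on the grid, peak-normalized to 1."""
    rho_deg = np.asarray(frequency_conversion(display, grid.rho))
    e = rho_deg**params.exponent * np.exp(-params.c * rho_deg**2)
    peak = params.peak_cyc_per_deg**params.exponent * np.exp(
        -params.c * params.peak_cyc_per_deg**2
    )
    return e / peak


def _radial_interp(
    freq: np.ndarray, values: np.ndarray, rho: np.ndarray, beyond: str
) -> np.ndarray:
    """Linear radial interpolation onto the grid.

    ``beyond`` sets extrapolation past the last measured frequency:
    ``"last"`` (hold the last value; used for TTF) or ``"zero"`` (used for
    NPS).
    """
    right = values[-1] if beyond == "last" else 0.0
    return np.interp(rho, freq, values, left=values[0], right=right)


def dprime_npwe(
    task: TaskSpec,
    ttf: TTFResult | None,
    nps: NPSResult | None,
    display: DisplayModel | None,
    grid: FrequencyGrid,
    nps_exponent: int = 1,
    eye_params: EyeFilterParams = EyeFilterParams(),
    white_nps_value: float | None = None,
) -> DPrimeResult:
    """NPWE detectability index on a Cartesian frequency grid.

    ``ttf=None`` means ideal resolution (TTF ≡ 1); ``display=None`` means no
    eye filter (E ≡ 1); ``nps=None`` with ``white_nps_value`` uses a flat
    spectrum of that value (HU^2 mm^2).  Numerator and denominator are
    discrete Riemann sums; the stored components allow auditing.
    """
    w = task_function(task, grid)
    rho = grid.rho
    if ttf is None:
        t = np.ones_like(rho)
    else:
        t = _radial_interp(ttf.freq_mm_inv, ttf.ttf, rho, beyond="last")
    if nps is None:
        if white_nps_value is None:
            raise ValueError("provide an NPSResult or white_nps_value")
        s = np.full_like(rho, float(white_nps_value))
    else:
        s = _radial_interp(nps.radial.freq, nps.radial.values, rho, beyond="zero")
    e = np.ones_like(rho) if display is None else eye_filter(display, grid, eye_params)
    da = grid.step_u * grid.step_v
    w2t2 = w**2 * t**2
    numerator = float((w2t2 * e**2).sum() * da)
    denominator = float((w2t2 * s**nps_exponent * e**4).sum() * da)
    if denominator <= 0:
        raise ValueError(
            "zero noise in the task band: d' undefined (add a noise floor)"
        )
    d2 = numerator**2 / denominator
    return DPrimeResult(
        d_prime=float(np.sqrt(d2)),
        task=task,
        components={
            "numerator_integral": numerator,
            "denominator_integral": denominator,
            "nps_exponent": nps_exponent,
        },
    )
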