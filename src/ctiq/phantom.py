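"""Synthetic phantom-image generator.

Produces :class:`~ctiq.stack.ImageStack` objects with *known* statistical
structure so that every analysis stage has ground truth:

* uniform modules carrying stationary noise of a prescribed magnitude
  (standard deviation, HU) and radial power-spectral shape, emulating the
  uniform section of a QA phantom;
* circular inserts of known contrast blurred by a Gaussian point-spread
  function, emulating an acrylic resolution insert or iodine inserts, whose
  ground-truth task transfer function is exactly
  ``TTF(f) = exp(-2 pi^2 sigma_b^2 f^2)``.

Noise shaping: a white Gaussian field is filtered in the frequency domain
with ``sqrt(S(f))``, where the radial spectral shape is either flat
(``white``) or CT-like ``S(f) ∝ f * exp(-f / f0)`` (``ramp_gauss``), which
rises to a maximum at ``f0`` and decays — the typical look of filtered-
backprojection / mildly regularized CT noise.  The filter is normalized on
the discrete grid, so the expected empirical variance equals ``sigma_hu**2``
exactly and the implied noise power spectrum integrates to the variance.

Slices are generated as independent realizations: the analysis treats
slices as ensemble members, and this is the cleanest null structure.  Real
CT stacks have inter-slice noise correlation; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy import integrate, optimize
from scipy.stats import ncx2

from .stack import GeometryError, ImageStack

__all__ = [
    "NoiseModel",
    "InsertSpec",
    "SceneSpec",
    "shaped_noise_field",
    "generate_uniform_stack",
    "generate_insert_stack",
    "generate_study",
    "theoretical_fav",
    "f0_for_target_fav",
]


@dataclass(frozen=True)
class NoiseModel:
    """Stationary noise description.

    sigma_hu
        Target noise magnitude: the standard deviation of the noise field
        in HU (equivalently the square root of the integrated NPS).
    shape
        ``"white"`` (flat spectrum) or ``"ramp_gauss"``
        (radial NPS ∝ f·exp(−f/f0)).
    f0_mm_inv
        Texture scale of the ramp_gauss shape; the radial NPS peaks at f0
        and the untruncated NPS-weighted mean frequency is 2·f0.
    seed
        Seed for the underlying white field.
    """

    sigma_hu: float
    shape: str = "white"
    f0_mm_inv: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_hu < 0:
            raise ValueError("sigma_hu must be >= 0")
        if self.shape not in ("white", "ramp_gauss"):
            raise ValueError(f"unknown noise shape {self.shape!r}")
        if self.shape == "ramp_gauss" and not (
            self.f0_mm_inv is not None and self.f0_mm_inv > 0
        ):
            raise ValueError("ramp_gauss requires f0_mm_inv > 0")

    def radial_density(self, f: np.ndarray) -> np.ndarray:
        """Unnormalized radial NPS shape S(f) (2D spectral density profile)."""
        f = np.asarray(f, dtype=float)
        if self.shape == "white":
            return np.ones_like(f)
        return f * np.exp(-f / self.f0_mm_inv)


@dataclass(frozen=True)
class InsertSpec:
    """A cylindrical (circular in-plane) insert above the background."""

    center_x_mm: float
    center_y_mm: float
    diameter_mm: float
    contrast_hu: float
    psf_sigma_mm: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be > 0")
        if self.psf_sigma_mm < 0:
            raise ValueError("psf_sigma_mm must be >= 0")


@dataclass
class SceneSpec:
    """Full description of a synthetic phantom scene."""

    image_size_pixels: int = 512
    pixel_spacing_mm: float = 0.488
    n_slices: int = 40
    background_hu: float = 0.0
    inserts: list[InsertSpec] = field(default_factory=list)
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(sigma_hu=0.0))
    slice_thickness_mm: float = 0.5

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        for i, a in enumerate(self.inserts):
            for b in self.inserts[i + 1 :]:
                d = np.hypot(a.center_x_mm - b.center_x_mm, a.center_y_mm - b.center_y_mm)
                if d < (a.diameter_mm + b.diameter_mm) / 2:
                    raise ValueError(f"inserts overlap: {a.label!r} and {b.label!r}")


def _radial_freq_grid(size: tuple[int, int], spacing: tuple[float, float]) -> np.ndarray:
    fy = np.fft.fftfreq(size[0], d=spacing[0])
    fx = np.fft.fftfreq(size[1], d=spacing[1])
    return np.hypot(*np.meshgrid(fy, fx, indexing="ij"))


def shaped_noise_field(
    noise: NoiseModel,
    size: int | tuple[int, int],
    pixel_spacing: float | tuple[float, float],
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One 2D realization of the noise model, in HU.

    The field has zero mean (exactly, for shaped noise, whose DC filter gain
    is zero; in expectation for white noise) and expected pixel variance
    ``sigma_hu**2``.
    """
    if isinstance(size, int):
        size = (size, size)
    if min(size) < 64:
        raise ValueError("noise field must be at least 64 pixels in each dimension")
    if isinstance(pixel_spacing, (int, float)):
        pixel_spacing = (float(pixel_spacing), float(pixel_spacing))
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    if noise.sigma_hu == 0:
        return np.zeros(size)
    white = rng.standard_normal(size)
    if noise.shape == "white":
        return noise.sigma_hu * white
    rho = _radial_freq_grid(size, pixel_spacing)
    gain2 = noise.radial_density(rho)
    gain2 *= noise.sigma_hu**2 / gain2.mean()
    field2 = np.fft.ifft2(np.fft.fft2(white) * np.sqrt(gain2)).real
    return field2


def _insert_profile(insert: InsertSpec, r_mm: np.ndarray) -> np.ndarray:
    """Gaussian-blurred disk evaluated at radial distances, exactly.

    The convolution of an indicator disk (radius R) with an isotropic 2D
    Gaussian (sigma) at distance r from the center equals the probability
    mass of the Gaussian inside the disk, i.e. a noncentral chi-square CDF:
    ``P = ncx2.cdf((R/sigma)^2, df=2, nc=(r/sigma)^2)``.
    """
    radius = insert.diameter_mm / 2.0
    if insert.psf_sigma_mm == 0:
        return insert.contrast_hu * (r_mm <= radius).astype(float)
    s = insert.psf_sigma_mm
    return insert.contrast_hu * ncx2.cdf((radius / s) ** 2, df=2, nc=(r_mm / s) ** 2)


def _noiseless_slice(scene: SceneSpec) -> np.ndarray:
    n = scene.image_size_pixels
    d = scene.pixel_spacing_mm
    coords = (np.arange(n) + 0.5) * d
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    img = np.full((n, n), scene.background_hu, dtype=float)
    fov = n * d
    for ins in scene.inserts:
        reach = ins.diameter_mm / 2 + 4 * ins.psf_sigma_mm
        if (
            ins.center_x_mm - reach < 0
            or ins.center_y_mm - reach < 0
            or ins.center_x_mm + reach > fov
            or ins.center_y_mm + reach > fov
        ):
            raise GeometryError(f"insert {ins.label!r} extends outside the field")
        r = np.hypot(yy - ins.center_y_mm, xx - ins.center_x_mm)
        img += _insert_profile(ins, r)
    return img


def _stack_from_scene(scene: SceneSpec, base_slice: np.ndarray) -> ImageStack:
    rng = np.random.default_rng(scene.noise.seed)
    n = scene.image_size_pixels
    slices = np.empty((scene.n_slices, n, n))
    for k in range(scene.n_slices):
        slices[k] = base_slice
        if scene.noise.sigma_hu > 0:
            slices[k] += shaped_noise_field(
                scene.noise, (n, n), scene.pixel_spacing_mm, rng=rng
            )
    meta = {
        "sigma_hu": scene.noise.sigma_hu,
        "noise_shape": scene.noise.shape,
        "f0_mm_inv": scene.noise.f0_mm_inv,
        "seed": scene.noise.seed,
        "background_hu": scene.background_hu,
        "inserts": [
            {
                "label": i.label,
                "center_x_mm": i.center_x_mm,
                "center_y_mm": i.center_y_mm,
                "diameter_mm": i.diameter_mm,
                "contrast_hu": i.contrast_hu,
                "psf_sigma_mm": i.psf_sigma_mm,
            }
            for i in scene.inserts
        ],
    }
    return ImageStack(
        voxels=slices,
        pixel_spacing_x=scene.pixel_spacing_mm,
        pixel_spacing_y=scene.pixel_spacing_mm,
        slice_thickness=scene.slice_thickness_mm,
        slice_increment=scene.slice_thickness_mm,
        meta=meta,
    )


def generate_uniform_stack(scene: SceneSpec) -> ImageStack:
    """Uniform-module stack: background + independent noise per slice."""
    if scene.inserts:
        raise ValueError("uniform scene must have no inserts")
    n = scene.image_size_pixels
    base = np.full((n, n), scene.background_hu, dtype=float)
    return _stack_from_scene(scene, base)


def generate_insert_stack(scene: SceneSpec) -> ImageStack:
    """Insert stack: Gaussian-blurred disks on the background, plus noise."""
    return _stack_from_scene(scene, _noiseless_slice(scene))


# ------------------------------------------------------------- texture math

def theoretical_fav(noise: NoiseModel, nyquist_mm_inv: float) -> float:
    """NPS-weighted mean radial frequency of the model spectrum.

    Numerical quadrature of ``∫ f·S(f) df / ∫ S(f) df`` over the radial
    profile, truncated at the given Nyquist frequency — the same convention
    the NPS analysis uses for measured spectra.
    """
    num, _ = integrate.quad(lambda f: f * noise.radial_density(np.array(f)), 0, nyquist_mm_inv)
    den, _ = integrate.quad(lambda f: noise.radial_density(np.array(f)), 0, nyquist_mm_inv)
    if den == 0:
        raise ValueError("degenerate spectral shape")
    return num / den


def f0_for_target_fav(target_fav: float, nyquist_mm_inv: float) -> float:
    """Invert :func:`theoretical_fav` for the ramp_gauss shape."""
    if not 0 < target_fav < 2 * nyquist_mm_inv / 3:
        raise ValueError("target f_av out of attainable range for ramp_gauss")

    def gap(f0: float) -> float:
        return (
            theoretical_fav(NoiseModel(1.0, "ramp_gauss", f0), nyquist_mm_inv)
            - target_fav
        )

    return optimize.brentq(gap, 1e-4, 10.0, xtol=1e-8)


# ------------------------------------------------------------- study design

@dataclass
class StudyCase:
    """All synthetic stacks for one (version, level, keV) condition."""

    version: str
    level: str
    keV: int
    uniform: list[ImageStack]
    ttf_insert: list[ImageStack]
    multi_energy: list[ImageStack]


def generate_study(
    table1_contrasts: Mapping[tuple[float, int, str, str], float],
    table2_noise: Mapping[tuple[str, str, int], float],
    texture_fav: Mapping[tuple[str, str, int], float],
    ttf50_targets: Mapping[tuple[str, str, int], float],
    keys: Iterable[tuple[str, str, int]] | None = None,
    n_replicates: int = 3,
    seed_base: int = 0,
    acr_size: int = 512,
    acr_slices_nps: int = 40,
    acr_slices_ttf: int = 20,
    me_size: int = 512,
    me_slices: int = 8,
) -> dict[tuple[str, str, int], StudyCase]:
    """Generate the full emulated study, keyed by (version, level, keV).

    For each key three kinds of stacks are produced per replicate:

    * a uniform ACR-like stack (pixel 0.488 mm) whose noise magnitude is the
      noise table entry and whose texture realizes the target f_av;
    * an acrylic-insert stack with the same noise and a Gaussian PSF chosen
      so the ground-truth TTF_50 equals the TTF_50 target;
    * a multi-energy-phantom-like stack (pixel 0.82 mm) with a solid-water
      insert and iodine inserts at the contrast-table values, with noise.

    ``table1_contrasts`` is keyed (concentration_mg_ml, keV, version, level);
    the other tables are keyed (version, level, keV).  Replicate ``r`` uses
    seed ``seed_base + hash-free arithmetic offset + r`` so regeneration is
    deterministic.
    """
    acr_spacing = 0.488
    me_spacing = 0.82
    if keys is None:
        keys = sorted(table2_noise.keys())
    out: dict[tuple[str, str, int], StudyCase] = {}
    _versions = {"V1": 1, "V2": 2}
    _levels = {"mild": 0, "standard": 1, "strong": 2}
    key_list = list(keys)
    for key in key_list:
        version, level, keV = key
        # Stable per-condition seed offset, independent of iteration order.
        ki = _versions.get(version, 3) * 40 + _levels.get(level, 3) * 10 + keV // 10
        if key not in table2_noise:
            raise KeyError(f"noise table missing {key}")
        if key not in texture_fav:
            raise KeyError(f"texture table missing {key}")
        if key not in ttf50_targets:
            raise KeyError(f"TTF50 table missing {key}")
        sigma = table2_noise[key]
        nyq = 1.0 / (2 * acr_spacing)
        f0 = f0_for_target_fav(texture_fav[key], nyq)
        ttf50 = ttf50_targets[key]
        psf_sigma = float(np.sqrt(np.log(2) / 2) / (np.pi * ttf50))
        concs = sorted(
            {c for (c, k, v, l) in table1_contrasts if (v, l, k) == key},
            reverse=True,
        )
        uniform, ttf_ins, multi = [], [], []
        for r in range(n_replicates):
            seed = seed_base + 1000 * ki + r
            noise = NoiseModel(sigma, "ramp_gauss", f0, seed=seed)
            uni_scene = SceneSpec(
                image_size_pixels=acr_size,
                pixel_spacing_mm=acr_spacing,
                n_slices=acr_slices_nps,
                noise=noise,
            )
            stk = generate_uniform_stack(uni_scene)
            stk.meta.update(version=version, level=level, energy_keV=keV, replicate=r)
            uniform.append(stk)

            half_acr = acr_size * acr_spacing / 2
            ttf_scene = SceneSpec(
                image_size_pixels=acr_size,
                pixel_spacing_mm=acr_spacing,
                n_slices=acr_slices_ttf,
                inserts=[
                    InsertSpec(half_acr, half_acr, 25.0, 120.0, psf_sigma, "acrylic")
                ],
                noise=NoiseModel(sigma, "ramp_gauss", f0, seed=seed + 500),
            )
            stk = generate_insert_stack(ttf_scene)
            stk.meta.update(
                version=version, level=level, energy_keV=keV, replicate=r,
                ttf50_target=ttf50,
            )
            ttf_ins.append(stk)

            fov_me = me_size * me_spacing
            offsets = [
                (fov_me / 2 - fov_me / 5, fov_me / 2 - fov_me / 5),
                (fov_me / 2 + fov_me / 5, fov_me / 2 - fov_me / 5),
                (fov_me / 2 - fov_me / 5, fov_me / 2 + fov_me / 5),
                (fov_me / 2 + fov_me / 5, fov_me / 2 + fov_me / 5),
            ]
            inserts = [
                InsertSpec(offsets[0][0], offsets[0][1], 28.0, 0.0, psf_sigma, "solid_water")
            ]
            for ci, conc in enumerate(concs[:3]):
                contrast = table1_contrasts[(conc, keV, version, level)]
                inserts.append(
                    InsertSpec(
                        offsets[ci + 1][0], offsets[ci + 1][1],
                        28.0, contrast, psf_sigma, f"iodine_{conc}",
                    )
                )
            me_scene = SceneSpec(
                image_size_pixels=me_size,
                pixel_spacing_mm=me_spacing,
                n_slices=me_slices,
                inserts=inserts,
                noise=NoiseModel(sigma, "ramp_gauss", f0, seed=seed + 900),
            )
            stk = generate_insert_stack(me_scene)
            stk.meta.update(version=version, level=level, energy_keV=keV, replicate=r)
            multi.append(stk)
        out[key] = StudyCase(version, level, keV, uniform, ttf_ins, multi)
    return out
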