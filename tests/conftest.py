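import numpy as np
import pytest

from ctiq.phantom import InsertSpec, NoiseModel, SceneSpec, generate_insert_stack
from ctiq.stack import ImageStack


@pytest.fixture()
def constant_stack() -> ImageStack:
    """Three 64x64 slices of uniform 100 HU."""
    return ImageStack(
        voxels=np.full((3, 64, 64), 100.0),
        pixel_spacing_x=0.5,
        pixel_spacing_y=0.5,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def make_disk_stack(
    sigma_b: float,
    noise_sigma: float = 0.0,
    n_slices: int = 1,
    size: int = 256,
    seed: int = 0,
    contrast: float = 120.0,
    spacing: float = 0.488,
    noise_shape: str = "white",
    f0: float | None = None,
    center_offset_mm: tuple[float, float] = (0.0, 0.0),
) -> ImageStack:
    """Acrylic-like blurred disk centered (optionally offset) in the field."""
    half = size * spacing / 2
    scene = SceneSpec(
        image_size_pixels=size,
        pixel_spacing_mm=spacing,
        n_slices=n_slices,
        inserts=[
            InsertSpec(
                half + center_offset_mm[0],
                half + center_offset_mm[1],
                25.0,
                contrast,
                sigma_b,
                "insert",
            )
        ],
        noise=NoiseModel(noise_sigma, noise_shape, f0, seed=seed),
    )
    return generate_insert_stack(scene)
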