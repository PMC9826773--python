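"""Reference tables and generator calibration defaults.

Two CSVs transcribed from the source study ship with the package:

* ``contrast_vmi.csv`` — iodine-insert contrast (HU) per iodine
  concentration, VMI energy level, reconstruction version (V1/V2) and
  reconstruction level (mild/standard/strong);
* ``noise_magnitude.csv`` — uniform-module noise magnitude (HU) per
  version, energy and reconstruction level.

These are the *targets the simulator emulates* (the raw scanner images are
not public), and the inputs to the derived-percentage reproduction.

The texture (f_av) and TTF_50 calibration tables below are the package's
own defaults: the study reports those quantities only as figures and
percent differences, so the values here were chosen once to place each
condition in the reported qualitative regime — f_av decreasing from mild
to strong at every energy, higher f_av and TTF_50 for V2 than V1, V2's
texture coarsening from 40 to 60 keV — at realistic abdominal-CT
magnitudes (f_av ~ 0.15-0.31 mm^-1, TTF_50 ~ 0.21-0.51 mm^-1).  See the
methods note for the calibration rationale.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_contrast_table",
    "load_noise_table",
    "contrast_lookup",
    "noise_lookup",
    "DEFAULT_FAV_TARGETS",
    "DEFAULT_TTF50_TARGETS",
    "VERSIONS",
    "LEVELS",
    "ENERGIES_KEV",
    "CONCENTRATIONS_MG_ML",
]

VERSIONS = ("V1", "V2")
LEVELS = ("mild", "standard", "strong")
ENERGIES_KEV = (40, 50, 60, 70)
CONCENTRATIONS_MG_ML = (2.0, 1.0, 0.5)


def _read(name: str) -> pd.DataFrame:
    with resources.files("ctiq.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_contrast_table() -> pd.DataFrame:
    """Iodine contrast reference table (long format)."""
    return _read("contrast_vmi.csv")


def load_noise_table() -> pd.DataFrame:
    """Noise-magnitude reference table (long format)."""
    return _read("noise_magnitude.csv")


def contrast_lookup() -> dict[tuple[float, int, str, str], float]:
    """{(concentration, keV, version, level): contrast HU}."""
    df = load_contrast_table()
    return {
        (float(r.concentration_mg_ml), int(r.keV), r.version, r.level): float(r.mean_hu)
        for r in df.itertuples()
    }


def noise_lookup() -> dict[tuple[str, str, int], float]:
    """{(version, level, keV): noise magnitude HU}."""
    df = load_noise_table()
    return {
        (r.version, r.level, int(r.keV)): float(r.mean_hu) for r in df.itertuples()
    }


# Noise-texture calibration: target NPS-weighted mean frequency (mm^-1)
# per (version, level, keV).
DEFAULT_FAV_TARGETS: dict[tuple[str, str, int], float] = {
    ("V1", "mild", 40): 0.220,
    ("V1", "mild", 50): 0.220,
    ("V1", "mild", 60): 0.200,
    ("V1", "mild", 70): 0.208,
    ("V1", "standard", 40): 0.190,
    ("V1", "standard", 50): 0.190,
    ("V1", "standard", 60): 0.175,
    ("V1", "standard", 70): 0.182,
    ("V1", "strong", 40): 0.160,
    ("V1", "strong", 50): 0.160,
    ("V1", "strong", 60): 0.147,
    ("V1", "strong", 70): 0.156,
    ("V2", "mild", 40): 0.310,
    ("V2", "mild", 50): 0.265,
    ("V2", "mild", 60): 0.228,
    ("V2", "mild", 70): 0.235,
    ("V2", "standard", 40): 0.235,
    ("V2", "standard", 50): 0.205,
    ("V2", "standard", 60): 0.175,
    ("V2", "standard", 70): 0.181,
    ("V2", "strong", 40): 0.220,
    ("V2", "strong", 50): 0.195,
    ("V2", "strong", 60): 0.165,
    ("V2", "strong", 70): 0.145,
}

# Spatial-resolution calibration: target TTF_50 (mm^-1) per
# (version, level, keV); the generator converts these to Gaussian PSF
# widths sigma_b = sqrt(ln 2 / 2) / (pi * TTF_50).
DEFAULT_TTF50_TARGETS: dict[tuple[str, str, int], float] = {
    ("V1", "mild", 40): 0.30,
    ("V1", "mild", 50): 0.30,
    ("V1", "mild", 60): 0.29,
    ("V1", "mild", 70): 0.28,
    ("V1", "standard", 40): 0.29,
    ("V1", "standard", 50): 0.28,
    ("V1", "standard", 60): 0.26,
    ("V1", "standard", 70): 0.25,
    ("V1", "strong", 40): 0.22,
    ("V1", "strong", 50): 0.23,
    ("V1", "strong", 60): 0.22,
    ("V1", "strong", 70): 0.21,
    ("V2", "mild", 40): 0.51,
    ("V2", "mild", 50): 0.49,
    ("V2", "mild", 60): 0.46,
    ("V2", "mild", 70): 0.44,
    ("V2", "standard", 40): 0.35,
    ("V2", "standard", 50): 0.33,
    ("V2", "standard", 60): 0.31,
    ("V2", "standard", 70): 0.30,
    ("V2", "strong", 40): 0.27,
    ("V2", "strong", 50): 0.27,
    ("V2", "strong", 60): 0.27,
    ("V2", "strong", 70): 0.28,
}
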