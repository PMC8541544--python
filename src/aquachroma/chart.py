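"""Reference colour chart: nominal patch values and synthetic reflectances.

The 24-patch classic chart ships as nominal 8-bit sRGB render values (CSV
asset).  For the synthetic scene each patch needs a smooth reflectance
spectrum; since measured chart reflectances are not available here, a
three-Gaussian spectral uplift of the linearised triple is used — a
synthetic stand-in whose only job is to give the correction fit a diverse,
physically plausible set of known colours.  The same spectra feed both the
camera simulation and the reference rendering, so the two sides of the
correction fit are consistent by construction.
"""

from __future__ import annotations

import importlib.resources
from functools import lru_cache

import numpy as np
import pandas as pd

from .colorimetry import (
    M_XYZ_TO_RGB,
    chromaticity_of_spectrum,
    integrate_tristimulus,
    srgb_eocf,
)
from .optics import Illuminant
from .spectra import Spectrum

#: spectral uplift basis: broad R/G/B reflectance lobes (centre nm, sigma nm)
UPLIFT_BASES = ((610.0, 55.0), (545.0, 45.0), (465.0, 40.0))
UPLIFT_FLOOR = 0.02
UPLIFT_SCALE = 0.9


@lru_cache(maxsize=1)
def load_chart() -> pd.DataFrame:
    """Patch table with linearised sRGB triples (columns lin_r/lin_g/lin_b).

    The patch name column is exposed as ``name_`` so the frame iterates
    cleanly with ``itertuples``.
    """
    ref = importlib.resources.files("aquachroma.data") / "colorchecker_classic_srgb.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, comment="#")
    lin = srgb_eocf(df[["srgb_r", "srgb_g", "srgb_b"]].to_numpy() / 255.0)
    df["lin_r"], df["lin_g"], df["lin_b"] = lin.T
    df = df.rename(columns={"name": "name_"})
    return df


def patch_reflectance(lin_rgb, grid: np.ndarray) -> np.ndarray:
    """Synthetic smooth reflectance for one patch from its linear triple."""
    r = np.zeros_like(grid, dtype=float)
    for weight, (centre, sd) in zip(lin_rgb, UPLIFT_BASES):
        r += weight * np.exp(-0.5 * ((grid - centre) / sd) ** 2)
    return np.clip(UPLIFT_SCALE * r + UPLIFT_FLOOR, 0.0, 1.0)


def reference_patch_rgb(ill: Illuminant) -> np.ndarray:
    """(24, 3) ideal linear-RGB rendering of the patches under ``ill``.

    This is the target side of the correction fit: patch radiance
    E(λ)·R(λ) is reduced to XYZ with the standard observer, normalised by
    the illuminant's Y, and mapped through the linear-sRGB bridge.  The
    level scalar cancels by construction, so correction matrices also
    normalise exposure.
    """
    grid = ill.spectrum.wavelengths
    y_ill = integrate_tristimulus(ill.spectrum).Y
    chart = load_chart()
    out = []
    for row in chart.itertuples():
        refl = patch_reflectance((row.lin_r, row.lin_g, row.lin_b), grid)
        t = integrate_tristimulus(
            Spectrum(grid, ill.spectrum.values * refl, unit="relative_radiance")
        )
        out.append(M_XYZ_TO_RGB @ (t.as_array() / y_ill))
    return np.array(out)


def illuminant_chromaticity(ill: Illuminant):
    return chromaticity_of_spectrum(ill.spectrum)
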