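"""Device-independent colour math.

The retrieval of "true water colour" reduces a sensed spectrum I(λ) to CIE
tristimulus values by weighting with the standard-observer colour matching
functions,

    X = ∫ I(λ) x̄(λ) dλ,   Y = ∫ I(λ) ȳ(λ) dλ,   Z = ∫ I(λ) z̄(λ) dλ,

normalises them to chromaticity coordinates x = X/(X+Y+Z) (and cyclically for
y, z), and expresses the colour as the hue angle

    α = atan2(y − y_w, x − x_w)  mod 2π

around the equal-energy white point (x_w, y_w) = (1/3, 1/3).  The module also
provides the fixed linear-sRGB/D65 bridge between linear RGB triples and XYZ,
used after camera colour correction.

The colour matching functions are shipped as a 5 nm CSV tabulation of an
analytic representation of the CIE 1931 2° observer, renormalised so all
three curves integrate identically — the equal-energy spectrum then maps to
(1/3, 1/3) exactly.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import (
    AchromaticSampleError,
    RangeError,
    SpectrumDomainError,
    UndefinedChromaticityError,
)
from .spectra import Spectrum, union_grid

WHITE_POINT = (1.0 / 3.0, 1.0 / 3.0)

#: linear sRGB -> XYZ, D65 white (IEC 61966-2-1 primaries)
M_RGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
M_XYZ_TO_RGB = np.linalg.inv(M_RGB_TO_XYZ)


@dataclass(frozen=True)
class TristimulusTriple:
    X: float
    Y: float
    Z: float

    def __post_init__(self) -> None:
        if min(self.X, self.Y, self.Z) < 0:
            raise SpectrumDomainError("tristimulus values must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.X, self.Y, self.Z])


@dataclass(frozen=True)
class Chromaticity:
    x: float
    y: float

    @property
    def z(self) -> float:
        return 1.0 - self.x - self.y

    def __post_init__(self) -> None:
        for v in (self.x, self.y, self.z):
            if not -1e-9 <= v <= 1 + 1e-9:
                raise SpectrumDomainError("chromaticity coordinates must lie in [0, 1]")

    def distance_to_white(self) -> float:
        return float(np.hypot(self.x - WHITE_POINT[0], self.y - WHITE_POINT[1]))


@dataclass(frozen=True)
class HueAngle:
    """Hue angle in radians, reduced to [0, 2π)."""

    alpha: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", float(self.alpha) % (2 * np.pi))

    @property
    def degrees(self) -> float:
        return float(np.degrees(self.alpha))


class ColorMatchingFunctions:
    """Standard-observer weighting functions x̄, ȳ, z̄ on a wavelength grid."""

    def __init__(self, wavelengths, xbar, ybar, zbar):
        w = np.asarray(wavelengths, dtype=float)
        bars = np.vstack([xbar, ybar, zbar]).astype(float)
        if np.any(bars < 0):
            raise SpectrumDomainError("colour matching functions must be non-negative")
        if w[0] > 380 or w[-1] < 780:
            raise SpectrumDomainError("CMF grid must cover [380, 780] nm")
        self.wavelengths = w
        self.xbar, self.ybar, self.zbar = bars

    def resample(self, grid: np.ndarray) -> np.ndarray:
        """(3, n) array of the three curves linearly interpolated onto ``grid``."""
        return np.vstack(
            [np.interp(grid, self.wavelengths, b) for b in (self.xbar, self.ybar, self.zbar)]
        )

    def as_spectrum(self, which: str = "ybar") -> Spectrum:
        return Spectrum(self.wavelengths, getattr(self, which), unit="dimensionless")


@lru_cache(maxsize=1)
def cie_1931_cmfs() -> ColorMatchingFunctions:
    """The shipped 5 nm tabulation of the CIE 1931 2° observer."""
    import pandas as pd

    ref = importlib.resources.files("aquachroma.data") / "cie1931_2deg_5nm.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, comment="#")
    return ColorMatchingFunctions(
        df["wavelength_nm"], df["xbar"], df["ybar"], df["zbar"]
    )


def _refine_grid(grid: np.ndarray, max_step: float = 1.0) -> np.ndarray:
    """Subdivide grid segments so no step exceeds ``max_step`` nm."""
    pieces = [grid[:1]]
    for a, b in zip(grid[:-1], grid[1:]):
        n = int(np.ceil((b - a) / max_step))
        pieces.append(np.linspace(a, b, n + 1)[1:])
    return np.concatenate(pieces)


def integrate_tristimulus(
    intensity: Spectrum, cmfs: ColorMatchingFunctions | None = None
) -> TristimulusTriple:
    """Tristimulus integrals of a sensed spectrum by trapezoidal quadrature.

    The intensity and the CMFs are resampled (linear interpolation) onto the
    union of their grids, refined to at most 1 nm spacing so the trapezoid
    rule also captures the piecewise-quadratic product of the two
    piecewise-linear factors.  Linear in the input:
    ``integrate_tristimulus(k·I) == k · integrate_tristimulus(I)``.
    """
    cmfs = cmfs or cie_1931_cmfs()
    intensity.require_coverage()
    intensity.require_integration_grid()
    cmf_spec = cmfs.as_spectrum()
    grid = _refine_grid(union_grid(intensity, cmf_spec), max_step=1.0)
    i = intensity.resample(grid).values
    bars = cmfs.resample(grid)
    X, Y, Z = (np.trapezoid(i * b, grid) for b in bars)
    return TristimulusTriple(float(X), float(Y), float(Z))


def chromaticity_from_xyz(t: TristimulusTriple) -> Chromaticity:
    """x = X/(X+Y+Z) etc.; scale-invariant; undefined for the zero triple."""
    total = t.X + t.Y + t.Z
    if total <= 0:
        raise UndefinedChromaticityError("chromaticity undefined for X+Y+Z = 0")
    return Chromaticity(t.X / total, t.Y / total)


def hue_angle(c: Chromaticity, eps: float = 1e-6) -> HueAngle:
    """Polar angle of (x, y) around the white point, reduced to [0, 2π).

    Raises :class:`AchromaticSampleError` within ``eps`` of the white point,
    where hue carries no information.  Note the convention: the first atan2
    argument is (y − y_w); part of the satellite literature measures hue from
    a different axis, so absolute angles are not comparable across
    conventions without a fixed offset.
    """
    dx = c.x - WHITE_POINT[0]
    dy = c.y - WHITE_POINT[1]
    if np.hypot(dx, dy) < eps:
        raise AchromaticSampleError(
            "sample is achromatic (within eps of the white point); no meaningful hue"
        )
    return HueAngle(np.arctan2(dy, dx))


def rgb_to_xyz(rgb) -> TristimulusTriple:
    """Fixed linear-sRGB (D65) bridge from a linear RGB triple in [0, 1]."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape != (3,):
        raise RangeError("expected a single RGB triple")
    if np.any(rgb < -1e-12) or np.any(rgb > 1 + 1e-12):
        raise RangeError("linear RGB channels must lie in [0, 1]; clip upstream and flag")
    X, Y, Z = M_RGB_TO_XYZ @ rgb
    return TristimulusTriple(float(max(X, 0.0)), float(max(Y, 0.0)), float(max(Z, 0.0)))


def xyz_to_rgb(t: TristimulusTriple) -> np.ndarray:
    """Inverse bridge; may return out-of-gamut (negative) components."""
    return M_XYZ_TO_RGB @ t.as_array()


def chromaticity_of_spectrum(intensity: Spectrum) -> Chromaticity:
    """Convenience: spectrum -> tristimulus -> chromaticity."""
    return chromaticity_from_xyz(integrate_tristimulus(intensity))


def srgb_eocf(u: np.ndarray) -> np.ndarray:
    """sRGB electro-optical conversion: encoded [0,1] -> linear [0,1]."""
    u = np.asarray(u, dtype=float)
    return np.where(u <= 0.04045, u / 12.92, ((u + 0.055) / 1.055) ** 2.4)
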