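"""Forward optical model of the cuvette scene.

Light from a white LED passes once through the water sample and reaches the
camera; only absorption is modelled (no scattering, fluorescence or multiple
reflections), so the sensed spectrum is

    I(λ) = level · E(λ) · T(λ),        T(λ) = exp(−a(λ) · l),

with E the relative illuminant power, ``level`` a scalar illumination level
(lux-equivalent; only ratios matter), a(λ) the total absorption coefficient
in m⁻¹ and l the cuvette path length in cm (converted internally).

Two constituent models are provided:

* CDOM (humic acid proxy): the classical exponential decay
  a(λ) = c · a_ref · exp(−S (λ − λ_ref)), with spectral slope S in nm⁻¹.
* Phytoplankton pigment proxy: a two-Gaussian chlorophyll-like template with
  a blue (Soret) and a red absorption band; the concentration axis is the
  dimensionless inverse dilution of an extract.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import SpectrumDomainError, UnitError
from .spectra import Spectrum

DEFAULT_GRID = np.arange(380.0, 781.0, 5.0)

ABSORPTION_UNIT = "m^-1"
TRANSMISSION_UNIT = "dimensionless"
RADIANCE_UNIT = "relative_radiance"


@dataclass(frozen=True)
class CDOMModel:
    """Exponential CDOM absorption: a(λ) = c · a_ref · exp(−S(λ−λ_ref)).

    ``a_ref`` is the specific absorption at ``lambda_ref`` in m⁻¹ per
    (mgC/L).  The default slope S = 0.0105 nm⁻¹ sits mid-way in the
    0.010–0.011 nm⁻¹ range measured for technical humic acid; the default
    a_ref places the near-white chromaticity crossing inside the 0–100 mgC/L
    working range of the bench (see docs/methods.md).
    """

    a_ref: float = 0.855
    lambda_ref: float = 440.0
    S: float = 0.0105

    def __post_init__(self) -> None:
        if self.a_ref <= 0:
            raise SpectrumDomainError("a_ref must be positive")
        if not 0 < self.S < 0.05:
            raise SpectrumDomainError("spectral slope S must lie in (0, 0.05) nm^-1")
        if not 380 <= self.lambda_ref <= 780:
            raise SpectrumDomainError("lambda_ref must lie in the visible range")


@dataclass(frozen=True)
class PigmentModel:
    """Two-band Gaussian pigment absorption template (chlorophyll-a-like).

    Band centres/widths in nm, dimensionless weights (≥ 2 bands: the blue
    Soret band and the red band), and an overall specific absorption scale in
    m⁻¹ per unit inverse-dilution level.
    """

    centers: tuple = (435.0, 675.0)
    widths: tuple = (30.0, 20.0)
    weights: tuple = (1.6, 1.0)
    scale: float = 2500.0

    def __post_init__(self) -> None:
        if len(self.centers) < 2 or not (
            len(self.centers) == len(self.widths) == len(self.weights)
        ):
            raise SpectrumDomainError("need >= 2 consistent bands (Soret + red)")
        if any(w < 0 for w in self.weights):
            raise SpectrumDomainError("band weights must be non-negative")
        if self.scale <= 0:
            raise SpectrumDomainError("absorption scale must be positive")


@dataclass(frozen=True)
class SampleComposition:
    """A water sample: CDOM in mgC/L, pigment in inverse-dilution units,
    and the cuvette path length in cm (standard 1 cm cuvette by default)."""

    cdom_concentration: float = 0.0
    pigment_level: float = 0.0
    pathlength_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.cdom_concentration < 0 or self.pigment_level < 0:
            raise SpectrumDomainError("concentrations must be non-negative")
        if self.pathlength_cm <= 0:
            raise SpectrumDomainError("path length must be positive")


@dataclass(frozen=True)
class Illuminant:
    """Relative spectral power plus a scalar illumination level.

    ``level`` is carried on a lux-equivalent scale (the bench uses 510 and
    1010); it is a pure multiplier, never photometrically converted.
    """

    spectrum: Spectrum
    level: float = 1.0

    def __post_init__(self) -> None:
        if self.level <= 0:
            raise SpectrumDomainError("illumination level must be positive")

    def at_level(self, level: float) -> "Illuminant":
        return replace(self, level=level)


# ---------------------------------------------------------------------------
# constituent absorption


def cdom_absorption(
    model: CDOMModel, concentration: float, grid: np.ndarray | None = None
) -> Spectrum:
    """Exponential CDOM absorption spectrum; linear in concentration."""
    if concentration < 0:
        raise SpectrumDomainError("concentration must be non-negative")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    a = concentration * model.a_ref * np.exp(-model.S * (grid - model.lambda_ref))
    return Spectrum(grid, a, unit=ABSORPTION_UNIT)


def pigment_absorption(
    model: PigmentModel, level: float, grid: np.ndarray | None = None
) -> Spectrum:
    """Gaussian-band pigment absorption spectrum; linear in level."""
    if level < 0:
        raise SpectrumDomainError("pigment level must be non-negative")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    a = np.zeros_like(grid)
    for c, w, wt in zip(model.centers, model.widths, model.weights):
        a += wt * np.exp(-0.5 * ((grid - c) / w) ** 2)
    return Spectrum(grid, level * model.scale * a, unit=ABSORPTION_UNIT)


def total_absorption(
    sample: SampleComposition,
    cdom: CDOMModel | None = None,
    pigment: PigmentModel | None = None,
    grid: np.ndarray | None = None,
) -> Spectrum:
    """Pointwise sum of the component absorptions (standard additivity)."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    a = cdom_absorption(cdom or CDOMModel(), sample.cdom_concentration, grid).values
    a = a + pigment_absorption(pigment or PigmentModel(), sample.pigment_level, grid).values
    return Spectrum(grid, a, unit=ABSORPTION_UNIT)


def beer_lambert_transmission(absorption: Spectrum, pathlength_cm: float = 1.0) -> Spectrum:
    """T(λ) = exp(−a(λ)·l), with a in m⁻¹ and l in cm (converted to m)."""
    if absorption.unit != ABSORPTION_UNIT:
        raise UnitError(
            f"transmission needs an absorption spectrum in {ABSORPTION_UNIT}, "
            f"got unit {absorption.unit!r}"
        )
    if pathlength_cm <= 0:
        raise SpectrumDomainError("path length must be positive")
    t = np.exp(-absorption.values * (pathlength_cm / 100.0))
    return Spectrum(absorption.wavelengths, t, unit=TRANSMISSION_UNIT)


def sensed_spectrum(ill: Illuminant, transmission: Spectrum) -> Spectrum:
    """I(λ) = level · E(λ) · T(λ); single-pass geometry, black background."""
    if transmission.unit != TRANSMISSION_UNIT:
        raise UnitError("sensed_spectrum expects a dimensionless transmission")
    product = ill.spectrum * transmission
    return Spectrum(product.wavelengths, ill.level * product.values, unit=RADIANCE_UNIT)


def sample_spectrum(
    sample: SampleComposition,
    ill: Illuminant,
    cdom: CDOMModel | None = None,
    pigment: PigmentModel | None = None,
) -> Spectrum:
    """Full forward chain: composition -> absorption -> transmission -> I(λ)."""
    a = total_absorption(sample, cdom, pigment, grid=ill.spectrum.wavelengths)
    t = beer_lambert_transmission(a, sample.pathlength_cm)
    return sensed_spectrum(ill, t)


# ---------------------------------------------------------------------------
# illuminants

#: default LED template parameters: narrow blue pump plus broad phosphor hump.
#: Amplitudes/positions were fixed once so that (i) the template chromaticity
#: lies within 0.02 of the 6000 K Planckian point and (ii) the ideal
#: chromaticity-vs-CDOM trajectory of the bench is near-linear before
#: saturation, as observed for the real setup.  See docs/methods.md.
LED_PUMP_NM = 463.553
LED_PUMP_SD = 9.114
LED_PUMP_AMPLITUDE = 2.601
LED_PHOSPHOR_NM = 548.644
LED_PHOSPHOR_SD_BLUE = 53.166
LED_PHOSPHOR_SD_RED = 97.842


def led_illuminant_6000k(
    grid: np.ndarray | None = None,
    level: float = 1.0,
    pump_amplitude: float = LED_PUMP_AMPLITUDE,
) -> Illuminant:
    """White-LED template (6000 K class): blue pump + phosphor hump.

    The spectrum is normalised to unit mean.  ``pump_amplitude`` is exposed
    because drive-level changes of real LEDs slightly shift the pump/phosphor
    balance; the camera bench jitters it between captures.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    pump = pump_amplitude * np.exp(-0.5 * ((grid - LED_PUMP_NM) / LED_PUMP_SD) ** 2)
    sd = np.where(grid < LED_PHOSPHOR_NM, LED_PHOSPHOR_SD_BLUE, LED_PHOSPHOR_SD_RED)
    phosphor = np.exp(-0.5 * ((grid - LED_PHOSPHOR_NM) / sd) ** 2)
    e = pump + phosphor
    return Illuminant(Spectrum(grid, e / e.mean(), unit=RADIANCE_UNIT), level=level)


def blackbody_spectrum(temperature_k: float, grid: np.ndarray | None = None) -> Spectrum:
    """Planck spectral radiance (relative, unit mean) at the given temperature.

    Used as the independent oracle for the LED template's correlated colour
    temperature.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    h, c, k = 6.62607015e-34, 2.99792458e8, 1.380649e-23
    lam = grid * 1e-9
    b = (2 * h * c**2 / lam**5) / np.expm1(h * c / (lam * k * temperature_k))
    return Spectrum(grid, b / b.mean(), unit=RADIANCE_UNIT)
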