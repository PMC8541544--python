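"""Sampled spectra on a wavelength grid.

A :class:`Spectrum` is the common currency of the optical chain: illuminant
power, absorption coefficients, transmissions and sensed intensity all travel
as (wavelength, value) pairs with a unit tag.  Wavelengths are nanometres and
must be strictly increasing inside the visible window [380, 780].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CoverageError, SpectrumDomainError

VISIBLE_MIN = 380.0
VISIBLE_MAX = 780.0

#: grids used as integration inputs must be at least this dense (nm)
MAX_GRID_SPACING = 5.0


@dataclass(frozen=True)
class Spectrum:
    """A sampled function of wavelength.

    Parameters
    ----------
    wavelengths : array_like
        Strictly increasing grid in nm, within [380, 780].
    values : array_like
        Sample values, same length as ``wavelengths``.  Radiance and
        absorption spectra must be non-negative.
    unit : str
        Unit tag carried as metadata, e.g. ``"relative_radiance"``,
        ``"m^-1"`` (absorption coefficient) or ``"dimensionless"``
        (transmission).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    unit: str = "relative_radiance"

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if w.ndim != 1 or v.ndim != 1 or w.size != v.size:
            raise SpectrumDomainError("wavelengths and values must be 1-D and equally long")
        if w.size < 2:
            raise SpectrumDomainError("a spectrum needs at least two samples")
        if np.any(np.diff(w) <= 0):
            raise SpectrumDomainError("wavelength grid must be strictly increasing")
        if w[0] < VISIBLE_MIN - 1e-9 or w[-1] > VISIBLE_MAX + 1e-9:
            raise SpectrumDomainError(
                f"wavelengths must lie within [{VISIBLE_MIN:g}, {VISIBLE_MAX:g}] nm"
            )
        if not np.all(np.isfinite(v)):
            raise SpectrumDomainError("spectrum values must be finite")
        if np.any(v < 0):
            raise SpectrumDomainError("negative values are not allowed for this spectrum")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "values", v)

    # -- basic queries -----------------------------------------------------

    @property
    def grid_spacing(self) -> float:
        return float(np.max(np.diff(self.wavelengths)))

    def covers(self, lo: float = VISIBLE_MIN, hi: float = VISIBLE_MAX) -> bool:
        return self.wavelengths[0] <= lo + 1e-9 and self.wavelengths[-1] >= hi - 1e-9

    def require_coverage(self, lo: float = VISIBLE_MIN, hi: float = VISIBLE_MAX) -> None:
        if not self.covers(lo, hi):
            raise CoverageError(
                f"spectrum [{self.wavelengths[0]:g}, {self.wavelengths[-1]:g}] nm "
                f"does not cover [{lo:g}, {hi:g}] nm"
            )

    def require_integration_grid(self) -> None:
        if self.grid_spacing > MAX_GRID_SPACING + 1e-9:
            raise SpectrumDomainError(
                f"grid spacing {self.grid_spacing:g} nm too coarse for integration "
                f"(max {MAX_GRID_SPACING:g} nm)"
            )

    # -- operations --------------------------------------------------------

    def resample(self, grid: np.ndarray) -> "Spectrum":
        """Linear interpolation onto a new grid (must lie inside coverage)."""
        grid = np.asarray(grid, dtype=float)
        if grid[0] < self.wavelengths[0] - 1e-9 or grid[-1] > self.wavelengths[-1] + 1e-9:
            raise CoverageError("resampling grid extends beyond the spectrum coverage")
        return Spectrum(grid, np.interp(grid, self.wavelengths, self.values), self.unit)

    def scaled(self, k: float) -> "Spectrum":
        if k < 0:
            raise SpectrumDomainError("scale factor must be non-negative")
        return Spectrum(self.wavelengths, self.values * k, self.unit)

    def __mul__(self, other: "Spectrum") -> "Spectrum":
        """Pointwise product on the union grid of the overlap."""
        grid = union_grid(self, other)
        a = self.resample(grid).values
        b = other.resample(grid).values
        return Spectrum(grid, a * b, self.unit)


def union_grid(a: Spectrum, b: Spectrum) -> np.ndarray:
    """Union of two wavelength grids over their common coverage."""
    lo = max(a.wavelengths[0], b.wavelengths[0])
    hi = min(a.wavelengths[-1], b.wavelengths[-1])
    if hi <= lo:
        raise CoverageError("spectra have disjoint wavelength coverage")
    g = np.union1d(a.wavelengths, b.wavelengths)
    return g[(g >= lo - 1e-9) & (g <= hi + 1e-9)]


def read_spectrum_csv(path, unit: str | None = None) -> Spectrum:
    """Read a ``wavelength_nm,value`` CSV; ``# unit: ...`` comment sets the unit."""
    import pandas as pd

    file_unit = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "unit:" in line:
                file_unit = line.split("unit:", 1)[1].strip()
            elif not line.startswith("#"):
                break
    df = pd.read_csv(path, comment="#")
    return Spectrum(
        df["wavelength_nm"].to_numpy(),
        df["value"].to_numpy(),
        unit or file_unit or "relative_radiance",
    )


def write_spectrum_csv(path, spec: Spectrum) -> None:
    with open(path, "w") as fh:
        fh.write(f"# unit: {spec.unit}\n")
        fh.write("wavelength_nm,value\n")
        for w, v in zip(spec.wavelengths, spec.values):
            fh.write(f"{w:.6g},{v:.10g}\n")
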