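"""Typed exceptions for the colorimetry pipeline."""


class AquachromaError(Exception):
    """Base class for all package errors."""


class CoverageError(AquachromaError):
    """A spectrum does not cover the required wavelength range."""


class SpectrumDomainError(AquachromaError, ValueError):
    """Invalid spectral data (negative radiance, bad grid, ...)."""


class UnitError(AquachromaError):
    """Spectrum carries the wrong unit for this operation."""


class UndefinedChromaticityError(AquachromaError, ZeroDivisionError):
    """Chromaticity requested for an all-zero tristimulus triple."""


class AchromaticSampleError(AquachromaError):
    """Hue angle requested within the epsilon-disk around the white point."""


class RangeError(AquachromaError, ValueError):
    """Channel value outside the valid [0, 1] linear range."""


class FitError(AquachromaError):
    """A least-squares or nonlinear fit could not be carried out."""


class SegmentationError(AquachromaError):
    """ROI segmentation produced an empty mask."""


class SampleSizeError(AquachromaError):
    """Too few pixels (or points) for a reliable statistic."""


class OverexposureError(AquachromaError):
    """Clip fraction in the ROI exceeds the safe limit."""


class InversionError(AquachromaError):
    """Observed colour index cannot be inverted with this model."""
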