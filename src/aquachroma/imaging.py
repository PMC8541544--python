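"""Measurement-side pipeline: colour correction, segmentation, aggregation.

This module turns a raw scene image into one corrected linear RGB triple per
sample: a least-squares 3×3 correction matrix fitted on the reference chart
replaces the interactive chart-profiling step of the original protocol; the
cuvette is segmented by a global Otsu threshold on luminance; pixel
statistics are refined by iterative confidence-interval trimming; and the
corrected triple is pushed through the sRGB bridge to chromaticity and hue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import colorimetry
from .camera import SceneImage
from .errors import (
    AchromaticSampleError,
    FitError,
    OverexposureError,
    SampleSizeError,
    SegmentationError,
)

CLIP_FRACTION_LIMIT = 0.05


@dataclass(frozen=True)
class CorrectionMatrix:
    """3×3 map from camera linear RGB to reference linear RGB."""

    matrix: np.ndarray
    residual_rms: float
    n_patches: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3) or not np.all(np.isfinite(m)):
            raise FitError("correction matrix must be a finite 3x3 matrix")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "CorrectionMatrix":
        return cls(np.eye(3), 0.0, 0)


@dataclass(frozen=True)
class RoiResult:
    """Trimmed per-channel statistics of an ROI pixel population."""

    mean: np.ndarray
    sd: np.ndarray
    n_raw: int
    n_trimmed: int
    clip_fraction: float

    def __post_init__(self) -> None:
        if self.n_trimmed > self.n_raw:
            raise SampleSizeError("trimmed count cannot exceed raw count")
        if not 0 <= self.clip_fraction <= 1:
            raise SampleSizeError("clip fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ColorMeasurement:
    """End-to-end result of :func:`extract_color` for one sample."""

    rgb: np.ndarray  # corrected linear RGB (reference space, unnormalised)
    xyz: np.ndarray
    x: float
    y: float
    hue_deg: float | None  # None when the sample is achromatic
    n_pixels: int
    n_trimmed: int
    clip_fraction: float


def fit_correction(measured_patches, reference_patches, clipped=None) -> CorrectionMatrix:
    """Least-squares 3×3 correction matrix from chart patch pairs.

    Clipped patches are excluded with a warning; fewer than 4 usable pairs or
    a rank-deficient design raise :class:`FitError`.
    """
    measured = np.asarray(measured_patches, dtype=float)
    reference = np.asarray(reference_patches, dtype=float)
    if measured.shape != reference.shape or measured.ndim != 2 or measured.shape[1] != 3:
        raise FitError("measured and reference patch lists must both be (n, 3)")
    if clipped is not None:
        clipped = np.asarray(clipped, dtype=bool)
        if clipped.any():
            warnings.warn(
                f"excluding {int(clipped.sum())} clipped patch(es) from the correction fit",
                stacklevel=2,
            )
        measured, reference = measured[~clipped], reference[~clipped]
    if len(measured) < 4:
        raise FitError("need at least 4 unclipped patches to fit a correction matrix")
    sol, _, rank, _ = np.linalg.lstsq(measured, reference, rcond=None)
    if rank < 3:
        raise FitError("patch design is rank deficient; colours are not diverse enough")
    matrix = sol.T
    resid = measured @ matrix.T - reference
    return CorrectionMatrix(matrix, float(np.sqrt(np.mean(resid**2))), len(measured))


def apply_correction(values, m: CorrectionMatrix, return_clamp_count: bool = False):
    """Apply the correction per pixel/triple; negatives clamp to 0 (counted)."""
    values = np.asarray(values, dtype=float)
    corrected = values @ m.matrix.T
    n_clamped = int(np.sum(corrected < 0))
    corrected = np.maximum(corrected, 0.0)
    if return_clamp_count:
        return corrected, n_clamped
    return corrected


def segment_roi(image: SceneImage, roi_rect=None) -> np.ndarray:
    """Boolean cuvette mask: Otsu threshold on luminance, largest component.

    If ``roi_rect`` (x, y, w, h) is given — normally from the sidecar — the
    mask is constrained inside it before the largest connected component is
    taken.  An empty mask raises :class:`SegmentationError`.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label

    lum = image.pixels.astype(float).mean(axis=2)
    if lum.max() - lum.min() < 1e-9:
        raise SegmentationError("uniform image; nothing to segment")
    mask = lum > threshold_otsu(lum)
    if roi_rect is not None:
        x, y, w, h = roi_rect
        window = np.zeros_like(mask)
        window[y : y + h, x : x + w] = True
        mask &= window
    if not mask.any():
        raise SegmentationError("empty mask after thresholding")
    labels = label(mask)
    largest = np.argmax(np.bincount(labels[labels > 0]))
    return labels == largest


def aggregate_pixels(pixels, confidence: float = 0.95, max_iter: int = 10) -> RoiResult:
    """Iterative confidence-interval trimming of ROI pixels.

    Pixels outside mean ± z(confidence)·sd are dropped per channel; a pixel
    is kept if any channel keeps it (union rule); the procedure repeats to a
    fixed point or ``max_iter``.  Requires at least 30 pixels.
    """
    from scipy.stats import norm

    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2 or pixels.shape[1] != 3:
        raise SampleSizeError("expected an (n, 3) pixel array")
    n_raw = len(pixels)
    if n_raw < 30:
        raise SampleSizeError(f"need >= 30 pixels, got {n_raw}")
    z = norm.ppf(0.5 + confidence / 2.0)
    kept = pixels
    for _ in range(max_iter):
        mean = kept.mean(axis=0)
        sd = kept.std(axis=0, ddof=1)
        inside = np.abs(kept - mean) <= z * np.maximum(sd, 1e-12)
        keep = inside.any(axis=1)
        if keep.all():
            break
        kept = kept[keep]
        if len(kept) < 2:
            break
    return RoiResult(
        mean=kept.mean(axis=0),
        sd=kept.std(axis=0, ddof=1) if len(kept) > 1 else np.zeros(3),
        n_raw=n_raw,
        n_trimmed=len(kept),
        clip_fraction=0.0,
    )


def extract_color(
    image: SceneImage,
    m: CorrectionMatrix,
    sample_index: int = 0,
    blank_rgb=None,
    confidence: float = 0.95,
    clip_limit: float = CLIP_FRACTION_LIMIT,
) -> ColorMeasurement:
    """Segment → aggregate → correct → chromaticity/hue for one cuvette.

    ``blank_rgb`` (optional corrected triple of a pure-water image) switches
    on blank-ratio normalisation.  A clip fraction above ``clip_limit``
    raises :class:`OverexposureError`; hue is reported as None for samples
    inside the achromatic disk around the white point.
    """
    rect = image.roi_rects[sample_index]
    mask = segment_roi(image, roi_rect=rect)
    pixels = image.pixels[mask].astype(float)
    clip_fraction = float(np.mean(np.any(pixels >= image.meta["full_well"], axis=1)))
    if clip_fraction > clip_limit:
        raise OverexposureError(
            f"clip fraction {clip_fraction:.3f} exceeds {clip_limit:.2f}; "
            "reduce illumination or gain"
        )
    stats = aggregate_pixels(pixels, confidence=confidence)
    signal = stats.mean - image.meta["black_level"]
    corrected = apply_correction(signal, m)
    if blank_rgb is not None:
        corrected = corrected / np.maximum(np.asarray(blank_rgb, float), 1e-12)
    scale = corrected.max()
    if scale <= 0:
        raise SegmentationError("no signal above black level in the ROI")
    t = colorimetry.rgb_to_xyz(corrected / scale)
    chroma = colorimetry.chromaticity_from_xyz(t)
    try:
        hue = colorimetry.hue_angle(chroma).degrees
    except AchromaticSampleError:
        hue = None
    return ColorMeasurement(
        rgb=corrected,
        xyz=t.as_array() * scale,
        x=chroma.x,
        y=chroma.y,
        hue_deg=hue,
        n_pixels=stats.n_raw,
        n_trimmed=stats.n_trimmed,
        clip_fraction=clip_fraction,
    )


def measure_patches(image: SceneImage) -> tuple:
    """Mean black-subtracted DN per chart patch plus the clip flags."""
    means, clipped = [], []
    for name, rect in image.patch_rects.items():
        px = image.patch_pixels(name).astype(float)
        means.append(px.mean(axis=0) - image.meta["black_level"])
        clipped.append(image.meta["patch_clipped"].get(name, False))
    return np.array(means), np.array(clipped, dtype=bool)
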