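"""Synthetic camera: image formation, noise, clipping, scene rendering.

The simulated device integrates the sensed spectrum against per-channel
spectral sensitivities,

    DN_expected = gain · level · K · ∫ I(λ) s_c(λ) dλ  (+ stray-light floor),

adds the black level, Gaussian read noise and a Gaussian approximation to
Poisson shot noise, quantises to integer digital numbers (DN) and clips to
the 16-bit full well.  Two presets with shifted sensitivity peaks stand in
for different physical cameras; ISO 400 and ISO 800 map to gains 1 and 2.

Real RAW sensor curves for consumer cameras are unpublished; Gaussian
channel sensitivities are the standard surrogate and are fully documented in
docs/methods.md, together with the stray-light floor that bounds the usable
concentration range at low illumination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import SpectrumDomainError
from .optics import Illuminant, led_illuminant_6000k, sample_spectrum, SampleComposition
from .spectra import Spectrum, union_grid

FULL_WELL_16BIT = 65535


@dataclass(frozen=True)
class CameraModel:
    """Spectral sensitivities plus the radiometric chain parameters.

    ``shot_noise_scale`` is the variance per DN of the shot-noise term
    (var = read_noise_sd² + shot_noise_scale · DN).  ``ambient_dn`` is a
    neutral stray-light / veiling floor in DN at unit gain, independent of
    the LED level — the leakage that makes low illumination saturate early.
    """

    name: str
    sensitivities: tuple  # (R, G, B) Spectrum
    iso_gain: float = 1.0
    exposure_scale: float = 1.0
    black_level: float = 800.0
    read_noise_sd: float = 40.0
    shot_noise_scale: float = 2.0
    ambient_dn: float = 900.0
    full_well: int = FULL_WELL_16BIT

    def __post_init__(self) -> None:
        if len(self.sensitivities) != 3:
            raise SpectrumDomainError("need exactly three channel sensitivities (R, G, B)")
        if self.full_well <= self.black_level or self.black_level < 0:
            raise SpectrumDomainError("require full_well > black_level >= 0")
        if min(self.read_noise_sd, self.shot_noise_scale, self.ambient_dn) < 0:
            raise SpectrumDomainError("noise parameters must be non-negative")
        if self.iso_gain <= 0:
            raise SpectrumDomainError("gain must be positive")

    def with_iso(self, iso: int) -> "CameraModel":
        """ISO 400 -> gain 1.0, ISO 800 -> gain 2.0 (linear in ISO)."""
        return replace(self, iso_gain=iso / 400.0)

    # -- radiometry --------------------------------------------------------

    def expected_dn(self, intensity: Spectrum, level: float, include_floor: bool = True):
        """Noise-free expected DN above black for the three channels."""
        dn = np.array(
            [
                expose_channel(intensity, s, self.iso_gain, level, self.exposure_scale)
                for s in self.sensitivities
            ]
        )
        if include_floor:
            dn = dn + self.iso_gain * self.ambient_dn
        return dn

    def draw_pixels(self, expected_dn: np.ndarray, n: int, rng: np.random.Generator):
        """(3, n) noisy, quantised, clipped raw pixels including black level."""
        mean = np.asarray(expected_dn, dtype=float)[:, None] + self.black_level
        sd = np.sqrt(self.read_noise_sd**2 + self.shot_noise_scale * np.maximum(mean, 0.0))
        px = mean + rng.normal(0.0, 1.0, size=(3, n)) * sd
        return np.clip(np.round(px), 0, self.full_well).astype(np.uint16)


def expose_channel(
    intensity: Spectrum,
    sensitivity: Spectrum,
    gain: float = 1.0,
    level: float = 1.0,
    exposure_scale: float = 1.0,
) -> float:
    """Expected DN of one channel: gain · level · K · ∫ I(λ) s(λ) dλ.

    Linear in both gain and level; trapezoidal quadrature on the union grid.
    """
    grid = union_grid(intensity, sensitivity)
    i = intensity.resample(grid).values
    s = sensitivity.resample(grid).values
    return float(gain * level * exposure_scale * np.trapezoid(i * s, grid))


def gaussian_sensitivities(peaks_nm, sd_nm: float = 35.0, grid=None) -> tuple:
    """Three Gaussian channel curves (R, G, B order of peaks)."""
    from .optics import DEFAULT_GRID

    grid = DEFAULT_GRID if grid is None else np.asarray(grid, float)
    return tuple(
        Spectrum(grid, np.exp(-0.5 * ((grid - p) / sd_nm) ** 2), unit="dimensionless")
        for p in peaks_nm
    )


def default_cameras() -> tuple:
    """Two documented presets with sensitivity peaks shifted by >= 10 nm.

    Preset A peaks at 600/530/460 nm, preset B at 612/542/448 nm (σ 35 nm).
    The exposure constant is fixed once so preset A reads ≈ 12000 DN above
    black on the green channel for a pure-water blank at level 1010, gain 1 —
    mid-range with headroom, so deliberate overexposure still clips.
    """
    sens_a = gaussian_sensitivities((600.0, 530.0, 460.0))
    sens_b = gaussian_sensitivities((612.0, 542.0, 448.0))
    blank = sample_spectrum(SampleComposition(), led_illuminant_6000k(level=1.0))
    green_integral = expose_channel(blank, sens_a[1], gain=1.0, level=1010.0)
    k = 12000.0 / green_integral
    cam_a = CameraModel(name="preset_a", sensitivities=sens_a, exposure_scale=k)
    cam_b = CameraModel(name="preset_b", sensitivities=sens_b, exposure_scale=k)
    return cam_a, cam_b


# ---------------------------------------------------------------------------
# scene rendering

PATCH_SIZE = 16
PATCH_GAP = 4
CUVETTE_SIZE = 40
CUVETTE_GAP = 8


@dataclass
class SceneImage:
    """A rendered 3-channel linear raster plus its geometry sidecar.

    ``pixels`` is (H, W, 3) uint16.  ``meta`` carries the ROI rectangles
    (x, y, w, h), the patch map, clip flags, seed and the ground-truth sample
    compositions, exactly as written to the JSON sidecar.
    """

    pixels: np.ndarray
    meta: dict

    @property
    def roi_rects(self) -> list:
        return [tuple(r) for r in self.meta["cuvette_rects"]]

    @property
    def patch_rects(self) -> dict:
        return {k: tuple(v) for k, v in self.meta["patch_rects"].items()}

    def roi_pixels(self, index: int = 0) -> np.ndarray:
        x, y, w, h = self.roi_rects[index]
        return self.pixels[y : y + h, x : x + w].reshape(-1, 3)

    def patch_pixels(self, name: str) -> np.ndarray:
        x, y, w, h = self.patch_rects[name]
        return self.pixels[y : y + h, x : x + w].reshape(-1, 3)

    def truth_mask(self, index: int = 0) -> np.ndarray:
        m = np.zeros(self.pixels.shape[:2], dtype=bool)
        x, y, w, h = self.roi_rects[index]
        m[y : y + h, x : x + w] = True
        return m

    # -- persistence (16-bit TIFF + JSON sidecar) -------------------------

    def save(self, path) -> None:
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.pixels, photometric="rgb")
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(self.meta, fh, indent=1)

    @classmethod
    def load(cls, path) -> "SceneImage":
        import tifffile

        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            meta = json.load(fh)
        return cls(pixels=tifffile.imread(path), meta=meta)


def render_scene(
    samples,
    camera: CameraModel,
    ill: Illuminant,
    cdom=None,
    pigment=None,
    seed: int = 0,
    include_chart: bool = True,
    rng: np.random.Generator | None = None,
) -> SceneImage:
    """Render cuvette ROIs (one per sample) and the 24 reference patches.

    Deterministic given ``seed``: the same seed and configuration produce a
    bit-identical image.  Expected DN above the full well is rendered clipped
    and flagged in the metadata.
    """
    from .chart import load_chart, patch_reflectance

    samples = list(samples)
    rng = np.random.default_rng(seed) if rng is None else rng

    chart = load_chart() if include_chart else None
    chart_h = (4 * (PATCH_SIZE + PATCH_GAP) + PATCH_GAP) if include_chart else 0
    width = max(
        6 * (PATCH_SIZE + PATCH_GAP) + PATCH_GAP if include_chart else 0,
        CUVETTE_GAP + len(samples) * (CUVETTE_SIZE + CUVETTE_GAP),
    )
    height = chart_h + CUVETTE_SIZE + 2 * CUVETTE_GAP

    # background: black holder at the sensor floor
    bg = camera.draw_pixels(np.zeros(3), height * width, rng)
    img = bg.T.reshape(height, width, 3).copy()

    patch_rects: dict = {}
    clip_flags: dict = {}
    if include_chart:
        for i, row in enumerate(chart.itertuples()):
            r, c = divmod(i, 6)
            x = PATCH_GAP + c * (PATCH_SIZE + PATCH_GAP)
            y = PATCH_GAP + r * (PATCH_SIZE + PATCH_GAP)
            refl = patch_reflectance((row.lin_r, row.lin_g, row.lin_b), ill.spectrum.wavelengths)
            radiance = Spectrum(
                ill.spectrum.wavelengths,
                ill.level * ill.spectrum.values * refl,
                unit="relative_radiance",
            )
            dn = camera.expected_dn(radiance, level=1.0)
            clip_flags[row.name_] = bool(np.any(dn + camera.black_level > camera.full_well))
            px = camera.draw_pixels(dn, PATCH_SIZE * PATCH_SIZE, rng)
            img[y : y + PATCH_SIZE, x : x + PATCH_SIZE] = px.T.reshape(
                PATCH_SIZE, PATCH_SIZE, 3
            )
            patch_rects[row.name_] = (x, y, PATCH_SIZE, PATCH_SIZE)

    cuvette_rects = []
    sample_meta = []
    for i, sample in enumerate(samples):
        x = CUVETTE_GAP + i * (CUVETTE_SIZE + CUVETTE_GAP)
        y = chart_h + CUVETTE_GAP
        intensity = sample_spectrum(sample, ill, cdom, pigment)
        dn = camera.expected_dn(intensity, level=1.0)
        clipped = bool(np.any(dn + camera.black_level > camera.full_well))
        px = camera.draw_pixels(dn, CUVETTE_SIZE * CUVETTE_SIZE, rng)
        img[y : y + CUVETTE_SIZE, x : x + CUVETTE_SIZE] = px.T.reshape(
            CUVETTE_SIZE, CUVETTE_SIZE, 3
        )
        cuvette_rects.append((x, y, CUVETTE_SIZE, CUVETTE_SIZE))
        sample_meta.append(
            {
                "cdom_mgC_L": sample.cdom_concentration,
                "pigment_level": sample.pigment_level,
                "pathlength_cm": sample.pathlength_cm,
                "clipped": clipped,
            }
        )

    meta = {
        "seed": seed,
        "camera": camera.name,
        "iso_gain": camera.iso_gain,
        "level": ill.level,
        "black_level": camera.black_level,
        "full_well": camera.full_well,
        "cuvette_rects": cuvette_rects,
        "patch_rects": patch_rects,
        "patch_clipped": clip_flags,
        "samples": sample_meta,
    }
    return SceneImage(pixels=img, meta=meta)
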