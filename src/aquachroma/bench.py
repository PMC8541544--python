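"""Synthetic measurement bench: the study conditions, end to end.

This module wires the forward optics, the simulated cameras and the
measurement pipeline into the experiments the calibration is built from:

* a dissolved humic-acid (CDOM) series, 0–100 mgC/L;
* an algae-pigment dilution series on the inverse-dilution axis;
* two illumination levels (510 and 1010, lux-equivalent) × two ISO gains
  (400, 800) × two camera presets;
* per-capture LED spectral jitter and a neutral stray-light floor — the
  imperfections that bound the usable range at low illumination.

Every capture derives its random generator from ``(seed, capture index)``,
so runs at different illumination levels with the same seed share their
noise realisation ("matched seeds") and level effects can be compared
pairwise.

The bench offers two equivalent measurement paths: the full image pipeline
(:func:`capture_scene` + imaging functions) and a fast path that draws only
the ROI/patch pixel populations.  Both use the same camera draw code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import imaging
from .camera import CameraModel, SceneImage, default_cameras, render_scene
from .chart import load_chart, patch_reflectance, reference_patch_rgb
from .colorimetry import chromaticity_of_spectrum, hue_angle, Chromaticity
from .errors import AchromaticSampleError
from .imaging import CorrectionMatrix, aggregate_pixels, apply_correction, fit_correction
from .optics import (
    CDOMModel,
    Illuminant,
    PigmentModel,
    SampleComposition,
    led_illuminant_6000k,
    sample_spectrum,
)
from .spectra import Spectrum


def _default_onset_series() -> tuple:
    return tuple(np.concatenate([np.arange(0.0, 50.0, 5.0), np.arange(50.0, 100.01, 2.5)]))


@dataclass(frozen=True)
class BenchConfig:
    """Frozen study conditions of the synthetic bench."""

    levels: tuple = (510.0, 1010.0)
    isos: tuple = (400, 800)
    cdom: CDOMModel = field(default_factory=CDOMModel)
    pigment: PigmentModel = field(default_factory=PigmentModel)
    #: humic-acid calibration series, mgC/L
    cdom_series: tuple = tuple(np.linspace(0.0, 100.0, 10))
    #: denser series for saturation-onset detection
    onset_series: tuple = field(default_factory=_default_onset_series)
    #: inverse dilutions of the pigment extract (10×–50× dilutions plus blank)
    pigment_series: tuple = (0.0, 0.02, 0.04, 0.06, 0.08, 0.1)
    replicates: int = 3
    #: relative sd of the per-capture LED pump-amplitude jitter
    pump_jitter_sd: float = 0.013
    roi_pixels: int = 1600


# ---------------------------------------------------------------------------
# captures


def _capture_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, index])


def _jittered_illuminant(level: float, rng, cfg: BenchConfig) -> Illuminant:
    from .optics import LED_PUMP_AMPLITUDE

    z = float(np.clip(rng.standard_normal(), -4.0, 4.0))
    amp = LED_PUMP_AMPLITUDE * (1.0 + cfg.pump_jitter_sd * z)
    return led_illuminant_6000k(level=level, pump_amplitude=amp)


def capture_scene(
    samples,
    camera: CameraModel,
    level: float,
    seed: int,
    capture_index: int = 0,
    cfg: BenchConfig | None = None,
) -> SceneImage:
    """One photograph: jittered LED state, full frame with chart + cuvettes."""
    cfg = cfg or BenchConfig()
    rng = _capture_rng(seed, capture_index)
    ill = _jittered_illuminant(level, rng, cfg)
    return render_scene(
        samples, camera, ill, cdom=cfg.cdom, pigment=cfg.pigment, seed=seed, rng=rng
    )


def _fast_roi_stats(camera, intensity, rng, n) -> np.ndarray:
    """Mean black-subtracted DN of a simulated ROI pixel population."""
    dn = camera.expected_dn(intensity, level=1.0)
    px = camera.draw_pixels(dn, n, rng).astype(float).T
    stats = aggregate_pixels(px)
    return stats.mean - camera.black_level


def calibrate_camera(
    camera: CameraModel,
    level: float,
    seed: int,
    capture_index: int = 0,
    cfg: BenchConfig | None = None,
) -> CorrectionMatrix:
    """Photograph the chart once and fit the 3×3 correction matrix."""
    cfg = cfg or BenchConfig()
    rng = _capture_rng(seed, capture_index)
    ill = _jittered_illuminant(level, rng, cfg)
    grid = ill.spectrum.wavelengths
    chart = load_chart()
    measured, clipped = [], []
    for row in chart.itertuples():
        refl = patch_reflectance((row.lin_r, row.lin_g, row.lin_b), grid)
        radiance = Spectrum(
            grid, ill.level * ill.spectrum.values * refl, unit="relative_radiance"
        )
        dn = camera.expected_dn(radiance, level=1.0)
        clipped.append(bool(np.any(dn + camera.black_level > camera.full_well)))
        px = camera.draw_pixels(dn, 256, rng).astype(float)
        measured.append(px.mean(axis=1) - camera.black_level)
    reference = reference_patch_rgb(led_illuminant_6000k(level=1.0))
    return fit_correction(np.array(measured), reference, clipped=np.array(clipped))


def measure_sample(
    sample: SampleComposition,
    camera: CameraModel,
    level: float,
    ccm: CorrectionMatrix,
    seed: int,
    capture_index: int,
    cfg: BenchConfig | None = None,
) -> dict:
    """Fast-path single capture: corrected triple, chromaticity, hue."""
    cfg = cfg or BenchConfig()
    rng = _capture_rng(seed, capture_index)
    ill = _jittered_illuminant(level, rng, cfg)
    intensity = sample_spectrum(sample, ill, cfg.cdom, cfg.pigment)
    signal = _fast_roi_stats(camera, intensity, rng, cfg.roi_pixels)
    corrected = apply_correction(signal, ccm)
    from .colorimetry import chromaticity_from_xyz, rgb_to_xyz

    scale = max(corrected.max(), 1e-12)
    chroma = chromaticity_from_xyz(rgb_to_xyz(corrected / scale))
    try:
        hue = hue_angle(chroma)
        hue_rad, hue_deg = hue.alpha, hue.degrees
    except AchromaticSampleError:
        hue_rad = hue_deg = np.nan
    # uncorrected chromaticity: raw camera DN pushed straight through the bridge
    raw = signal / max(signal.max(), 1e-12)
    raw_chroma = chromaticity_from_xyz(rgb_to_xyz(np.clip(raw, 0, 1)))
    return {
        "cdom_mgC_L": sample.cdom_concentration,
        "pigment_level": sample.pigment_level,
        "R": corrected[0],
        "G": corrected[1],
        "B": corrected[2],
        "x": chroma.x,
        "y": chroma.y,
        "hue_rad": hue_rad,
        "hue_deg": hue_deg,
        "x_raw": raw_chroma.x,
        "y_raw": raw_chroma.y,
    }


def measure_series(
    samples,
    camera: CameraModel,
    level: float,
    seed: int,
    cfg: BenchConfig | None = None,
    replicates: int | None = None,
) -> pd.DataFrame:
    """Chart capture + replicate sample captures, replicate-averaged.

    Capture indices run identically whatever the level, so matched seeds
    share their jitter and noise draws across levels.
    """
    cfg = cfg or BenchConfig()
    reps = cfg.replicates if replicates is None else replicates
    ccm = calibrate_camera(camera, level, seed, capture_index=0, cfg=cfg)
    rows = []
    idx = 1
    for sample in samples:
        reps_rows = []
        for _ in range(reps):
            reps_rows.append(
                measure_sample(sample, camera, level, ccm, seed, idx, cfg=cfg)
            )
            idx += 1
        df = pd.DataFrame(reps_rows)
        row = df.mean(numeric_only=True).to_dict()
        row["x_sem"] = df["x"].std(ddof=1) / np.sqrt(reps) if reps > 1 else 0.0
        row["y_sem"] = df["y"].std(ddof=1) / np.sqrt(reps) if reps > 1 else 0.0
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["level"] = level
    out.attrs["camera"] = camera.name
    out.attrs["seed"] = seed
    return out


# ---------------------------------------------------------------------------
# ideal (noise-free, device-free) trajectories


def ideal_trajectory(
    concentrations, cfg: BenchConfig | None = None, pigment_levels=None
) -> pd.DataFrame:
    """Noise-free chromaticity/hue along a concentration axis.

    Either a CDOM concentration series (mgC/L) or, with ``pigment_levels``,
    an inverse-dilution series for the pigment proxy.
    """
    cfg = cfg or BenchConfig()
    ill = led_illuminant_6000k(level=1.0)
    rows = []
    if pigment_levels is None:
        combos = [(c, 0.0) for c in concentrations]
    else:
        combos = [(0.0, p) for p in pigment_levels]
    for c, p in combos:
        spec = sample_spectrum(
            SampleComposition(cdom_concentration=c, pigment_level=p), ill, cfg.cdom, cfg.pigment
        )
        chroma = chromaticity_of_spectrum(spec)
        try:
            hue = hue_angle(chroma).alpha
        except AchromaticSampleError:
            hue = np.nan
        rows.append(
            {
                "cdom_mgC_L": c,
                "pigment_level": p,
                "x": chroma.x,
                "y": chroma.y,
                "hue_rad": hue,
                "dist_white": chroma.distance_to_white(),
            }
        )
    return pd.DataFrame(rows)


def ideal_mixture_chromaticity(cdom_mgc_l: float, pigment_level: float, cfg=None) -> Chromaticity:
    cfg = cfg or BenchConfig()
    ill = led_illuminant_6000k(level=1.0)
    spec = sample_spectrum(
        SampleComposition(cdom_concentration=cdom_mgc_l, pigment_level=pigment_level),
        ill,
        cfg.cdom,
        cfg.pigment,
    )
    return chromaticity_of_spectrum(spec)


def white_point_crossing(cfg: BenchConfig | None = None, n_grid: int = 1001) -> float:
    """Concentration of closest approach to the white point (grid search)."""
    cfg = cfg or BenchConfig()
    grid = np.linspace(0.0, 100.0, n_grid)
    traj = ideal_trajectory(grid, cfg)
    return float(grid[np.argmin(traj["dist_white"].to_numpy())])


# ---------------------------------------------------------------------------
# experiments


def saturation_onsets(
    seed: int, camera: CameraModel | None = None, iso: int = 800, cfg=None
) -> dict:
    """Deviation-from-linearity onset per illumination level, matched seed."""
    from .calibration import LinearXYCalibration

    cfg = cfg or BenchConfig()
    camera = (camera or default_cameras()[0]).with_iso(iso)
    samples = [SampleComposition(cdom_concentration=c) for c in cfg.onset_series]
    out = {}
    for level in cfg.levels:
        df = measure_series(samples, camera, level, seed, cfg=cfg)
        model = LinearXYCalibration(
            df["cdom_mgC_L"].to_numpy(),
            df[["x", "y"]].to_numpy(),
            meas_sem=df[["x_sem", "y_sem"]].to_numpy(),
        )
        onset = model.fit().saturation_onset
        out[level] = np.inf if onset is None else onset
    return out


def device_grid_series(seed: int, cfg: BenchConfig | None = None, replicates: int = 1):
    """The CDOM series measured under every camera × ISO × level condition."""
    cfg = cfg or BenchConfig()
    samples = [SampleComposition(cdom_concentration=c) for c in cfg.cdom_series]
    out = {}
    for camera in default_cameras():
        for iso in cfg.isos:
            for level in cfg.levels:
                df = measure_series(
                    samples, camera.with_iso(iso), level, seed, cfg=cfg, replicates=replicates
                )
                out[(camera.name, iso, level)] = df
    return out


def pairwise_max_distance(series: dict, cols=("x", "y"), mask=None) -> float:
    """Largest pairwise per-sample chromaticity distance across conditions."""
    keys = list(series)
    dmax = 0.0
    for i, a in enumerate(keys):
        for b in keys[:i]:
            da = series[a][list(cols)].to_numpy()
            db = series[b][list(cols)].to_numpy()
            if mask is not None:
                da, db = da[mask], db[mask]
            dmax = max(dmax, float(np.max(np.hypot(*(da - db).T))))
    return dmax
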