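"""Colour correction, ROI segmentation and pixel aggregation."""

import numpy as np
import pytest

from aquachroma import (
    CorrectionMatrix,
    aggregate_pixels,
    apply_correction,
    extract_color,
    fit_correction,
    segment_roi,
)
from aquachroma.errors import (
    FitError,
    OverexposureError,
    SampleSizeError,
    SegmentationError,
)


def _random_patches(rng, n=24):
    return rng.uniform(0.05, 1.0, size=(n, 3))


class TestFitCorrection:
    def test_identity_when_measured_equals_reference(self):
        patches = _random_patches(np.random.default_rng(0))
        ccm = fit_correction(patches, patches)
        assert np.allclose(ccm.matrix, np.eye(3), atol=1e-12)
        assert ccm.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_recovers_inverse_of_known_mixing(self):
        rng = np.random.default_rng(1)
        reference = _random_patches(rng)
        mixing = np.array([[0.9, 0.15, 0.0], [0.1, 0.8, 0.1], [0.05, 0.1, 1.1]])
        measured = reference @ mixing.T
        ccm = fit_correction(measured, reference)
        assert np.allclose(ccm.matrix, np.linalg.inv(mixing), atol=1e-8)

    def test_too_few_patches(self):
        p = _random_patches(np.random.default_rng(2), n=3)
        with pytest.raises(FitError):
            fit_correction(p, p)

    def test_clipped_patches_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        p = _random_patches(rng, n=6)
        clipped = np.array([False, False, True, False, False, False])
        with pytest.warns(UserWarning):
            ccm = fit_correction(p, p, clipped=clipped)
        assert ccm.n_patches == 5
        with pytest.warns(UserWarning), pytest.raises(FitError):
            fit_correction(p, p, clipped=np.array([True] * 3 + [False] * 3))

    def test_rank_deficient_design(self):
        grey = np.outer(np.linspace(0.1, 1.0, 8), np.ones(3))  # colinear colours
        with pytest.raises(FitError):
            fit_correction(grey, grey * 1.1)


class TestApplyCorrection:
    def test_identity_leaves_input(self):
        v = np.random.default_rng(0).uniform(0, 1, (5, 3))
        assert np.allclose(apply_correction(v, CorrectionMatrix.identity()), v)

    def test_linearity_and_roundtrip(self):
        rng = np.random.default_rng(1)
        m = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        ccm = CorrectionMatrix(m, 0.0, 24)
        inv = CorrectionMatrix(np.linalg.inv(m), 0.0, 24)
        p = rng.uniform(0.1, 1.0, 3)
        assert np.allclose(apply_correction(3 * p, ccm), 3 * apply_correction(p, ccm))
        assert np.allclose(apply_correction(apply_correction(p, ccm), inv), p, atol=1e-6)

    def test_negatives_clamped_and_counted(self):
        ccm = CorrectionMatrix(-np.eye(3), 0.0, 24)
        out, n = apply_correction(np.ones((2, 3)), ccm, return_clamp_count=True)
        assert np.all(out == 0) and n == 6


class TestSegmentRoi:
    def test_known_roi_high_iou(self, scene):
        rect = scene.roi_rects[0]
        mask = segment_roi(scene, roi_rect=rect)
        truth = scene.truth_mask(0)
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou >= 0.95

    def test_uniform_image_fails(self, scene):
        from aquachroma.camera import SceneImage

        flat = SceneImage(np.zeros_like(scene.pixels), scene.meta)
        with pytest.raises(SegmentationError):
            segment_roi(flat)

    def test_rect_constrains_mask(self, scene):
        x, y, w, h = scene.roi_rects[1]
        mask = segment_roi(scene, roi_rect=(x, y, w, h))
        outside = mask.copy()
        outside[y : y + h, x : x + w] = False
        assert not outside.any()


class TestAggregatePixels:
    def test_constant_pixels(self):
        px = np.full((100, 3), 7.0)
        r = aggregate_pixels(px)
        assert np.allclose(r.mean, 7.0) and np.allclose(r.sd, 0.0)
        assert r.n_trimmed == r.n_raw

    def test_outliers_removed_matches_trimmed_oracle(self):
        px = np.full((1000, 3), 100.0)
        px += np.random.default_rng(0).normal(0, 1e-6, px.shape)
        outliers = np.full((10, 3), 5000.0)
        r = aggregate_pixels(np.vstack([px, outliers]))
        assert r.mean == pytest.approx(np.full(3, 100.0), abs=1e-3)
        assert r.n_trimmed <= 1000

    def test_trimming_reaches_fixed_point(self):
        # once converged, extra iterations change nothing
        rng = np.random.default_rng(1)
        px = rng.normal(50, 2, (500, 3))
        a = aggregate_pixels(px, max_iter=10)
        b = aggregate_pixels(px, max_iter=50)
        assert np.allclose(a.mean, b.mean) and a.n_trimmed == b.n_trimmed

    def test_sample_size_guard(self):
        with pytest.raises(SampleSizeError):
            aggregate_pixels(np.ones((10, 3)))

    def test_gaussian_trim_bounded(self):
        rng = np.random.default_rng(2)
        px = rng.normal(1000, 30, (2000, 3))
        r = aggregate_pixels(px)
        assert r.n_trimmed >= 0.8 * r.n_raw


class TestExtractColor:
    def test_blank_matches_illuminant_chromaticity(self, scene):
        from aquachroma.chart import reference_patch_rgb
        from aquachroma.colorimetry import chromaticity_of_spectrum
        from aquachroma.imaging import measure_patches
        from aquachroma.optics import led_illuminant_6000k

        measured, clipped = measure_patches(scene)
        ccm = fit_correction(measured, reference_patch_rgb(led_illuminant_6000k()), clipped=clipped)
        m = extract_color(scene, ccm, sample_index=0)
        ill = chromaticity_of_spectrum(led_illuminant_6000k().spectrum)
        assert np.hypot(m.x - ill.x, m.y - ill.y) < 0.01

    def test_two_cameras_agree_after_correction(self, cameras):
        from aquachroma.bench import calibrate_camera, measure_sample
        from aquachroma.optics import SampleComposition

        sample = SampleComposition(cdom_concentration=40.0)
        points = []
        for cam in cameras:
            ccm = calibrate_camera(cam, 1010.0, seed=4)
            row = measure_sample(sample, cam, 1010.0, ccm, seed=4, capture_index=1)
            points.append((row["x"], row["y"]))
        (xa, ya), (xb, yb) = points
        assert np.hypot(xa - xb, ya - yb) <= 0.01

    def test_clipped_scene_raises_overexposure(self, cameras):
        from aquachroma.bench import capture_scene
        from aquachroma.optics import SampleComposition

        scene = capture_scene(
            [SampleComposition()], cameras[0].with_iso(800), level=60000.0, seed=2
        )
        with pytest.raises(OverexposureError):
            extract_color(scene, CorrectionMatrix.identity(), sample_index=0)

    def test_rgb_difference_ordering_blue_first(self, cameras, cfg):
        # corrected blank-minus-sample differences: |dB| >= |dG| >= |dR|
        from aquachroma.bench import measure_series
        from aquachroma.optics import SampleComposition

        samples = [SampleComposition(cdom_concentration=c) for c in (0.0, 30.0, 60.0, 90.0)]
        df = measure_series(samples, cameras[0], 1010.0, seed=6, cfg=cfg)
        rgb = df[["R", "G", "B"]].to_numpy()
        diff = rgb[0] - rgb[1:]
        assert np.all(np.abs(diff[:, 2]) >= np.abs(diff[:, 1]) - 1e-12)
        assert np.all(np.abs(diff[:, 1]) >= np.abs(diff[:, 0]) - 1e-12)
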