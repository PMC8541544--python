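"""Calibration families: fitting, saturation onset, inversion, mixtures."""

import numpy as np
import pandas as pd
import pytest

from aquachroma import (
    ExponentialDilutionCalibration,
    HueSigmoidCalibration,
    LinearXYCalibration,
    mixture_bias_report,
    saturation_onset,
)
from aquachroma.calibration import _rebuild_results
from aquachroma.errors import FitError, InversionError


def _line(conc, slope=(1e-3, 1.2e-3), intercept=(0.31, 0.32)):
    conc = np.asarray(conc, dtype=float)
    return np.stack([slope[0] * conc + intercept[0], slope[1] * conc + intercept[1]], axis=1)


class TestLinearXY:
    def test_exact_line_recovered(self):
        conc = np.linspace(0, 100, 8)
        res = LinearXYCalibration(conc, _line(conc)).fit()
        assert res.params["slope_x"] == pytest.approx(1e-3, abs=1e-10)
        assert res.params["intercept_y"] == pytest.approx(0.32, abs=1e-10)
        assert res.rsquared == pytest.approx(1.0, abs=1e-12)
        assert res.saturation_onset is None

    def test_breakpoint_detected_within_one_spacing(self):
        # line that flattens beyond a known breakpoint
        conc = np.arange(0, 101, 5.0)
        v = _line(conc)
        brk = 70.0
        for k in range(2):
            v[conc > brk, k] = v[conc == brk, k]
        res = LinearXYCalibration(conc, v).fit()
        assert res.saturation_onset is not None
        assert abs(res.saturation_onset - brk) <= 10.0
        assert res.fit_range[1] < brk + 5.0

    def test_noisy_slope_within_three_standard_errors(self):
        conc = np.linspace(0, 100, 11)
        truth = _line(conc)
        hits = 0
        n = 200
        rng = np.random.default_rng(0)
        sem = np.full_like(truth, 0.002)
        for _ in range(n):
            noisy = truth + rng.normal(0, 0.002, truth.shape)
            res = LinearXYCalibration(conc, noisy, meas_sem=sem).fit()
            ok = abs(res.params["slope_x"] - 1e-3) < 3 * res.bse["slope_x"]
            ok &= abs(res.params["slope_y"] - 1.2e-3) < 3 * res.bse["slope_y"]
            hits += ok
        assert hits / n >= 0.95

    def test_preconditions(self):
        with pytest.raises(FitError):
            LinearXYCalibration([0, 1], _line([0, 1]))
        with pytest.raises(FitError):
            LinearXYCalibration([0, 1, 1], _line([0, 1, 1]))
        with pytest.raises(FitError):
            LinearXYCalibration([0, 1, 2], np.full((3, 2), 0.4))

    def test_summary_mentions_fit(self):
        conc = np.linspace(0, 100, 6)
        text = LinearXYCalibration(conc, _line(conc)).fit().summary()
        assert "slope_x" in text and "R-squared" in text


class TestExponentialDilution:
    @staticmethod
    def _curve(levels, a=(0.45, 0.56), b=(0.14, 0.24), k=(14.0, 15.0)):
        levels = np.asarray(levels, dtype=float)
        return np.stack(
            [a[i] - b[i] * np.exp(-k[i] * levels) for i in range(2)], axis=1
        )

    def test_exact_recovery(self):
        levels = np.array([0.0, 0.02, 0.04, 0.06, 0.08, 0.1])
        res = ExponentialDilutionCalibration(levels, self._curve(levels)).fit()
        assert res.params["asymptote_x"] == pytest.approx(0.45, abs=1e-6)
        assert res.params["rate_y"] == pytest.approx(15.0, abs=1e-4)

    def test_monotone_prediction_on_monotone_data(self):
        levels = np.linspace(0, 0.1, 6)
        res = ExponentialDilutionCalibration(levels, self._curve(levels)).fit()
        pred = res.predict(np.linspace(0, 0.1, 50))
        assert np.all(np.diff(pred, axis=0) > 0)

    def test_near_linear_data_flagged_by_large_uncertainty(self):
        # k -> 0 limit: parameters are barely identified
        levels = np.linspace(0, 0.1, 8)
        v = self._curve(levels, k=(0.05, 0.05))
        v += np.random.default_rng(0).normal(0, 5e-4, v.shape)
        res = ExponentialDilutionCalibration(levels, v).fit()
        assert res.bse["rate_x"] > abs(res.params["rate_x"])

    def test_too_few_points(self):
        with pytest.raises(FitError):
            ExponentialDilutionCalibration([0, 0.05, 0.1], self._curve([0, 0.05, 0.1]))


class TestHueSigmoid:
    @staticmethod
    def _logistic(conc, amin=1.0, amax=3.6, c0=44.0, width=9.0):
        conc = np.asarray(conc, dtype=float)
        return amin + (amax - amin) / (1 + np.exp((conc - c0) / width))

    def test_exact_recovery(self):
        conc = np.linspace(0, 100, 15)
        res = HueSigmoidCalibration(conc, self._logistic(conc)).fit()
        for name, truth in (("alpha_min", 1.0), ("alpha_max", 3.6), ("c0", 44.0), ("width", 9.0)):
            assert res.params[name] == pytest.approx(truth, abs=1e-6)
        assert res.turning_point == pytest.approx(44.0, abs=1e-6)

    def test_turning_point_matches_white_crossing(self, cfg):
        from aquachroma.bench import ideal_trajectory, white_point_crossing

        tr = ideal_trajectory(np.linspace(0, 100, 21), cfg)
        res = HueSigmoidCalibration(tr["cdom_mgC_L"], tr["hue_rad"]).fit()
        c_star = white_point_crossing(cfg, n_grid=401)
        assert abs(res.turning_point - c_star) / c_star <= 0.10

    def test_constant_hue_degenerate(self):
        with pytest.raises(FitError):
            HueSigmoidCalibration(np.linspace(0, 100, 6), np.full(6, 2.0))

    def test_non_monotone_data_warns(self):
        conc = np.linspace(0, 100, 9)
        v = self._logistic(conc)
        v[4] += 1.5
        with pytest.warns(UserWarning):
            HueSigmoidCalibration(conc, v).fit()


class TestInversion:
    def test_linear_roundtrip_noise_free(self):
        conc = np.linspace(0, 100, 9)
        res = LinearXYCalibration(conc, _line(conc)).fit()
        inv = res.invert(res.predict(37.0))
        assert inv.estimate == pytest.approx(37.0, abs=1e-6)
        assert not inv.extrapolated
        assert inv.lower <= inv.estimate <= inv.upper

    def test_sigmoid_roundtrip_and_plateau_error(self):
        conc = np.linspace(0, 100, 15)
        res = HueSigmoidCalibration(conc, TestHueSigmoid._logistic(conc)).fit()
        inv = res.invert(res.predict(np.array(50.0)))
        assert inv.estimate == pytest.approx(50.0, abs=1e-6)
        with pytest.raises(InversionError):
            res.invert(0.2)  # below the lower plateau

    def test_exponential_roundtrip_and_asymptote_error(self):
        levels = np.linspace(0, 0.1, 6)
        res = ExponentialDilutionCalibration(
            levels, TestExponentialDilution._curve(levels)
        ).fit()
        inv = res.invert(res.predict(0.05))
        assert inv.estimate == pytest.approx(0.05, abs=1e-6)
        with pytest.raises(InversionError):
            res.invert((0.46, 0.57))  # beyond both asymptotes

    def test_monotone_inversion_order_preserving(self):
        conc = np.linspace(0, 100, 9)
        res = LinearXYCalibration(conc, _line(conc)).fit()
        estimates = [res.invert(res.predict(c)).estimate for c in (10.0, 35.0, 60.0, 90.0)]
        assert np.all(np.diff(estimates) > 0)

    def test_extrapolation_flagged(self):
        conc = np.linspace(0, 50, 6)
        res = LinearXYCalibration(conc, _line(conc)).fit()
        inv = res.invert(res.predict(80.0))
        assert inv.extrapolated

    def test_near_white_flagged(self):
        conc = np.linspace(0, 100, 9)
        res = LinearXYCalibration(conc, _line(conc, intercept=(0.3283, 0.3283))).fit()
        inv = res.invert((1 / 3 + 0.002, 1 / 3))
        assert inv.near_white

    def test_model_json_roundtrip(self):
        conc = np.linspace(0, 100, 9)
        res = LinearXYCalibration(conc, _line(conc)).fit()
        payload = {
            "schema_version": 1,
            "family": res.family,
            "params": res.params.to_dict(),
            "bse": res.bse.to_dict(),
            "rsquared": res.rsquared,
            "rmse": res.rmse,
            "fit_range": list(res.fit_range),
            "saturation_onset": res.saturation_onset,
        }
        rebuilt = _rebuild_results(payload)
        assert rebuilt.invert(res.predict(42.0)).estimate == pytest.approx(42.0, abs=1e-6)


class TestSaturationOnsetRule:
    def test_clean_line_has_no_onset(self):
        conc = np.linspace(0, 100, 21)
        assert saturation_onset(conc, 0.3 + 1e-3 * conc) is None

    def test_flat_tail_detected(self):
        conc = np.linspace(0, 100, 21)
        v = 0.3 + 1e-3 * np.minimum(conc, 70.0)
        onset = saturation_onset(conc, v)
        assert onset is not None and 70.0 < onset <= 85.0

    def test_single_spike_ignored(self):
        conc = np.linspace(0, 100, 21)
        v = 0.3 + 1e-3 * conc
        v[15] += 0.05
        assert saturation_onset(conc, v, meas_sem=np.full(21, 1e-4)) is None


@pytest.fixture(scope="module")
def cdom_model(cfg):
    from aquachroma.bench import ideal_trajectory

    tr = ideal_trajectory(np.linspace(0, 100, 11), cfg)
    return LinearXYCalibration(tr["cdom_mgC_L"], tr[["x", "y"]].to_numpy()).fit()


class TestMixtureBias:
    def test_pure_cdom_has_negligible_bias(self, cfg, cdom_model):
        from aquachroma.bench import ideal_mixture_chromaticity

        ch = ideal_mixture_chromaticity(40.0, 0.0, cfg)
        df = pd.DataFrame([{"x": ch.x, "y": ch.y, "cdom": 40.0}])
        report = mixture_bias_report(df, {"cdom": cdom_model})
        assert abs(report["bias"].iloc[0]) < 2.0

    def test_mixtures_overestimated(self, cfg, cdom_model):
        from aquachroma.bench import ideal_mixture_chromaticity

        rows = []
        for c in (20.0, 30.0, 40.0, 45.0, 50.0):
            for lev in (0.01, 0.02, 0.04, 0.06):
                ch = ideal_mixture_chromaticity(c, lev, cfg)
                rows.append({"x": ch.x, "y": ch.y, "cdom": c})
        report = mixture_bias_report(pd.DataFrame(rows), {"cdom": cdom_model})
        assert report.attrs["positive_bias_fraction"] >= 0.9
        assert len(report) == len(rows)  # rows x single model
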