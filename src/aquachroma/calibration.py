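"""Concentration–colour calibration models.

Three relationship families link a colour index to constituent
concentration, mirroring what the colorimetry bench actually produces:

* ``LinearXYCalibration`` — chromaticity x and y rise linearly with CDOM
  concentration before saturation; fitted per coordinate by OLS with an
  explicit saturation-onset rule that excludes the flattened tail.
* ``ExponentialDilutionCalibration`` — pigment chromaticity saturates with
  inverse dilution, v(c) = A − B·exp(−k·c); A is the saturation asymptote.
* ``HueSigmoidCalibration`` — the hue angle falls along a four-parameter
  decreasing logistic whose turning point c₀ marks the white-point crossing.

Each model object is built from data and ``fit()`` returns a
:class:`CalibrationResults` carrying the estimates, their standard errors,
goodness of fit, a ``summary()`` table, inversion (``invert``) with
uncertainty propagation, and plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colorimetry import WHITE_POINT
from .errors import FitError, InversionError

Z95 = 1.959963984540054

NEAR_WHITE_RADIUS = 0.01


# ---------------------------------------------------------------------------
# saturation-onset rule


def saturation_onset(
    conc,
    values,
    meas_sem=None,
    low_fraction: float = 0.5,
    z: float = 3.0,
    sustain: int = 2,
):
    """First concentration where the response departs from the low-range line.

    A straight line is fitted to the points in the lower ``low_fraction`` of
    the concentration range.  The detection threshold is ``z`` times the
    larger of the low-range fit RMSE and the typical per-point measurement
    uncertainty (``meas_sem``), so clean data cannot trigger on invisible
    lack of fit.  An excursion must be sustained for ``sustain`` consecutive
    points (a single outlier is not saturation).  Returns ``None`` when no
    departure is found.
    """
    conc = np.asarray(conc, dtype=float)
    values = np.asarray(values, dtype=float)
    low = conc <= conc.min() + low_fraction * (conc.max() - conc.min())
    if low.sum() < 3:
        return None
    coeffs = np.polyfit(conc[low], values[low], 1)
    resid_low = values[low] - np.polyval(coeffs, conc[low])
    rmse = float(np.sqrt(np.mean(resid_low**2)))
    floor = float(np.median(np.asarray(meas_sem, float))) if meas_sem is not None else 0.0
    threshold = z * max(rmse, floor, 1e-9)
    resid = np.abs(values - np.polyval(coeffs, conc))
    candidates = np.flatnonzero(~low)
    over = resid > threshold
    for j, i in enumerate(candidates):
        if not over[i]:
            continue
        follow = candidates[j + 1 : j + sustain]
        if over[follow].all():  # sustained excursion (or last point)
            return float(conc[i])
    return None


# ---------------------------------------------------------------------------
# results container


@dataclass
class InversionResult:
    """A concentration estimate with its uncertainty interval and flags."""

    estimate: float
    lower: float
    upper: float
    extrapolated: bool = False
    near_white: bool = False

    def __post_init__(self) -> None:
        if not self.lower - 1e-12 <= self.estimate <= self.upper + 1e-12:
            raise InversionError("interval must contain the point estimate")


class CalibrationResults:
    """Fit results common to all calibration families.

    Attributes
    ----------
    params, bse : pandas.Series
        Point estimates and standard errors, indexed by parameter name.
    rsquared, rmse : float
        Goodness of fit on the points inside ``fit_range``.
    fit_range : (float, float)
        Concentration window actually used (pre-saturation for linear fits).
    saturation_onset : float or None
        Estimated onset of departure from the calibration relationship.
    """

    def __init__(self, model, params, bse, fitted, used, extra=None):
        self.model = model
        self.family = model.family
        self.params = pd.Series(params)
        self.bse = pd.Series(bse)
        self.nobs = int(np.sum(used))
        conc = model.conc[used]
        self.fit_range = (float(conc.min()), float(conc.max()))
        resid = model.endog[used] - fitted[used]
        self.rmse = float(np.sqrt(np.mean(resid**2)))
        total = np.sum((model.endog[used] - model.endog[used].mean(axis=0)) ** 2)
        self.rsquared = float(1.0 - np.sum(resid**2) / total) if total > 0 else 1.0
        self.saturation_onset = None
        self.fittedvalues = fitted
        self.used = used
        for key, val in (extra or {}).items():
            setattr(self, key, val)

    # -- delegation --------------------------------------------------------

    def predict(self, conc):
        return self.model._predict(self.params, np.asarray(conc, dtype=float))

    def invert(self, observation) -> InversionResult:
        return self.model._invert(self, observation)

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} results",
            "=" * 46,
            f"family            {self.family}",
            f"n points used     {self.nobs}",
            f"fit range         [{self.fit_range[0]:g}, {self.fit_range[1]:g}]",
            f"R-squared         {self.rsquared:.6f}",
            f"RMSE              {self.rmse:.3e}",
            f"saturation onset  {self.saturation_onset}",
            "-" * 46,
            f"{'parameter':<18}{'estimate':>14}{'std err':>14}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<18}{self.params[name]:>14.6g}{self.bse.get(name, np.nan):>14.3g}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data, fitted curve and fit range on a matplotlib axis."""
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        grid = np.linspace(self.model.conc.min(), self.model.conc.max(), 200)
        pred = np.atleast_2d(self.predict(grid))
        endog = np.atleast_2d(self.model.endog.T)
        for k in range(endog.shape[0]):
            ax.plot(self.model.conc, endog[k], "o", ms=4)
            ax.plot(grid, pred.reshape(len(grid), -1).T[k], "-")
        ax.axvspan(*self.fit_range, alpha=0.08, color="grey")
        ax.set_xlabel("concentration")
        ax.set_ylabel("colour index")
        return ax


# ---------------------------------------------------------------------------
# model families


class _CalibrationModel:
    """Shared constructor: concentrations plus one or two colour columns."""

    family = "abstract"

    def __init__(self, conc, endog, meas_sem=None):
        self.conc = np.asarray(conc, dtype=float)
        self.endog = np.asarray(endog, dtype=float)
        self.meas_sem = None if meas_sem is None else np.asarray(meas_sem, dtype=float)
        if self.conc.ndim != 1:
            raise FitError("concentrations must be a 1-D array")
        if len(self.conc) != len(self.endog):
            raise FitError("concentrations and colour values must align")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, conc_col: str, value_cols, **kw):
        return cls(df[conc_col].to_numpy(), df[list(np.atleast_1d(value_cols))].to_numpy().squeeze(), **kw)


class LinearXYCalibration(_CalibrationModel):
    """Per-coordinate OLS of chromaticity (x, y) against concentration.

    The two coordinates are fitted jointly over the same pre-saturation
    window: the saturation onset is the earliest onset found on either
    coordinate, points at or beyond it are excluded and both lines refitted.
    """

    family = "linear-xy"

    def __init__(self, concentrations, chromaticities, meas_sem=None):
        endog = np.asarray(chromaticities, dtype=float)
        if endog.ndim != 2 or endog.shape[1] != 2:
            raise FitError("chromaticities must be an (n, 2) array of (x, y)")
        super().__init__(concentrations, endog, meas_sem)
        if len(self.conc) < 3:
            raise FitError("need at least 3 points for a linear calibration")
        if len(np.unique(self.conc)) < len(self.conc):
            raise FitError("concentrations must be distinct")
        if np.allclose(endog.std(axis=0), 0):
            raise FitError("degenerate fit: all chromaticities identical")

    def fit(self) -> CalibrationResults:
        onsets = []
        for k in range(2):
            sem = self.meas_sem[:, k] if self.meas_sem is not None else None
            o = saturation_onset(self.conc, self.endog[:, k], meas_sem=sem)
            if o is not None:
                onsets.append(o)
        onset = min(onsets) if onsets else None
        used = np.ones(len(self.conc), dtype=bool) if onset is None else self.conc < onset
        if used.sum() < 3:
            used = np.ones(len(self.conc), dtype=bool)
        params, bse = {}, {}
        fitted = np.empty_like(self.endog)
        for k, name in enumerate("xy"):
            design = np.vander(self.conc[used], 2)
            coef, res, *_ = np.linalg.lstsq(design, self.endog[used, k], rcond=None)
            fitted[:, k] = np.polyval(coef, self.conc)
            dof = max(used.sum() - 2, 1)
            s2 = np.sum((self.endog[used, k] - fitted[used, k]) ** 2) / dof
            cov = s2 * np.linalg.inv(design.T @ design)
            params[f"slope_{name}"], params[f"intercept_{name}"] = coef
            bse[f"slope_{name}"], bse[f"intercept_{name}"] = np.sqrt(np.diag(cov))
        res = CalibrationResults(self, params, bse, fitted, used)
        res.saturation_onset = onset
        return res

    def _predict(self, params, conc):
        return np.stack(
            [
                params["slope_x"] * conc + params["intercept_x"],
                params["slope_y"] * conc + params["intercept_y"],
            ],
            axis=-1,
        )

    def _invert(self, results, observation) -> InversionResult:
        """Closed-form inversion, inverse-variance weighted over x and y."""
        obs = np.asarray(observation, dtype=float)
        if obs.shape != (2,):
            raise InversionError("linear-xy inversion expects an (x, y) pair")
        ests, variances = [], []
        for k, name in enumerate("xy"):
            slope = results.params[f"slope_{name}"]
            if abs(slope) < 1e-15:
                continue
            ests.append((obs[k] - results.params[f"intercept_{name}"]) / slope)
            variances.append((results.rmse / slope) ** 2)
        if not ests:
            raise InversionError("calibration has no usable slope")
        w = 1.0 / np.asarray(variances)
        est = float(np.sum(w * np.asarray(ests)) / np.sum(w))
        sd = float(np.sqrt(1.0 / np.sum(w)))
        lo, hi = results.fit_range
        return InversionResult(
            estimate=est,
            lower=est - Z95 * sd,
            upper=est + Z95 * sd,
            extrapolated=not lo <= est <= hi,
            near_white=float(np.hypot(obs[0] - WHITE_POINT[0], obs[1] - WHITE_POINT[1]))
            < NEAR_WHITE_RADIUS,
        )


class ExponentialDilutionCalibration(_CalibrationModel):
    """Saturating exponential v(c) = A − B·exp(−k·c) per chromaticity
    coordinate, for pigment dilution series.

    Initialisation: A from the largest-concentration value, B from the span,
    k from a log-linear regression of (A − v); bounded restarts with k
    perturbed if the solver fails.
    """

    family = "exponential-dilution"

    def __init__(self, inverse_dilutions, chromaticities, meas_sem=None):
        endog = np.asarray(chromaticities, dtype=float)
        if endog.ndim != 2 or endog.shape[1] != 2:
            raise FitError("chromaticities must be an (n, 2) array of (x, y)")
        super().__init__(inverse_dilutions, endog, meas_sem)
        if len(self.conc) < 4:
            raise FitError("need at least 4 points for the exponential fit")

    def fit(self) -> CalibrationResults:
        from scipy.optimize import curve_fit

        def f(c, a, b, k):
            return a - b * np.exp(-k * c)

        params, bse = {}, {}
        fitted = np.empty_like(self.endog)
        span = self.conc.max() - self.conc.min()
        for k_idx, name in enumerate("xy"):
            v = self.endog[:, k_idx]
            a0 = v[np.argmax(self.conc)] + 0.05 * np.ptp(v)
            b0 = max(a0 - v[np.argmin(self.conc)], 1e-6)
            k0 = 2.0 / max(span, 1e-9)
            last_err = None
            for attempt, kk in enumerate([k0, 5 * k0, 0.2 * k0]):
                try:
                    popt, pcov = curve_fit(
                        f, self.conc, v, p0=[a0, b0, kk], maxfev=20000
                    )
                    break
                except RuntimeError as err:  # pragma: no cover - rare
                    last_err = err
            else:
                raise FitError(f"exponential fit did not converge: {last_err}")
            fitted[:, k_idx] = f(self.conc, *popt)
            errs = np.sqrt(np.diag(pcov))
            for p, e, pname in zip(popt, errs, ("asymptote", "span", "rate")):
                params[f"{pname}_{name}"] = p
                bse[f"{pname}_{name}"] = e
        used = np.ones(len(self.conc), dtype=bool)
        return CalibrationResults(self, params, bse, fitted, used)

    def _predict(self, params, conc):
        return np.stack(
            [
                params[f"asymptote_{n}"]
                - params[f"span_{n}"] * np.exp(-params[f"rate_{n}"] * conc)
                for n in "xy"
            ],
            axis=-1,
        )

    def _invert(self, results, observation) -> InversionResult:
        obs = np.asarray(observation, dtype=float)
        ests, variances = [], []
        for k_idx, name in enumerate("xy"):
            a = results.params[f"asymptote_{name}"]
            b = results.params[f"span_{name}"]
            rate = results.params[f"rate_{name}"]
            arg = (a - obs[k_idx]) / b
            if arg <= 0 or rate <= 0:
                continue
            est = -np.log(arg) / rate
            slope = b * rate * np.exp(-rate * est)  # dv/dc at the estimate
            if abs(slope) < 1e-12:
                continue
            ests.append(est)
            variances.append((results.rmse / slope) ** 2)
        if not ests:
            raise InversionError("observation lies beyond the exponential asymptote")
        w = 1.0 / np.asarray(variances)
        est = float(np.sum(w * np.asarray(ests)) / np.sum(w))
        sd = float(np.sqrt(1.0 / np.sum(w)))
        lo, hi = results.fit_range
        return InversionResult(
            estimate=est,
            lower=est - Z95 * sd,
            upper=est + Z95 * sd,
            extrapolated=not lo <= est <= hi,
        )


class HueSigmoidCalibration(_CalibrationModel):
    """Decreasing four-parameter logistic for hue angle vs concentration:

        α(c) = α_min + (α_max − α_min) / (1 + exp((c − c₀)/w)).

    ``c₀`` is the turning point — for CDOM it coincides with the
    concentration of closest approach to the white point.
    """

    family = "sigmoid-hue"

    def __init__(self, concentrations, hue_angles, meas_sem=None):
        endog = np.asarray(hue_angles, dtype=float)
        if endog.ndim != 1:
            raise FitError("hue angles must be a 1-D array (radians)")
        super().__init__(concentrations, endog, meas_sem)
        if len(self.conc) < 5:
            raise FitError("need at least 5 points spanning the inflection")
        if np.ptp(endog) < 1e-9:
            raise FitError("degenerate fit: hue angles are constant")

    @staticmethod
    def _logistic(c, amin, amax, c0, width):
        return amin + (amax - amin) / (1.0 + np.exp((c - c0) / width))

    def fit(self) -> CalibrationResults:
        import warnings as _warnings

        from scipy.optimize import curve_fit

        v = self.endog
        increases = np.diff(v)
        if np.any(increases > 0.05 * np.ptp(v)):
            _warnings.warn("hue series is not monotone beyond noise tolerance", stacklevel=2)
        amin0, amax0 = float(v.min()), float(v.max())
        mid = 0.5 * (amin0 + amax0)
        c00 = float(self.conc[np.argmin(np.abs(v - mid))])
        span = self.conc.max() - self.conc.min()
        last_err = None
        for w0 in (span / 10, span / 4, span / 25):
            try:
                popt, pcov = curve_fit(
                    self._logistic, self.conc, v, p0=[amin0, amax0, c00, w0], maxfev=30000
                )
                break
            except RuntimeError as err:  # pragma: no cover - rare
                last_err = err
        else:
            raise FitError(f"sigmoid fit did not converge: {last_err}")
        errs = np.sqrt(np.diag(pcov))
        names = ("alpha_min", "alpha_max", "c0", "width")
        params = dict(zip(names, popt))
        bse = dict(zip(names, errs))
        fitted = self._logistic(self.conc, *popt)
        used = np.ones(len(self.conc), dtype=bool)
        res = CalibrationResults(self, params, bse, fitted, used)
        res.turning_point = float(params["c0"])
        return res

    def _predict(self, params, conc):
        return self._logistic(
            conc, params["alpha_min"], params["alpha_max"], params["c0"], params["width"]
        )

    def _invert(self, results, observation) -> InversionResult:
        from scipy.optimize import brentq

        alpha = float(observation)
        p = results.params
        lo, hi = results.fit_range
        f = lambda c: self._predict(p, np.asarray(c)) - alpha
        flo, fhi = f(lo), f(hi)
        if flo * fhi > 0:
            raise InversionError(
                "hue observation lies beyond the sigmoid plateau on the fit range"
            )
        est = float(brentq(f, lo, hi, xtol=1e-10))
        # local slope for interval propagation
        eps = max((hi - lo) * 1e-6, 1e-9)
        slope = (f(est + eps) - f(est - eps)) / (2 * eps)
        sd = abs(results.rmse / slope) if abs(slope) > 1e-15 else np.inf
        return InversionResult(
            estimate=est,
            lower=est - Z95 * sd,
            upper=est + Z95 * sd,
            extrapolated=False,
            near_white=abs(est - p["c0"]) < 0.05 * (hi - lo),
        )


# ---------------------------------------------------------------------------
# (de)serialisation

_FAMILY_CLASSES = {}


def _rebuild_results(payload: dict):
    """Reconstruct a results object from the versioned model JSON."""
    if payload.get("schema_version") != 1:
        raise FitError("unknown calibration model schema version")
    cls = _FAMILY_CLASSES[payload["family"]]
    model = cls.__new__(cls)
    results = CalibrationResults.__new__(CalibrationResults)
    results.model = model
    results.family = payload["family"]
    results.params = pd.Series(payload["params"])
    results.bse = pd.Series(payload["bse"])
    results.rsquared = payload["rsquared"]
    results.rmse = payload["rmse"]
    results.fit_range = tuple(payload["fit_range"])
    results.saturation_onset = payload.get("saturation_onset")
    return results


# ---------------------------------------------------------------------------
# mixture bias


def mixture_bias_report(mixtures: pd.DataFrame, models: dict) -> pd.DataFrame:
    """Invert mixture observations with single-component calibrations.

    Parameters
    ----------
    mixtures : DataFrame
        One row per mixture with columns ``x``, ``y`` (observed chromaticity)
        and the ground-truth columns named after each model key (e.g.
        ``cdom_mgC_L``).
    models : dict
        Mapping from truth-column name to a fitted
        :class:`CalibrationResults` of a single-component model.

    Returns
    -------
    DataFrame with one row per mixture × model: estimate, truth, signed bias
    and flags; inversion failures are tabulated (NaN estimate), not fatal.
    """
    rows = []
    for i, mix in mixtures.iterrows():
        for truth_col, results in models.items():
            try:
                inv = results.invert((mix["x"], mix["y"]))
                est, extrap = inv.estimate, inv.extrapolated
            except InversionError:
                est, extrap = np.nan, True
            truth = float(mix[truth_col])
            rows.append(
                {
                    "mixture": i,
                    "model": truth_col,
                    "estimate": est,
                    "truth": truth,
                    "bias": est - truth,
                    "extrapolated": extrap,
                }
            )
    report = pd.DataFrame(rows)
    valid = report["bias"].dropna()
    report.attrs["positive_bias_fraction"] = (
        float((valid > 0).mean()) if len(valid) else np.nan
    )
    return report


_FAMILY_CLASSES.update(
    {
        LinearXYCalibration.family: LinearXYCalibration,
        ExponentialDilutionCalibration.family: ExponentialDilutionCalibration,
        HueSigmoidCalibration.family: HueSigmoidCalibration,
    }
)
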