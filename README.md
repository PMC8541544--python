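# aquachroma

Digital-camera colorimetry of optically active water constituents.

Water colour is a long-standing proxy for water quality: coloured dissolved
organic matter (CDOM) absorbs blue light and pushes water toward yellow–brown,
phytoplankton pigments push it toward green. `aquachroma` implements the full
measurement chain of a low-cost cuvette colorimetry setup — and, because the
physical rig (LED box, cuvette, consumer camera) is not required, a
physics-based synthetic bench that emulates it, so the whole chain is testable
on a desk.

The chain:

1. **Forward optics** — constituent absorption
   (CDOM: `a(λ) = c·a*(λ₀)·exp(−S(λ−λ₀))` with slope `S ≈ 0.0105 nm⁻¹`;
   pigment: a two-band Gaussian chlorophyll-like template), Beer–Lambert
   transmission `T(λ) = exp(−a(λ)·l)` through a 1 cm cuvette, and a 6000 K
   white-LED illuminant.
2. **Camera simulation** — Gaussian channel sensitivities, ISO gain, shot and
   read noise, a stray-light floor, 16-bit quantisation and clipping; two
   presets with shifted sensitivity peaks stand in for different devices.
3. **Image pipeline** — a least-squares 3×3 colour-correction matrix fitted on
   a 24-patch reference chart, Otsu ROI segmentation, confidence-interval
   pixel trimming.
4. **Colorimetry** — CIE 1931 tristimulus integration
   `X = ∫I(λ)x̄(λ)dλ` (and Y, Z), chromaticity `x = X/(X+Y+Z)`,
   and the hue angle `α = atan2(y−1/3, x−1/3) mod 2π` around the white point.
5. **Calibration** — statsmodels-style model objects linking colour to
   concentration: linear x,y–concentration fits with an explicit
   saturation-onset rule, a saturating exponential for pigment dilution
   series, and a four-parameter decreasing logistic for hue, each invertible
   with uncertainty.

## Worked example

Measure a humic-acid series with the simulated camera at 1010 lux / ISO 800,
fit the linear chromaticity calibration, and invert an unknown:

```python
import numpy as np
from aquachroma import LinearXYCalibration, HueSigmoidCalibration
from aquachroma.bench import BenchConfig, measure_series, white_point_crossing
from aquachroma.camera import default_cameras
from aquachroma.optics import SampleComposition

cfg = BenchConfig()
cam = default_cameras()[0].with_iso(800)
concs = np.linspace(0.0, 100.0, 11)
samples = [SampleComposition(cdom_concentration=c) for c in concs]
df = measure_series(samples, cam, level=1010.0, seed=1, cfg=cfg)

res = LinearXYCalibration(concs, df[["x", "y"]].to_numpy(),
                          meas_sem=df[["x_sem", "y_sem"]].to_numpy()).fit()
print(res.summary())
inv = res.invert((0.345, 0.358))
print(f"inverted concentration: {inv.estimate:.1f} "
      f"[{inv.lower:.1f}, {inv.upper:.1f}] mgC/L")
```

prints

```
LinearXYCalibration results
==============================================
family            linear-xy
n points used     9
fit range         [0, 80]
R-squared         0.997457
RMSE              6.229e-04
saturation onset  90.0
----------------------------------------------
parameter               estimate       std err
slope_x              0.000475658      7.21e-06
intercept_x             0.306932      0.000343
slope_y              0.000479797      1.07e-05
intercept_y              0.32139      0.000509
inverted concentration: 78.2 [76.3, 80.0] mgC/L
```

Chromaticity x and y rise near-linearly with CDOM until the stray-light floor
flattens the response (here detected at 90 mgC/L and excluded from the fit);
the inversion combines the x and y lines inverse-variance weighted and
propagates the fit RMSE into the interval. The hue angle falls from ~204°
(bluish blank) to ~59° (yellow–orange) along the same series; its logistic
turning point (40.7 mgC/L on this run) coincides with the concentration whose
ideal chromaticity passes closest to the white point (43.4 mgC/L):

```python
hue = HueSigmoidCalibration(concs, df["hue_rad"].to_numpy()).fit()
print(hue.turning_point, white_point_crossing(cfg))
```

A thin CLI covers the same workflow on files
(`aquachroma simulate / extract / calibrate / invert`); scenes are written as
16-bit TIFF with a JSON geometry sidecar.

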