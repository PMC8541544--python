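# Methods

This note documents the models behind `aquachroma`, the defaults of the
synthetic bench, and the design choices that were genuinely open.

## Colorimetry

Tristimulus values are trapezoidal integrals of the sensed spectrum weighted
by the CIE 1931 2° colour matching functions; the integration grid is the
union of the spectrum and CMF grids refined to ≤ 1 nm so the product of the
two piecewise-linear factors is integrated accurately (verified against a
0.1 nm Riemann sum to better than 0.05%). Chromaticity is the usual
projective normalisation, and the hue angle is

    α = atan2(y − 1/3, x − 1/3)  mod 2π,

measured around the equal-energy white point with the (y − y_w) component as
the first argument. Part of the satellite hue-angle literature measures the
angle from a different axis/orientation; absolute angles are therefore only
comparable within one convention. Hue is undefined at the white point: inside
a configurable ε-disk (default 1e−6) the package raises a typed
achromatic-sample error instead of returning an arbitrary angle — the
S-curve turning point of the hue calibration is precisely the concentration
whose colour passes closest to this singularity.

**CMF table.** The shipped asset `data/cie1931_2deg_5nm.csv` tabulates, at
5 nm over 380–780 nm, the multi-lobe Gaussian analytic representation of the
CIE 1931 2° observer (Wyman, Sloan & Shirley, *JCGT* 2013), renormalised so
all three curves integrate identically. Consequences: the equal-energy
spectrum maps to (1/3, 1/3) essentially exactly; ȳ peaks at 555 nm; the
Planck 6000 K chromaticity computed through these curves is (0.3222, 0.3317)
against the published (0.3221, 0.3318). The representation deviates from the
official table by ~1% pointwise, which is irrelevant at the chromaticity
precision (~1e−3) this pipeline works at.

**RGB↔XYZ bridge.** The fixed linear-sRGB/D65 matrix (IEC 61966-2-1
primaries) is embedded as a constant. It is a pure bookkeeping bridge between
the corrected camera space and chromaticity; any fixed, published RGB space
would do, and bit-reproducibility is the reason it is hard-coded.

## Forward optics

Single-pass geometry: light from the LED passes once through the cuvette to
the camera; the black holder absorbs the rest. Only absorption is modelled —
no scattering, turbidity, fluorescence or multiple reflections — which is
the idealisation appropriate for dissolved/filtered samples in a cuvette.

* **CDOM (humic acid proxy):** `a(λ) = c · a_ref · exp(−S(λ−440))` with
  `S = 0.0105 nm⁻¹` (mid-point of the 0.010–0.011 nm⁻¹ range measured for
  technical humic acid) and `a_ref = 0.855 m⁻¹ per (mgC/L)`. `a_ref` for a
  specific commercial humic acid is not published; the default was fixed once
  so that the chromaticity trajectory's closest approach to the white point
  falls mid-range (≈ 43 mgC/L) of the 0–100 mgC/L working window, the regime
  the method is designed for. It is configurable.
* **Pigment proxy:** two Gaussian bands, a blue Soret band at 435 nm
  (σ 30 nm, weight 1.6) and a red band at 675 nm (σ 20 nm, weight 1.0),
  scaled by 2500 m⁻¹ per unit inverse dilution. The concentration axis is
  the dimensionless inverse dilution of an extract (0.02–0.1 ≙ 50×–10×
  dilutions); no absolute pigment mass is implied. The template stands in
  for a measured extract spectrum and is replaceable via CSV.
* **Units:** absorption in m⁻¹, path length in cm (standard 1 cm cuvette),
  conversion inside `beer_lambert_transmission`; spectra carry a unit tag and
  mismatches raise a typed unit error.
* **Illuminant:** a 6000 K-class white LED template — narrow blue pump
  (463.6 nm, σ 9.1 nm, amplitude 2.60) plus a broad phosphor hump
  (548.6 nm, σ 53/98 nm), normalised to unit mean. Its chromaticity sits
  0.0195 from the 6000 K Planckian point (contract: ≤ 0.02, checked against
  a Planck-law oracle computed through the package's own colorimetry). The
  template parameters were fixed once, jointly with `a_ref`, so that the
  ideal chromaticity-vs-concentration trajectory is near-linear before
  saturation and monotone (x, y rising, hue falling) — the behaviour the
  physical setup exhibits — and were not revisited afterwards.
  The illumination level ("lux") is a relative scalar multiplying the
  spectrum; only the 510/1010 ratio ever matters.

## Camera bench

Per channel, expected signal is `gain · level · K · ∫I(λ)s(λ)dλ` with
Gaussian sensitivities (preset A peaks 600/530/460 nm, preset B 612/542/448
nm, σ 35 nm — consumer-sensor curves are unpublished, Gaussians are the
standard surrogate). ISO 400/800 map to gains 1/2. The exposure constant K is
fixed so preset A reads ≈ 12 000 DN above black on green for the blank at
level 1010, gain 1: mid-range, with headroom so deliberate overexposure still
clips at the 16-bit full well. Pixels receive black level 800 DN, Gaussian
read noise (σ 40 DN), a Gaussian approximation to shot noise
(variance 2 DN per DN), rounding, and clipping; rendering is bit-reproducible
given a seed.

Two imperfections are deliberately part of the bench, because they bound the
method exactly as in a real enclosure:

* **Stray-light floor:** a neutral additive floor of 900 DN at unit gain
  (≈ 7% of the blank signal at 1010, ≈ 15% at 510) representing room-light
  leakage and veiling flare. In a purely multiplicative imaging model,
  corrected chromaticity is *exactly* independent of the illumination level,
  so a level-independent additive floor is the only mechanism by which low
  illumination can saturate earlier — which it does: the floor is a larger
  fraction of a dimmer signal, so the chromaticity response flattens at a
  lower concentration at 510 than at 1010.
* **LED spectral jitter:** the pump amplitude varies between captures with
  relative σ 1.3%, emulating drive-level spectral instability of dimmable
  LEDs. This produces realistic capture-to-capture chromaticity scatter
  (σ ≈ 5×10⁻⁴), which is what the saturation detector's threshold is
  calibrated against. Because every capture derives its generator from
  (seed, capture index), runs at different levels with the same seed share
  the jitter and noise realisation — "matched seeds" — so level effects can
  be compared pairwise without Monte-Carlo averaging over nuisance noise.

The scene layout (24 chart patches, 16×16 px; cuvette ROIs 40×40 px) and a
fast path that simulates only the ROI pixel populations share the same draw
code; the fast path exists because the calibration experiments need hundreds
of captures.

## Image pipeline

* **Colour correction.** The interactive chart-profiling step of the
  original protocol is replaced by an explicit least-squares 3×3 matrix from
  measured patch triples to an ideal rendering of the same patches
  (XYZ under the same illuminant, normalised by the illuminant's Y, through
  the sRGB bridge). The reference values therefore retain the illuminant
  colour — a corrected blank reproduces the illuminant chromaticity — while
  exposure, gain and the camera's spectral response are normalised away.
  Chart reflectances are a documented synthetic uplift (three broad Gaussian
  lobes at 610/545/465 nm) of the nominal patch triples; both sides of the
  fit use the same spectra, so the fit target is self-consistent. Clipped
  patches are excluded (error below 4 usable patches).
* **Segmentation.** Global Otsu threshold on luminance, intersected with the
  sidecar ROI rectangle when provided, then the largest connected component.
* **Aggregation.** Iterative confidence-interval trimming (z at the given
  confidence, default 0.95), at most 10 iterations, per channel with the
  union of kept pixels; requires ≥ 30 pixels. Whether the original
  procedure trimmed per channel or on luminance is not specified anywhere;
  per-channel with union is the implemented contract.
* **Extraction.** Corrected triples are scaled by their maximum before the
  sRGB bridge (chromaticity is scale-invariant; this keeps the bridge's
  [0, 1] domain). Blank-ratio normalisation is available but off by default:
  RGB-difference analyses use blank differences, chromaticity analyses use
  absolute values. Clip fraction > 5% raises an overexposure error.

## Calibration

* **Linear x,y fits.** OLS per coordinate over a common pre-saturation
  window. The saturation onset rule: fit a line to the lower half of the
  concentration range; flag the first point whose residual exceeds
  3 × max(low-range RMSE, typical replicate standard error) *sustained for
  two consecutive points*; exclude from the flagged point on and refit. The
  uncertainty floor and the two-point sustain are refinements over a bare
  3×RMSE rule: without them, any smooth lack of fit or a single jitter
  excursion triggers spuriously on noise-free or lightly-noisy data.
* **Exponential dilution fits.** `v(c) = A − B·exp(−k·c)` per coordinate by
  Levenberg–Marquardt; initialisation from the series endpoints and a
  log-linear rate guess, with bounded restarts. In the k→0 (near-linear)
  limit the parameters are barely identified; the fit degrades gracefully
  and the large standard errors flag it.
* **Hue sigmoid.** Four-parameter decreasing logistic; the turning point c₀
  is reported and, for CDOM, coincides with the white-point-closest
  concentration found by grid search (within ~0.5% on the default bench;
  the package asserts 10%).
* **Inversion.** Linear: closed form per coordinate, combined
  inverse-variance weighted. Exponential and sigmoid: monotone root finding
  on the fit range. Intervals propagate the fit RMSE through the local slope
  (±1.96σ); forward-model uncertainty is *not* propagated — a documented
  limitation. Flags: extrapolation outside the fit range; near-white when a
  chromaticity observation lies within 0.01 of the white point (hue
  unreliable there).
* **Mixture bias.** Mixtures of CDOM and pigment, inverted with a
  CDOM-only calibration, are overestimated essentially always on the default
  bench: the pigment's Soret band mimics additional blue absorption. The
  package quantifies the effect as a signed-bias table and a positive-bias
  fraction; two-component unmixing from (x, y) alone is explicitly out of
  scope.

## What the bench does and does not show

Passing tests demonstrate the *structure* of the method: device independence
after correction (≤ 0.01 in xy across cameras, gains and levels,
pre-saturation, vs > 0.005 uncorrected), monotone colour trajectories,
blue-first RGB sensitivity to CDOM, earlier saturation at lower illumination
(paired sign test over matched seeds), and parameter/inversion recovery. The
bench does not emulate scattering, real reagent absorption magnitudes,
demosaicing, lens effects or chart aging, so absolute concentrations
(turning point, onset values) are properties of the documented defaults, not
predictions for any particular laboratory; with the defaults they land in
the same range as the physical setup they emulate (turning point ≈ 43
mgC/L, onsets in the 60–95 mgC/L decade, earlier at 510).

## Problem sizes

Defaults used by the test suite and the acceptance script: 21–31-point
concentration series, 3 replicate captures per point, 1600-pixel ROIs,
12 matched seed pairs for the saturation comparison, 200 Monte-Carlo
repetitions for inversion error, a 40-point mixture grid. These sizes give
stable statistics while keeping a full run in the tens of seconds.
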