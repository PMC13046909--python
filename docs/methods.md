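# Methods

## Model

Image-space two-material decomposition treats every voxel of a paired
low/high-energy acquisition as a mixture of a base material and one contrast
material. With the base on the water line (LE = HE) and the contrast
material on the material line (LE = DER · HE), projecting the measured point
(HE, LE) onto the material line parallel to the water line removes the base
contribution and yields the contrast components

    HE_CM = (LE − HE) / (DER − 1),   LE_CM = DER · HE_CM.

The concentration-map value is the blend CM = w·LE_CM + (1 − w)·HE_CM =
(DER·w + 1 − w)(LE − HE)/(DER − 1). Two systematic effects bias this on real
scanners: the base material's low- and high-energy CT numbers are not equal
(residual calibration offsets of a few HU are within accepted QA tolerance),
and the DER depends on tube voltage, dose and habitus. The corrected form
adds the mismatch Δ_base = HE_base − LE_base inside the difference,

    CM_corrected = (DER·w + 1 − w)(LE − HE + Δ_base)/(DER − 1),

and a scaling factor α (HU per mg/mL) converts to concentration, C = CM/α.
The sign convention for Δ_base is the unique one for which a pure-base voxel
(LE = LE_base, HE = HE_base) maps to exactly 0 HU, which is the stated
purpose of the correction; it also matches the negative calibrated values
observed when the base reads higher at low energy.

Assumptions: exactly two basis materials; the two energy images are
co-registered and already in HU; decomposition is post-reconstruction
(projection-domain decomposition, beam hardening and scatter are out of
scope).

## Calibration fits

Per scan configuration (material, kV, dose, fat ring), three free-intercept
OLS fits on rod-level ROI means:

1. **Base intercepts** — LE and HE each regressed on known concentration;
   intercepts are LE_base and HE_base, Δ_base their difference.
2. **DER** — LE regressed on HE; the slope is the DER. The orientation is
   fixed by the material-line definition LE = DER·HE and by DER > 1 for
   iodine and iron; regressing the other way would estimate 1/DER.
3. **α** — corrected CM (computed with the fitted DER and Δ_base and the
   configured w) regressed on concentration; the slope is α, because
   C = CM/α makes α the HU response per mg/mL. The fit intercept should be
   near zero after the Δ_base correction and is kept as a QC diagnostic.

All fits are unweighted (no noise- or ROI-size weighting) with free
intercepts; exactly collinear input is an exact fit; fewer than two distinct
concentrations, or zero predictor variance, raises an insufficient-data
error. Diagnostics (slope, intercept, R², residual SE) are stored per fit.

The **mean method** averages Δ_base, DER and α per (material, kV) across
dose levels and fat-ring states — arithmetic mean and sample SD (n − 1
denominator), SD reported as 0 for a single configuration. Aggregating
across mixed materials or voltages is an error, not a silent pool.

## The weighting factor w

w is vendor-specific and generally unpublished. It defaults to 0.5 and is a
plain configuration parameter because the end-to-end concentration is
invariant to it: the blend factor (DER·w + 1 − w) multiplies both the CM
value and the fitted α, so it cancels in C = CM/α whenever calibration and
quantification share the same w. This invariance is asserted in the tests
for w ∈ {0, 0.3, 0.5, 1}. Consequently the *absolute* α values calibrated on
synthetic data depend on w (α = (DER·w + 1 − w)·s_low/DER for a generator
with low-energy slope s_low), while concentrations do not.

## ROI geometry

Positions are in millimetres, origin at the centre of the first pixel; ROI
centres are physical coordinates so specifications survive resampling. A
circular ROI includes a pixel iff its centre lies inside the circle —
deterministic, identical across the two energy channels, and trivially
checked against a brute-force per-pixel oracle. For 3-D volumes the
per-slice means over the ROI's slice range are averaged with equal weights;
the default is the single central slice. Supported inputs: NIfTI files,
DICOM series directories (rescale slope/intercept applied; missing rescale
is an error), and a raw `.npy` + JSON-sidecar fixture format written by the
phantom generator.

A note on ROI size: a circular 4 cm² ROI (radius 11.28 mm) cannot fit inside
a 20 mm rod (cross-section 3.14 cm²). The 4 cm² default of `RoiSpec` is kept
as the documented measurement convention, but synthetic-study extraction
defaults to 2 cm² (radius 7.98 mm) so the ROI stays strictly inside the rod.

## Synthetic phantom

The generator emulates an abdomen-sized spectral QA phantom: an elliptical
body of base material (half-axes 150 × 100 mm), an optional fat ring
(175 × 125 mm, about −115/−95 HU) simulating a larger habitus, and 20 mm
rods on a 60 mm circle holding the insert concentrations (iodine 0.5, 1, 2,
5, 10, 15 mg/mL in water-equivalent; iron 2, 5, 15, 25 mg/mL in
liver-equivalent). Rod CT numbers follow the linear spectral model
LE = LE_base + s_low·C, HE = HE_base + (s_low/DER)·C, so a noiseless phantom
round-trips exactly through calibration — the primary correctness oracle.

Ground-truth parameters are fixed at magnitudes typical of a clinical
photon-counting system: iodine s_low = 26.3 HU·mL/mg with DER 2.10 (120 kV)
and 2.49 (140 kV), water base LE −2 / HE −7 HU (Δ_base = −5); iron s_low =
8.0 HU·mL/mg with DER 1.93/2.18, liver base LE 54 / HE 50 HU (Δ_base = −4).
The study design is 12 configurations per material (2 kV × 3 dose levels ×
2 ring states) with a distinct true DER per kV.

Noise is independent additive Gaussian per channel — default SD 15 HU (LE)
and 10 HU (HE) at 100 % dose, scaled by 1/sqrt(dose fraction) — the simplest
model that exercises the fits. Deliberately **not** simulated: spectral
physics (kV dependence is imposed through the per-kV DER, not modelled),
beam hardening, scatter, noise correlation between bins, streaks, iterative-
reconstruction texture, and partial-volume effects at rod edges. Passing
tests therefore demonstrate the correctness of the estimation and correction
chain under the linear model, not robustness to every artefact of real
scanner data; on real images the residual errors after correction are
expected to be larger than the numerically exact recovery seen here.

Images are 256² at 1.5 mm spacing (384 mm field of view, large enough for
the ringed phantom); rasterization uses pixel-centre membership. Each study
configuration draws its seed from a `SeedSequence` spawned off the study
seed, so studies are reproducible and configurations independent.

## Numerical choices

- DER values with DER − 1 ≤ 1e−6 are rejected (invalid-parameter error)
  rather than allowed to produce near-infinite projections.
- Relative error (C_est − C_true)/C_true·100 % raises on C_true = 0; rods at
  zero concentration are still quantified but excluded from error columns.
- Negative CM and concentration values are preserved (no clipping); any
  display clipping is the caller's choice.
- ROI tables are written with 17 significant digits and read with
  round-trip float parsing, so table round-trips are lossless.
- Sample SD (ddof = 1) everywhere a spread is reported.

## Problem sizes used in validation

The test suite and the acceptance script validate on: noiseless
12-configuration studies per material (exact recovery to ≤ 1e−6 relative,
measured at ~1e−15), a 200-replicate Monte-Carlo at 2 HU channel noise
(mean DER error ~1e−3, mean Δ_base error ~0.2 HU), 1,000 randomized voxels
for the algebraic identities at 1e−9 relative tolerance, and end-to-end
corrected-vs-uncorrected quantification on noiseless rods where the injected
base mismatch is the only bias source (uncorrected error ∝ 1/C, corrected
error at floating-point zero). These sizes give stable statistics while the
whole suite runs in a few seconds.

## Known limitations

- The mean method averages over dose and habitus; a configuration far from
  the calibrated set (e.g. much larger patients) is extrapolation.
- Unweighted OLS is assumed; rod-level heteroscedasticity (dose-dependent
  noise) is ignored in the fits, matching common practice.
- Only two energy images are supported; multi-bin decompositions are out of
  scope.
- DICOM support reads standard CT series; vendor-private spectral tags are
  not interpreted.
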