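# spectralcal

Phantom-based calibration and correction for two-material decomposition in
spectral CT, aimed at medical physicists and imaging scientists doing
quantitative iodine and iron imaging on photon-counting detector (PCD) CT.

## The problem

Image-space two-material decomposition converts a paired low/high-energy
acquisition into a concentration map (CM). In the (HE, LE) plane, voxels of
pure base material (water- or liver-equivalent tissue) lie on the *water
line* LE = HE, and voxels of pure contrast material on the *material line*
LE = DER · HE, where the dual-energy ratio DER > 1. A mixed voxel is
projected onto the material line parallel to the water line:

    HE_CM = (LE − HE) / (DER − 1),    LE_CM = DER · HE_CM

and the CM value is the blend CM = w·LE_CM + (1 − w)·HE_CM with a vendor
weighting w ∈ [0, 1]. Real scanners leave a small residual mismatch between
the base material's low- and high-energy CT numbers (a few HU is within
accepted QA tolerance), and the DER varies with tube voltage, dose and
patient habitus. Both propagate into large relative errors at the low
concentrations that matter clinically (lesion enhancement, early hepatic
iron overload).

The correction calibrated here adds the base mismatch Δ_base = HE_base −
LE_base inside the projection and scales by α (HU per mg/mL):

    CM_corrected = (DER·w + 1 − w) · (LE − HE + Δ_base) / (DER − 1)
    C = CM_corrected / α

Per scan configuration, three ordinary least-squares fits on phantom rods of
known concentration estimate the parameters: the intercepts of LE and HE
versus concentration give LE_base and HE_base; the slope of LE versus HE
gives the DER; the slope of corrected CM versus concentration gives α.
Averaging the three parameters per (material, tube voltage) across dose and
fat-ring configurations gives the *mean method* used for routine conversion:

    C = (CM_measured + (DER_avg·w + 1 − w) · Δ_base,avg / (DER_avg − 1)) / α_avg

The end-to-end concentration is provably independent of w when α is fitted
with the same w, so the unknown vendor weighting is harmless.

## Worked example

Generate a noiseless synthetic iodine study (12 configurations: 2 kV × 3
dose levels × with/without fat ring), calibrate it from the images, and
aggregate published per-configuration values into a per-kV summary:

```bash
spectralcal simulate --out study --seed 5 --material iodine --noiseless
spectralcal calibrate --study study --out calib
spectralcal aggregate --table published.csv --out agg   # per-config Δ_base/DER/α table
```

The aggregate report (mean ± sample SD over the 6 configurations per group):

```
material  kv   delta_base         der        alpha  n_configs   w
  iodine 120 -5.98 ± 1.32 2.10 ± 0.02 26.29 ± 0.11          6 0.5
  iodine 140 -5.74 ± 1.09 2.49 ± 0.02 26.58 ± 0.20          6 0.5
    iron 120 -4.21 ± 1.03 1.93 ± 0.02  4.06 ± 0.04          6 0.5
    iron 140 -4.10 ± 0.92 2.18 ± 0.03  4.32 ± 0.03          6 0.5
```

(`published.csv` here is the bundled example table,
`spectralcal.datasets.example_calibration_frame()`.) Quantifying the
synthetic rods with and without the Δ_base correction:

```bash
spectralcal aggregate --records calib/records.json --out agg2
spectralcal quantify --table calib/roi_table.csv --params agg2/params.json --out quant --digits 3
```

```
material  kv  ...  concentration_mg_ml  concentration_corrected  concentration_uncorrected  error_corrected_pct  error_uncorrected_pct
  iodine 120  ...                  0.5                      0.5                      0.863                  0.0                 72.589
  iodine 120  ...                  1.0                      1.0                      1.363                  0.0                 36.295
  iodine 120  ...                  2.0                      2.0                      2.363                  0.0                 18.147
  iodine 120  ...                  5.0                      5.0                      5.363                  0.0                  7.259
```

With a −5 HU base mismatch as the only bias source, the uncorrected estimate
carries a fixed +0.36 mg/mL offset — a 73 % relative error at 0.5 mg/mL,
shrinking as 1/C — while the corrected estimate is exact. The same pipeline
runs on real data: point `calibrate --table` at a CSV of ROI means exported
from the scanner console, or `calibrate --study` at NIfTI/DICOM image pairs.

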