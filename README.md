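# ctdose

Simulation toolkit for studying how far the radiation dose of retrospectively
gated cardiac CT can be reduced before left-ventricular ejection fraction
(LVEF) measurements degrade.

Measuring LVEF on CT would let oncology patients get cardiac function
monitoring from the same scan session as their routine chest CT, but a full
retrospectively gated acquisition costs ~20 mSv. `ctdose` emulates
tube-current reduction *in silico*: it transforms a reconstructed HU image
into parallel-beam sinogram space with the Radon transform, inserts Poisson
noise controlled by a photon-flux parameter `I0` (linear in dose), and
reconstructs with filtered backprojection (FBP). Lowering `I0` to a fraction
*d* of its full-dose value produces an image statistically equivalent to a
scan at relative dose *d*.

The package provides:

* **`ctdose.phantom`** — digital chest/heart phantoms: piecewise-constant HU
  ellipsoids (body, lungs, spine, myocardial shell, contrast-filled LV
  cavity at 450 HU, papillary-muscle inserts) with cosine cavity motion and
  exact analytic EDV/ESV/LVEF ground truth.
* **`ctdose.projection`** — the noise-simulation engine: `forward_project`,
  `insert_poisson_noise` (counts `N ~ Poisson(I0 e^{-p})`, floored at one
  photon, re-logged), `fbp_reconstruct` with five apodization windows
  (Ram-Lak, Shepp-Logan, Cosine, Hamming, Hann) and a frequency cutoff, and
  the `DoseSimulator` scikit-learn transformer composing them.
* **`ctdose.metrics`** — ROI statistics, myocardium-to-LV contrast-to-noise
  ratio `CNR = 2|HU(X)-HU(Y)|/(SD(X)+SD(Y))`, masked SSIM, trapezoidal
  `AUC_SSIM` over the dose axis, CNR regression, and the deviation norm
  `sqrt((1-|slope|_n)^2 + (1-R^2_n)^2 + (1-AUC_n)^2)` over min-max
  normalized metrics.
* **`ctdose.optimize`** — `SimulationGridSearch` (exhaustive deviation-norm
  minimization over flux x sampling interval x filter x cutoff against a
  13-level reference dose ladder) and `FluxCalibrator` (per-study photon
  flux matching the study's intrinsic noise, 200 log-spaced candidates over
  1e3..1e7).
* **`ctdose.volumetry`** — threshold-based LV segmentation in two modes:
  blood-volume (BV, papillary muscles excluded) and standard (ST, papillary
  muscles absorbed by morphological closing), time-volume curves, LVEF, and
  sliding-average output resampling.
* **`ctdose.analysis`** — the five-dose-level study pipeline (100, 25, 10,
  5, 2%), synthetic cohorts, Bland-Altman bias and 95% limits of agreement
  against the simulated 100% level, and dose-record arithmetic (effective
  dose = DLP x 0.026 mSv/mGycm for the chest).

## Worked example

```python
import ctdose as cd

# a 6-phase dynamic heart phantom with exactly 60% ejection fraction
series = cd.make_dynamic_series(target_lvef=60.0)
print(round(series.truth.edv_ml, 1), round(series.truth.esv_ml, 1))
# 134.8 53.9

# simulate the five dose levels and measure LVEF in both modes
table = cd.run_study_pipeline(series, seed=5)
print(table[table.dose_level == 1.0][["mode", "lvef_pct"]].round(2).to_string(index=False))
# mode  lvef_pct
#   bv     60.22
#   st     55.77
```

At simulated full dose the blood-volume measurement recovers the analytic
truth within a quarter of an EF point (60.22 vs 60.00); the standard-mode
value is lower because the papillary muscles (~8% of the cavity) count
toward the ventricular volume in both ED and ES phases. Collecting 20 such
phantoms with `cd.synthetic_cohort(...)` and passing the LVEF table to
`cd.agreement_report(...)` yields the Bland-Altman table per dose level: the
standard-mode bias grows monotonically as dose falls (about +2 EF points at
25% down to double digits at 2%) while the blood-volume limits of agreement
widen — the precision-versus-accuracy trade-off between the two measurement
modes.

A command-line interface mirrors the library:

```bash
ctdose phantom --matrix 192 --phases 6 --lvef 60 --out phantom.nii.gz
ctdose run --in phantom.nii.gz --flux 2e4 --seed 1 --out results/
# agreement analysis needs >= 3 studies; concatenate their lvef.csv tables
ctdose agree --in cohort_lvef.csv --out agreement.csv
```

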