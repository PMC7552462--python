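# glucospec

Chemometric calibration of **glucobrassicin (GBS)** — the indole
glucosinolate that is the dietary precursor of the chemopreventive
compound indole-3-carbinol — from **near-infrared reflectance spectra**
of freeze-dried cabbage and Brussels sprout leaf tissue.

Wet-chemistry GBS quantification (extraction, desulfation, HPLC) takes
days per batch; an NIR scan takes seconds. This package implements the
full calibration workflow a breeding or screening program needs to
replace the slow assay with a spectroscopic prediction, plus a synthetic
spectra generator so every stage is testable without instrument data.

## The method

Spectra are absorbance A = log₁₀(1/R) on a uniform 950–1650 nm grid at
5 nm (141 points); each sample is scanned twice and the replicate scans
averaged. The calibration chain is:

1. **Preprocessing** — four standard variants: raw; standard normal
   variate plus second-order polynomial detrend (SNV + DT); Savitzky–Golay
   first derivative; first derivative followed by SNV + DT.
2. **PLS1 regression (NIPALS)** — latent components tₐ = X wₐ extracted
   to maximize covariance with the GBS concentration, with predictors and
   response mean-centred and (by default) autoscaled. Implemented in-repo;
   verified in the test suite against an ordinary-least-squares oracle at
   full rank and against scikit-learn's PLS as an independent cross-check.
3. **Component selection** — leave-one-out cross-validation on the
   training partition; the number of components A is the smallest whose
   RMSECV is within one standard error of the minimum (one-sigma rule),
   with the 0-component mean model as a legal fallback.
4. **Evaluation** — a quantile-stratified random split holds out 24 of
   92 samples; the refitted model reports R²cal and RMSEC on the training
   set, R²CV and RMSEP on the held-out set, and
   **RPD = sd(reference values) / RMSEP**. RPD < 2 is not useful,
   2–3 supports qualitative screening, ≥ 3 supports quantification.

Models are fit on two response bases: µmol GBS·100 g⁻¹ fresh weight and
µmol GBS·g⁻¹ dry weight, linked by the dry-matter fraction
(gbs_dry = gbs_fresh / (100 · dm)).

The synthetic generator emulates the published study population:
n = 92 samples, fresh-weight GBS right-skewed (lognormal, mean 65.16,
sd 80.01, range 3.69–379.16 µmol·100 g⁻¹), spectra built from
Beer–Lambert Gaussian bands with a GBS band at 1450 nm deliberately
overlapped by water O–H bands, a quadratic baseline, per-scan
multiplicative scatter and channel noise. See `docs/methods.md`.

## Worked example

```python
from glucospec import ExperimentConfig, SyntheticConfig, classify_rpd, run_experiment
from glucospec.pipeline import metrics_frame

config = ExperimentConfig(synthetic=SyntheticConfig(seed=7), seed=7)
metrics = run_experiment(config)
print(metrics_frame(metrics).round(3).to_string(index=False))
best = max(metrics, key=lambda m: m.rpd)
print(f"\nbest model: {best.preprocessing} ({best.basis} basis), "
      f"RPD = {best.rpd:.2f} -> {classify_rpd(best.rpd)}")
```

prints

```
     preprocessing basis  r2_cal  rmsec  r2_cv  rmsep    rpd  terms
               raw fresh   0.999  2.385  0.990  7.015 10.914      6
               raw   dry   0.980  0.983  0.911  1.624  4.069      3
       snv_detrend fresh   0.981 10.721  0.986  8.424  9.088      4
       snv_detrend   dry   0.957  1.441  0.858  2.051  3.221      4
            deriv1 fresh   0.999  2.152  0.997  3.634 21.066      8
            deriv1   dry   0.980  0.979  0.888  1.822  3.627      4
deriv1_snv_detrend fresh   0.985  9.656  0.984  8.759  8.740      5
deriv1_snv_detrend   dry   0.951  1.525  0.855  2.078  3.180      4

best model: deriv1 (fresh basis), RPD = 21.07 -> quantification
```

Each row is one (preprocessing variant, concentration basis)
calibration: `r2_cal`/`rmsec` describe training fit, `r2_cv`/`rmsep` the
held-out 24-sample validation, `rpd` the screening quality, and `terms`
the PLS components chosen by the one-sigma rule. Synthetic spectra are
far cleaner than instrument data, so these R²/RPD values are upper
bounds on what field samples give — the workflow, not the numbers,
is what transfers.

The same experiment is available from the shell:

```bash
glucospec simulate --seed 7 --out-dir data/
glucospec experiment --config experiment.yaml --out metrics.csv
glucospec calibrate --spectra data/spectra.csv --reference data/reference.csv \
    --variant raw --basis fresh --seed 7 --out calibration.txt
glucospec report --config experiment.yaml --out-dir report/
```

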