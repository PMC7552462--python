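# Methods

## Data model

All spectra live on a shared `WavelengthGrid` — by default 950–1650 nm
at 5 nm, i.e. 141 points — and are stored as absorbance, A = log₁₀(1/R).
Base 10 is the spectroscopy convention for absorbance units; the
conversion `absorbance_from_reflectance` rejects R ≤ 0. Replicate scans
are averaged into one spectrum per sample *before* any preprocessing or
modelling, matching standard practice for diffuse-reflectance work where
repacking variation between scans is noise. The canonical file dialect
is a wide CSV (`sample_id` + numeric wavelength headers) written at full
float precision and parsed with round-trip float handling, so
write → read is bit-exact.

Reference chemistry carries GBS on two bases — µmol·100 g⁻¹ fresh weight
and µmol·g⁻¹ dry weight — plus the dry-matter fraction that links them,
gbs_dry = gbs_fresh / (100 · dm); the container validates this identity
to 0.1 % so inconsistent tables fail at load time.

## Preprocessing

* **SNV** standardizes each spectrum (row) to mean 0 and unit *sample*
  (n−1 denominator) standard deviation. A row whose sd is at rounding
  level (≤ 1e−12 relative to its mean magnitude) is rejected as a
  constant spectrum, naming the sample.
* **Detrend** subtracts a per-spectrum least-squares polynomial of the
  wavelength. Default order 2, the classical pairing with SNV for
  removing baseline curvature. The fit uses a standardized wavelength
  basis for conditioning; the residual is basis-invariant.
* **Derivatives** are Savitzky–Golay local-polynomial derivatives with
  respect to wavelength (per-nm units): default window 11 points
  (55 nm), polynomial order 2 for first derivatives, 3 for second.
  Edge points are computed from polynomial fits in truncated windows
  (`mode="interp"`), keeping the output on the full grid so loading
  vectors stay aligned with wavelengths; a `trim_edges` flag zeroes the
  half-window margins instead. The window is exposed because published
  NIR work rarely reports it and alternatives (e.g. gap-segment
  derivatives) can be emulated by varying it.
* The four standard variants (`STANDARD_VARIANTS`) are raw; SNV + DT;
  first derivative; first derivative → SNV → DT. Composition order in
  the combined variant is derivative first, then SNV, then detrend.

## PLS1 core

NIPALS for a single response, implemented directly (no inner iteration
is needed in the one-response case):
w = Xᵀy/‖Xᵀy‖, t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt, then deflation
X ← X − t pᵀ, y ← y − q t. Coefficients on the working scale are
b\* = W(PᵀW)⁻¹q, solved incrementally over the leading triangular blocks
so one decomposition yields the whole coefficient path over component
counts — the property the fast leave-one-out loop exploits. A zero
diagonal in PᵀW marks a fully deflated response (exact fit); the path is
frozen there rather than inverted.

"Autoscaling" (mean-centring plus unit-variance scaling of predictors
and response) is the default, with centre-only one flag away; which was
used is recorded in every log line because the two can select different
component counts. Coefficients and intercept are always returned on the
original measurement scale, and predictions from (coef, intercept) agree
with predictions reconstructed from (W, P, q) to numerical tolerance
(tested).

`ncomp = 0` is a legal model predicting the training mean, so component
selection can fall all the way back to the null model.

## Cross-validation and the one-sigma rule

`loo_cv` refits on every leave-one-out subset with centring/scaling
recomputed inside the fold (no information leak), evaluating all
candidate component counts 0…max_ncomp from one NIPALS pass per fold.
The returned `se` is the uncertainty of RMSECV itself: the standard
error of the mean per-sample squared error, propagated to the RMSE scale
by the delta method, se_rmse = se_mse / (2·rmse). The one-sigma rule
then selects the smallest component count with
rmsecv ≤ min(rmsecv) + se[argmin]; ties break toward fewer components.
Candidate max_ncomp defaults to 20, capped by training-set size.

## Evaluation protocol

Leave-one-out CV serves *component selection only*. Reported R²CV and
RMSEP come from a held-out test partition (24 of 92 by default), drawn
by quantile stratification on the response: samples are ranked, cut into
n_bins = 4 equal-size strata, and test samples allocated proportionally
(largest-remainder rounding) and drawn uniformly within strata from a
single seeded generator. Stratification matters because the response is
strongly right-skewed; a simple random split frequently leaves the upper
tail unrepresented (the test suite checks the mean Kolmogorov–Smirnov
train/test distance over 50 seeds does not exceed the unstratified
one). With proportional largest-remainder allocation a stratum can never
be asked for more samples than it holds; the allocation-error path is
retained defensively for alternative allocation schemes.

RPD divides the standard deviation of the reference values by RMSEP.
The sd defaults to the *full* sample set's sd rather than the test
subset's — that convention reproduces the published RPD values exactly
from their printed sd and RMSEP — and is switchable (`sd_source`)
because the convention differs between laboratories. Screening bands:
RPD < 2 not useful; [2, 3) qualitative screening (the conventional
2.0–2.5 screening band and the 2.5–3.0 gap are merged, boundaries closed
on the left); ≥ 3 quantification. This boundary choice is this package's
documented convention, not a claim about any particular author's intent.

## Synthetic data generator

The generator's defaults are the study conditions: 92 samples, 2
replicate scans each, on the 141-point grid.

* **Reference chemistry.** Fresh-weight GBS is lognormal, truncated by
  rejection to the observed range [3.69, 379.16] µmol·100 g⁻¹. The
  lognormal (µ, σ) are solved so that the *truncated* distribution has
  mean 65.16 and sd 80.01 — matching the parent's moments instead would
  bias the clipped sample low (clipping removes the heavy upper tail).
  The solve uses the closed-form lognormal partial moments and rejects
  infeasible mean/sd pairs. Dry-matter fraction is Normal(0.122, 0.02)
  truncated to (0.05, 0.30); 0.122 is implied by the two published mean
  concentrations (65.16/(100·5.33)), and 0.02 is a plausible placeholder
  for tissue-to-tissue variability, which is not published. A
  truncated-normal alternative for the concentrations sits behind
  `fresh_distribution`.
* **Spectra.** One scan is
  A(λ) = (1+m)·Σₖ cₖGₖ(λ) + baseline(λ) + ε(λ): Gaussian constituent
  bands Gₖ, per-scan multiplicative scatter m ~ N(0, scatter_sd) on the
  chemical signal, a fixed quadratic baseline, i.i.d. channel noise
  ε ~ N(0, noise_sd). Scatter multiplies the chemical signal and not the
  baseline so that SNV's benefit is attributable to the artifact it
  targets, while the additive baseline is the artifact detrending
  targets. The default band library places the GBS band at 1450 nm
  (σ = 25 nm, amplitude 8·10⁻⁴ per µmol·100 g⁻¹) deliberately overlapped
  by water O–H bands at 1420 and 1450 nm — real leaf-tissue spectra
  carry moisture bands across the indole N–H first-overtone region, so
  loading inspection has realistic ambiguity — plus two interfering
  constituents at 1200 and 1550 nm with random concentrations. Water
  concentration is nearly constant (N(1, 0.03)), as for a freeze-dried
  powder's residual moisture. Defaults scatter_sd = 0.05 and
  noise_sd = 0.002 AU represent a well-behaved instrument; both are
  exposed.
* All randomness derives from one seed through named `numpy` generator
  streams (CRC-tagged so stream separation is process-stable); fixture
  files are byte-identical across calls.

**What the generator does and does not emulate.** It reproduces the
sample size, replicate structure, grid, response distribution and the
qualitative artifact inventory (scatter, baseline, band overlap,
interferents). It does not simulate instrument response functions,
wavelength-dependent noise, particle-size-dependent effective path
length, or chemistry beyond four constituents — so synthetic R²/RPD
values are optimistic upper bounds, and passing recovery tests shows the
*workflow* is sound, not that any instrument will achieve those numbers
on cabbage.

**Stress setting.** The documented elevated-scatter setting for
demonstrating SNV's benefit is scatter_sd = 0.30, noise_sd = 0, flat
baseline. A single simulation's LOO-CV comparison is noisy at n = 92, so
the documented comparison aggregates mean LOO RMSECV over five replicate
simulations, where SNV + detrend clearly beats raw.

## Numerical choices and degenerate inputs

* SNV degenerate (constant) rows: relative 1e−12 sd floor, error names
  the sample.
* Zero-variance predictor columns are rejected when scaling is on
  (division by zero), reported by column index.
* `rmsecv = 0` folds give `se = 0` (delta method guarded).
* Grid uniformity tolerance: 1e−9 relative on header spacing.
* CSVs are written at %.17g and read with round-trip float parsing, so
  file-based and in-memory runs agree exactly.

## Known limitations

* Published derivative rows are only qualitatively comparable even with
  the original data, since the original derivative window/gap parameters
  are unreported.
* Whether the published models autoscaled or only centred is ambiguous;
  both run here, neither is asserted as the original behaviour.
* The serialized calibration stores (coefficients, centres, scales,
  intercept), sufficient for bit-exact prediction, but not the W/P/q
  decomposition — reloaded models cannot produce loading plots.
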