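# Methods

`podnirs` implements the calibration workflow used in VIS/NIR
spectroscopy of plant and food quality: a spectra matrix of apparent
absorbance log10(1/R) on a 400–2500 nm grid at 2 nm steps (1050 points)
is related to per-sample laboratory reference values by modified partial
least squares after scatter correction, derivative pretreatment and
outlier elimination, and the resulting equations are graded with the
RPD/RER/R² statistics. This note records the model, the numerical
choices, and what the synthetic data do and do not demonstrate.

## Preprocessing

**SNV + detrend ("SNV-DT").** Each spectrum is standardized to mean 0,
SD 1 (n−1 denominator), then the least-squares quadratic in wavelength
is subtracted. SNV removes multiplicative scatter exactly (it is
invariant under `a·x + b`, a > 0); detrend removes the offset/slope/
curvature baseline produced by particle-size differences. The order —
SNV first, detrend second — follows the Barnes convention; the reverse
order differs only through second-order interaction of the two
corrections, which the property suite bounds (residual → 0 as the
injected artifact amplitude → 0). The quadratic fit uses a Legendre
basis on a mapped [−1, 1] axis purely for conditioning; fitted values
equal the monomial fit.

**Gap–segment derivatives.** The four-integer code `d,g,s1,s2` (all in
data points) means: boxcar (segment-mean) smoothing of width `s1`, then
`s2`, then `d` successive gap differences `x[i+g] − x[i]`. Smoothing is
a plain segment mean — the "segment" of these codes names a boxcar, not
a Savitzky–Golay polynomial. Edges are trimmed rather than padded, so
every output value is computed from measured data; the output grid keeps
the 2 nm step and shifts its start to the composite window midpoint
(fractional shifts are allowed). A treatment consumes
`(s1−1) + (s2−1) + d·g` points: `2,5,5,2` maps 1050 points to 1035 on
415–2483 nm.

## Outlier screening

**GH (spectral).** `GH_i = (1/k) Σ_j (t_ij / s_j)²` — the squared
Mahalanobis distance from the population mean in the retained
principal-component space, standardized by the in-sample score SDs and
divided by the component count `k`. The in-sample mean is `(n−1)/n ≈ 1`,
which is the scale on which the conventional `H > 3` limit operates. `k`
is chosen by a 99% explained-variance rule and the PCA is refitted after
every elimination pass, since removals change the covariance.

**T (chemistry).** During cross-validation, samples with
`|y − ŷ| / SECV > 2.5` are flagged, with SECV the current
cross-validation error. The protocol performs at most two elimination
passes (each pass re-runs the whole cross-validation and the PCA) and
then stops, even if further samples would be flagged — the two-pass
limit is part of the protocol, not a convergence criterion. Elimination
also stops if it would leave fewer than twice the segment count.

## Modified PLS

PLS1 factors are extracted by NIPALS: weight ∝ covariance of the X
residual with the y residual, scores, loadings, deflation. The
"modified" step standardizes every wavelength's residual column by its
SD after each deflation (optionally also the y residual, behind a flag;
default X-only), so later factors see all wavelengths on a common
residual scale. Prediction replays the same sequence on a new centered
spectrum, making the map affine in the input. With scaling off the
procedure is *exactly* NIPALS PLS1; the test suite asserts equality with
an independent PLS1 implementation to 1e-8 over random instances, which
anchors the shared machinery. Near-zero residual SDs are replaced by 1
before division; factor extraction stops early when the y residual is
exhausted (noiseless low-rank data), truncating the factor count.

**Cross-validation.** Samples are ordered by their first PC score and
dealt round-robin into 6 segments, so each segment spans the spectral
variability (114 samples → six segments of 19). SECV per factor count is
the bias-corrected standard error of the pooled held-out residuals. The
optimal factor count is the smallest whose SECV is within ε = 2% of the
minimum — a parsimony rule standing in for the unpublished rule of the
commercial package this emulates. ε, the T/H limits and the pass count
are all configurable.

## Evaluation statistics

SD uses n−1. SEC uses n−p−1 degrees of freedom with p the factor count;
SECV and SEP use the bias-corrected n−1 form. The published formulas
divide by `N−K−1` with K "the number of wavelengths", which is unusable
for full-spectrum regression (K ≥ N); the conventions above reproduce
the arithmetic of the published summary tables (SD/SECV and range/SEP
ratios match the printed RPD/RER at 2-decimal rounding), so they are
what those tables actually used. R² is the ratio of the sum of squares
of predictions about the reference mean to the total sum of squares —
the printed convention; for an OLS fit it equals the squared Pearson
correlation, but on external-validation predictions it can slightly
exceed 1. Report rounding is 2 decimals, round-half-even; raw values are
kept alongside.

Quality bands: R² <0.26 / 0.26–0.49 / 0.50–0.64 / 0.65–0.81 / 0.82–0.90
/ >0.90 (very low … excellent); RPD <1.5 unsuitable, 1.5–2.5 screening,
2.5–3 very good, >3 excellent; RER <4 unsuitable, 4–8 discriminates
high/low, ≥8 quantitative. The combined label is the most conservative
of the three on a shared ordinal scale.

## Validation-set selection

Samples are ordered by ascending GH distance (ties broken by id) — a
reduction of the proprietary CENTER ordering to the same statistic used
for outlier screening — and roughly one in five is set aside for
external validation at evenly spaced positions over the interior of the
ordering. When k divides n exactly n/k samples are taken; otherwise two
extra picks extend the selection to both tails, while the two endpoint
samples (most central, most extreme) always stay in calibration. For the
144-sample design with k = 5 this yields the 30/114 validation/
calibration split of the study protocol; a strict integer stride of 5
cannot produce 30 from 144, so the even-spacing rule is this package's
reading of "approximately 1 of every 5".

## Synthetic data

The generator emulates the study conditions: 144 samples (8 cultivars ×
2 fertigation levels × 9), six replicate scans per sample, eight traits
with the published means/SDs/ranges, and Beer–Lambert linear mixing.
Trait values are truncated Gaussians with a cultivar (30% of variance)
and treatment (4%) group structure; columns are standardized and
re-colored so the empirical mean, SD and cross-trait correlation match
their targets by construction (default correlation: a mild 0.3 block
among protein, polyphenols and ascorbate). Each spectrally active trait
contributes Gaussian bands (widths 10–40 nm) at its assigned
wavelengths — chlorophyll 444/546/670 nm for the color parameters,
protein 1512/2056/2174 nm, cellulose 1436/2270 nm for firmness,
carbohydrate O-H 1210 nm for soluble solids, phenolic windows
1460/1700/1995 nm for total polyphenols — as
`amplitude · (1 + 0.3·z) · signature(λ)` on a shared broad baseline with
water/O-H bands at 1450/1940 nm. Scatter artifacts (per-sample gain
SD 0.08, offset SD 0.05, slope/curvature SDs 0.03/0.02 on a normalized
wavelength axis) are shared by a sample's replicates; i.i.d. additive
noise (SD 5e-4 absorbance per replicate scan, 2e-4 per sample) is not.
Replicates therefore model detector noise only, not cup repacking.

Band amplitudes were set once from signal-to-noise reasoning to realize
the qualitative regime of real pod data: protein is the strongest
constituent (amplitude 0.08 at mean concentration) and pH is only
weakly coupled (0.0012, on the order of the noise), so pH calibrations
are expected to fail — mirroring the ordering observed on real pods,
where protein calibrates best and pH worst.

**What the synthetic results do and do not show.** Real reference
chemistry carries laboratory measurement error, which bounds the
achievable SECV; the generator omits it, so on synthetic data the
well-coupled traits reach R² ≈ 0.98–0.99 and RPD ≈ 15–20 — far beyond
what real pod spectra support (RPD ≈ 1.5–3.5). Passing tests therefore
demonstrate that the pipeline recovers linear spectral chemistry,
ranks traits by their spectral coupling, and does not manufacture
predictivity from noise (null-signal RPD ≈ 1); they do not certify
accuracy levels on real material. Real bands are also broader and
asymmetric, and scatter is wavelength-dependent; the Gaussian/quadratic
approximations are the simplest structure the preprocessing is designed
to remove.

## Problem sizes and determinism

Default runs use the full 144 × 1050 design (about six seconds end to
end for all eight traits); unit tests use 48–96 samples on the full
grid or compact 50–200-point grids. All randomness flows through
`numpy.random.default_rng` seeds; segment assignment and the validation
split are deterministic given the data, and a rerun with the same
config and seed produces byte-identical reports.

## Known limitations

- The "modified" scaling step follows the public description of the
  Shenk–Westerhaus algorithm; the commercial implementation's exact
  deflation and factor-selection rules are proprietary, so equivalence
  is asserted in the unscaled PLS1 limit, not against its outputs.
- Whether detrend precedes or follows SNV in that software is likewise
  unpublished; the Barnes order is used.
- No wavelength resampling: spectra must share the model's grid.
- PLS2, variable selection, MSC/OSC and robust PCA are out of scope.
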