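# podnirs

VIS/NIR chemometric calibration for pod quality traits.

Breeders and food technologists use visible/near-infrared reflectance
spectroscopy to replace slow, destructive laboratory assays: a single
2-minute scan of a freeze-dried, ground pod sample predicts color
(C\*, h\*), firmness, total soluble solids, pH, protein, ascorbic acid
and total polyphenol content at once. `podnirs` implements the full
calibration workflow behind such predictions, plus a synthetic spectra
generator so the whole pipeline runs and is testable without instrument
data.

## What it implements

Working on apparent absorbance log10(1/R) over 400–2500 nm at 2 nm
steps (1050 points):

- **Scatter correction** — standard normal variate + quadratic detrend
  (SNV-DT), removing particle-size gain and baseline artifacts.
- **Math treatments** — WinISI-style four-integer codes `d,g,s1,s2`
  (derivative order, gap, two smoothing segment widths), e.g.
  `1,4,4,1` or `2,5,5,2`, implemented as boxcar smoothing plus gap
  differences with edge trimming.
- **Outlier screening** — standardized Mahalanobis distance in PC space
  (GH > 3) for spectral outliers and standardized cross-validation
  residuals (T > 2.5) for chemistry outliers, with the two-pass
  elimination protocol.
- **Modified partial least squares (MPLS)** — PLS1 with per-wavelength
  standardization of the spectral residuals after each factor
  (Shenk–Westerhaus); reduces exactly to NIPALS PLS1 with scaling off.
  Factor count chosen by six-segment cross-validation.
- **Validation design** — CENTER-style spectral ordering and a 1-in-5
  external validation split (144 samples → 114 calibration + 30
  validation).
- **Evaluation** — SEC, SECV, bias-corrected SEP, R², and the
  dimensionless ratios

  RPD = SD / SE  RER = range / SE

  with the standard interpretation bands (RPD > 3 excellent, < 1.5
  unsuitable; RER 4–8 discriminates high/low, 8–12 quantitative).
- **Synthetic study generator** — 144 samples × 6 replicate scans of
  Beer–Lambert mixtures: eight traits with realistic means/SDs/ranges,
  absorption bands at their assigned wavelengths (protein at
  1512/2056/2174 nm, chlorophyll at 670 nm, cellulose at 1436/2270 nm,
  …), particle-size scatter artifacts and detector noise.

See `docs/methods.md` for the model details and numerical conventions.

## Worked example

```python
from podnirs import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=1))   # synthetic 144-sample study
print(result.report.to_text())
```

prints (abridged):

```
   trait      treatment  n_factors    sd  sec  r2_cv  secv  rpd_cv  r2_val  rpd_p   rer quality_band
  chroma 1,4,4,1 snv_dt          5  5.31 0.23   0.99  0.27   19.91    1.08  15.15 46.24 quantitative
      ph 1,4,4,1 snv_dt          1  0.26 0.26   0.04  0.27    0.98    0.29   0.94  3.17   unsuitable
 protein 1,4,4,1 snv_dt          5  2.92 0.14   0.99  0.16   18.33    1.05  16.00 61.16 quantitative
     tpc 1,4,4,1 snv_dt          6 99.34 4.49   0.98  5.69   17.47    1.00  14.96 57.36 quantitative
```

Each row is one trait's calibration: the winning math treatment, the
factor count chosen by cross-validation, the standard errors
(SEC/SECV/SEP in the trait's units), and the R²/RPD/RER grades. On this
noise-only synthetic chemistry the spectrally active traits calibrate
near-perfectly (RPD ≫ 3, "quantitative"), while pH — deliberately
generated with almost no spectral signature — is "unsuitable"
(RPD ≈ 1): the pipeline finds exactly the chemistry that is in the
spectra, and nothing when there is none.

The scripts in `examples/` walk through each stage (generation,
preprocessing, outlier screening, cross-validation, full pipeline). A
thin CLI wraps the same functions:

```sh
podnirs generate --n 144 --replicates 6 --seed 1 --outdir synthetic
podnirs calibrate config.yaml --outdir run1
podnirs predict run1/model_protein.json synthetic/spectra.csv
```

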