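"""Synthetic pod spectra and reference chemistry.

The generator emulates the statistical structure the calibration pipeline
assumes, so every stage is testable without instrument data:

* 144 samples from a 8-cultivar x 2-fertigation-treatment x 9 design,
  with six replicate scans per sample that share chemistry and baseline
  and differ only by detector noise;
* eight quality traits (color C* and h*, firmness, total soluble solids,
  pH, protein, ascorbic acid, total polyphenols) drawn as truncated
  Gaussians around published-style means/SDs, clipped to their observed
  ranges, with cultivar and treatment group shifts and a mild positive
  protein-polyphenol-ascorbate correlation block;
* Beer-Lambert linear mixing: each spectrally active trait contributes
  Gaussian absorption bands at its assigned wavelengths (chlorophyll at
  444/546/670 nm for the color parameters, protein N-H/amide bands at
  1512/2056/2174 nm, cellulose at 1436/2270 nm for firmness,
  carbohydrate O-H at 1210 nm for soluble solids, phenolic bands in the
  1415-1512 / 1650-1750 / 1955-2035 nm windows for polyphenols), on top
  of a shared broad baseline with O-H bands at 1450/1940 nm;
* particle-size scatter artifacts — per-sample multiplicative gain and a
  quadratic additive baseline — which SNV + detrend is designed to
  remove, plus i.i.d. additive noise per replicate.

pH is only weakly coupled to the spectrum by design, so its calibration
is expected to be the weakest — the generator reproduces the qualitative
trait ordering of real pod data, not its absolute accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import ReferenceTable, SpectralSet, WavelengthGrid

__all__ = [
    "ConstituentSpec",
    "NoiseSpec",
    "default_constituents",
    "default_correlation",
    "generate_reference",
    "generate_spectra",
    "generate_dataset",
    "TRAIT_UNITS",
]

TRAIT_UNITS = {
    "chroma": "C*",
    "hue": "h*",
    "firmness": "N",
    "tss": "Brix",
    "ph": "pH",
    "protein": "g/100 g dw",
    "aac": "mg/100 g fw",
    "tpc": "mg GAE/kg fw",
}


@dataclass(frozen=True)
class ConstituentSpec:
    """Distributional and spectral parameters of one quality trait."""

    name: str
    target_mean: float
    target_sd: float
    target_range: tuple[float, float]
    band_centers_nm: tuple[float, ...] = ()
    band_widths_nm: tuple[float, ...] = ()
    band_weights: tuple[float, ...] = ()
    #: band amplitude (absorbance units) at the mean concentration
    amplitude: float = 0.0
    #: relative modulation of the band by the standardized trait value
    modulation: float = 0.3

    def __post_init__(self) -> None:
        if not (len(self.band_centers_nm) == len(self.band_widths_nm)
                == len(self.band_weights)):
            raise ValueError(f"{self.name}: band lists must have equal length")
        if any(w <= 0 for w in self.band_widths_nm):
            raise ValueError(f"{self.name}: band widths must be > 0")
        lo, hi = self.target_range
        if not lo < hi:
            raise ValueError(f"{self.name}: empty target range")

    @property
    def spectrally_active(self) -> bool:
        return self.amplitude > 0 and len(self.band_centers_nm) > 0

    def signature(self, wavelengths: np.ndarray) -> np.ndarray:
        """Unit-peak sum of Gaussian bands on the given wavelength grid."""
        s = np.zeros_like(wavelengths, dtype=float)
        for c, w, a in zip(self.band_centers_nm, self.band_widths_nm,
                           self.band_weights):
            s += a * np.exp(-0.5 * ((wavelengths - c) / w) ** 2)
        peak = np.max(np.abs(s))
        return s / peak if peak > 0 else s


@dataclass(frozen=True)
class NoiseSpec:
    """Amplitudes of the instrumental/scatter artifacts, absorbance units."""

    additive_sd: float = 2e-4          # i.i.d. detector noise per point
    multiplicative_scatter_sd: float = 0.08   # per-sample gain spread
    baseline_offset_sd: float = 0.05
    baseline_slope_sd: float = 0.03    # per unit of normalized wavelength
    baseline_curvature_sd: float = 0.02
    replicate_noise_sd: float = 5e-4   # extra i.i.d. noise per replicate scan

    def __post_init__(self) -> None:
        for f in ("additive_sd", "multiplicative_scatter_sd",
                  "baseline_offset_sd", "baseline_slope_sd",
                  "baseline_curvature_sd", "replicate_noise_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    def scaled(self, factor: float) -> "NoiseSpec":
        return NoiseSpec(*(getattr(self, f) * factor for f in
                           ("additive_sd", "multiplicative_scatter_sd",
                            "baseline_offset_sd", "baseline_slope_sd",
                            "baseline_curvature_sd", "replicate_noise_sd")))


def default_constituents() -> list[ConstituentSpec]:
    """The eight pod quality traits with their published-style statistics
    and assigned absorption bands."""
    return [
        ConstituentSpec("chroma", 27.87, 6.15, (15.20, 35.58),
                        (444.0, 670.0), (18.0, 24.0), (0.5, 1.0),
                        amplitude=0.10),
        ConstituentSpec("hue", 109.46, 1.49, (105.13, 112.91),
                        (546.0, 670.0), (20.0, 24.0), (1.0, 0.6),
                        amplitude=0.06),
        ConstituentSpec("firmness", 43.62, 12.74, (20.59, 67.52),
                        (1436.0, 2270.0, 1932.0), (30.0, 28.0, 26.0),
                        (1.0, 0.9, 0.4), amplitude=0.06),
        ConstituentSpec("tss", 7.53, 0.65, (6.08, 8.85),
                        (1210.0, 1990.0), (24.0, 30.0), (1.0, 0.5),
                        amplitude=0.05),
        ConstituentSpec("ph", 6.80, 0.27, (5.99, 7.28),
                        (1412.0,), (30.0,), (1.0,),
                        amplitude=0.0012),
        ConstituentSpec("protein", 23.48, 3.02, (11.50, 29.75),
                        (1512.0, 2056.0, 2174.0), (26.0, 28.0, 26.0),
                        (1.0, 0.9, 0.8), amplitude=0.08),
        ConstituentSpec("aac", 43.82, 10.82, (19.75, 68.86),
                        (1128.0, 1726.0), (24.0, 24.0), (1.0, 0.5),
                        amplitude=0.035),
        ConstituentSpec("tpc", 389.09, 111.52, (202.30, 685.05),
                        (1460.0, 1700.0, 1995.0), (30.0, 32.0, 30.0),
                        (1.0, 0.7, 0.6), amplitude=0.06),
    ]


def default_correlation(names: list[str]) -> np.ndarray:
    """Mild positive correlation block among protein, polyphenols and
    ascorbate (shared biochemistry); other traits independent."""
    r = np.eye(len(names))
    block = [n for n in ("protein", "tpc", "aac") if n in names]
    for a in block:
        for b in block:
            if a != b:
                r[names.index(a), names.index(b)] = 0.3
    return r


# ---------------------------------------------------------------------------
# Reference chemistry
# ---------------------------------------------------------------------------

def generate_reference(
    n: int = 144,
    specs: list[ConstituentSpec] | None = None,
    correlation: np.ndarray | None = None,
    seed: int | None = None,
    n_cultivars: int = 8,
    n_treatments: int = 2,
) -> ReferenceTable:
    """Draw per-sample laboratory values for all traits.

    Trait values are truncated Gaussians around the target mean/SD,
    clipped to the target range, composed of a cultivar shift, a smaller
    fertigation-treatment shift and a correlated residual. Deterministic
    under ``seed``.
    """
    specs = specs or default_constituents()
    names = [s.name for s in specs]
    corr = default_correlation(names) if correlation is None else np.asarray(correlation)
    if corr.shape != (len(names), len(names)):
        raise ValueError("correlation matrix shape does not match traits")
    eig = np.linalg.eigvalsh((corr + corr.T) / 2)
    if eig.min() < -1e-10:
        raise ValueError("correlation matrix is not positive semi-definite")
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(names)))

    rng = np.random.default_rng(seed)
    cultivar = np.arange(n) % n_cultivars
    treatment = (np.arange(n) // n_cultivars) % n_treatments
    # variance split: cultivar 30%, treatment 4%, residual 66%
    cult_eff = rng.standard_normal((n_cultivars, len(names))) * np.sqrt(0.30)
    treat_eff = rng.standard_normal((n_treatments, len(names))) * np.sqrt(0.04)
    resid = rng.standard_normal((n, len(names))) * np.sqrt(0.66)
    z = cult_eff[cultivar] + treat_eff[treatment] + resid
    # match the published moments by construction: standardize each trait
    # column, then re-color so the empirical correlation equals the target
    z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=1)
    if len(names) > 1 and n > len(names):
        emp = np.linalg.cholesky(np.corrcoef(z, rowvar=False)
                                 + 1e-10 * np.eye(len(names)))
        z = z @ np.linalg.inv(emp).T @ chol.T
        z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=1)

    values = {}
    for j, s in enumerate(specs):
        v = s.target_mean + s.target_sd * z[:, j]
        values[s.name] = np.clip(v, *s.target_range)
    ids = [f"S{i + 1:03d}" for i in range(n)]
    df = pd.DataFrame(values, index=pd.Index(ids, name="sample_id"))
    df["cultivar"] = [f"cv{c + 1}" for c in cultivar]
    df["treatment"] = [f"T{50 * (t + 1)}" for t in treatment]
    labels = df[["cultivar", "treatment"]]
    table = ReferenceTable(df[names].copy(),
                           {n_: TRAIT_UNITS.get(n_, "") for n_ in names})
    table.labels = labels  # carried for the spectra generator
    return table


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def _baseline(wavelengths: np.ndarray) -> np.ndarray:
    """Shared broad log(1/R) baseline with O-H bands at 1450 and 1940 nm."""
    u = (wavelengths - 400.0) / 2100.0
    base = 0.35 + 0.55 * u + 0.15 * u ** 2
    for c, w, a in ((1450.0, 55.0, 0.25), (1940.0, 60.0, 0.35),
                    (2300.0, 80.0, 0.12)):
        base += a * np.exp(-0.5 * ((wavelengths - c) / w) ** 2)
    return base


def generate_spectra(
    refs: ReferenceTable,
    specs: list[ConstituentSpec] | None = None,
    noise: NoiseSpec | None = None,
    replicates: int = 6,
    grid: WavelengthGrid | None = None,
    seed: int | None = None,
) -> SpectralSet:
    """Build replicate-level absorbance spectra from reference chemistry.

    Each sample's clean spectrum is the shared baseline plus one
    Beer-Lambert term per spectrally active trait,
    ``amplitude * (1 + modulation * z) * signature(lambda)`` with z the
    standardized trait value. Scatter (gain + quadratic baseline) is
    per-sample and shared by its replicates; additive noise is drawn per
    replicate scan.
    """
    specs = specs or default_constituents()
    noise = noise or NoiseSpec()
    grid = grid or WavelengthGrid.default()
    rng = np.random.default_rng(seed)
    wl = grid.wavelengths
    u = (wl - wl.mean()) / (0.5 * (wl[-1] - wl[0]))  # in [-1, 1]

    ids = refs.sample_ids
    n = len(ids)
    clean = np.tile(_baseline(wl), (n, 1))
    for s in specs:
        if not s.spectrally_active:
            continue
        if s.name not in refs.traits:
            raise ValueError(f"reference table lacks active trait {s.name!r}")
        v = refs.values[s.name].to_numpy(dtype=float)
        z = (v - s.target_mean) / s.target_sd
        conc = 1.0 + s.modulation * np.clip(z, -3.0, 3.0)
        clean += s.amplitude * np.outer(conc, s.signature(wl))

    gain = 1.0 + noise.multiplicative_scatter_sd * rng.standard_normal(n)
    gain = np.clip(gain, 0.5, None)
    offs = noise.baseline_offset_sd * rng.standard_normal(n)
    slope = noise.baseline_slope_sd * rng.standard_normal(n)
    curv = noise.baseline_curvature_sd * rng.standard_normal(n)
    sample_spec = (gain[:, None] * clean
                   + offs[:, None] + np.outer(slope, u) + np.outer(curv, u ** 2)
                   + noise.additive_sd * rng.standard_normal((n, wl.size)))

    rows, out_ids, lab_rows = [], [], []
    labels = getattr(refs, "labels", None)
    for i, sid in enumerate(ids):
        for r in range(replicates):
            rows.append(sample_spec[i]
                        + noise.replicate_noise_sd * rng.standard_normal(wl.size))
            out_ids.append(f"{sid}:{r + 1}" if replicates > 1 else sid)
            row = {"sample": sid, "replicate": r + 1}
            if labels is not None:
                row.update(labels.loc[sid].to_dict())
            lab_rows.append(row)
    label_df = pd.DataFrame(lab_rows, index=pd.Index(out_ids, name="sample_id"))
    return SpectralSet(grid, np.array(rows), out_ids, label_df)


def generate_dataset(
    n: int = 144,
    replicates: int = 6,
    specs: list[ConstituentSpec] | None = None,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
) -> tuple[SpectralSet, ReferenceTable]:
    """Convenience wrapper: reference chemistry + replicate spectra with
    independent sub-seeds derived from ``seed``."""
    ss = np.random.SeedSequence(seed).spawn(2)
    refs = generate_reference(n, specs=specs,
                              seed=int(ss[0].generate_state(1)[0] % (2**31)))
    spectra = generate_spectra(refs, specs=specs, noise=noise,
                               replicates=replicates,
                               seed=int(ss[1].generate_state(1)[0] % (2**31)))
    return spectra, refs
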