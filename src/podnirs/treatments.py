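"""Scatter correction and derivative math treatments.

A pretreatment is written as the four-integer WinISI-style code
``"d,g,s1,s2"`` — derivative order, gap, first and second smoothing segment
widths, all in data points — optionally followed by a scatter tag, e.g.
``"2,5,5,2 snv_dt"``. The pipeline applies, per spectrum:

1. SNV (standard normal variate): subtract the spectrum mean, divide by
   its standard deviation — removes multiplicative scatter (gain).
2. Detrend: subtract the least-squares quadratic in wavelength — removes
   baseline offset and curvature caused by particle-size dispersion.
3. Gap-segment derivative: two boxcar (segment-mean) smoothing passes of
   widths s1 and s2, then ``d`` successive gap differences
   ``x[i+g] - x[i]``. Edge positions whose windows are incomplete are
   trimmed, so every output value is computed from real data; the output
   grid is shifted to window midpoints.

The SNV-then-detrend order follows the Barnes et al. convention for
"SNV-DT". Smoothing is a plain segment mean, not Savitzky-Golay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import SpectralSet, WavelengthGrid

__all__ = [
    "MathTreatment",
    "parse_math_treatment",
    "snv",
    "detrend",
    "gap_segment_derivative",
    "apply_treatment",
]

SCATTER_MODES = ("none", "snv_dt")


@dataclass(frozen=True)
class MathTreatment:
    """Four-integer derivative code plus scatter-correction flag."""

    derivative_order: int = 0
    gap: int = 1
    smooth1: int = 1
    smooth2: int = 1
    scatter: str = "none"

    def __post_init__(self) -> None:
        if self.derivative_order < 0:
            raise ValueError("derivative order must be >= 0")
        if min(self.gap, self.smooth1, self.smooth2) < 1:
            raise ValueError("gap and smoothing widths must be >= 1")
        if self.scatter not in SCATTER_MODES:
            raise ValueError(f"scatter must be one of {SCATTER_MODES}")

    @property
    def code(self) -> str:
        c = f"{self.derivative_order},{self.gap},{self.smooth1},{self.smooth2}"
        return c if self.scatter == "none" else f"{c} {self.scatter}"

    @property
    def is_identity(self) -> bool:
        return (self.derivative_order == 0 and self.smooth1 == 1
                and self.smooth2 == 1 and self.scatter == "none")

    #: points consumed from the spectrum by the composite window
    @property
    def window_loss(self) -> int:
        return (self.smooth1 - 1) + (self.smooth2 - 1) + self.derivative_order * self.gap


def parse_math_treatment(code: str) -> MathTreatment:
    """Parse ``"d,g,s1,s2[ scatter]"`` into a :class:`MathTreatment`.

    A gap or width of 0 in the code is normalized to 1 (WinISI writes
    "0,0,1,1" for the identity).
    """
    parts = code.strip().split()
    if not parts or len(parts) > 2:
        raise ValueError(f"cannot parse treatment code {code!r}")
    scatter = parts[1] if len(parts) == 2 else "none"
    fields = parts[0].split(",")
    if len(fields) != 4:
        raise ValueError(
            f"treatment code needs four comma-separated integers, got {parts[0]!r}"
        )
    try:
        d, g, s1, s2 = (int(f) for f in fields)
    except ValueError:
        raise ValueError(f"non-integer value in treatment code {parts[0]!r}")
    if min(d, g, s1, s2) < 0:
        raise ValueError(f"negative value in treatment code {parts[0]!r}")
    return MathTreatment(d, max(g, 1), max(s1, 1), max(s2, 1), scatter)


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum standardization to mean 0, SD 1.

    Uses the n-1 denominator. Invariant under affine rescaling
    ``a*x + b`` (a > 0), which is what makes it a scatter correction.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("snv needs a 1-D spectrum of length >= 2")
    sd = x.std(ddof=1)
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("constant spectrum: SNV undefined")
    return (x - x.mean()) / sd


def detrend(spectrum: np.ndarray, grid: WavelengthGrid, degree: int = 2) -> np.ndarray:
    """Subtract the least-squares polynomial of wavelength of given degree.

    The residual is orthogonal (ordinary least squares on the grid) to all
    polynomials of degree <= ``degree``; in particular any exact polynomial
    baseline of that degree maps to zero.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.size != grid.n_points:
        raise ValueError("spectrum length does not match grid")
    if degree >= x.size:
        raise ValueError("polynomial degree must be < spectrum length")
    # Legendre basis on [-1, 1] for conditioning; fitted values are
    # identical to a monomial fit of the same degree.
    u = np.linspace(-1.0, 1.0, x.size)
    fit = np.polynomial.legendre.Legendre.fit(u, x, degree)
    return x - fit(u)


def _boxcar(x: np.ndarray, width: int) -> np.ndarray:
    """Segment-mean smoothing, valid mode (output length n - width + 1)."""
    if width == 1:
        return x
    if width > x.size:
        raise ValueError("smoothing segment wider than spectrum")
    c = np.concatenate(([0.0], np.cumsum(x)))
    return (c[width:] - c[:-width]) / width


def gap_segment_derivative(spectrum: np.ndarray, t: MathTreatment) -> np.ndarray:
    """Apply the segment smoothing + gap differences of a math treatment.

    Output length is ``n - (s1-1) - (s2-1) - d*g``; callers track the grid
    shift via :func:`treated_grid`.
    """
    x = np.asarray(spectrum, dtype=float)
    if t.window_loss >= x.size:
        raise ValueError(
            f"treatment window ({t.window_loss + 1} points) exceeds "
            f"spectrum length {x.size}"
        )
    y = _boxcar(_boxcar(x, t.smooth1), t.smooth2)
    for _ in range(t.derivative_order):
        y = y[t.gap:] - y[:-t.gap]
    return y


def treated_grid(grid: WavelengthGrid, t: MathTreatment) -> WavelengthGrid:
    """Grid of a treated spectrum: trimmed edges, points at window midpoints."""
    half = t.window_loss / 2.0
    return grid.trimmed(half, half)


def apply_treatment(spectra: SpectralSet, t: MathTreatment) -> SpectralSet:
    """Apply scatter correction then derivative math to every spectrum."""
    if t.is_identity:
        return spectra
    mat = spectra.absorbance
    if t.scatter == "snv_dt":
        mat = np.stack([detrend(snv(row), spectra.grid) for row in mat])
    if t.derivative_order > 0 or t.smooth1 > 1 or t.smooth2 > 1:
        mat = np.stack([gap_segment_derivative(row, t) for row in mat])
        grid = treated_grid(spectra.grid, t)
    else:
        grid = spectra.grid
    return SpectralSet(grid, mat, list(spectra.sample_ids), spectra.labels.copy())
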