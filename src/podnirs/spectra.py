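"""Spectral data model and I/O.

The working unit throughout the package is apparent absorbance, log10(1/R),
where R is diffuse reflectance. Spectra live on a shared arithmetic
wavelength grid; the instrument convention emulated here is a 400-2500 nm
scan at 2 nm intervals (1050 points), covering the visible and
near-infrared regions.

On-disk dialects:

* wide CSV (canonical): first column ``sample_id``, optional label columns
  (``sample``, ``cultivar``, ``treatment``, ``replicate``), remaining
  headers wavelengths in nm, "." decimal separator.
* a minimal JCAMP-DX-like per-spectrum text format (``##TITLE=`` header,
  one "wavelength,absorbance" pair per line) read from a directory;
  lossy-tolerant, for interoperability only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "SpectralSet",
    "ReferenceTable",
    "read_spectra",
    "write_spectra",
    "read_reference",
    "to_absorbance",
    "average_replicates",
]

#: label columns recognized in wide-CSV spectra files (everything else
#: must be a numeric wavelength header)
LABEL_COLUMNS = ("sample", "cultivar", "treatment", "replicate")


class SpectraFormatError(ValueError):
    """Raised for malformed spectra files (ragged rows, bad headers...)."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Arithmetic wavelength grid in nanometres.

    ``n_points = (stop - start)/step + 1`` and wavelengths are strictly
    increasing. After derivative treatments the start may be fractional
    (window midpoints) but the step is preserved.
    """

    start_nm: float
    stop_nm: float
    step_nm: float

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive")
        n = (self.stop_nm - self.start_nm) / self.step_nm + 1.0
        if abs(n - round(n)) > 1e-6 or round(n) < 1:
            raise ValueError(
                f"grid {self.start_nm}-{self.stop_nm} nm is not an integer "
                f"number of {self.step_nm} nm steps"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    @classmethod
    def default(cls) -> "WavelengthGrid":
        """The 400-2500 nm VIS+NIR grid at 2 nm intervals (1050 points)."""
        return cls(400.0, 2498.0, 2.0)

    @classmethod
    def from_wavelengths(cls, wavelengths: np.ndarray) -> "WavelengthGrid":
        w = np.asarray(wavelengths, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("need at least two wavelengths")
        steps = np.diff(w)
        if np.any(steps <= 0):
            raise SpectraFormatError("wavelengths must be strictly increasing")
        step = float(np.median(steps))
        if not np.allclose(steps, step, rtol=0, atol=1e-6 * max(1.0, step)):
            raise SpectraFormatError("wavelengths are not on an arithmetic grid")
        return cls(float(w[0]), float(w[-1]), step)

    def trimmed(self, n_left: float, n_right: float) -> "WavelengthGrid":
        """Grid after dropping ``n_left``/``n_right`` (possibly half-integer)
        step units from each edge, as derivative windows do."""
        return WavelengthGrid(
            self.start_nm + n_left * self.step_nm,
            self.stop_nm - n_right * self.step_nm,
            self.step_nm,
        )


@dataclass
class SpectralSet:
    """Sample-indexed absorbance matrix on a shared wavelength grid."""

    grid: WavelengthGrid
    absorbance: np.ndarray  # (n_samples, n_points), log10(1/R)
    sample_ids: list[str]
    labels: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        n, p = self.absorbance.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"{n} spectra but {len(self.sample_ids)} sample ids"
            )
        if p != self.grid.n_points:
            raise ValueError(
                f"{p} wavelength columns but grid declares {self.grid.n_points}"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample_ids")
        if not np.all(np.isfinite(self.absorbance)):
            bad = [self.sample_ids[i] for i in
                   np.unique(np.argwhere(~np.isfinite(self.absorbance))[:, 0])]
            raise ValueError(f"non-finite absorbance in samples {bad}")
        if self.labels.empty:
            self.labels = pd.DataFrame(index=pd.Index(self.sample_ids, name="sample_id"))
        else:
            self.labels = self.labels.loc[self.sample_ids]

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    def subset(self, ids: Iterable[str]) -> "SpectralSet":
        ids = list(ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids {missing}")
        rows = [pos[s] for s in ids]
        return SpectralSet(self.grid, self.absorbance[rows], ids,
                           self.labels.iloc[rows].copy())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.absorbance,
                          index=pd.Index(self.sample_ids, name="sample_id"),
                          columns=[f"{w:g}" for w in self.grid.wavelengths])
        return pd.concat([self.labels, df], axis=1)


@dataclass
class ReferenceTable:
    """Per-sample laboratory values for named traits, with units.

    ``values`` is indexed by sample_id with one column per trait; missing
    laboratory determinations are NaN and are excluded trait-wise by the
    calibration pipeline.
    """

    values: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample_ids in reference table")
        self.values.index.name = "sample_id"

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    def trait(self, name: str, ids: Iterable[str] | None = None) -> pd.Series:
        if name not in self.values.columns:
            raise KeyError(f"unknown trait {name!r}")
        s = self.values[name]
        return s if ids is None else s.loc[list(ids)]

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path,
                 units: Mapping[str, str] | None = None) -> "ReferenceTable":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        return cls(df, dict(units or {}))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_spectra(path: str | Path, dialect: str = "wide-csv") -> SpectralSet:
    """Read a spectra file into a :class:`SpectralSet`.

    ``dialect='wide-csv'`` expects one row per spectrum; ``dialect='jcamp'``
    expects a directory of per-spectrum JCAMP-DX-like text files.
    Wavelength columns are re-sorted ascending if needed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "wide-csv":
        return _read_wide_csv(path)
    if dialect == "jcamp":
        return _read_jcamp_dir(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_wide_csv(path: Path) -> SpectralSet:
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 3:
        raise SpectraFormatError(f"{path}: expected sample_id + wavelength columns")
    id_col = df.columns[0]
    label_cols = [c for c in df.columns[1:] if c in LABEL_COLUMNS]
    wl_cols = [c for c in df.columns[1:] if c not in LABEL_COLUMNS]
    try:
        wl = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: non-numeric wavelength header: {exc}")
    order = np.argsort(wl)
    wl = wl[order]
    wl_cols = [wl_cols[i] for i in order]
    grid = WavelengthGrid.from_wavelengths(wl)

    ids = df[id_col].astype(str).tolist()
    raw = df[wl_cols]
    # ragged rows surface as NaN after pandas parsing
    for i, sid in enumerate(ids):
        row = raw.iloc[i]
        if row.isna().any():
            col = row.index[int(np.argmax(row.isna().to_numpy()))]
            raise SpectraFormatError(
                f"{path}: sample {sid!r} is missing a value at {col} nm "
                "(ragged or incomplete row)"
            )
    try:
        mat = raw.to_numpy(dtype=float)
    except ValueError:
        for i, sid in enumerate(ids):
            for c in wl_cols:
                try:
                    float(raw.iloc[i][c])
                except ValueError:
                    raise SpectraFormatError(
                        f"{path}: non-numeric cell at sample {sid!r}, "
                        f"wavelength {c} nm: {raw.iloc[i][c]!r}"
                    )
        raise
    labels = (df.set_index(pd.Index(ids, name="sample_id"))[label_cols]
              if label_cols else pd.DataFrame(index=pd.Index(ids, name="sample_id")))
    return SpectralSet(grid, mat, ids, labels)


def _read_jcamp_dir(path: Path) -> SpectralSet:
    files = sorted(path.glob("*.jdx")) + sorted(path.glob("*.dx"))
    if not files:
        raise SpectraFormatError(f"{path}: no .jdx/.dx files found")
    ids, rows, grid = [], [], None
    for f in files:
        title = f.stem
        pairs = []
        for line in f.read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("##"):
                if line.upper().startswith("##TITLE="):
                    title = line.split("=", 1)[1].strip() or f.stem
                continue
            try:
                x, y = line.replace(";", ",").split(",")[:2]
                pairs.append((float(x), float(y)))
            except ValueError:
                continue  # lossy-tolerant: skip unparsable lines
        if len(pairs) < 2:
            raise SpectraFormatError(f"{f}: no XY data")
        pairs.sort()
        w = np.array([p[0] for p in pairs])
        g = WavelengthGrid.from_wavelengths(w)
        if grid is None:
            grid = g
        elif g != grid:
            raise SpectraFormatError(f"{f}: grid differs from {files[0]}")
        ids.append(title)
        rows.append([p[1] for p in pairs])
    return SpectralSet(grid, np.array(rows), ids)


def write_spectra(spectra: SpectralSet, path: str | Path) -> None:
    """Write the canonical wide-CSV dialect (round-trips with read_spectra)."""
    spectra.to_frame().to_csv(path, float_format="%.10g")


def read_reference(path: str | Path) -> ReferenceTable:
    return ReferenceTable.from_csv(path)


# ---------------------------------------------------------------------------
# Elementary transforms
# ---------------------------------------------------------------------------

def to_absorbance(reflectance: np.ndarray) -> np.ndarray:
    """Convert diffuse reflectance R in (0, 1] to apparent absorbance log10(1/R)."""
    r = np.asarray(reflectance, dtype=float)
    if np.any(r <= 0) or np.any(~np.isfinite(r)):
        raise ValueError("reflectance must be finite and > 0")
    if np.any(r > 1.0 + 1e-12):
        raise ValueError("reflectance must be <= 1")
    return -np.log10(r)


def average_replicates(spectra: SpectralSet, group_by: str = "sample") -> SpectralSet:
    """Average replicate scans into one mean spectrum per group.

    ``group_by`` names a label column (e.g. ``'sample'``); group order is
    stable by first occurrence. Idempotent on already-averaged sets where
    each group has one member.
    """
    if group_by not in spectra.labels.columns:
        raise KeyError(
            f"label column {group_by!r} not present "
            f"(have {list(spectra.labels.columns)})"
        )
    keys = spectra.labels[group_by].astype(str).to_numpy()
    seen: dict[str, int] = {}
    order: list[str] = []
    for k in keys:
        if k not in seen:
            seen[k] = len(order)
            order.append(k)
    rows = np.empty((len(order), spectra.grid.n_points))
    label_rows = []
    for j, k in enumerate(order):
        mask = keys == k
        rows[j] = spectra.absorbance[mask].mean(axis=0)
        first = spectra.labels[mask].iloc[0].drop(labels=["replicate"], errors="ignore")
        label_rows.append(first)
    labels = pd.DataFrame(label_rows, index=pd.Index(order, name="sample_id"))
    return SpectralSet(spectra.grid, rows, order, labels)
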