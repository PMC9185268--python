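"""Representative external-validation set selection.

The selection emulates the CENTER-style protocol used by NIRS calibration
software: samples are ordered by their standardized Mahalanobis (GH)
distance from the population mean in principal-component space, then
roughly one of every k samples along that ordering is set aside for
external validation. Because both subsets follow the same spectral
ordering they have similar trait means and standard deviations.

When k does not divide the sample count the validation picks are spread
evenly over the interior of the ordering with two extra picks so the
validation set reaches both tails; the two endpoint samples (the most
central and the most extreme spectrum) always stay in calibration. For
the 144-sample pod design with k=5 this yields the 30/114
validation/calibration split.
"""

from __future__ import annotations

import numpy as np

from .outliers import fit_pca, gh_distances
from .spectra import SpectralSet

__all__ = ["center_order", "split_every_k"]


def center_order(spectra: SpectralSet, k: int | float = 0.99) -> list[str]:
    """Order sample ids by ascending GH distance from the population mean.

    Ties are broken by sample id, so the ordering is invariant to the
    input row order.
    """
    if spectra.n_samples < 2:
        raise ValueError("need at least 2 samples to order")
    space = fit_pca(spectra, k=k)
    h = gh_distances(space, spectra)
    if not np.all(np.isfinite(h)):
        raise ValueError("degenerate covariance: GH distances not finite")
    pairs = sorted(zip(h, spectra.sample_ids), key=lambda p: (p[0], p[1]))
    return [sid for _, sid in pairs]


def split_every_k(ordered_ids: list[str], k: int = 5) -> tuple[list[str], list[str]]:
    """Split a spectrally ordered id list into calibration and validation.

    Approximately one of every ``k`` ids, at evenly spaced positions over
    the interior of the ordering, goes to validation; the rest form the
    calibration set. If ``k`` divides ``n`` exactly ``n/k`` samples are
    taken; otherwise two additional picks extend the selection to both
    tails. Returns ``(cal_ids, val_ids)``.
    """
    n = len(ordered_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    n_val = n // k if n % k == 0 else n // k + 2
    n_val = min(n_val, n - 2)  # endpoints always stay in calibration
    # evenly spaced interior positions (0-indexed 1 .. n-2)
    pos = np.round(np.linspace(1, n - 2, n_val)).astype(int)
    pos = np.unique(pos)
    val_mask = np.zeros(n, dtype=bool)
    val_mask[pos] = True
    val_ids = [sid for sid, v in zip(ordered_ids, val_mask) if v]
    cal_ids = [sid for sid, v in zip(ordered_ids, val_mask) if not v]
    return cal_ids, val_ids
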