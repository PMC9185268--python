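"""Spectral (GH) and chemical (T) outlier screening.

GH is the standardized Mahalanobis distance of a spectrum from the
population mean, computed in the space of the retained principal
components:

    GH_i = (1/k) * sum_j (score_ij / sd_j)^2

where sd_j is the in-sample standard deviation of the j-th PC score. With
this normalization the in-sample average GH is (n-1)/n, close to 1, and
the conventional H > 3 limit flags spectra far from the population.

T flags chemistry outliers during cross-validation: a sample whose
absolute residual exceeds ``t_limit`` times the current cross-validation
error (SECV). The calibration protocol removes outliers in at most two
elimination passes before the final model is fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .spectra import SpectralSet

__all__ = [
    "PCASubspace",
    "OutlierReport",
    "fit_pca",
    "gh_distances",
    "remove_spectral_outliers",
    "t_outliers",
]


@dataclass
class PCASubspace:
    """Centered principal-component basis of a treated spectra matrix."""

    center: np.ndarray          # (p,)
    loadings: np.ndarray        # (k, p), orthonormal rows
    score_sd: np.ndarray        # (k,), in-sample SD of each score (ddof=1)
    k: int

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.center.size:
            raise ValueError(
                f"spectra have {X.shape[1]} points, PCA space expects "
                f"{self.center.size}"
            )
        return (X - self.center) @ self.loadings.T


@dataclass
class OutlierReport:
    """What an elimination step removed and why."""

    h_values: np.ndarray
    removed_ids: list[str]
    pass_count: int = 1
    t_values: np.ndarray | None = None
    reasons: dict[str, str] = field(default_factory=dict)  # id -> "H" | "T"

    def to_rows(self) -> list[dict]:
        return [
            {"sample_id": sid, "pass": self.pass_count,
             "reason": self.reasons.get(sid, "H")}
            for sid in self.removed_ids
        ]


def fit_pca(spectra: SpectralSet, k: int | float = 0.99) -> PCASubspace:
    """Fit a centered PCA of the (treated) spectra.

    ``k`` is either an explicit component count or a variance fraction in
    (0, 1); components are ordered by decreasing explained variance.
    """
    X = spectra.absorbance
    n = X.shape[0]
    if isinstance(k, float) and 0 < k < 1:
        pca = PCA(n_components=None).fit(X)
        ratio = np.cumsum(pca.explained_variance_ratio_)
        k_eff = int(np.searchsorted(ratio, k) + 1)
    else:
        k_eff = int(k)
        if k_eff >= n:
            raise ValueError(f"k={k_eff} must be < n={n}")
        pca = PCA(n_components=k_eff).fit(X)
    k_eff = min(k_eff, n - 1)
    sd = np.sqrt(pca.explained_variance_[:k_eff])
    keep = sd > 1e-12 * max(sd[0], 1e-300)
    k_eff = int(np.sum(keep)) or 1
    return PCASubspace(
        center=pca.mean_.copy(),
        loadings=pca.components_[:k_eff].copy(),
        score_sd=np.maximum(sd[:k_eff], 1e-300),
        k=k_eff,
    )


def gh_distances(space: PCASubspace, spectra: SpectralSet) -> np.ndarray:
    """Standardized Mahalanobis (GH) distance of each spectrum from the
    population mean in the retained PC space."""
    t = space.scores(spectra.absorbance)
    return np.mean((t / space.score_sd) ** 2, axis=1)


def remove_spectral_outliers(
    spectra: SpectralSet,
    h_limit: float = 3.0,
    space: PCASubspace | None = None,
    k: int | float = 0.99,
    pass_count: int = 1,
) -> tuple[SpectralSet, OutlierReport]:
    """Drop samples whose GH exceeds ``h_limit``.

    A PCA is fitted on the set itself unless ``space`` is supplied;
    refitting between elimination passes is the caller's responsibility.
    """
    if space is None:
        space = fit_pca(spectra, k=k)
    h = gh_distances(space, spectra)
    mask = h <= h_limit
    if not np.any(mask):
        raise ValueError("H limit removed every sample")
    removed = [sid for sid, keep in zip(spectra.sample_ids, mask) if not keep]
    kept = [sid for sid, keep in zip(spectra.sample_ids, mask) if keep]
    report = OutlierReport(
        h_values=h, removed_ids=removed, pass_count=pass_count,
        reasons={sid: "H" for sid in removed},
    )
    return spectra.subset(kept), report


def t_outliers(
    y: np.ndarray,
    yhat: np.ndarray,
    scale: float,
    t_limit: float = 2.5,
) -> np.ndarray:
    """Indices where the standardized residual |y - yhat| / scale exceeds
    ``t_limit``; ``scale`` is the current cross-validation error (SECV)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    if not (scale > 0):
        raise ValueError("scale must be > 0")
    return np.flatnonzero(np.abs(y - yhat) / scale > t_limit)
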